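"""Proxy expansion, gene implication, sentinel classification and
cross-cell-type summaries."""

import pytest

from capv2g import io as cio
from capv2g.contacts import PromoterContact
from capv2g.genome import (
    GeneModel,
    GenomicInterval,
    promoter_window,
)
from capv2g.io import VariantRecord
from capv2g.ocr import OCR, NONPIR_OCR, PIR_OCR, PROMOTER_OCR
from capv2g.v2g import (
    classify_sentinels,
    cross_celltype_summary,
    expand_proxies,
    export_cre_annotation,
    implicate_genes,
    v2g_table,
)


def sentinel(vid, pos, chrom="chr1"):
    return VariantRecord(vid, chrom, pos, "A", "G", role="sentinel")


def proxy(vid, sid, pos, r2, chrom="chr1"):
    return VariantRecord(vid, chrom, pos, "A", "G", role="proxy",
                         sentinel_id=sid, r2=r2)


class TestExpandProxies:
    def test_strict_threshold(self):
        s = [sentinel("rs1", 100)]
        ld = [proxy("p80", "rs1", 200, 0.80), proxy("p81", "rs1", 300, 0.81)]
        out = expand_proxies(s, ld)
        assert {v.variant_id for v in out} == {"rs1", "p81"}

    def test_sentinel_is_its_own_proxy(self):
        out = expand_proxies([sentinel("rs1", 100)], [])
        assert len(out) == 1 and out[0].r2 == 1.0

    def test_unknown_sentinel_rejected(self):
        with pytest.raises(ValueError, match="unknown sentinel"):
            expand_proxies([sentinel("rs1", 100)],
                           [proxy("p1", "rs9", 200, 0.95)])


def ocr(s, e, cls, chrom="chr1"):
    return OCR(GenomicInterval(chrom, s, e), support=2, ocr_class=cls,
               pir_flag=(cls == PIR_OCR))


def contact(gene, oe_start, oe_end, resolution="1frag"):
    return PromoterContact(
        gene_id=gene,
        bait_unit=("chr1", 0),
        oe_unit=("chr1", 1),
        bait_interval=GenomicInterval("chr1", 0, 1000),
        oe_interval=GenomicInterval("chr1", oe_start, oe_end),
        score=7.0,
        resolution=resolution,
        cell_type="EndoC_BH1",
        is_bait_to_bait=False,
    )


class TestImplicateGenes:
    GENES = [
        GeneModel("gG", "G", "chr1", 1500, "+"),
        GeneModel("gH", "H", "chr1", 80_000, "+"),
    ]

    @property
    def promoters(self):
        return [promoter_window(g, 200_000) for g in self.GENES]

    def test_planted_chain_recovered_exactly_once(self):
        proxies = expand_proxies(
            [sentinel("rs1", 50_000)], [proxy("p1", "rs1", 20_100, 0.95)]
        )
        ocrs = [ocr(20_000, 20_400, PIR_OCR)]
        contacts = [contact("gG", 19_900, 20_500)]
        recs = implicate_genes(proxies, ocrs, contacts, self.promoters,
                               cell_type="EndoC_BH1")
        assert len(recs) == 1
        r = recs[0]
        assert (r.sentinel_id, r.gene_id, r.mechanism) == (
            "rs1", "gG", "pir_contact"
        )
        assert r.resolution == "1frag"

    def test_both_routes_fire_for_promoter_ocr(self):
        # proxy in G's promoter OCR, which also contacts H's promoter
        proxies = expand_proxies(
            [sentinel("rs1", 50_000)], [proxy("p1", "rs1", 1000, 0.9)]
        )
        ocrs = [ocr(500, 1400, PROMOTER_OCR)]
        contacts = [contact("gH", 600, 1300)]
        recs = implicate_genes(proxies, ocrs, contacts, self.promoters)
        found = {(r.gene_id, r.mechanism) for r in recs}
        assert found == {("gG", "promoter_overlap"), ("gH", "pir_contact")}

    def test_proxy_in_nonpir_ocr_yields_nothing(self):
        proxies = expand_proxies(
            [sentinel("rs1", 50_000)], [proxy("p1", "rs1", 40_100, 0.9)]
        )
        ocrs = [ocr(40_000, 40_400, NONPIR_OCR)]
        recs = implicate_genes(proxies, ocrs, [], self.promoters)
        assert recs == []

    def test_records_deduplicated_per_mechanism(self):
        proxies = expand_proxies(
            [sentinel("rs1", 50_000)],
            [proxy("p1", "rs1", 20_100, 0.95),
             proxy("p2", "rs1", 20_200, 0.92)],
        )
        ocrs = [ocr(20_000, 20_400, PIR_OCR)]
        contacts = [contact("gG", 19_900, 20_500),
                    contact("gG", 19_900, 20_500, resolution="4frag")]
        recs = implicate_genes(proxies, ocrs, contacts, self.promoters)
        assert len(recs) == 1

    def test_nearest_gene_flag(self):
        proxies = expand_proxies(
            [sentinel("rs1", 2000)], [proxy("p1", "rs1", 20_100, 0.95)]
        )
        ocrs = [ocr(20_000, 20_400, PIR_OCR)]
        contacts = [contact("gG", 19_900, 20_500)]
        recs = implicate_genes(proxies, ocrs, contacts, self.promoters,
                               genes=self.GENES)
        assert recs[0].is_nearest_gene is True

    def test_table_export(self):
        proxies = expand_proxies(
            [sentinel("rs1", 50_000)], [proxy("p1", "rs1", 20_100, 0.95)]
        )
        recs = implicate_genes(
            proxies, [ocr(20_000, 20_400, PIR_OCR)],
            [contact("gG", 19_900, 20_500)], self.promoters,
        )
        df = v2g_table(recs)
        assert df.iloc[0]["gene_id"] == "gG"
        assert df.iloc[0]["mechanism"] == "pir_contact"


class TestClassifySentinels:
    GENES = [
        GeneModel("gNear", "N", "chr1", 1000, "+"),
        GeneModel("gFar", "F", "chr1", 90_000, "+"),
        GeneModel("gOther", "O", "chr1", 95_000, "+"),
    ]

    def record(self, sid, gene):
        from capv2g.v2g import V2GRecord

        return V2GRecord(sid, "p1", 0.9, "EndoC_BH1", "pir_contact",
                         GenomicInterval("chr1", 0, 100), "1frag", gene)

    def classify(self, gene_sets):
        sentinels = [sentinel(f"rs{i}", 900) for i in range(len(gene_sets))]
        records = [
            self.record(f"rs{i}", g)
            for i, gene_set in enumerate(gene_sets)
            for g in gene_set
        ]
        return classify_sentinels(records, self.GENES, sentinels)

    def test_three_categories(self):
        out = self.classify([
            {"gNear"},
            {"gNear", "gFar"},
            {"gFar", "gOther"},
        ])
        categories = {c.sentinel_id: c.category for c in out}
        assert categories == {
            "rs0": "nearest_only",
            "rs1": "multiple_including_nearest",
            "rs2": "not_nearest",
        }

    def test_categories_partition(self):
        out = self.classify([{"gNear"}, {"gFar"}, {"gNear", "gOther"}])
        assert len(out) == 3
        assert len({(c.sentinel_id, c.cell_type) for c in out}) == 3


class TestCrossCellSummary:
    def test_counts_and_percentages(self):
        genes = {
            "A": {"g1", "g2", "g5"},
            "B": {"g3", "g5"},
            "C": {"g4", "g5"},
        }
        s = cross_celltype_summary(genes)
        assert s.union_size == 5
        assert s.exclusive_counts == {"A": 2, "B": 1, "C": 1}
        assert s.n_single == 4 and s.n_shared_two_plus == 1
        assert s.n_shared_all == 1
        assert s.pct_single + s.pct_shared_two_plus == pytest.approx(
            100.0, abs=0.1
        )

    def test_requires_two_cell_types(self):
        with pytest.raises(ValueError):
            cross_celltype_summary({"A": {"g1"}})


class TestCreExport:
    def test_merged_export_and_round_trip(self, tmp_path):
        ocrs = [ocr(0, 100, PROMOTER_OCR), ocr(50, 200, PIR_OCR),
                ocr(500, 600, NONPIR_OCR)]
        path = tmp_path / "cre.bed"
        cre = export_cre_annotation(ocrs, path)
        assert list(cre) == [("chr1", 0, 200)]
        back = cio.read_regions(path)
        assert back[["chrom", "start", "end"]].values.tolist() == [
            ["chr1", 0, 200]
        ]

    def test_only_nonpir_gives_empty_file_with_header(self, tmp_path):
        path = tmp_path / "cre.bed"
        cre = export_cre_annotation([ocr(0, 100, NONPIR_OCR)], path)
        assert not cre
        text = path.read_text()
        assert text.startswith("#")
        assert len(cio.read_regions(path)) == 0
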