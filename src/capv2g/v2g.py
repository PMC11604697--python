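"""Variant-to-gene (V2G) mapping.

The core procedure: expand GWAS sentinels to their high-LD proxies
(r2 strictly > 0.8), keep the proxies that land in open chromatin, and
implicate genes by two routes — the proxy's OCR overlaps a gene's
promoter window (``promoter_overlap``), or it overlaps the other end of
a significant promoter contact (``pir_contact``).  Sentinels are then
classified by whether the implicated genes include the gene nearest to
the sentinel, and gene lists are summarised across cell types
upset-style.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contacts import PromoterContact
from .genome import GeneModel, GenomicInterval, PromoterWindow, nearest_gene
from .intervals import IntervalSet
from .io import VariantRecord, write_bed
from .ocr import OCR, PIR_OCR, PROMOTER_OCR

__all__ = [
    "V2GRecord",
    "SentinelClassification",
    "CrossCellSummary",
    "expand_proxies",
    "implicate_genes",
    "classify_sentinels",
    "cross_celltype_summary",
    "export_cre_annotation",
    "v2g_table",
]

DEFAULT_R2_THRESHOLD = 0.8


@dataclass(frozen=True, slots=True)
class V2GRecord:
    """One sentinel -> proxy -> OCR -> gene implication chain."""

    sentinel_id: str
    proxy_id: str
    r2: float
    cell_type: str
    mechanism: str            # {"promoter_overlap", "pir_contact"}
    ocr_interval: GenomicInterval
    resolution: str | None    # contact resolution, None for promoter_overlap
    gene_id: str
    is_nearest_gene: bool | None = None


def expand_proxies(
    sentinels: Sequence[VariantRecord],
    ld_table: Sequence[VariantRecord],
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> list[VariantRecord]:
    """Sentinels plus their proxies with r2 strictly above the threshold.

    Every sentinel is included as its own proxy (r2 = 1); a proxy
    referencing an unknown sentinel raises.
    """
    known = {s.variant_id for s in sentinels}
    out: list[VariantRecord] = list(sentinels)
    for proxy in ld_table:
        if proxy.role == "sentinel":
            continue
        if proxy.sentinel_id not in known:
            raise ValueError(
                f"proxy {proxy.variant_id} references unknown sentinel "
                f"{proxy.sentinel_id}"
            )
        if proxy.r2 > r2_threshold:
            out.append(proxy)
    return out


def implicate_genes(
    proxies: Sequence[VariantRecord],
    ocrs: Sequence[OCR],
    contacts: Sequence[PromoterContact],
    promoters: Sequence[PromoterWindow],
    cell_type: str = ".",
    genes: Sequence[GeneModel] | None = None,
) -> list[V2GRecord]:
    """Implicate effector genes for proxies lying in open chromatin.

    For each proxy inside an OCR: (a) every gene whose promoter window
    overlaps the OCR is implicated via ``promoter_overlap``; (b) every
    contact whose other end overlaps the OCR implicates its bait gene
    via ``pir_contact`` (with the contact's resolution).  Records are
    deduplicated per (sentinel, gene, cell type, mechanism); proxies
    outside every OCR yield nothing.
    """
    # sort OCRs per chromosome for point queries
    by_chrom: dict[str, list[OCR]] = {}
    for o in ocrs:
        by_chrom.setdefault(o.interval.chrom, []).append(o)
    for lst in by_chrom.values():
        lst.sort(key=lambda o: o.interval.start)

    seen: dict[tuple[str, str, str, str], V2GRecord] = {}
    sentinel_pos: dict[str, tuple[str, int]] = {}
    for p in proxies:
        if p.role == "sentinel":
            sentinel_pos[p.variant_id] = (p.chrom, p.pos0)

    for proxy in proxies:
        hits = [
            o
            for o in by_chrom.get(proxy.chrom, [])
            if o.interval.start <= proxy.pos0 < o.interval.end
        ]
        for ocr in hits:
            iv = ocr.interval
            # route (a): OCR overlaps a promoter window
            for win in promoters:
                if win.interval.overlaps(iv):
                    _add_record(
                        seen, proxy, ocr, win.gene_id, "promoter_overlap",
                        None, cell_type,
                    )
            # route (b): OCR overlaps a contact's other end
            for contact in contacts:
                if contact.oe_interval.overlaps(iv):
                    _add_record(
                        seen, proxy, ocr, contact.gene_id, "pir_contact",
                        contact.resolution, cell_type,
                    )

    records = list(seen.values())
    if genes is not None:
        records = [
            _with_nearest(rec, sentinel_pos, genes) for rec in records
        ]
    return records


def _add_record(seen, proxy, ocr, gene_id, mechanism, resolution, cell_type):
    sentinel = proxy.sentinel_id or proxy.variant_id
    key = (sentinel, gene_id, cell_type, mechanism)
    if key not in seen:
        seen[key] = V2GRecord(
            sentinel_id=sentinel,
            proxy_id=proxy.variant_id,
            r2=proxy.r2,
            cell_type=cell_type,
            mechanism=mechanism,
            ocr_interval=ocr.interval,
            resolution=resolution,
            gene_id=gene_id,
        )


def _with_nearest(rec: V2GRecord, sentinel_pos, genes) -> V2GRecord:
    loc = sentinel_pos.get(rec.sentinel_id)
    if loc is None:
        return rec
    try:
        nearest = nearest_gene(loc[0], loc[1], genes)
    except LookupError:
        return rec
    return V2GRecord(
        rec.sentinel_id, rec.proxy_id, rec.r2, rec.cell_type, rec.mechanism,
        rec.ocr_interval, rec.resolution, rec.gene_id,
        is_nearest_gene=(rec.gene_id == nearest),
    )


@dataclass(frozen=True)
class SentinelClassification:
    sentinel_id: str
    cell_type: str
    category: str  # {"nearest_only", "multiple_including_nearest", "not_nearest"}
    implicated_genes: tuple[str, ...]
    nearest_gene_id: str


def classify_sentinels(
    v2g: Sequence[V2GRecord],
    genes: Sequence[GeneModel],
    sentinels: Sequence[VariantRecord],
) -> list[SentinelClassification]:
    """Classify each (sentinel, cell type) by nearest-gene membership.

    ``nearest_only`` when the implicated set is exactly the nearest
    gene; ``multiple_including_nearest`` when it is larger but contains
    it; ``not_nearest`` otherwise.  Sentinels with no implications do
    not appear in ``v2g`` and are therefore excluded.
    """
    pos = {s.variant_id: (s.chrom, s.pos0) for s in sentinels}
    implicated: dict[tuple[str, str], set[str]] = {}
    for rec in v2g:
        implicated.setdefault((rec.sentinel_id, rec.cell_type), set()).add(
            rec.gene_id
        )
    out: list[SentinelClassification] = []
    for (sentinel, cell_type), gene_set in sorted(implicated.items()):
        if sentinel not in pos:
            raise ValueError(f"sentinel {sentinel} has no position record")
        chrom, p = pos[sentinel]
        nearest = nearest_gene(chrom, p, genes)
        if gene_set == {nearest}:
            category = "nearest_only"
        elif nearest in gene_set:
            category = "multiple_including_nearest"
        else:
            category = "not_nearest"
        out.append(
            SentinelClassification(
                sentinel, cell_type, category, tuple(sorted(gene_set)), nearest
            )
        )
    return out


def _pct(numerator: int, denominator: int) -> float:
    value = 100.0 * numerator / denominator
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass
class CrossCellSummary:
    """Upset-style sharing of implicated genes across cell types."""

    membership: dict[str, frozenset[str]]   # gene -> cell types
    union_size: int
    exclusive_counts: dict[str, int]        # per cell type, genes only there
    n_single: int
    n_shared_two_plus: int
    n_shared_all: int
    pct_single: float
    pct_shared_two_plus: float
    pct_shared_all: float


def cross_celltype_summary(
    genes_by_cell_type: Mapping[str, Iterable[str]],
) -> CrossCellSummary:
    """Summarise how implicated genes are shared across cell types.

    Percentages are of the union of implicated genes, rounded half-up
    to one decimal; the single / shared strata sum to the union.
    """
    cell_types = list(genes_by_cell_type)
    if len(cell_types) < 2:
        raise ValueError("need at least two cell types")
    membership: dict[str, set[str]] = {}
    for ct, gene_list in genes_by_cell_type.items():
        for g in gene_list:
            membership.setdefault(g, set()).add(ct)
    union = len(membership)
    if union == 0:
        raise ValueError("no implicated genes in any cell type")
    n_single = sum(1 for cts in membership.values() if len(cts) == 1)
    n_two_plus = union - n_single
    n_all = sum(1 for cts in membership.values() if len(cts) == len(cell_types))
    exclusive = {
        ct: sum(1 for cts in membership.values() if cts == {ct})
        for ct in cell_types
    }
    return CrossCellSummary(
        membership={g: frozenset(cts) for g, cts in membership.items()},
        union_size=union,
        exclusive_counts=exclusive,
        n_single=n_single,
        n_shared_two_plus=n_two_plus,
        n_shared_all=n_all,
        pct_single=_pct(n_single, union),
        pct_shared_two_plus=_pct(n_two_plus, union),
        pct_shared_all=_pct(n_all, union),
    )


def export_cre_annotation(ocrs: Sequence[OCR], path) -> IntervalSet:
    """Write the putative cRE set (promoter OCRs + PIR-OCRs) as a merged
    sorted BED; suitable as annotation input for partitioned-heritability
    tooling.  Returns the merged set."""
    cre = IntervalSet.from_intervals(
        o.interval for o in ocrs if o.ocr_class in (PROMOTER_OCR, PIR_OCR)
    )
    write_bed(
        list(cre),
        path,
        header_comment="cRE annotation: merged promoter OCRs + PIR-OCRs"
        if not cre
        else None,
    )
    return cre


def v2g_table(records: Sequence[V2GRecord]) -> pd.DataFrame:
    """Flatten V2G records to a DataFrame (one row per record)."""
    rows = [
        {
            "sentinel_id": r.sentinel_id,
            "proxy_id": r.proxy_id,
            "r2": r.r2,
            "cell_type": r.cell_type,
            "mechanism": r.mechanism,
            "ocr_chrom": r.ocr_interval.chrom,
            "ocr_start": r.ocr_interval.start,
            "ocr_end": r.ocr_interval.end,
            "resolution": r.resolution if r.resolution else ".",
            "gene_id": r.gene_id,
            "is_nearest_gene": r.is_nearest_gene,
        }
        for r in records
    ]
    columns = [
        "sentinel_id", "proxy_id", "r2", "cell_type", "mechanism",
        "ocr_chrom", "ocr_start", "ocr_end", "resolution", "gene_id",
        "is_nearest_gene",
    ]
    return pd.DataFrame(rows, columns=columns)
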