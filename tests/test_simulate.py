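"""Synthetic bundle generation: determinism, feasibility, audit replay
and distributional targets."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest

from capv2g.contacts import contact_distance_stats, filter_contacts
from capv2g.simulate import (
    SimConfig,
    analyze_cell_type,
    audit_truth,
    generate_bundle,
    load_bundle,
    pipeline_connected_genes,
    write_bundle,
)


def tree_digest(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(str(f.relative_to(path)).encode())
            h.update(f.read_bytes())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundle(self, tmp_path):
        cfg = SimConfig(seed=5)
        a = write_bundle(generate_bundle(cfg), tmp_path / "a")
        b = write_bundle(generate_bundle(SimConfig(seed=5)), tmp_path / "b")
        assert tree_digest(a) == tree_digest(b)

    def test_different_seed_differs(self, tmp_path):
        a = write_bundle(generate_bundle(SimConfig(seed=5)), tmp_path / "a")
        b = write_bundle(generate_bundle(SimConfig(seed=6)), tmp_path / "b")
        assert tree_digest(a) != tree_digest(b)


class TestFeasibility:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"n_planted_chains": 50, "n_sentinels": 10},
            {"n_planted_chains": 100, "n_connected_genes": 100, "n_genes": 120},
            {"replicate_dropout": 1.5},
            {"chain_celltype_probs": (0.5, 0.5)},
            {"n_contacts": 10},
            {"n_genes": 2000},
            {"chromhmm_state_fractions": {"a": 0.5, "b": 0.2}},
        ],
    )
    def test_infeasible_config_rejected_before_writing(self, overrides):
        with pytest.raises(ValueError):
            generate_bundle(SimConfig(seed=0, **overrides))


class TestBundleContent:
    def test_round_trip_through_files(self, tmp_path, default_bundle):
        out = write_bundle(default_bundle, tmp_path / "bundle")
        back = load_bundle(out)
        assert back.sequences == default_bundle.sequences
        assert back.genes == default_bundle.genes
        assert back.variants == default_bundle.variants
        assert [c.chain_id for c in back.truth.chains] == [
            c.chain_id for c in default_bundle.truth.chains
        ]
        for ct in default_bundle.config.cell_types:
            a = default_bundle.cell_data[ct].contacts
            b = back.cell_data[ct].contacts
            assert len(a) == len(b)
            assert np.allclose(a["score"], b["score"])

    def test_subthreshold_contacts_present_and_filtered(self, default_bundle):
        ct = default_bundle.config.cell_types[0]
        table = default_bundle.cell_data[ct].contacts
        kept = filter_contacts(table)
        assert len(kept) < len(table)
        assert (table["score"] < 5).any()

    def test_gatc_density_matches_mean_fragment_length(self, default_bundle):
        from capv2g.genome import digest_sequence

        cfg = default_bundle.config
        for chrom, seq in default_bundle.sequences.items():
            frags = digest_sequence(seq, chrom)
            mean = len(seq) / len(frags)
            assert mean == pytest.approx(cfg.mean_fragment_length, rel=0.25)

    def test_expression_nonnegative(self, default_bundle):
        assert (default_bundle.expression.values >= 0).all()


class TestAudit:
    def test_fresh_bundle_passes(self, default_bundle):
        report = audit_truth(default_bundle)
        assert report.ok, report.failures
        assert report.n_chains_checked >= default_bundle.config.n_planted_chains

    def test_empty_truth_trivially_passes(self, default_bundle):
        from capv2g.simulate import TruthTable

        empty = TruthTable(chains=[], motif_planted={}, connected_genes={},
                           shifted_genes={})
        assert audit_truth(default_bundle, empty).ok

    def test_tampered_bundle_reports_failures(self, default_bundle):
        import copy

        tampered = copy.deepcopy(default_bundle)
        # destroy the open-chromatin evidence in one cell type
        victims = [
            ct for ct in tampered.config.cell_types
            if any(ct in c.cell_types for c in tampered.truth.chains)
        ]
        ct = victims[0]
        tampered.cell_data[ct].replicate_peaks = [
            [] for _ in range(tampered.config.n_replicates)
        ]
        report = audit_truth(tampered)
        assert not report.ok
        assert any(ct in f for f in report.failures)


class TestStudyGeometry:
    def test_connected_genes_truth_matches_pipeline(self, default_bundle):
        for ct in default_bundle.config.cell_types:
            assert pipeline_connected_genes(default_bundle, ct) == set(
                default_bundle.truth.connected_genes[ct]
            )

    def test_bait_to_bait_share_in_study_range(self, default_bundle):
        ct = default_bundle.config.cell_types[0]
        analysis = analyze_cell_type(default_bundle, ct)
        recs = analysis["annotated_1frag"]
        # each b2b contact yields two records
        n_contacts = len([r for r in recs if not r.is_bait_to_bait]) + \
            len([r for r in recs if r.is_bait_to_bait]) // 2
        frac = (len([r for r in recs if r.is_bait_to_bait]) // 2) / n_contacts
        assert 0.05 < frac < 0.35

    def test_contact_distance_mean_matches_lognormal_target(self):
        cfg = SimConfig(
            seed=101,
            chrom_lengths={"chr1": 6_000_000},
            n_genes=200,
            cell_types=("EndoC_BH1",),
            chain_celltype_probs=(1.0,),
            n_planted_chains=0,
            n_connected_genes=0,
            n_sentinels=5,
            n_consensus_peaks=40,
            promoter_peak_fraction=0.5,
            n_contacts=5000,
            frac_bait_to_bait=0.0,
            frac_subthreshold_contacts=0.0,
        )
        bundle = generate_bundle(cfg)
        table = bundle.cell_data["EndoC_BH1"].contacts
        stats = contact_distance_stats(table[table["resolution"] == "1frag"])
        assert stats.n_cis == 5000
        assert stats.mean == pytest.approx(
            cfg.contact_distance_mean_bp, rel=0.10
        )

    def test_config_serialisable(self, default_bundle):
        # manifest round trip keeps every config field
        d = dataclasses.asdict(default_bundle.config)
        rebuilt = SimConfig(**{
            **d,
            "cell_types": tuple(d["cell_types"]),
            "chain_celltype_probs": tuple(d["chain_celltype_probs"]),
        })
        assert rebuilt == default_bundle.config
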