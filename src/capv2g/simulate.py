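"""Seeded synthetic-data generator with planted ground truth.

Emulates the processed forms of a promoter Capture-C / ATAC-seq /
RNA-seq study at desk scale: a small multi-chromosome genome with GATC
sites placed at a configurable density (so in-silico digestion is
exercised end to end), gene models, per-replicate ATAC peak sets with
jitter and dropout, ibed contact tables at 1-fragment and 4-fragment
resolution with a configurable fraction of sub-threshold scores,
sentinel/proxy variant tables, TPM expression shifted upward for
promoter-connected genes, a ChromHMM-style segmentation and a small set
of synthetic JASPAR count matrices.

Planted variant -> OCR -> contact -> gene chains are kept in reserved
genomic zones and all background elements are rejection-sampled away
from them, so that on a freshly generated bundle the variant-to-gene
procedure recovers exactly the planted (sentinel, gene) pairs and the
motif scanner flags exactly the planted disrupting proxies.  The
``TruthTable`` records what was planted; :func:`audit_truth` replays
every chain through the real pipeline operations.

Background sequence is drawn from the {A, C, T} alphabet with GATC
written at cut sites, so guanine appears only inside cut-site motifs.
The synthetic motif consensi each require guanines, on both strands,
that neither a GATC context nor a single substituted allele can supply;
a full-score motif window therefore cannot arise away from a planted
site, which makes exact motif recovery a structural property rather
than a statistical one.

All randomness flows from a single integer seed: the same config yields
a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .contacts import (
    annotate_baits,
    derive_pirs,
    filter_contacts,
    genes_contacting,
)
from .genome import (
    GeneModel,
    GenomicInterval,
    PromoterWindow,
    UnitMap,
    bin_fragments,
    digest_sequence,
    promoter_window,
)
from .intervals import IntervalSet
from .io import PWMRecord, VariantRecord
from .motifs import scan_variants
from .ocr import OCR, PIR_OCR, classify_ocrs, consensus_ocrs
from .v2g import V2GRecord, expand_proxies, implicate_genes

__all__ = [
    "SimConfig",
    "TruthChain",
    "TruthTable",
    "Bundle",
    "AuditReport",
    "generate_bundle",
    "write_bundle",
    "load_bundle",
    "audit_truth",
    "analyze_cell_type",
    "recovery_metrics",
    "motif_recovery_metrics",
    "pipeline_connected_genes",
]

# Synthetic count matrices (consensus base 97, others 1).  Consensi avoid
# the GATC recognition site and are chosen so that no single-base
# substitution of valid background sequence (on either strand) can
# complete a full-score window: background guanines only occur as GATC
# cut sites, and each consensus keeps at least two G requirements per
# strand that a lone variant allele cannot satisfy.
BASE_PWMS: list[tuple[str, str, str]] = [
    ("MA9001.1", "KLF_SYN", "GGCACTGGC"),
    ("MA9002.1", "GLI_SYN", "GGTGTGGCC"),
    ("MA9003.1", "SP1_SYN", "CCGTGTGCC"),
    ("MA9004.1", "HNF1_SYN", "GGCTTACCG"),
]

MIN_SCORE = 5.0  # significance threshold for called contacts

# clearances (bp) used when placing planted and background elements
_CHAIN_WINDOW_CLEARANCE = 5500
_CHAIN_ZONE_PAD = 5000
_LANDING_WINDOW_PAD = 150
_VARIANT_PAD = 150
_PEAK_WINDOW_PAD = 1300
_BIN_PAD = 200


def _default_chroms() -> dict[str, int]:
    return {"chr1": 1_200_000, "chr2": 800_000}


def _default_states() -> dict[str, float]:
    return {
        "1_TssA": 0.04,
        "2_TssFlnk": 0.04,
        "7_Enh": 0.10,
        "10_TxWk": 0.20,
        "15_Quies": 0.62,
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle.

    Defaults mirror the design of the emulated study at desk scale:
    four cell lines assayed in triplicate, DpnII-density fragments
    (~400 bp), a log-normal contact-distance distribution with a
    ~130 kb mean, a 10-30%-range bait-to-bait share, strict r2 > 0.8
    proxy expansion inputs and a one-log2-unit expression shift for
    promoter-connected genes.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    mean_fragment_length: int = 400
    min_fragment_length: int = 50
    max_fragment_length: int = 1200
    n_genes: int = 120
    min_tss_spacing: int = 8000
    cell_types: tuple[str, ...] = (
        "EndoC_BH1", "HepG2", "SGBS_diff", "SGBS_undiff",
    )
    n_replicates: int = 3
    n_consensus_peaks: int = 250
    promoter_peak_fraction: float = 0.3
    peak_width_mean: int = 500
    peak_width_sd: int = 100
    peak_jitter_bp: int = 25
    replicate_dropout: float = 0.15
    n_contacts: int = 300
    frac_subthreshold_contacts: float = 0.3
    contact_distance_mean_bp: float = 130_000.0
    contact_distance_sigma: float = 0.8
    frac_bait_to_bait: float = 0.15
    n_connected_genes: int = 40
    n_sentinels: int = 30
    proxies_per_sentinel_mean: float = 4.0
    r2_min: float = 0.5
    n_planted_chains: int = 12
    frac_promoter_overlap_chains: float = 0.25
    chain_celltype_probs: tuple[float, ...] = (0.60, 0.25, 0.10, 0.05)
    expression_log2_shift: float = 1.0
    expression_log2_mean: float = 2.5
    expression_log2_sd: float = 1.25
    chromhmm_state_fractions: dict[str, float] = field(
        default_factory=_default_states
    )
    chromhmm_segment_mean_bp: int = 2000
    planted_motif_fraction: float = 0.5

    def validate(self) -> None:
        probs = [
            self.promoter_peak_fraction, self.replicate_dropout,
            self.frac_subthreshold_contacts, self.frac_bait_to_bait,
            self.frac_promoter_overlap_chains, self.planted_motif_fraction,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all fractions must lie in [0, 1]")
        counts = [
            self.n_genes, self.n_consensus_peaks, self.n_contacts,
            self.n_connected_genes, self.n_sentinels, self.n_planted_chains,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not (0 < self.min_fragment_length
                <= self.mean_fragment_length
                <= self.max_fragment_length):
            raise ValueError("fragment length parameters are inconsistent")
        if len(self.chain_celltype_probs) != len(self.cell_types):
            raise ValueError(
                "chain_celltype_probs needs one entry per cell type"
            )
        if not math.isclose(sum(self.chain_celltype_probs), 1.0, abs_tol=1e-6):
            raise ValueError("chain_celltype_probs must sum to 1")
        if self.n_planted_chains > self.n_sentinels:
            raise ValueError("more planted chains than sentinels")
        if self.n_planted_chains + self.n_connected_genes > self.n_genes:
            raise ValueError("more planted chains + connected genes than genes")
        n_b2b = round(self.frac_bait_to_bait * self.n_contacts)
        if (self.n_planted_chains + self.n_connected_genes + n_b2b
                > self.n_contacts):
            raise ValueError("more planted contacts than the contact budget")
        frac = abs(sum(self.chromhmm_state_fractions.values()) - 1.0)
        if frac > 1e-6:
            raise ValueError("chromhmm state fractions must sum to 1")
        alloc = _gene_allocation(self)
        for chrom, n_chrom in alloc.items():
            if n_chrom < 1:
                continue
            slot = self.chrom_lengths[chrom] // n_chrom
            if slot < self.min_tss_spacing + 400:
                raise ValueError(
                    f"{chrom}: too many genes for min_tss_spacing="
                    f"{self.min_tss_spacing}"
                )
        n_prom = round(self.promoter_peak_fraction * self.n_consensus_peaks)
        if (n_prom + self.n_connected_genes + self.n_planted_chains
                > self.n_consensus_peaks):
            raise ValueError("peak budget too small for planted elements")


def _gene_allocation(config: SimConfig) -> dict[str, int]:
    total = sum(config.chrom_lengths.values())
    raw = {
        c: config.n_genes * length / total
        for c, length in config.chrom_lengths.items()
    }
    alloc = {c: int(v) for c, v in raw.items()}
    remainder = config.n_genes - sum(alloc.values())
    for c in sorted(raw, key=lambda c: raw[c] - alloc[c], reverse=True):
        if remainder <= 0:
            break
        alloc[c] += 1
        remainder -= 1
    return alloc


@dataclass(frozen=True)
class TruthChain:
    chain_id: int
    sentinel_id: str
    proxy_id: str
    gene_id: str
    mechanism: str
    cell_types: tuple[str, ...]
    ocr: tuple[str, int, int]


@dataclass
class TruthTable:
    chains: list[TruthChain]
    motif_planted: dict[str, str]           # proxy_id -> matrix_id
    connected_genes: dict[str, list[str]]   # cell type -> shifted genes
    shifted_genes: dict[str, list[str]]     # alias of connected (delta applied)

    def planted_pairs(self, cell_type: str) -> set[tuple[str, str, str]]:
        return {
            (c.sentinel_id, c.gene_id, c.mechanism)
            for c in self.chains
            if cell_type in c.cell_types
        }


@dataclass
class CellTypeData:
    replicate_peaks: list[list[GenomicInterval]]
    contacts: pd.DataFrame


@dataclass
class Bundle:
    config: SimConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    variants: list[VariantRecord]
    pwms: list[PWMRecord]
    chromhmm: pd.DataFrame
    expression: pd.DataFrame
    cell_data: dict[str, CellTypeData]
    truth: TruthTable


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_cuts(rng, length: int, config: SimConfig) -> np.ndarray:
    gaps = []
    pos = 0
    lo, hi = config.min_fragment_length, config.max_fragment_length
    mean = config.mean_fragment_length
    while True:
        gap = int(np.clip(rng.exponential(mean), lo, hi))
        pos += gap
        if pos >= length - 8:
            break
        gaps.append(pos)
    return np.asarray(gaps, dtype=np.int64)


def _build_sequences(rng, config: SimConfig) -> dict[str, np.ndarray]:
    seqs = {}
    filler = np.frombuffer(b"ACT", dtype=np.uint8)
    motif = np.frombuffer(b"GATC", dtype=np.uint8)
    for chrom, length in config.chrom_lengths.items():
        arr = rng.choice(filler, size=length)
        for cut in _sample_cuts(rng, length, config):
            arr[cut : cut + 4] = motif
        seqs[chrom] = arr
    return seqs


def _place_genes(rng, config: SimConfig) -> list[GeneModel]:
    genes: list[GeneModel] = []
    margin = config.min_tss_spacing // 2
    gid = 1
    for chrom, n_chrom in _gene_allocation(config).items():
        length = config.chrom_lengths[chrom]
        if n_chrom < 1:
            continue
        slot = length // n_chrom
        for i in range(n_chrom):
            lo = i * slot + margin
            hi = (i + 1) * slot - margin
            tss = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"G{gid:04d}", f"GENE{gid}", chrom, tss, strand)
            )
            gid += 1
    return genes


def _min_gap_to_set(iset: IntervalSet, chrom: str, start: int, end: int,
                    pad: int) -> bool:
    """True when [start, end) padded by ``pad`` avoids ``iset``."""
    return not iset.overlaps(chrom, max(0, start - pad), end + pad)


class _FragmentIndex:
    def __init__(self, fragments_by_chrom):
        self.fragments = fragments_by_chrom
        self.starts = {
            c: np.array([f.interval.start for f in frags], dtype=np.int64)
            for c, frags in fragments_by_chrom.items()
        }

    def index_at(self, chrom: str, pos: int) -> int:
        return int(np.searchsorted(self.starts[chrom], pos, side="right") - 1)

    def interval(self, chrom: str, idx: int) -> GenomicInterval:
        return self.fragments[chrom][idx].interval

    def bin_interval(self, chrom: str, idx: int, k: int = 4) -> GenomicInterval:
        frags = self.fragments[chrom]
        b = idx // k
        members = frags[b * k : (b + 1) * k]
        return GenomicInterval(
            chrom, members[0].interval.start, members[-1].interval.end
        )


def generate_bundle(config: SimConfig) -> Bundle:
    """Generate a complete, internally consistent input bundle.

    Raises on infeasible configurations before any work is done; the
    same config (including seed) always yields an identical bundle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_lengths = dict(config.chrom_lengths)

    seq_arrays = _build_sequences(rng, config)
    genes = _place_genes(rng, config)
    genes_by_id = {g.gene_id: g for g in genes}
    promoters = [
        promoter_window(g, chrom_lengths[g.chrom]) for g in genes
    ]
    windows_by_gene = {w.gene_id: w for w in promoters}
    window_set = IntervalSet.from_intervals(w.interval for w in promoters)

    # ---- planted chains -------------------------------------------------
    n_chains = config.n_planted_chains
    picked = rng.choice(len(genes), size=n_chains + config.n_connected_genes,
                        replace=False)
    chain_genes = [genes[i] for i in picked[:n_chains]]
    connected_genes = [genes[i] for i in picked[n_chains:]]

    n_pov = round(config.frac_promoter_overlap_chains * n_chains)
    mech_order = rng.permutation(n_chains)
    mechanisms = [
        "promoter_overlap" if rank < n_pov else "pir_contact"
        for rank in np.argsort(mech_order, kind="stable")
    ]
    # cell-type membership per chain
    n_ct = len(config.cell_types)
    chain_cts: list[tuple[str, ...]] = []
    for _ in range(n_chains):
        k = int(rng.choice(np.arange(1, n_ct + 1),
                           p=np.asarray(config.chain_celltype_probs)))
        members = rng.choice(n_ct, size=k, replace=False)
        chain_cts.append(
            tuple(ct for i, ct in enumerate(config.cell_types) if i in members)
        )

    mu = math.log(config.contact_distance_mean_bp) - \
        config.contact_distance_sigma**2 / 2

    def sample_distance() -> int:
        return int(rng.lognormal(mu, config.contact_distance_sigma))

    chain_zones_list: list[tuple[str, int, int]] = []
    chain_specs = []  # dicts describing each chain
    for idx, (gene, mech) in enumerate(zip(chain_genes, mechanisms)):
        win = windows_by_gene[gene.gene_id]
        chrom_len = chrom_lengths[gene.chrom]
        if mech == "promoter_overlap":
            center = (win.interval.start + win.interval.end) // 2
            width = 400
            ocr = (gene.chrom, center - width // 2, center + width // 2)
            zone = (gene.chrom, win.interval.start, win.interval.end)
        else:
            zone_set = IntervalSet.from_tuples(chain_zones_list)
            ocr = None
            for _ in range(2000):
                d = sample_distance()
                if d < 20_000:
                    continue
                sign = -1 if rng.random() < 0.5 else 1
                center = gene.tss + sign * d
                width = int(rng.integers(400, 701))
                s, e = center - width // 2, center + width // 2
                if s < 1000 or e > chrom_len - 1000:
                    continue
                if window_set.overlaps(
                    gene.chrom, s - _CHAIN_WINDOW_CLEARANCE,
                    e + _CHAIN_WINDOW_CLEARANCE,
                ):
                    continue
                if not _min_gap_to_set(zone_set, gene.chrom, s, e,
                                       2 * _CHAIN_ZONE_PAD):
                    continue
                ocr = (gene.chrom, s, e)
                break
            if ocr is None:
                raise RuntimeError(
                    f"could not place chain {idx} for {gene.gene_id}; "
                    "config too dense"
                )
            zone = ocr
        chain_zones_list.append(zone)
        proxy_pos = (ocr[1] + ocr[2]) // 2
        chain_specs.append(
            {
                "chain_id": idx,
                "gene": gene,
                "mechanism": mech,
                "cell_types": chain_cts[idx],
                "ocr": ocr,
                "proxy_pos": proxy_pos,
            }
        )
    chain_zones = IntervalSet.from_tuples(chain_zones_list) \
        if chain_zones_list else IntervalSet()

    # ---- planted motifs -------------------------------------------------
    pwms = [
        PWMRecord(mid, name, np.where(
            np.array([[b == c for c in consensus] for b in "ACGT"]),
            97.0, 1.0,
        ))
        for mid, name, consensus in BASE_PWMS
    ]
    motif_planted: dict[str, str] = {}
    n_motif = round(config.planted_motif_fraction * n_chains)
    motif_chain_ids = set(
        int(i) for i in rng.choice(n_chains, size=n_motif, replace=False)
    ) if n_chains else set()
    base_codes = {b: ord(b) for b in "ACGT"}
    for spec in chain_specs:
        if spec["chain_id"] not in motif_chain_ids:
            continue
        pwm = pwms[spec["chain_id"] % len(pwms)]
        consensus = pwm.consensus
        L = len(consensus)
        start = spec["proxy_pos"] - L // 2
        arr = seq_arrays[spec["ocr"][0]]
        arr[start : start + L] = np.frombuffer(
            consensus.encode(), dtype=np.uint8
        )
        spec["motif"] = pwm
        col = spec["proxy_pos"] - start
        ref = consensus[col]
        counts_col = pwm.counts[:, col]
        alt_idx = min(
            (i for i in range(4) if "ACGT"[i] != ref),
            key=lambda i: (counts_col[i], i),
        )
        spec["ref"], spec["alt"] = ref, "ACGT"[alt_idx]

    sequences = {
        c: arr.tobytes().decode("ascii") for c, arr in seq_arrays.items()
    }

    # ---- fragments ------------------------------------------------------
    fragments_by_chrom = {
        c: digest_sequence(seq, c) for c, seq in sequences.items()
    }
    frag_index = _FragmentIndex(fragments_by_chrom)

    # ---- variants -------------------------------------------------------
    variants: list[VariantRecord] = []
    variant_positions: dict[str, list[int]] = {c: [] for c in chrom_lengths}

    def base_at(chrom: str, pos: int) -> str:
        return sequences[chrom][pos]

    def alt_for(chrom: str, pos: int) -> str:
        ref = base_at(chrom, pos)
        choices = [b for b in "ACGT" if b != ref]
        return choices[int(rng.integers(len(choices)))]

    def sample_closed_position() -> tuple[str, int]:
        chroms = list(chrom_lengths)
        for _ in range(5000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(2000, chrom_lengths[chrom] - 2000))
            if window_set.overlaps(chrom, pos - 300, pos + 300):
                continue
            if chain_zones.overlaps(chrom, pos - _CHAIN_ZONE_PAD,
                                    pos + _CHAIN_ZONE_PAD):
                continue
            return chrom, pos
        raise RuntimeError("could not place a closed variant")

    sentinel_ids = [f"rsS{i:04d}" for i in range(config.n_sentinels)]
    chain_sentinels = {
        spec["chain_id"]: sentinel_ids[spec["chain_id"]]
        for spec in chain_specs
    }
    for sid in sentinel_ids:
        chrom, pos = sample_closed_position()
        variants.append(
            VariantRecord(sid, chrom, pos, base_at(chrom, pos),
                          alt_for(chrom, pos), role="sentinel", r2=1.0)
        )
        variant_positions[chrom].append(pos)

    proxy_counter = 0
    for spec in chain_specs:
        chrom, pos = spec["ocr"][0], spec["proxy_pos"]
        ref = spec.get("ref", base_at(chrom, pos))
        alt = spec.get("alt", alt_for(chrom, pos))
        pid = f"rsP{proxy_counter:05d}"
        proxy_counter += 1
        r2 = float(rng.uniform(0.85, 0.999))
        variants.append(
            VariantRecord(pid, chrom, pos, ref, alt, role="proxy",
                          sentinel_id=chain_sentinels[spec["chain_id"]],
                          r2=round(r2, 4))
        )
        variant_positions[chrom].append(pos)
        spec["proxy_id"] = pid
        if "motif" in spec:
            motif_planted[pid] = spec["motif"].matrix_id

    for sid in sentinel_ids:
        n_prox = int(rng.poisson(max(config.proxies_per_sentinel_mean - 1, 0)))
        for _ in range(n_prox):
            chrom, pos = sample_closed_position()
            pid = f"rsP{proxy_counter:05d}"
            proxy_counter += 1
            r2 = float(rng.uniform(config.r2_min, 1.0))
            variants.append(
                VariantRecord(pid, chrom, pos, base_at(chrom, pos),
                              alt_for(chrom, pos), role="proxy",
                              sentinel_id=sid, r2=round(r2, 4))
            )
            variant_positions[chrom].append(pos)

    variant_arr = {
        c: np.sort(np.asarray(p, dtype=np.int64))
        for c, p in variant_positions.items()
    }

    def near_variant(chrom: str, start: int, end: int, pad: int) -> bool:
        arr = variant_arr[chrom]
        lo = int(np.searchsorted(arr, start - pad))
        hi = int(np.searchsorted(arr, end + pad))
        return hi > lo

    # ---- landing sites for connected genes ------------------------------
    landing_sites: dict[str, tuple[str, int, int]] = {}
    landing_list: list[tuple[str, int, int]] = []
    for gene in connected_genes:
        chrom_len = chrom_lengths[gene.chrom]
        placed = False
        for _ in range(2000):
            d = sample_distance()
            if d < 15_000:
                continue
            sign = -1 if rng.random() < 0.5 else 1
            center = gene.tss + sign * d
            width = int(rng.integers(350, 651))
            s, e = center - width // 2, center + width // 2
            if s < 1000 or e > chrom_len - 1000:
                continue
            if window_set.overlaps(gene.chrom, s - _LANDING_WINDOW_PAD,
                                   e + _LANDING_WINDOW_PAD):
                continue
            if near_variant(gene.chrom, s, e, _VARIANT_PAD):
                continue
            fidx = frag_index.index_at(gene.chrom, center)
            bin_iv = frag_index.bin_interval(gene.chrom, fidx)
            if chain_zones.overlaps(gene.chrom, bin_iv.start - _BIN_PAD,
                                    bin_iv.end + _BIN_PAD):
                continue
            landing_sites[gene.gene_id] = (gene.chrom, s, e)
            landing_list.append((gene.chrom, s, e))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a contact landing site for {gene.gene_id}"
            )
    landing_set = IntervalSet.from_tuples(landing_list) \
        if landing_list else IntervalSet()

    # ---- ChromHMM segmentation ------------------------------------------
    states = list(config.chromhmm_state_fractions)
    state_p = np.asarray(
        [config.chromhmm_state_fractions[s] for s in states], dtype=float
    )
    seg_rows = []
    for chrom, length in chrom_lengths.items():
        pos = 0
        while pos < length:
            seg_len = max(200, int(rng.exponential(config.chromhmm_segment_mean_bp)))
            end = min(length, pos + seg_len)
            state = states[int(rng.choice(len(states), p=state_p))]
            seg_rows.append((chrom, pos, end, state))
            pos = end
    chromhmm = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "state"]
    )

    # ---- per-cell-type peaks and contacts --------------------------------
    cell_data: dict[str, CellTypeData] = {}
    truth_connected: dict[str, list[str]] = {}
    n_b2b = round(config.frac_bait_to_bait * config.n_contacts)
    n_prom_peaks = round(
        config.promoter_peak_fraction * config.n_consensus_peaks
    )
    chain_gene_ids = {g.gene_id for g in chain_genes}
    non_chain_genes = [g for g in genes if g.gene_id not in chain_gene_ids]

    for ct in config.cell_types:
        active = [s for s in chain_specs if ct in s["cell_types"]]
        # peak intents: (interval, forced)
        intents: list[tuple[GenomicInterval, bool]] = []
        for spec in active:
            chrom, s, e = spec["ocr"]
            intents.append((GenomicInterval(chrom, s, e), True))
        for gene in connected_genes:
            chrom, s, e = landing_sites[gene.gene_id]
            intents.append((GenomicInterval(chrom, s, e), False))
        prom_pick = rng.choice(
            len(non_chain_genes), size=min(n_prom_peaks, len(non_chain_genes)),
            replace=False,
        )
        for gi in prom_pick:
            win = windows_by_gene[non_chain_genes[int(gi)].gene_id]
            center = (win.interval.start + win.interval.end) // 2 + int(
                rng.integers(-300, 301)
            )
            width = 400
            intents.append(
                (GenomicInterval(win.interval.chrom, center - width // 2,
                                 center + width // 2), False)
            )
        n_background = config.n_consensus_peaks - len(intents)
        chroms = list(chrom_lengths)
        for _ in range(n_background):
            for _ in range(2000):
                chrom = chroms[int(rng.integers(len(chroms)))]
                width = int(np.clip(
                    rng.normal(config.peak_width_mean, config.peak_width_sd),
                    150, 1200,
                ))
                s = int(rng.integers(1000, chrom_lengths[chrom] - 1000 - width))
                e = s + width
                if window_set.overlaps(chrom, s - _PEAK_WINDOW_PAD,
                                       e + _PEAK_WINDOW_PAD):
                    continue
                if chain_zones.overlaps(chrom, s - 500, e + 500):
                    continue
                if landing_set.overlaps(chrom, s - 150, e + 150):
                    continue
                if near_variant(chrom, s, e, _VARIANT_PAD):
                    continue
                intents.append((GenomicInterval(chrom, s, e), False))
                break
            else:
                raise RuntimeError("could not place a background peak")

        # replicate realization
        jit = config.peak_jitter_bp
        replicate_peaks: list[list[GenomicInterval]] = [
            [] for _ in range(config.n_replicates)
        ]
        intent_support: list[int] = []
        for iv, forced in intents:
            present = [
                rng.random() >= config.replicate_dropout
                for _ in range(config.n_replicates)
            ]
            if forced:
                present[0] = present[1] = True
            support = 0
            for rep, ok in enumerate(present):
                ds = int(rng.integers(-jit, jit + 1))
                de = int(rng.integers(-jit, jit + 1))
                if not ok:
                    continue
                support += 1
                replicate_peaks[rep].append(
                    GenomicInterval(iv.chrom, iv.start + ds, iv.end + de)
                )
            intent_support.append(support)
        # peaks of this cell type, for background-contact avoidance
        peak_set = IntervalSet.from_tuples(
            (iv.chrom, iv.start, iv.end) for iv, _ in intents
        )

        # contacts
        rows = []

        def add_row(bait_iv, bait_name, oe_iv, oe_name, score):
            rows.append(
                {
                    "bait_chr": bait_iv.chrom,
                    "bait_start": bait_iv.start,
                    "bait_end": bait_iv.end,
                    "bait_name": bait_name,
                    "oe_chr": oe_iv.chrom,
                    "oe_start": oe_iv.start,
                    "oe_end": oe_iv.end,
                    "oe_name": oe_name,
                    "n_reads": int(rng.poisson(12) + 1),
                    "score": round(float(score), 2),
                }
            )

        def bait_fragment(gene: GeneModel) -> GenomicInterval:
            return frag_index.interval(
                gene.chrom, frag_index.index_at(gene.chrom, gene.tss)
            )

        for spec in active:
            if spec["mechanism"] != "pir_contact":
                continue
            gene = spec["gene"]
            chrom = spec["ocr"][0]
            oe_iv = frag_index.interval(
                chrom, frag_index.index_at(chrom, spec["proxy_pos"])
            )
            add_row(bait_fragment(gene), gene.gene_id, oe_iv, ".",
                    rng.uniform(6.0, 15.0))

        surviving_connected = []
        for i, gene in enumerate(connected_genes):
            chrom, s, e = landing_sites[gene.gene_id]
            center = (s + e) // 2
            oe_iv = frag_index.interval(
                chrom, frag_index.index_at(chrom, center)
            )
            add_row(bait_fragment(gene), gene.gene_id, oe_iv, ".",
                    rng.uniform(5.5, 14.0))
            # intent order: active chains first, then connected genes
            if intent_support[len(active) + i] >= 2:
                surviving_connected.append(gene.gene_id)

        n_b2b_done = 0
        genes_by_chrom: dict[str, list[GeneModel]] = {}
        for g in non_chain_genes:
            genes_by_chrom.setdefault(g.chrom, []).append(g)
        for _ in range(5000):
            if n_b2b_done >= n_b2b:
                break
            chrom = chroms[int(rng.integers(len(chroms)))]
            cands = genes_by_chrom.get(chrom, [])
            if len(cands) < 2:
                continue
            a, h = (cands[int(i)] for i in
                    rng.choice(len(cands), size=2, replace=False))
            ok = True
            for g in (a, h):
                fidx = frag_index.index_at(g.chrom, g.tss)
                fiv = frag_index.interval(g.chrom, fidx)
                biv = frag_index.bin_interval(g.chrom, fidx)
                if chain_zones.overlaps(g.chrom, biv.start - _BIN_PAD,
                                        biv.end + _BIN_PAD):
                    ok = False
                elif landing_set.overlaps(g.chrom, fiv.start - 150,
                                          fiv.end + 150):
                    ok = False
            if not ok:
                continue
            add_row(bait_fragment(a), a.gene_id, bait_fragment(h), h.gene_id,
                    rng.uniform(5.0, 12.0))
            n_b2b_done += 1

        n_closed = config.n_contacts - len(rows)
        for _ in range(n_closed):
            for _ in range(2000):
                gene = genes[int(rng.integers(len(genes)))]
                d = sample_distance()
                sign = -1 if rng.random() < 0.5 else 1
                center = gene.tss + sign * d
                if not (1000 < center < chrom_lengths[gene.chrom] - 1000):
                    continue
                fidx = frag_index.index_at(gene.chrom, center)
                fiv = frag_index.interval(gene.chrom, fidx)
                biv = frag_index.bin_interval(gene.chrom, fidx)
                if peak_set.overlaps(gene.chrom, fiv.start - jit - 100,
                                     fiv.end + jit + 100):
                    continue
                if chain_zones.overlaps(gene.chrom, biv.start - _BIN_PAD,
                                        biv.end + _BIN_PAD):
                    continue
                if landing_set.overlaps(gene.chrom, fiv.start - 150,
                                        fiv.end + 150):
                    continue
                # the 4frag bin must stay clear of promoter windows too,
                # else the binned row turns bait-to-bait
                if window_set.overlaps(gene.chrom, biv.start - 150,
                                       biv.end + 150):
                    continue
                add_row(bait_fragment(gene), gene.gene_id, fiv, ".",
                        rng.uniform(5.0, 13.0))
                break
            else:
                raise RuntimeError("could not place a background contact")

        n_sub = round(config.frac_subthreshold_contacts * config.n_contacts)
        for _ in range(n_sub):
            gene = genes[int(rng.integers(len(genes)))]
            d = sample_distance()
            sign = -1 if rng.random() < 0.5 else 1
            center = int(
                np.clip(gene.tss + sign * d, 1000,
                        chrom_lengths[gene.chrom] - 1000)
            )
            fiv = frag_index.interval(
                gene.chrom, frag_index.index_at(gene.chrom, center)
            )
            add_row(bait_fragment(gene), gene.gene_id, fiv, ".",
                    rng.uniform(0.5, 4.99))

        table = pd.DataFrame(rows)
        table["resolution"] = "1frag"
        table["cell_type"] = ct
        # 4frag rows: bin both ends, keep the best score per bin pair
        four = table.copy()
        for side in ("bait", "oe"):
            bins = [
                frag_index.bin_interval(
                    row[f"{side}_chr"],
                    frag_index.index_at(
                        row[f"{side}_chr"], (row[f"{side}_start"]
                                             + row[f"{side}_end"]) // 2
                    ),
                )
                for _, row in four.iterrows()
            ]
            four[f"{side}_start"] = [b.start for b in bins]
            four[f"{side}_end"] = [b.end for b in bins]
        four["resolution"] = "4frag"
        four = (
            four.sort_values("score", ascending=False)
            .drop_duplicates(
                ["bait_chr", "bait_start", "bait_end",
                 "oe_chr", "oe_start", "oe_end"]
            )
        )
        table = pd.concat([table, four], ignore_index=True)
        table = table.sort_values(
            ["resolution", "bait_chr", "bait_start", "oe_chr", "oe_start"],
            kind="stable",
        ).reset_index(drop=True)

        cell_data[ct] = CellTypeData(replicate_peaks, table)
        truth_connected[ct] = sorted(
            {s["gene"].gene_id for s in active
             if s["mechanism"] == "pir_contact"}
            | set(surviving_connected)
        )

    # ---- expression ------------------------------------------------------
    expr = {}
    for ct in config.cell_types:
        shifted = set(truth_connected[ct])
        vals = []
        for g in genes:
            x = rng.normal(config.expression_log2_mean,
                           config.expression_log2_sd)
            if g.gene_id in shifted:
                x += config.expression_log2_shift
            x = max(0.0, x)
            vals.append(round(2.0**x - 1.0, 4))
        expr[ct] = vals
    expression = pd.DataFrame(
        expr, index=pd.Index([g.gene_id for g in genes], name="gene_id")
    )

    truth = TruthTable(
        chains=[
            TruthChain(
                s["chain_id"], chain_sentinels[s["chain_id"]], s["proxy_id"],
                s["gene"].gene_id, s["mechanism"], s["cell_types"], s["ocr"],
            )
            for s in chain_specs
        ],
        motif_planted=motif_planted,
        connected_genes=truth_connected,
        shifted_genes={ct: list(v) for ct, v in truth_connected.items()},
    )
    return Bundle(
        config=config,
        sequences=sequences,
        genes=genes,
        variants=variants,
        pwms=pwms,
        chromhmm=chromhmm,
        expression=expression,
        cell_data=cell_data,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_bundle(bundle: Bundle, out_dir: str | Path) -> Path:
    """Write the bundle as plain-text files plus a manifest and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_fasta(bundle.sequences, out / "genome.fa")
    cio.write_genes(bundle.genes, out / "genes.tsv")
    cio.write_variants(bundle.variants, out / "variants.tsv")
    cio.write_pwm_jaspar(bundle.pwms, out / "pwms.jaspar")
    bundle.chromhmm.to_csv(
        out / "chromhmm.bed", sep="\t", header=False, index=False
    )
    cio.write_expression(bundle.expression, out / "expression.tsv")
    for ct, data in bundle.cell_data.items():
        ct_dir = out / "cells" / ct
        ct_dir.mkdir(parents=True, exist_ok=True)
        for rep, peaks in enumerate(data.replicate_peaks, 1):
            cio.write_bed(peaks, ct_dir / f"atac_rep{rep}.bed")
        cio.write_contacts_ibed(data.contacts, ct_dir / "contacts.ibed")
    truth_dict = {
        "chains": [dataclasses.asdict(c) for c in bundle.truth.chains],
        "motif_planted": bundle.truth.motif_planted,
        "connected_genes": bundle.truth.connected_genes,
        "shifted_genes": bundle.truth.shifted_genes,
    }
    (out / "truth.json").write_text(
        json.dumps(truth_dict, indent=1, sort_keys=True) + "\n"
    )
    manifest = {
        "format": "capv2g-bundle-v1",
        "config": dataclasses.asdict(bundle.config),
        "cell_types": list(bundle.config.cell_types),
        "files": {
            "genome": "genome.fa",
            "genes": "genes.tsv",
            "variants": "variants.tsv",
            "pwms": "pwms.jaspar",
            "chromhmm": "chromhmm.bed",
            "expression": "expression.tsv",
            "truth": "truth.json",
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return out


def load_bundle(path: str | Path) -> Bundle:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cfg_dict = manifest["config"]
    for key in ("cell_types", "chain_celltype_probs"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = SimConfig(**cfg_dict)
    truth_dict = json.loads((path / "truth.json").read_text())
    truth = TruthTable(
        chains=[
            TruthChain(
                c["chain_id"], c["sentinel_id"], c["proxy_id"], c["gene_id"],
                c["mechanism"], tuple(c["cell_types"]), tuple(c["ocr"]),
            )
            for c in truth_dict["chains"]
        ],
        motif_planted=truth_dict["motif_planted"],
        connected_genes=truth_dict["connected_genes"],
        shifted_genes=truth_dict["shifted_genes"],
    )
    cell_data = {}
    for ct in config.cell_types:
        ct_dir = path / "cells" / ct
        reps = []
        for rep in range(1, config.n_replicates + 1):
            df = cio.read_regions(ct_dir / f"atac_rep{rep}.bed")
            reps.append(cio.as_intervals(df))
        contacts = cio.read_contacts_ibed(ct_dir / "contacts.ibed")
        cell_data[ct] = CellTypeData(reps, contacts)
    return Bundle(
        config=config,
        sequences=cio.read_fasta(path / "genome.fa"),
        genes=cio.read_genes(path / "genes.tsv"),
        variants=cio.read_variants(path / "variants.tsv"),
        pwms=cio.read_pwm_jaspar(path / "pwms.jaspar"),
        chromhmm=cio.read_chromhmm(path / "chromhmm.bed"),
        expression=cio.read_expression(path / "expression.tsv"),
        cell_data=cell_data,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# pipeline replay, audit and recovery metrics
# ---------------------------------------------------------------------------

def analyze_cell_type(bundle: Bundle, cell_type: str) -> dict:
    """Run the full pipeline for one cell type of a bundle.

    Returns consensus OCRs (classified), annotated contacts at both
    resolutions, the PIR set and the V2G records.
    """
    chrom_lengths = {c: len(s) for c, s in bundle.sequences.items()}
    fragments = {
        c: digest_sequence(seq, c) for c, seq in bundle.sequences.items()
    }
    bins = {c: bin_fragments(f, 4) for c, f in fragments.items()}
    units1 = UnitMap.from_fragments(fragments)
    units4 = UnitMap.from_bins(bins)
    promoters = [
        promoter_window(g, chrom_lengths[g.chrom]) for g in bundle.genes
    ]
    data = bundle.cell_data[cell_type]
    table = filter_contacts(data.contacts, MIN_SCORE)
    ann1 = annotate_baits(
        table[table["resolution"] == "1frag"], promoters, units1
    )
    ann4 = annotate_baits(
        table[table["resolution"] == "4frag"], promoters, units4
    )
    annotated = ann1 + ann4
    pirs = derive_pirs(annotated)
    ocrs = consensus_ocrs(data.replicate_peaks, min_support=2,
                          cell_type=cell_type)
    labelled, class_counts = classify_ocrs(ocrs, promoters, pirs)
    sentinels = [v for v in bundle.variants if v.role == "sentinel"]
    proxies = expand_proxies(
        sentinels, [v for v in bundle.variants if v.role == "proxy"]
    )
    records = implicate_genes(
        proxies, labelled, annotated, promoters, cell_type=cell_type,
        genes=bundle.genes,
    )
    return {
        "ocrs": labelled,
        "class_counts": class_counts,
        "annotated_1frag": ann1,
        "annotated_4frag": ann4,
        "pirs": pirs,
        "records": records,
        "promoters": promoters,
    }


def pipeline_connected_genes(bundle: Bundle, cell_type: str,
                             analysis: dict | None = None) -> set[str]:
    """Genes whose promoter contacts a PIR-OCR, at fragment resolution."""
    analysis = analysis or analyze_cell_type(bundle, cell_type)
    pir_ocrs = IntervalSet.from_intervals(
        o.interval for o in analysis["ocrs"] if o.ocr_class == PIR_OCR
    )
    return genes_contacting(analysis["annotated_1frag"], pir_ocrs)


@dataclass
class AuditReport:
    ok: bool
    n_chains_checked: int
    failures: list[str]
    recovered: dict[str, set[tuple[str, str, str]]]
    planted: dict[str, set[tuple[str, str, str]]]


def audit_truth(bundle: Bundle, truth: TruthTable | None = None) -> AuditReport:
    """Replay every planted chain through the real pipeline operations.

    A chain passes when its (sentinel, gene, mechanism) triple is among
    the V2G records of every cell type it was planted in; planted motif
    proxies must be flagged by the scanner.  Failures are report
    entries, not exceptions.
    """
    truth = truth or bundle.truth
    failures: list[str] = []
    recovered: dict[str, set[tuple[str, str, str]]] = {}
    planted: dict[str, set[tuple[str, str, str]]] = {}
    for ct in bundle.config.cell_types:
        analysis = analyze_cell_type(bundle, ct)
        recovered[ct] = {
            (r.sentinel_id, r.gene_id, r.mechanism)
            for r in analysis["records"]
        }
        planted[ct] = truth.planted_pairs(ct)
    n_checked = 0
    for chain in truth.chains:
        for ct in chain.cell_types:
            n_checked += 1
            triple = (chain.sentinel_id, chain.gene_id, chain.mechanism)
            if triple not in recovered.get(ct, set()):
                failures.append(
                    f"chain {chain.chain_id} not recovered in {ct}: {triple}"
                )
    if truth.motif_planted:
        hits = scan_variants(
            [v for v in bundle.variants
             if v.variant_id in truth.motif_planted],
            bundle.sequences, bundle.pwms,
        )
        flagged = {h.proxy_id for h in hits}
        for pid in truth.motif_planted:
            if pid not in flagged:
                failures.append(f"planted motif proxy {pid} not flagged")
    return AuditReport(
        ok=not failures,
        n_chains_checked=n_checked,
        failures=failures,
        recovered=recovered,
        planted=planted,
    )


def recovery_metrics(bundle: Bundle) -> dict[str, float]:
    """Sensitivity and precision of V2G recovery of planted chains,
    over (sentinel, gene, mechanism, cell type) tuples."""
    report = audit_truth(bundle)
    planted = {
        (ct, *t) for ct, triples in report.planted.items() for t in triples
    }
    found = {
        (ct, *t) for ct, triples in report.recovered.items() for t in triples
    }
    tp = len(planted & found)
    sens = tp / len(planted) if planted else float("nan")
    prec = tp / len(found) if found else float("nan")
    return {
        "sensitivity": sens,
        "precision": prec,
        "n_planted": len(planted),
        "n_recovered": len(found),
    }


def motif_recovery_metrics(bundle: Bundle) -> dict[str, float]:
    """Precision/recall of the motif scanner against planted disrupting
    proxies, scanning every variant in the bundle."""
    hits = scan_variants(bundle.variants, bundle.sequences, bundle.pwms)
    flagged = {h.proxy_id for h in hits}
    planted = set(bundle.truth.motif_planted)
    tp = len(flagged & planted)
    recall = tp / len(planted) if planted else float("nan")
    precision = tp / len(flagged) if flagged else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "n_planted": len(planted),
        "n_flagged": len(flagged),
    }
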