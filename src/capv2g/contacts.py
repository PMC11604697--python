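"""Promoter contact maps: score filtering, bait annotation, PIRs and
distance summaries.

Contacts arrive pre-called (e.g. by CHiCAGO) as an ibed-like table and
are filtered at the conventional significance threshold (score >= 5).
Each retained contact is attributed to the promoter(s) its bait
overlaps; contacts joining two promoters are flagged bait-to-bait and
attributed to both.  The union of non-bait other ends forms the
promoter-interacting regions (PIRs) against which open chromatin is
classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval, PromoterWindow, UnitMap
from .intervals import IntervalSet

__all__ = [
    "PromoterContact",
    "DistanceStats",
    "filter_contacts",
    "annotate_baits",
    "derive_pirs",
    "contact_distance_stats",
    "bait_to_bait_fraction",
    "genes_contacting",
]


@dataclass(frozen=True, slots=True)
class PromoterContact:
    """One called contact attributed to one bait gene."""

    gene_id: str
    bait_unit: tuple[str, int]
    oe_unit: tuple[str, int]
    bait_interval: GenomicInterval
    oe_interval: GenomicInterval
    score: float
    resolution: str
    cell_type: str
    is_bait_to_bait: bool


def filter_contacts(table: pd.DataFrame, min_score: float = 5.0) -> pd.DataFrame:
    """Keep rows with score >= ``min_score`` (inclusive threshold).

    Idempotent, and monotone in ``min_score``.
    """
    return table[table["score"] >= min_score].reset_index(drop=True)


def annotate_baits(
    contacts: pd.DataFrame,
    promoters: Sequence[PromoterWindow],
    units: UnitMap,
) -> list[PromoterContact]:
    """Label contact ends as bait/non-bait by promoter overlap.

    An end is a bait when one of its units overlaps a promoter window.
    Rows where both ends are baits are flagged ``is_bait_to_bait`` and
    yield one record per promoter side (each end is the other promoter's
    interacting region).  Rows whose ends cannot be mapped to any unit
    raise; rows touching no promoter at all are skipped.
    """
    unit_genes: dict[tuple[str, int], set[str]] = {}
    for win in promoters:
        for uid in units.assign(win.interval):
            unit_genes.setdefault(uid, set()).add(win.gene_id)

    records: list[PromoterContact] = []
    for row in contacts.itertuples(index=False):
        bait_iv = GenomicInterval(row.bait_chr, int(row.bait_start), int(row.bait_end))
        oe_iv = GenomicInterval(row.oe_chr, int(row.oe_start), int(row.oe_end))
        bait_units = units.assign(bait_iv)
        oe_units = units.assign(oe_iv)
        if not bait_units or not oe_units:
            raise ValueError(
                f"contact end not mappable to any unit: "
                f"{bait_iv.chrom}:{bait_iv.start}-{bait_iv.end} / "
                f"{oe_iv.chrom}:{oe_iv.start}-{oe_iv.end}"
            )
        bait_genes = sorted(
            set().union(*(unit_genes.get(u, set()) for u in bait_units))
        )
        oe_genes = sorted(
            set().union(*(unit_genes.get(u, set()) for u in oe_units))
        )
        if not bait_genes and not oe_genes:
            continue
        if not bait_genes:
            # table had the promoter on the other-end side; swap
            bait_iv, oe_iv = oe_iv, bait_iv
            bait_units, oe_units = oe_units, bait_units
            bait_genes, oe_genes = oe_genes, bait_genes
        b2b = bool(bait_genes and oe_genes)
        resolution = getattr(row, "resolution", "1frag")
        cell_type = getattr(row, "cell_type", ".")
        for gene in bait_genes:
            records.append(
                PromoterContact(
                    gene, bait_units[0], oe_units[0], bait_iv, oe_iv,
                    float(row.score), resolution, cell_type, b2b,
                )
            )
        if b2b:
            for gene in oe_genes:
                records.append(
                    PromoterContact(
                        gene, oe_units[0], bait_units[0], oe_iv, bait_iv,
                        float(row.score), resolution, cell_type, True,
                    )
                )
    return records


def derive_pirs(contacts: Sequence[PromoterContact]) -> IntervalSet:
    """Merged union of other-end intervals: the PIR set.

    Bait-to-bait records contribute both ends because each promoter is
    the other promoter's interacting region; ``annotate_baits`` already
    emits one record per side, so collecting every record's other end
    covers both.
    """
    return IntervalSet.from_intervals(c.oe_interval for c in contacts)


@dataclass
class DistanceStats:
    """Per-contact bait/other-end midpoint distances (cis only)."""

    distances: np.ndarray
    mean: float
    n_cis: int
    n_trans: int

    def cdf(self, value: float) -> float:
        """Empirical CDF of the distance distribution at ``value``."""
        if self.n_cis == 0:
            raise ValueError("no cis contacts: CDF undefined")
        return float(
            np.searchsorted(np.sort(self.distances), value, side="right")
            / self.n_cis
        )


def contact_distance_stats(contacts: pd.DataFrame) -> DistanceStats:
    """Midpoint-to-midpoint distances between contact ends.

    Distances are defined only for cis contacts; trans rows are excluded
    from the distribution and counted separately.
    """
    cis = contacts["bait_chr"] == contacts["oe_chr"]
    sub = contacts[cis]
    bait_mid = (sub["bait_start"].to_numpy() + sub["bait_end"].to_numpy()) / 2.0
    oe_mid = (sub["oe_start"].to_numpy() + sub["oe_end"].to_numpy()) / 2.0
    distances = np.abs(bait_mid - oe_mid)
    mean = float(distances.mean()) if len(distances) else float("nan")
    return DistanceStats(
        distances=distances,
        mean=mean,
        n_cis=int(cis.sum()),
        n_trans=int((~cis).sum()),
    )


def bait_to_bait_fraction(contacts: pd.DataFrame, promoters, units) -> float:
    """Fraction of table rows whose two ends both overlap promoters."""
    unit_has_gene: set[tuple[str, int]] = set()
    for win in promoters:
        unit_has_gene.update(units.assign(win.interval))
    n = b2b = 0
    for row in contacts.itertuples(index=False):
        bait_iv = GenomicInterval(row.bait_chr, int(row.bait_start), int(row.bait_end))
        oe_iv = GenomicInterval(row.oe_chr, int(row.oe_start), int(row.oe_end))
        bait_hit = any(u in unit_has_gene for u in units.assign(bait_iv))
        oe_hit = any(u in unit_has_gene for u in units.assign(oe_iv))
        if bait_hit or oe_hit:
            n += 1
            if bait_hit and oe_hit:
                b2b += 1
    if n == 0:
        return float("nan")
    return b2b / n


def genes_contacting(
    contacts: Sequence[PromoterContact], regions: IntervalSet
) -> set[str]:
    """Bait genes whose contact other end overlaps ``regions`` (e.g. the
    PIR-OCR set, giving the 'promoter connected to open chromatin' genes
    used in expression comparisons)."""
    hit = set()
    for c in contacts:
        if c.gene_id in hit:
            continue
        if regions.overlaps(c.oe_interval.chrom, c.oe_interval.start, c.oe_interval.end):
            hit.add(c.gene_id)
    return hit
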