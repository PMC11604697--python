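"""Restriction-fragment genome model, promoter windows and TSS geometry.

The contact maps in a promoter Capture-C experiment live on DpnII
restriction fragments: every GATC occurrence cuts the chromosome, and the
fragments between consecutive cuts tile it exactly.  Distant interactions
are additionally called on bins of four consecutive fragments ("4frag")
to gain power.  This module provides that fragment model plus the two
pieces of gene geometry the variant-to-gene procedure needs: the promoter
window (1500 bp transcriptionally upstream / 500 bp downstream of the
TSS) and nearest-gene lookup for sentinel classification.

Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "RestrictionFragment",
    "FragmentBin",
    "GeneModel",
    "PromoterWindow",
    "UnitMap",
    "digest_sequence",
    "bin_fragments",
    "promoter_window",
    "nearest_gene",
]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic region."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True, slots=True)
class RestrictionFragment:
    fragment_id: int
    interval: GenomicInterval


@dataclass(frozen=True, slots=True)
class FragmentBin:
    bin_id: int
    member_fragment_ids: tuple[int, ...]
    interval: GenomicInterval


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene reduced to the single attribute V2G needs: its TSS."""

    gene_id: str
    gene_name: str
    chrom: str
    tss: int  # 0-based position of the first transcribed base
    strand: str

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True, slots=True)
class PromoterWindow:
    gene_id: str
    interval: GenomicInterval


def digest_sequence(
    seq: str, chrom: str, motif: str = "GATC"
) -> list[RestrictionFragment]:
    """In-silico restriction digestion of one chromosome.

    Cut positions are the start index of every (case-insensitive) motif
    occurrence; ambiguous bases (N) never match.  Fragments are the
    intervals between consecutive cuts plus the leading and trailing
    remainders, so they tile the sequence exactly.  A motif longer than
    the sequence yields a single fragment.
    """
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    if not motif:
        raise ValueError("motif must be non-empty")
    s = seq.upper()
    m = motif.upper()
    # lookahead finds overlapping occurrences of general motifs
    cuts = [match.start() for match in re.finditer(f"(?={re.escape(m)})", s)]
    boundaries = sorted({0, *cuts, len(s)})
    fragments = []
    for i, (a, b) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        fragments.append(RestrictionFragment(i, GenomicInterval(chrom, a, b)))
    return fragments


def _check_tiling(fragments: Sequence[RestrictionFragment]) -> None:
    prev_end = None
    for frag in fragments:
        if prev_end is not None and frag.interval.start != prev_end:
            raise ValueError(
                "fragments must be sorted, non-overlapping and abutting; "
                f"gap/overlap before fragment {frag.fragment_id}"
            )
        prev_end = frag.interval.end


def bin_fragments(
    fragments: Sequence[RestrictionFragment], k: int = 4
) -> list[FragmentBin]:
    """Tile ``k`` consecutive fragments into non-overlapping bins.

    Bins are anchored at the chromosome's first fragment; the final bin
    may hold fewer than ``k`` members.  Every fragment lands in exactly
    one bin.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not fragments:
        return []
    chroms = {f.interval.chrom for f in fragments}
    if len(chroms) > 1:
        raise ValueError("bin_fragments operates on a single chromosome")
    _check_tiling(fragments)
    bins = []
    for bin_id, i in enumerate(range(0, len(fragments), k)):
        members = fragments[i : i + k]
        iv = GenomicInterval(
            members[0].interval.chrom,
            members[0].interval.start,
            members[-1].interval.end,
        )
        bins.append(
            FragmentBin(bin_id, tuple(f.fragment_id for f in members), iv)
        )
    return bins


def promoter_window(
    gene: GeneModel,
    chrom_length: int | None = None,
    upstream: int = 1500,
    downstream: int = 500,
) -> PromoterWindow:
    """The promoter window: ``upstream`` bp before / ``downstream`` bp
    after the TSS in the direction of transcription.

    For a '+' gene at ``tss`` this is ``[tss - upstream, tss + downstream)``;
    for a '-' gene the mirrored half-open span is
    ``[tss - downstream + 1, tss + upstream + 1)``.  The window is
    truncated at chromosome bounds when a length is supplied.
    """
    if chrom_length is not None and not (0 <= gene.tss < chrom_length):
        raise ValueError(
            f"TSS {gene.tss} outside chromosome {gene.chrom} "
            f"of length {chrom_length}"
        )
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream + 1, gene.tss + upstream + 1
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return PromoterWindow(gene.gene_id, GenomicInterval(gene.chrom, start, end))


def nearest_gene(chrom: str, pos: int, genes: Iterable[GeneModel]) -> str:
    """Gene whose TSS is closest to ``pos``; ties break to the
    lexicographically smallest gene_id."""
    candidates = [g for g in genes if g.chrom == chrom]
    if not candidates:
        raise LookupError(f"no gene on chromosome {chrom}: unmappable position")
    return min(candidates, key=lambda g: (abs(g.tss - pos), g.gene_id)).gene_id


class UnitMap:
    """Lookup from intervals to tiling units (fragments or bins).

    Unit ids are ``(chrom, ordinal)`` tuples because fragment/bin ordinals
    restart on every chromosome.
    """

    def __init__(self, per_chrom: dict[str, list]):
        # per_chrom: chrom -> list of fragments or bins, already tiled
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._ids: dict[str, list[int]] = {}
        self._intervals: dict[tuple[str, int], GenomicInterval] = {}
        for chrom, units in per_chrom.items():
            ivs = [u.interval for u in units]
            for iv in ivs:
                if iv.chrom != chrom:
                    raise ValueError("unit chromosome mismatch")
            ids = [
                u.fragment_id if isinstance(u, RestrictionFragment) else u.bin_id
                for u in units
            ]
            self._starts[chrom] = np.asarray([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.asarray([iv.end for iv in ivs], dtype=np.int64)
            self._ids[chrom] = ids
            for uid, iv in zip(ids, ivs):
                self._intervals[(chrom, uid)] = iv

    @classmethod
    def from_fragments(
        cls, fragments_by_chrom: dict[str, list[RestrictionFragment]]
    ) -> "UnitMap":
        return cls(fragments_by_chrom)

    @classmethod
    def from_bins(cls, bins_by_chrom: dict[str, list[FragmentBin]]) -> "UnitMap":
        return cls(bins_by_chrom)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def interval_of(self, unit_id: tuple[str, int]) -> GenomicInterval:
        return self._intervals[unit_id]

    def assign(self, interval: GenomicInterval) -> list[tuple[str, int]]:
        """All unit ids overlapping ``interval`` by >= 1 bp, in order.

        A chromosome absent from the map (or a query beyond the last
        unit) yields an empty list.
        """
        chrom = interval.chrom
        if chrom not in self._starts:
            return []
        starts, ends = self._starts[chrom], self._ends[chrom]
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        return [(chrom, self._ids[chrom][i]) for i in range(lo, hi)]

    def assign_point(self, chrom: str, pos: int) -> tuple[str, int] | None:
        hits = self.assign(GenomicInterval(chrom, pos, pos + 1))
        return hits[0] if hits else None
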