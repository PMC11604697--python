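"""Sorted-array genomic interval sets.

All coordinates are 0-based half-open throughout the package (BED-native).
An :class:`IntervalSet` stores, per chromosome, a merged ``(n, 2)`` int64
array of ``[start, end)`` rows.  Abutting intervals are merged, so every
stored set is sorted, non-overlapping and minimal — which makes
intersection and Jaccard computations simple two-pointer sweeps that the
test suite checks against a per-nucleotide brute-force oracle.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = ["IntervalSet", "merge_pairs"]


def merge_pairs(pairs: Iterable[tuple[int, int]]) -> np.ndarray:
    """Merge ``(start, end)`` pairs into a sorted non-overlapping array.

    Abutting intervals (``end == next start``) are coalesced.
    """
    arr = sorted((int(s), int(e)) for s, e in pairs)
    out: list[list[int]] = []
    for s, e in arr:
        if s >= e:
            raise ValueError(f"invalid interval [{s}, {e})")
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


class IntervalSet:
    """A genome-wide set of intervals keyed by chromosome."""

    def __init__(self, per_chrom: Mapping[str, np.ndarray] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if per_chrom:
            for chrom, arr in per_chrom.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                self._data[chrom] = merge_pairs(map(tuple, arr)) if len(arr) else arr

    @classmethod
    def from_intervals(cls, intervals: Iterable) -> "IntervalSet":
        """Build from objects exposing ``.chrom``, ``.start`` and ``.end``."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return cls.from_tuples(
            (c, s, e) for c, pairs in by_chrom.items() for s, e in pairs
        )

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in tuples:
            by_chrom.setdefault(chrom, []).append((s, e))
        obj = cls()
        for chrom, pairs in by_chrom.items():
            obj._data[chrom] = merge_pairs(pairs)
        return obj

    # -- basic accessors -------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def array(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return sum(len(a) for a in self._data.values())

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chroms:
            for s, e in self._data[chrom]:
                yield chrom, int(s), int(e)

    def __bool__(self) -> bool:
        return len(self) > 0

    # -- measures --------------------------------------------------------
    def total_bp(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values())
        )

    def intersection_bp(self, other: "IntervalSet") -> int:
        total = 0
        for chrom in self._data:
            a = self._data[chrom]
            b = other.array(chrom)
            if not len(a) or not len(b):
                continue
            i = j = 0
            while i < len(a) and j < len(b):
                lo = max(a[i, 0], b[j, 0])
                hi = min(a[i, 1], b[j, 1])
                if hi > lo:
                    total += int(hi - lo)
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
        return total

    def union_bp(self, other: "IntervalSet") -> int:
        return self.total_bp() + other.total_bp() - self.intersection_bp(other)

    def jaccard(self, other: "IntervalSet") -> float:
        union = self.union_bp(other)
        if union == 0:
            return 0.0
        return self.intersection_bp(other) / union

    # -- queries ---------------------------------------------------------
    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        arr = self.array(chrom)
        if not len(arr):
            return False
        # first stored interval with end > start
        i = int(np.searchsorted(arr[:, 1], start, side="right"))
        return i < len(arr) and arr[i, 0] < end

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.overlaps(chrom, pos, pos + 1)

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Return the stored rows overlapping ``[start, end)`` by >= 1 bp."""
        arr = self.array(chrom)
        if not len(arr):
            return arr
        lo = int(np.searchsorted(arr[:, 1], start, side="right"))
        hi = int(np.searchsorted(arr[:, 0], end, side="left"))
        return arr[lo:hi]

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet.from_tuples(list(self) + list(other))
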