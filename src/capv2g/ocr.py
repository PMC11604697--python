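"""Consensus open-chromatin regions (OCRs) and their classification.

An OCR is an ATAC-seq peak reproducible in at least two replicates.
Consensus calling clusters peaks across replicates by single-linkage
(>= 1 bp overlap) and emits the union interval of every cluster with
sufficient distinct-replicate support.  OCRs are then classified against
promoter windows and PIRs: promoter overlap takes precedence
(promoterOCR), then PIR overlap (PIR-OCR), else nonPIR-OCR; the three
classes partition the atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .genome import GenomicInterval, PromoterWindow
from .intervals import IntervalSet

__all__ = [
    "OCR",
    "consensus_ocrs",
    "classify_ocrs",
    "jaccard_index",
    "jaccard_matrix",
    "class_interval_set",
]

PROMOTER_OCR = "promoterOCR"
PIR_OCR = "PIR-OCR"
NONPIR_OCR = "nonPIR-OCR"


@dataclass(frozen=True, slots=True)
class OCR:
    interval: GenomicInterval
    support: int
    ocr_class: str | None = None
    pir_flag: bool = False
    cell_type: str = "."


def consensus_ocrs(
    replicate_peaks: Sequence[Iterable[GenomicInterval]],
    min_support: int = 2,
    cell_type: str = ".",
) -> list[OCR]:
    """Call consensus OCRs from per-replicate peak sets.

    Peaks from all replicates are pooled and clustered per chromosome by
    single-linkage (>= 1 bp overlap).  A cluster becomes an OCR spanning
    the union of its members when peaks from at least ``min_support``
    distinct replicates contribute.
    """
    if min_support > len(replicate_peaks):
        raise ValueError(
            f"min_support={min_support} exceeds the {len(replicate_peaks)} "
            "replicate sets provided"
        )
    pooled: dict[str, list[tuple[int, int, int]]] = {}
    for rep_idx, peaks in enumerate(replicate_peaks):
        for p in peaks:
            pooled.setdefault(p.chrom, []).append((p.start, p.end, rep_idx))
    ocrs: list[OCR] = []
    for chrom in sorted(pooled):
        peaks = sorted(pooled[chrom])
        cluster: list[tuple[int, int, int]] = []
        cluster_end = -1

        def flush():
            if not cluster:
                return
            reps = {r for _, _, r in cluster}
            if len(reps) >= min_support:
                start = min(s for s, _, _ in cluster)
                end = max(e for _, e, _ in cluster)
                ocrs.append(
                    OCR(GenomicInterval(chrom, start, end), len(reps),
                        cell_type=cell_type)
                )

        for start, end, rep in peaks:
            if cluster and start < cluster_end:
                cluster.append((start, end, rep))
                cluster_end = max(cluster_end, end)
            else:
                flush()
                cluster = [(start, end, rep)]
                cluster_end = end
        flush()
    return ocrs


def classify_ocrs(
    ocrs: Sequence[OCR],
    promoters: Sequence[PromoterWindow],
    pirs: IntervalSet,
) -> tuple[list[OCR], dict[str, int]]:
    """Assign each OCR its primary class and return per-class counts.

    Overlap with any promoter window wins (promoterOCR, with a secondary
    ``pir_flag`` when the OCR also touches a PIR); otherwise PIR overlap
    gives PIR-OCR; otherwise nonPIR-OCR.
    """
    prom_set = IntervalSet.from_intervals(w.interval for w in promoters)
    labelled: list[OCR] = []
    counts = {PROMOTER_OCR: 0, PIR_OCR: 0, NONPIR_OCR: 0}
    for ocr in ocrs:
        iv = ocr.interval
        in_prom = prom_set.overlaps(iv.chrom, iv.start, iv.end)
        in_pir = pirs.overlaps(iv.chrom, iv.start, iv.end)
        if in_prom:
            cls = PROMOTER_OCR
        elif in_pir:
            cls = PIR_OCR
        else:
            cls = NONPIR_OCR
        counts[cls] += 1
        labelled.append(replace(ocr, ocr_class=cls, pir_flag=in_pir))
    return labelled, counts


def _as_set(regions) -> IntervalSet:
    if isinstance(regions, IntervalSet):
        return regions
    return IntervalSet.from_intervals(
        r.interval if isinstance(r, OCR) else r for r in regions
    )


def jaccard_index(a, b) -> float:
    """Ratio of intersecting to union base pairs of two region sets.

    Both sets are merged to non-overlapping intervals first; an empty
    union is defined as Jaccard 0.
    """
    return _as_set(a).jaccard(_as_set(b))


def class_interval_set(
    ocrs: Sequence[OCR], classes: Iterable[str] = (PROMOTER_OCR, PIR_OCR)
) -> IntervalSet:
    """Merged intervals of the OCRs whose primary class is in ``classes``
    (default: the cRE set, promoter OCRs + PIR-OCRs)."""
    wanted = set(classes)
    return IntervalSet.from_intervals(
        o.interval for o in ocrs if o.ocr_class in wanted
    )


def jaccard_matrix(
    ocrs_by_cell_type: dict[str, Sequence[OCR]],
    mode: str = "cre",
) -> dict[tuple[str, str], float]:
    """Pairwise Jaccard of promoter-connected annotation across cell types.

    ``mode='cre'`` compares promoterOCR + PIR-OCR nucleotides (default);
    ``mode='pir_ocr'`` restricts to PIR-OCRs only.
    """
    classes = {
        "cre": (PROMOTER_OCR, PIR_OCR),
        "pir_ocr": (PIR_OCR,),
    }[mode]
    sets = {
        ct: class_interval_set(ocrs, classes)
        for ct, ocrs in ocrs_by_cell_type.items()
    }
    out: dict[tuple[str, str], float] = {}
    for a in sets:
        for b in sets:
            out[(a, b)] = sets[a].jaccard(sets[b])
    return out
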