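"""Allele-aware PWM scanning at proxy positions.

For each candidate causal variant sitting in open chromatin, every
window covering the variant on both strands is scored with the log-odds
form of each TF's count matrix, once with the reference and once with
the alternative allele substituted.  The best window (by the better of
the two allele scores) is retained when it reaches a configurable
fraction of the matrix's maximum achievable score, and the reported
delta is ``score_ref - score_alt`` in bits: a positive delta means the
alternative allele destabilises the predicted binding site
("decreasing" stability), a negative delta means it strengthens it.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PWMRecord, VariantRecord

__all__ = [
    "MotifHit",
    "pwm_logodds",
    "max_logodds_score",
    "scan_variant",
    "scan_variants",
    "summarize_tf_disruption",
    "TFDisruptionSummary",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT_ORDER = [3, 2, 1, 0]  # A<->T, C<->G row swap

DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_MIN_SCORE_FRACTION = 0.8


@dataclass(frozen=True, slots=True)
class MotifHit:
    proxy_id: str
    tf_name: str
    matrix_id: str
    strand: str           # strand of the best-scoring match
    window_start: int     # genomic start of the matched window
    score_ref: float      # bits
    score_alt: float      # bits
    delta: float          # score_ref - score_alt, bits

    @property
    def direction(self) -> str:
        """Stability of the alternative allele relative to reference."""
        return "decreasing" if self.delta > 0 else "increasing"


def pwm_logodds(
    pwm: PWMRecord,
    background: Sequence[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Convert a count matrix to a log2-odds matrix (bits).

    Per column: p = (count + pseudocount) / (total + 4 * pseudocount);
    entry = log2(p / background).
    """
    bg = np.asarray(background if background is not None else [0.25] * 4, float)
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must sum to 1")
    counts = pwm.counts
    totals = counts.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError(f"{pwm.matrix_id}: zero-total column with zero pseudocount")
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    return np.log2(probs / bg[:, None])


def max_logodds_score(logodds: np.ndarray) -> float:
    """Best achievable window score: the sum of per-column maxima."""
    return float(logodds.max(axis=0).sum())


def _reverse_complement_matrix(logodds: np.ndarray) -> np.ndarray:
    return logodds[_COMPLEMENT_ORDER, ::-1]


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def _window_score(codes: np.ndarray, logodds: np.ndarray, start: int) -> float:
    L = logodds.shape[1]
    window = codes[start : start + L]
    if (window < 0).any():
        return float("-inf")
    return float(logodds[window, np.arange(L)].sum())


def scan_variant(
    context_seq: str,
    context_start: int,
    variant: VariantRecord,
    pwm: PWMRecord,
    background: Sequence[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
) -> MotifHit | None:
    """Score one variant against one PWM over all covering windows.

    ``context_seq`` is genomic sequence starting at ``context_start``
    (0-based) and must span at least L-1 bases on each side of the
    variant.  The reference allele must match the context.  Returns the
    best hit, or None when no window reaches ``min_score_fraction`` of
    the matrix's maximum achievable score with either allele.
    """
    pos = variant.pos0 - context_start
    L = pwm.length
    if pos < 0 or pos >= len(context_seq):
        raise ValueError(f"{variant.variant_id}: variant outside context")
    if context_seq[pos].upper() != variant.ref:
        raise ValueError(
            f"{variant.variant_id}: reference allele {variant.ref} does not "
            f"match context base {context_seq[pos].upper()} at {variant.pos0}"
        )
    logodds = pwm_logodds(pwm, background, pseudocount)
    matrices = {"+": logodds, "-": _reverse_complement_matrix(logodds)}
    best_score = max_logodds_score(logodds)
    threshold = min_score_fraction * best_score

    ref_codes = _encode(context_seq)
    alt_codes = ref_codes.copy()
    alt_codes[pos] = _BASE_INDEX[variant.alt]

    best: MotifHit | None = None
    best_key = float("-inf")
    lo = max(0, pos - L + 1)
    hi = min(len(context_seq) - L, pos)
    for start in range(lo, hi + 1):
        for strand, matrix in matrices.items():
            s_ref = _window_score(ref_codes, matrix, start)
            s_alt = _window_score(alt_codes, matrix, start)
            key = max(s_ref, s_alt)
            if key > best_key:
                best_key = key
                best = MotifHit(
                    proxy_id=variant.variant_id,
                    tf_name=pwm.tf_name,
                    matrix_id=pwm.matrix_id,
                    strand=strand,
                    window_start=context_start + start,
                    score_ref=s_ref,
                    score_alt=s_alt,
                    delta=s_ref - s_alt,
                )
    if best is None or best_key < threshold:
        return None
    return best


def scan_variants(
    variants: Iterable[VariantRecord],
    sequences: Mapping[str, str],
    pwms: Sequence[PWMRecord],
    background: Sequence[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
) -> list[MotifHit]:
    """Scan every variant against every PWM using genome sequences."""
    hits: list[MotifHit] = []
    for v in variants:
        seq = sequences.get(v.chrom)
        if seq is None:
            raise KeyError(f"{v.variant_id}: chromosome {v.chrom} not in genome")
        max_l = max(p.length for p in pwms)
        lo = max(0, v.pos0 - max_l + 1)
        hi = min(len(seq), v.pos0 + max_l)
        context = seq[lo:hi]
        for pwm in pwms:
            hit = scan_variant(
                context, lo, v, pwm, background, pseudocount, min_score_fraction
            )
            if hit is not None:
                hits.append(hit)
    return hits


def _round_half_up(value: float, digits: int = 1) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TFDisruptionSummary:
    per_tf: pd.DataFrame
    n_tfs: int
    threshold_counts: dict[float, int]
    threshold_percentages: dict[float, float]


def summarize_tf_disruption(
    hits: Sequence[MotifHit],
    expr: pd.Series | Mapping[str, float],
    tpm_thresholds: Sequence[float] = (1.0, 10.0),
    target_gene_expression: Mapping[str, float] | None = None,
) -> TFDisruptionSummary:
    """Per-TF summary of predicted motif disruption.

    For every TF with at least one hit: number of distinct proxies, mean
    delta (bits), the TF's own TPM (NaN when absent from the expression
    table, flagged ``expression_known=False``) and pass flags at each
    TPM threshold.  Global counts report how many of the predicted TFs
    clear each threshold, with the percentage of all predicted TFs
    rounded half-up to one decimal.

    ``target_gene_expression`` optionally maps proxy ids to the mean
    expression of their contacted target genes, averaged per TF.
    """
    if not hits:
        raise ValueError("no motif hits to summarise")
    if not isinstance(expr, pd.Series):
        expr = pd.Series(dict(expr), dtype=float)
    rows = []
    by_tf: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_tf.setdefault(h.tf_name, []).append(h)
    for tf in sorted(by_tf):
        tf_hits = by_tf[tf]
        tpm = float(expr[tf]) if tf in expr.index else float("nan")
        known = tf in expr.index
        target_expr = float("nan")
        if target_gene_expression is not None:
            vals = [
                target_gene_expression[h.proxy_id]
                for h in tf_hits
                if h.proxy_id in target_gene_expression
            ]
            if vals:
                target_expr = float(np.mean(vals))
        row = {
            "tf_name": tf,
            "n_proxies": len({h.proxy_id for h in tf_hits}),
            "mean_delta": float(np.mean([h.delta for h in tf_hits])),
            "tpm": tpm,
            "expression_known": known,
            "mean_target_expression": target_expr,
        }
        for thr in tpm_thresholds:
            row[f"tpm_gt_{thr:g}"] = bool(known and tpm > thr)
        rows.append(row)
    per_tf = pd.DataFrame(rows)
    n_tfs = len(per_tf)
    counts = {
        float(thr): int(per_tf[f"tpm_gt_{thr:g}"].sum()) for thr in tpm_thresholds
    }
    pcts = {
        thr: _round_half_up(100.0 * cnt / n_tfs) for thr, cnt in counts.items()
    }
    return TFDisruptionSummary(per_tf, n_tfs, counts, pcts)
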