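"""Statistical comparisons for the pipeline.

Covers the rank-sum enrichment of expression for promoter-connected
genes, chromatin-state fold enrichment against a genome-fraction null,
hypergeometric gene-set overlap, and the qPCR/secretion-assay statistics
(DDCt normalisation and the paired t test).

The rank-sum test enumerates the exact permutation distribution for
small tie-free samples (n1 + n2 <= 10) and otherwise uses the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import IntervalSet
from .io import log2_tpm1

__all__ = [
    "RankSumResult",
    "StateEnrichment",
    "OverlapTestResult",
    "PairedTResult",
    "rank_sum_test",
    "expression_contact_comparison",
    "chromhmm_enrichment",
    "geneset_overlap_test",
    "qpcr_ddct",
    "paired_t_test",
    "format_pvalue",
]

EXACT_MAX_N = 10
P_FLOOR = 2.2e-16


def format_pvalue(p: float) -> str:
    """Conventional text rendering with the double-precision floor."""
    if p < P_FLOOR:
        return "< 2.2e-16"
    return f"{p:.4g}"


@dataclass
class RankSumResult:
    u: float                # Mann-Whitney U of the first sample
    p_two_sided: float
    p_greater: float        # one-sided: first sample tends larger
    n1: int
    n2: int
    median1: float
    median2: float
    method: str             # "exact" | "normal"

    @property
    def direction(self) -> str:
        return "greater" if self.median1 > self.median2 else (
            "less" if self.median1 < self.median2 else "equal"
        )


def _exact_rank_sum(x: np.ndarray, y: np.ndarray) -> RankSumResult:
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    order = np.argsort(combined)
    ranks = np.empty(len(combined))
    ranks[order] = np.arange(1, len(combined) + 1)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    # distribution of U over all C(n, n1) assignments of ranks to group 1
    all_ranks = np.arange(1, n1 + n2 + 1)
    us = [
        sum(c) - n1 * (n1 + 1) / 2 for c in combinations(all_ranks, n1)
    ]
    us = np.asarray(us)
    p_le = float((us <= u_obs).mean())
    p_ge = float((us >= u_obs).mean())
    p_two = min(1.0, 2.0 * min(p_le, p_ge))
    return RankSumResult(
        u_obs, p_two, p_ge, n1, n2,
        float(np.median(x)), float(np.median(y)), "exact",
    )


def _normal_rank_sum(x: np.ndarray, y: np.ndarray) -> RankSumResult:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankSumResult(
            u, 1.0, 1.0, n1, n2,
            float(np.median(x)), float(np.median(y)), "normal",
        )
    sd = math.sqrt(var)
    z_two = max(0.0, abs(u - mu) - 0.5) / sd
    p_two = min(1.0, 2.0 * float(sps.norm.sf(z_two)))
    z_gt = (u - mu - 0.5) / sd
    p_gt = float(sps.norm.sf(z_gt))
    return RankSumResult(
        u, p_two, p_gt, n1, n2,
        float(np.median(x)), float(np.median(y)), "normal",
    )


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Unpaired two-sample rank-sum (Mann-Whitney U) test.

    Exact enumeration when n1 + n2 <= 10 with no ties, else normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    if len(combined) <= EXACT_MAX_N and no_ties:
        return _exact_rank_sum(x, y)
    return _normal_rank_sum(x, y)


def expression_contact_comparison(
    expr: pd.DataFrame | pd.Series,
    connected_genes: Iterable[str],
    cell_type: str | None = None,
) -> RankSumResult:
    """Rank-sum comparison of log2(TPM+1) between genes whose promoter
    contacts open chromatin and all remaining genes in the table.

    Genes in ``connected_genes`` absent from the expression table are
    skipped.  The first sample of the result is the connected group, so
    ``p_greater`` is the one-sided p for higher expression of connected
    genes; the two-sided p is also reported.
    """
    if isinstance(expr, pd.DataFrame):
        if cell_type is None:
            if expr.shape[1] != 1:
                raise ValueError("cell_type required for a multi-column table")
            series = expr.iloc[:, 0]
        else:
            series = expr[cell_type]
    else:
        series = expr
    connected = [g for g in connected_genes if g in series.index]
    if not connected:
        raise ValueError("no connected genes found in the expression table")
    connected_set = set(connected)
    others = [g for g in series.index if g not in connected_set]
    if not others:
        raise ValueError("no unconnected genes left in the expression table")
    x = log2_tpm1(series.loc[connected].to_numpy())
    y = log2_tpm1(series.loc[others].to_numpy())
    return rank_sum_test(x, y)


@dataclass
class StateEnrichment:
    state: str
    observed_bp: int
    state_bp: int
    expected_fraction: float
    fold: float
    log2_fold: float


def chromhmm_enrichment(
    query, segmentation: pd.DataFrame, genome_size: int
) -> list[StateEnrichment]:
    """Fold enrichment of a query region set in each chromatin state.

    For state s the null expectation is the state's genome fraction:
    ``fold = (overlap / |query|) / (|s| / genome_size)``.  States with
    zero overlap are reported with a -inf log2 fold.
    """
    if not isinstance(query, IntervalSet):
        query = IntervalSet.from_intervals(query)
    q_bp = query.total_bp()
    if q_bp == 0:
        raise ValueError("empty query region set")
    out: list[StateEnrichment] = []
    for state, group in segmentation.groupby("state", sort=True):
        state_set = IntervalSet.from_tuples(
            (r.chrom, int(r.start), int(r.end))
            for r in group.itertuples(index=False)
        )
        s_bp = state_set.total_bp()
        overlap = query.intersection_bp(state_set)
        expected = s_bp / genome_size
        fold = (overlap / q_bp) / expected if expected > 0 else float("nan")
        log2_fold = math.log2(fold) if fold > 0 else float("-inf")
        out.append(
            StateEnrichment(str(state), overlap, s_bp, expected, fold, log2_fold)
        )
    return out


@dataclass
class OverlapTestResult:
    overlap: int
    p_one_sided: float
    n_hits: int
    n_reference: int
    n_universe: int

    @property
    def table(self) -> np.ndarray:
        """2x2 contingency table (hit x reference membership)."""
        a = self.overlap
        b = self.n_hits - a
        c = self.n_reference - a
        d = self.n_universe - self.n_hits - c
        return np.array([[a, b], [c, d]])


def geneset_overlap_test(
    hits: Iterable[str], reference: Iterable[str], universe: Iterable[str]
) -> OverlapTestResult:
    """One-sided (enrichment) hypergeometric test of gene-set overlap.

    Upper-tail probability of observing at least the seen overlap when
    ``hits`` are drawn from ``universe`` without replacement.
    """
    hits, reference, universe = set(hits), set(reference), set(universe)
    if not hits <= universe or not reference <= universe:
        raise ValueError("hits and reference must be subsets of the universe")
    k = len(hits & reference)
    m, big_k, n = len(universe), len(reference), len(hits)
    p = float(sps.hypergeom.sf(k - 1, m, big_k, n))
    return OverlapTestResult(k, min(1.0, p), n, big_k, m)


def qpcr_ddct(
    ct: pd.DataFrame, reference_sample: str
) -> pd.DataFrame:
    """Relative expression by the DDCt method.

    ``ct`` columns: ``sample``, ``target_ct``, ``control_ct``.  Per
    sample: dCt = target - control; ddCt = dCt - dCt(reference);
    relative expression = 2**(-ddCt), so the reference maps to 1.0.
    """
    required = {"sample", "target_ct", "control_ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if ct["control_ct"].isna().any() or ct["target_ct"].isna().any():
        raise ValueError("missing Ct value for at least one sample")
    out = ct.copy()
    out["dct"] = out["target_ct"] - out["control_ct"]
    ref_rows = out[out["sample"] == reference_sample]
    if ref_rows.empty:
        raise ValueError(f"reference sample {reference_sample!r} not in table")
    ref_dct = float(ref_rows["dct"].mean())
    out["ddct"] = out["dct"] - ref_dct
    out["relative_expression"] = 2.0 ** (-out["ddct"])
    return out


@dataclass
class PairedTResult:
    t: float
    p_two_sided: float
    mean_difference: float
    percent_change: float
    df: int
    degenerate: bool


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Paired two-sided t test on the differences y - x.

    ``percent_change`` is 100 * (mean(y) - mean(x)) / mean(x).  Zero
    variance of the differences is flagged degenerate, with p forced to
    1 when the mean difference is zero and 0 otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = y - x
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    pct = 100.0 * (float(y.mean()) - float(x.mean())) / float(x.mean())
    if sd == 0.0:
        if mean_d == 0.0:
            return PairedTResult(0.0, 1.0, 0.0, pct, n - 1, True)
        t = math.inf if mean_d > 0 else -math.inf
        return PairedTResult(t, 0.0, mean_d, pct, n - 1, True)
    t = mean_d / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedTResult(float(t), min(1.0, p), mean_d, pct, n - 1, False)
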