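# Methods

## Coordinate and fragment model

All coordinates are 0-based half-open (BED-native); GTF-like gene
tables and VCF-like variant tables are 1-based on disk and converted on
read. Chromosomes are digested at every occurrence of the restriction
motif (default `GATC`, the DpnII site), with the fragment boundary at
the first base of each occurrence; the fragments tile each chromosome
exactly. The cut convention is arbitrary in principle — any consistent
choice preserves every downstream invariant — and ours is documented
rather than inferred. Four-fragment bins are tiled (non-overlapping)
from each chromosome's first fragment, so every fragment belongs to
exactly one bin; anchoring bins on baited fragments would be equally
defensible, but tiling is deterministic and keeps the partition
invariant trivially checkable.

Promoter windows cover 1500 bp transcriptionally upstream and 500 bp
downstream of the TSS. On the minus strand the mirrored half-open span
is `[tss − 499, tss + 1501)`, obtained by enumerating which bases lie
≤ 1500 bp upstream / ≤ 500 bp downstream in transcription direction.
Windows are truncated at chromosome bounds. Nearest-gene queries
measure TSS distance from the sentinel position and break ties by
lexicographically smallest gene id, for reproducibility.

## Contact map

Contacts arrive pre-called (the interaction-calling model itself is out
of scope) and are filtered at score ≥ 5, applied inclusively. Ends are
labelled bait when one of their fragments/bins overlaps a promoter
window; both-bait rows are flagged and attributed to both promoters'
contact lists, with each end serving as the other promoter's
interacting region. Contact distances are measured midpoint-to-midpoint
— robust across the two resolutions, where end widths differ by ~4× —
and only cis contacts enter the distance distribution; trans rows are
counted separately because their distance is undefined. Distance
summaries can be computed per resolution or pooled, since it is not
obvious which convention a given study used.

## OCR atlas

Consensus calling pools all replicate peaks, clusters them per
chromosome by single-linkage ≥ 1 bp overlap, and emits the union
interval of each cluster supported by at least two distinct replicates.
The union (rather than intersection) is a conservative region capture
that is deterministic and needs no summit information; it can only
widen, never split, as replicates are added, giving the monotonicity
property the tests assert. Classification gives promoter overlap
precedence over PIR overlap (a promoter OCR may still carry a secondary
PIR flag), so the three classes partition the atlas. Cross-cell-type
similarity is the Jaccard index over merged nucleotide sets; because
the exact region set behind such comparisons is ambiguous in practice,
both the cRE variant (promoter OCRs + PIR-OCRs, default) and the
PIR-OCR-only variant are provided behind a flag.

## Variant-to-gene mapping

Proxy expansion is strictly `r² > 0.8`, and each sentinel participates
as its own proxy with r² = 1. Gene implication requires the proxy to
lie inside an OCR — open chromatin, not merely a PIR — and then fires
through two routes: promoter-window overlap of the OCR, and overlap of
the OCR with a contact's other end (carrying the contact's resolution).
Implications from the two resolutions are unioned, with resolution
recorded per record. Records are deduplicated per
(sentinel, gene, cell type, mechanism), so one gene is never counted
twice for one signal through the same route. Every record is auditable:
replaying proxy ∈ OCR, OCR ∩ promoter/other-end, and bait = promoter
succeeds by construction, and the synthetic-data audit does exactly
this replay.

Cross-cell-type summaries count unique genes per cell type and unique
genes in the union; percentages are of the union, rounded half-up to
one decimal, and the exclusive/shared strata sum to the union size.

## Statistics

The rank-sum test enumerates the exact permutation distribution of U
when n₁ + n₂ ≤ 10 and the data are tie-free, and otherwise uses the
normal approximation with tie and continuity corrections; the two paths
agree to |Δp| ≤ 0.02 at n₁ = n₂ = 10 on random data. The expression
comparison operates on log₂(TPM + 1) and reports the one-sided
direction alongside the two-sided p, covering either reading of how
such comparisons are reported. The "promoter-connected" gene group is
defined at fragment (1frag) resolution: a gene counts as connected when
one of its fragment-level contact other-ends overlaps a PIR-OCR.
p-values below 2.2 × 10⁻¹⁶ are printed as "< 2.2e-16" while the raw
float is returned.

Chromatin-state enrichment uses a genome-fraction null —
`fold = (overlap/|query|) / (|state|/genome)` — chosen over shuffling
for determinism (zero-overlap states report −inf log₂ fold). The folds
satisfy a conservation identity: weighted by state fraction of the
covered genome, their mean is 1. Gene-set overlap uses the one-sided
(upper-tail) hypergeometric test, cross-checked against a permutation
oracle in the tests. ΔΔCt maps the reference sample to exactly 1.0;
the paired t test flags zero-variance differences as degenerate rather
than dividing by zero, and percent change is computed on group means
(biological-replicate means in the knockdown design).

## Motif disruption

Count matrices become log₂-odds matrices in bits with pseudocount 0.25
per cell and a uniform background by default (both exposed). For each
variant, all windows covering it on both strands are scored with the
reference and alternative alleles; the window with the best
either-allele score is reported when it reaches 80% of the matrix's
maximum achievable score (the retention threshold is a flag — published
analyses of this kind rarely state their exact tool settings, so a
standard best-window scheme is adopted and documented). Δ =
score(ref) − score(alt); Δ > 0 is labelled "decreasing" stability for
the alternative allele. Δ is exactly antisymmetric under allele swap,
and reverse-complement scanning yields identical best scores. Motif
hits are required only to sit on an open proxy, not to overlap the OCR
beyond the variant itself.

## Synthetic data

The generator emulates the *processed* outputs of a four-cell-line
promoter Capture-C / ATAC / RNA-seq study at desk scale, with every
stage driven by one integer seed (same config ⇒ byte-identical bundle;
the RNG is numpy's PCG64 via `default_rng`).

Default study conditions: two chromosomes (1.2 Mb + 0.8 Mb), ~400 bp
mean fragment length (truncated exponential, 50–1200 bp), 120 genes
with ≥ 8 kb TSS spacing, four cell types × three ATAC replicates,
250 consensus peaks and 300 significant contacts per cell type plus a
30% sub-threshold fraction, log-normal contact distances with a 130 kb
mean (σ = 0.8, matching the order of published distance means),
bait-to-bait share 15% (published studies report 10–29%), 30 sentinels
with ~4 proxies each, 12 planted variant→OCR→contact→gene chains (25%
via direct promoter-OCR overlap), a one-log₂-unit TPM shift for
promoter-connected genes, a five-state ChromHMM-style segmentation and
four synthetic 9-bp count matrices. These sizes are roughly two orders
of magnitude below the real study's (tens of thousands of OCRs and
contacts) and were chosen so a full bundle generates and analyses in
well under a second.

Genome sequence is drawn from {A, C, T} with `GATC` written at planned
cut sites, so digestion is exercised end to end. This also makes motif
recovery structural: guanine occurs in background only as a cut site,
and the four consensi each require guanines on both strands that
neither a GATC context nor the variant's single substituted allele can
supply — verified by a brute-force single-substitution checker — so a
full-score window cannot arise away from a planted site at the default
80% retention threshold (one mismatch in a 9-mer scores far below it).

Planted chains live in reserved zones (promoter-window clearance 5.5 kb
for chain OCRs, 5 kb padding around zones) and all background elements
— peaks, variants, contact other-ends, including their 4-fragment bins
— are rejection-sampled away from them, while negative controls
(high-LD proxies in closed chromatin, sub-threshold contacts, dropout
of unforced peaks) are generated alongside. Exact recovery
(sensitivity = precision = 1.0 for the V2G chains, precision =
recall = 1.0 for planted disrupting proxies) is therefore a designed
property of a fresh bundle, and `audit_truth` replays every chain
through the real pipeline operations to confirm it.

What the generator does **not** emulate: realistic base composition or
mappability, read-level noise (inputs are post-peak-calling and
post-interaction-calling), LD structure beyond the proxy table,
overlapping genes or multiple TSSs per gene, and co-located regulatory
elements (reserved zones keep planted signals separable). Passing tests
therefore demonstrate correctness of the mapping logic and calibration
of the statistics under clean, internally consistent inputs — not
robustness to the artefacts of real sequencing data.

## Numerical choices and degenerate inputs

Score filtering is inclusive (≥ 5). Jaccard of two empty sets is 0.
Empty query sets, empty expression groups and unmappable contact ends
raise instead of returning silent defaults. Percentages use half-up
rounding to one decimal (`Decimal`, not banker's rounding). Rank-sum
with zero variance (all values tied) reports p = 1. The motif scanner
refuses a reference allele that contradicts the supplied sequence,
treating it as a coordinate/allele bookkeeping error.

## Problem sizes used in the checks

The recovery sweep runs 20 seeds of the default bundle; expression
calibration uses a single-cell-type config (2.4 Mb, 280 genes, 130
connected) over 200 null datasets (KS uniformity at α = 0.01) and 100
shifted datasets (detection rate ≥ 95% at α = 0.05); the interval
oracle comparison uses 1000 random fixtures against per-nucleotide
bitmaps; the hypergeometric test is checked against 10,000 resamples.
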