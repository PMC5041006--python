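# Methods

## The data model

The unit of analysis is a genome × COG gene-copy matrix `A`: entry `A[i, j]`
is the number of protein-coding genes of genome *i* assigned to orthologous
group *j*. A genome's *gene family* in COG *j* is that set of genes; its size
is `A[i, j]`. Zeros mean the family is absent and are ignored by every
per-genome statistic. Genomes with no COG-annotated gene at all carry no
information and are rejected at validation time. Two plain-text formats are
supported (dense TSV and a zero-free triplet TSV); the triplet format cannot
represent all-zero columns or a column order, so its round trip is identity
on the stored entries rather than on axis order.

## Per-genome measures of gene-family extension

With family sizes `s_1 .. s_{K'}` (all ≥ 1), `P` the number of families of
size ≥ 2 and `P2` the number of size > 2:

* `ave = (Σ s_j) / K'` — mean family size, singletons included. An option
  excludes singletons for comparison with older work that averaged over
  paralogous families only; the published Mycoplasma worked value (1.2 for
  *M. gallisepticum*, 489 copies over 410 families) confirms the
  singletons-included convention is the operative one.
* `p.i. = P / K'` — the paralog index, the fraction of families touched by
  duplication. Lies in [0, 1].
* `mp = P2 / P` — the multi-paralog index, the weight of larger families
  among duplicated ones. Undefined when `P = 0` (an all-singleton genome);
  such genomes are reported as missing, excluded from mp regressions, and
  can never be flagged as mp-atypical. In batch output the value is NaN.

Binned family-size tables (counts of families of size 1 / 2 / 3 / >3 plus
the total number of COG-annotated proteins NC) determine `K'`, `P`, `P2`,
`p.i.` and `mp` exactly, and `ave` as `NC / K'`; `profile_from_histogram`
implements this so published distribution tables can be used directly.

## Consensus ranking

Each COG induces a partial ranking of the genomes that carry it (fewer
copies = lower rank; ties and absences neutral). The Kemeny objective of a
total order is the summed number of pairwise contradictions against all
COG partial rankings; the Kemeny-optimal order minimises it, but finding it
is NP-hard, so the working solver is a sorting heuristic:

1. shuffle the genomes (each restart draws its own child seed from the
   master seed via `numpy` seed spawning);
2. repeat full adjacent-pair passes: for neighbours `g1` (earlier) and
   `g2`, count the COGs present in both where each has strictly more
   copies; swap when `g1` wins more (its families are bigger more often);
   a tied vote leaves the pair alone;
3. stop when a pass makes no swap, or after N passes (the pairwise majority
   relation may contain cycles, so convergence is not guaranteed; the order
   standing at the cap is kept).

Ten restarts (the default) yield a mean rank and standard deviation per
genome. The *consensus* is the order with the smallest Kemeny objective
among the ten restart end states and the mean-rank-sorted order, ties
broken toward the lexicographically smallest order. The objective-based
choice matters when the majority relation has ties or cycles: single
restarts can stall in locally stable orders (every adjacent pair satisfies
the majority vote while long-range inversions persist), and the plain
mean-rank sort inherits that noise; selecting the candidate that actually
minimises the objective is both closer to the Kemeny target and what makes
the packaged 3-genome example (whose A–C majority vote is exactly tied)
reproduce its published ranks 1/2/3 for every seed.

An exhaustive solver over all permutations (≤ 9 genomes) provides the
exact optimum for testing; ties go to the lexicographically smallest
optimal order so the oracle is deterministic. Tests verify the oracle
dominates the heuristic on 100 random instances and coincides with it when
the majority relation is a clean total order.

`rank_sd` uses the population convention (ddof = 0) so a single restart
reports 0 rather than NaN.

## Size trends and atypical genomes

Each measure is regressed on genome size (Mbp) with polynomials of degree
1–10. Fitting uses a centered/scaled predictor (numpy's mapped-domain
polynomial basis) to keep degree-10 Vandermonde systems well conditioned;
coefficients are reported in both the internal and the raw power basis.
Model selection minimises `n·ln(RSS/n) + penalty·(degree + 2)` with
penalty 2 (AIC, default) or `ln n` (BIC) — the additive Gaussian-likelihood
constants cancel across degrees and are dropped; the residual-variance
parameter is counted. Ties go to the smaller degree. An RSS below
`1e-12·n` is treated as numerically exact and short-circuits selection to
the smallest such degree, avoiding `ln 0`. The degree sweep requires
`n ≥ max(degree) + 2` points; smaller samples must pass a narrower degree
range (so a 3-genome input is refused with a clear error rather than
silently fit with a line).

A note on criteria: AIC is not a consistent selector over a nested degree
sweep — with seven larger candidates above the true degree it keeps the
true one only ~70% of the time regardless of sample size, which is the
expected behaviour, not a defect. Where exact degree recovery is the goal
(as in the cubic-truth simulation test) BIC is the appropriate criterion
and recovers the planted degree essentially always at n = 500.

Atypical genomes are the boxplot outliers of the residuals: quartiles by
Tukey hinges (halves include the median when n is odd; a flag switches to
linear-interpolation quantiles), `IQR = Q3 − Q1`, whiskers clamped to the
data range at `Q1 − 1.5·IQR` and `Q3 + 1.5·IQR`, outliers strictly outside
the whiskers, labelled above/below the trend. Under Gaussian residuals
this flags ~0.7% of points. Detection is translation-equivariant, and
`fitted + residual` reconstructs the observation to machine precision.

A piecewise-linear alternative (grid-searched breakpoint, two independent
least-squares lines, ≥ 4 points per segment) is provided for trends whose
slope changes between small and large genomes.

## Correlations between measures

All four measures trend with genome size, so pairwise association is
summarised by the first-order partial Kendall tau-b given size:
`τ_xy·z = (τ_xy − τ_xz τ_yz) / √((1−τ_xz²)(1−τ_yz²))`, every term being
tie-corrected tau-b. The p-value uses the two-sided normal approximation
with the no-tie variance `2(2n+5)/(9n(n−1))`; at the intended sample sizes
(hundreds to ~1500 genomes) the approximation is accurate, and the tests
validate tau itself against an O(n²) pair-count oracle rather than relying
on p-values. A control perfectly rank-correlated with either variable
makes the denominator vanish and raises an explicit degenerate-control
error. Tau-b rather than tau-a because genome sizes and the measures
contain ties at working precision. Rows with undefined mp are dropped
pairwise, with the per-pair n reported.

## The synthetic generator

`SimulationConfig` defaults define the study conditions for all simulation
tests: 300 genomes, sizes uniform on 0.5–10 Mbp, 2000 COGs. COG presence is
logistic in genome size (≈ 0.16 at the small end, ≈ 0.66 at the large end),
and a present family's size is `1 + Geometric`, with mean excess
`0.1 + 0.08·(size − 0.5)` copies — so mean family size runs ≈ 1.1 → 1.9
and the paralog index ≈ 0.09 → 0.46 across the size range, matching the
magnitudes seen in broad prokaryotic surveys. The COG universe is kept in
the thousands deliberately: the sorting heuristic's pairwise majority
votes only carry information when small genomes still share tens of
families, as they do in real COG collections; starving the universe
(hundreds of COGs) makes most votes exact ties and freezes the restart
shuffles. 5% of genomes are planted as atypical by multiplying the mean
excess by 2 (alternately above and below trend); scaling the excess rather
than the mean keeps family sizes on {1, 2, ...} and mp defined. A genome
that draws no COG at all is resampled once, then the configuration is
rejected as infeasible. Everything is reproducible bit-for-bit from the
seed.

What the generator does *not* emulate: phylogenetic correlation between
genomes (each genome is drawn independently), any distinction between
duplication and horizontal transfer, ORFans, or a biologically fitted
family-size law (the shifted geometric is a convenience with the right
qualitative tail behaviour). Passing recovery tests therefore show the
pipeline detects trend-displaced genomes under independent sampling — not
that it would separate lineage effects from genuine atypicality in real
data.

## End-to-end pipeline

`run_full_analysis` wires the stages (profiles → ranking → per-measure
trend + boxplot outliers → partial-correlation table) and writes TSVs plus
a JSON manifest recording library versions, the seed, a hash of the
analysis-relevant configuration (the output directory is excluded), and
dropped-genome counts. Reruns with identical inputs and seed are
byte-identical. Stage failures carry the stage name and the CLI maps them
to distinct exit codes (2 input, 3 numerical).

## Problem sizes used in the tests

Worked-example checks are exact arithmetic on 3×5 and 32-genome tables.
Simulation-based checks use: 100 random 6-genome instances for the
exact-vs-heuristic comparison; n ≤ 200 vectors for the tau oracle; 50
seeds × n = 500 for degree recovery; 20 seeds × 300 genomes × 2000 COGs
for planted-outlier recovery (a planted genome counts as recovered when
any of the four measures flags it; false positives are pooled the same
way). The whole suite runs in well under a minute on one CPU.
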