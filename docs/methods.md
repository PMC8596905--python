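# Methods

## Problem and data model

Input is a pair of cell-by-bin matrices over fixed-width genomic windows: raw
read counts `Y` (non-negative integers, `m` bins × `n` cells) and a normalized
matrix `Ŷ` giving each cell's expected coverage per bin *if the bin were
diploid*. Normalization is delegated: users may supply a matrix produced by
any cross-cell normalization model, or use the built-in rank-1 baseline
`Ŷ[i,j] = b_i·s_j` (per-bin mean over reference cells × per-cell library-size
factor). The baseline deliberately models no GC/mappability effects; it is
adequate whenever bin-level biases are shared across cells, which is exactly
when they cancel in the ratio `Y/Ŷ`. Zero entries of `Ŷ` are floored at
`eps = 1e-8` so ratios are defined. Bin coordinates are 1-based inclusive
internally; BED input/output converts at the boundary.

## Objective

A segmentation `S` of one chromosome into `ℓ` segments is scored by

```
β(S) = log(L_τ/L_0) − log C(m, ℓ−1) − (ℓ−1)(κ1 − κ2).
```

The first term is the generalized log-likelihood ratio of the segmented
Poisson model against the all-diploid null. Under the Poisson model
`Y[i,j] ~ Pois(Ŷ[i,j]·c/2)` with one shared integer copy number
`c = ⌊2X/X̂⌉` per (segment, cell), the ratio sums per bin, which for segment
`s_k` collapses to

```
Σ_j |s_k| · [ X̂_{k,j}(1 − c_{k,j}/2) + X_{k,j} log(c_{k,j}/2) ]
```

with `X, X̂` the per-cell segment means. Two properties make this objective
well behaved: a diploid (c = 2) cell-segment contributes exactly zero, and a
split that changes no cell's rounded copy number changes the log-likelihood by
exactly zero — so the penalty alone decides against uninformative splits.

The segment-length factor `|s_k|` is essential: without it the contribution of
an aberrant segment would not grow with its extent, and splitting any
non-diploid segment in half would roughly double its (positive) score,
rewarding arbitrary over-segmentation. Summation runs over both segments and
cells.

Degenerate case `c = 0` (homozygous deletion): `log(0)` is replaced by
`log(log_floor/2)` with `log_floor = 1e-4` — a finite but strong penalty,
roughly one lost unit of score per expected read. Rounding is half away from
zero (`2X/X̂ = 2.5 → 3`); ties at exact half-integers are a measure-zero event
on real data but the convention is fixed and tested. The copy-number cap
(`cn_cap = 10`, matching the usual "≥ 10" heatmap bucket) applies to
*reported* calls only; the likelihood always uses the uncapped rounded value.

## Penalty constants

Only the difference `κ1 − κ2` enters the score. Each added breakpoint grants
all `n` cells a new copy state — about `n` effective parameters — so a fixed
O(1) per-breakpoint charge cannot work at realistic cell counts: per-bin
Poisson fluctuations flip individual cells' rounded copy numbers with
appreciable probability (the per-bin ratio has standard deviation
`√(2c/depth)`, e.g. ≈ 0.37 for c = 7 at 100 reads/bin), and the log-likelihood
harvested from such flips by an extra segment sums over cells to tens of units
while the combinatorial term costs only `log((m−ℓ)/ℓ)` ≈ 2–3. The default is
therefore the BIC-style half-unit per effective parameter, `κ1 = n/2`,
`κ2 = 0`, resolved when a matrix is at hand (`MBICParams.kappa1 = None`
sentinel). Measured on the default design, the spurious-gain floor is ≈ 15–25
units per extra segment and the weakest planted boundary is worth several
hundred, so the working range for the penalty is wide and `n/2 = 50` sits
comfortably inside it. Explicit `κ` values are honored everywhere and the
small-instance oracle tests exercise arbitrary constants.

## Dynamic program

`L(k, i)`, the maximal log-likelihood of partitioning bins `0..i` into `k`
segments, satisfies `L(k,i) = max_{i'} L(k−1, i') + l(i'+1, i)` with `l` the
single-segment table built from prefix sums (`O(m²n)`). Since the penalty
depends only on `k`, it is constant within a DP layer and cannot change any
argmax; it is added per layer, `β(k,i) = L(k,i) − log C(m, k−1) −
(k−1)(κ1−κ2)`, which reconciles the per-transition recursion with the
ℓ-dependent penalty without multiple counting. `k* = argmax_k β(k, m−1)`;
ties break toward the smaller split position and the smaller `k`, so output is
deterministic. The maximum segment count per chromosome defaults to
`K = min(m, 15)`. Chromosomes are segmented independently. Total cost
`O(m²n + m²K)`; the acceptance script measures the empirical doubling ratio
(~2.7–3.7× for 2× bins at these sizes, interpreter overhead keeping it below
the asymptotic 4).

Correctness of the engine is established against a brute-force reference
(`scseg.reference`) that enumerates every turning-point subset and scores it
directly with the objective: on hundreds of random instances (m ≤ 12) the DP
equals the enumeration maximum for every layer `k` and its backtracked
turning points achieve it.

A caution on a tempting invariant: "refining a segmentation never lowers the
likelihood" is only approximately true under hard rounding. The integer
maximizer of the per-segment term switches at `2X/X̂ = 1/log((c+1)/c)`
(≈ c + 0.47), not at c + 0.5, so a refined part whose mean ratio lands in that
narrow band can score marginally below its parent. The property tests assert
monotonicity on count data with integer planted ratios, where it holds.

## Synthetic data generator

The generator emulates the standard spike-in design: one chromosome
(default chr22, 70 bins of 500 kb — bin width is free since only the bin
count matters to the algorithm), 100 cells of which half are diploid normals,
and 4 tumor subclones of near-equal size sharing 7 planted segments. Clone
profiles take integer copy numbers in `{1..6}` (the realistic aneuploidy
range), change state at every planted boundary (shared boundaries being the
union of clone breakpoints), and contain at least one non-diploid segment;
planted segments span at least two bins when the bin budget allows. Planted
profiles are drawn per seed rather than fixed, so recovery claims are about
the design, not one matrix.

Noise ("10 % random noise") is applied per (cell, segment) block: each block
is independently replaced by a uniformly drawn wrong copy number in
`{0..10}` with probability `noise_rate`, so the expected fraction of perturbed
*entries* equals `noise_rate` while perturbations remain piecewise constant on
planted segments. Entry-wise noise would be a different experiment: an
isolated wrong-copy bin is a genuine single-bin signal that any
likelihood-based optimizer must split out, making perfect precision
unattainable by construction.

Counts: `raw[i,j]` has mean `(cn/2)·depth·b_i·s_j` with mild log-normal bin
effects `b_i` and cell factors `s_j` (σ = 0.1 each); `norm[i,j] =
depth·b_i·s_j` is the matching diploid expectation, so `E[2·raw/norm] = cn`.
The `dispersion` parameter is the variance-to-mean ratio: 1 = Poisson
(default), 0 = deterministic rounding of the mean (the vanishing-noise limit
used for exact round-trip checks), > 1 = negative binomial, (0,1) = binomial
thinning. Default depth is 100 reads/bin — shallow whole-genome coverage of
the kind droplet-based CNV assays produce at 500 kb bins. All randomness
derives from a single integer seed (separate child streams for truth and
counts), so every dataset is exactly reproducible.

What the generator does *not* emulate: GC/mappability bias beyond the shared
`b_i` term, read-level artifacts (duplicates, mapping errors), doublets,
cell-specific breakpoints, and focal events below bin resolution. Passing
tests therefore demonstrate correctness of the optimization and calling
machinery under the stated count model, not robustness to every artifact of
real libraries.

## Evaluation suite

Turning-point accuracy matches found against planted positions greedily
within a bin tolerance (default 0 = exact); precision is over found points,
recall over planted ones, and an empty side scores 1 on its own ratio. Profile
agreement reports Pearson r (NaN-flagged for constant vectors) and RMSE over
shared bins. Cell clustering is agglomerative with Ward linkage on Euclidean
distances between copy-number vectors (the linkage is a configuration choice;
cluster count is user-supplied). External indices are adjusted Rand,
normalized mutual information, and the pair-counting Jaccard index
TP/(TP+FP+FN) over cell pairs. Aneuploidy flagging computes each cell's Gini
coefficient over its bin profile — scale-invariant, so counts need no prior
normalization — and flags cells above a cutoff (default 0.12) as tumor;
whether to feed it raw counts or called copy numbers is the caller's choice
(counts by default).

## Problem sizes and determinism

Default test and acceptance runs use the 100×70 design (single runs complete
in well under a second), a 27-run scenario grid (normal fraction ∈
{0.5, 0.7, 0.9}, clones ∈ {2, 4, 6}, segments ∈ {3, 7, 11}, three replicate
seeds), 200 random oracle instances at m ≤ 12, n ≤ 6, and runtime probes at
m = 150 vs 300 with n = 30. Every stochastic step is seeded; reruns are
byte-identical.

## Known limitations

- Breakpoints are shared across all cells; a private breakpoint in a rare
  clone is found only if its likelihood contribution outweighs the penalty.
- Integer copy states assume a diploid baseline; whole-genome-doubled cells
  are reported at their literal ratio (e.g. tetraploid = 4) without ploidy
  re-estimation.
- The Poisson likelihood understates overdispersion of real single-cell
  libraries; heavy overdispersion effectively lowers the signal-to-penalty
  margin.
- No quality-control filtering: cells and bins should be pre-filtered
  upstream.
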