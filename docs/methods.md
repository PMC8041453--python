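# Methods

This note documents the statistical model, the estimation and selection
procedures, the synthetic-data generators, and the numerical and design
choices made where the design was genuinely open.

## Model and estimation

The Rasch model assumes `P(X_vj = 1) = logistic(θ_v − β_j)` with person
ability `θ_v` and item difficulty `β_j`, responses independent given the
parameters. Item difficulties are estimated separately per group by
conditional maximum likelihood (CML): conditioning on each person's raw
score removes the ability parameters, leaving a likelihood in the
`ε_j = exp(−β_j)` through the elementary symmetric functions (ESFs)
`γ_r(ε) = Σ_{|x|=r} Π_j ε_j^{x_j}`. Persons with extreme raw scores (0 or
m) carry no conditional information and are dropped (reported in
`n_used`); an item answered in only one category within a group has no
CML estimate and raises an error naming the item.

**Optimisation.** Newton–Raphson on the conditional log-likelihood with
analytic gradient and Hessian, the first item's difficulty fixed at zero
during iteration and the result re-centred afterwards. The gradient is
`−s_j + Σ_r n_r π_jr`, where `s_j` is the item total, `n_r` the count of
persons at raw score `r`, and `π_jr = ε_j γ^{(j)}_{r−1} / γ_r` the
conditional probability of a correct response on item `j` at score `r`
(`γ^{(j)}` the ESFs with item `j` removed). The Hessian is minus the
conditional information, `I_jk = Σ_r n_r (π_jkr − π_jr π_kr)` with
diagonal `Σ_r n_r π_jr(1 − π_jr)`; for this conditional exponential
family observed and expected information coincide. Steps are damped by
halving until the likelihood improves; once the predicted quadratic gain
falls below the floating-point noise of the log-likelihood
(`1e−13 · (1 + |ll|)`), the full Newton step is taken without a line
search (the iteration is contractive there, and likelihood comparisons
below noise level are meaningless). Convergence: max-abs gradient below
1e−8, at most 100 iterations. Starting values are centred log-odds of the
item totals.

**ESF numerics.** ESFs are computed from mean-centred `β` (the scale
factor `exp(−r·mean)` is restored afterwards), which keeps intermediate
values inside double precision for test lengths up to ~100. All
leave-one-out and leave-two-out ESFs are built from prefix/suffix
generating-polynomial products combined by convolution: every coefficient
is nonnegative, so there is no cancellation and the results are accurate
to machine precision. Deflation (dividing the full generating polynomial
by `1 + ε_k t`) was rejected: its forward/backward recurrences lose up to
ten significant digits for mid-range `ε_k` at m = 80.

**Covariance.** The covariance of the estimates is the Moore–Penrose
inverse of the full conditional information, which equals the covariance
under the sum-to-zero restriction. Because the information's null space
is exactly the constant vector, the pseudo-inverse is computed as
`inv(I + a·11'/m) − 11'/(a·m)` with `a = trace(I)/m`; a spectral cutoff
(as in a generic `pinv`) occasionally misclassifies the near-null
eigenvalue and is not used. Restriction changes (`sum_zero` ↔
`first_zero`) are linear maps applied to both estimates and covariance.

## Anchor point selection

With per-group estimates `b1, b2` and distances
`d_j(c) = |b1_j − b2_j − c|`, the Gini index (rank form) and the CLF
criterion are evaluated over the candidate shifts
`{b1_j − b2_j : j = 1..m}` inside the search interval
`[min b1 − max b2, max b1 − min b2]`. Both criteria can have local maxima
only at candidates, so this sparse search is exact; a dense grid (default
1001 points) is traced solely for plotting. Property tests verify on
random instances that no point of a dense grid (step 1e−3, with the
candidates appended) beats the candidate-set maximum.

Numerical choices:

* Candidate shifts closer than 1e−12 are collapsed.
* `Σ d = 0` (perfect global alignment) defines `GI = 0` — the degenerate
  no-DIF case — and is logged.
* Ties at the optimum (within 1e−10) resolve to the candidate with the
  smallest |c|, deterministically. A tie between *adjacent* candidates
  under the CLF is the ordinary median plateau of a piecewise-linear
  objective with an even number of kinks and is only logged at debug
  level; any other tie is surfaced as a warning, since separated tying
  peaks signal a label-switching situation worth inspecting.
* The CLF exposes `ε ≥ 0` (`−Σ √(d² + ε)`) for fidelity to the original
  alignment formulation, but defaults to `ε = 0`: the grid search needs
  no smoothing, and with `ε = 0` the CLF optimum is a median of the
  candidate differences (verified against a direct median computation).

**Local optima.** A candidate is reported as a secondary local maximum
when the criterion value drops on both sides of it along the continuous
curve; the flanks are probed at the midpoints toward the neighbouring
candidates (or toward the interval ends for the outermost candidates).
This definition is deliberately curve-based rather than
candidate-neighbour-based: with candidates `{−0.75, 0}` in the one-DIF
toy, the secondary peak at −0.75 has a *larger* candidate neighbour yet
is a genuine local maximum of the curve, because the criterion dips
between the two candidates. Prominence is the height of the candidate
above the higher of its two flanking values (positive by construction).
Rank crossings of the Gini index occur exactly at these midpoints; the
criterion value there is tie-invariant, and the absence of off-candidate
maxima guarantees the flank comparison is decisive.

## Anchored Wald tests

Each item is tested with `t_j = (b1_j − b2_j − c)/se_j` against the
standard normal, two-sided, unadjusted by default (optional Bonferroni /
Benjamini–Hochberg flags exist but are off, matching the per-item 5%
convention of the simulation literature). When the shift comes from an
anchor set A — including the single-item anchor implied by a criterion
optimum — the standard errors are the diagonals of each group's
covariance re-expressed under the anchor restriction
(`V_jj + V_kk − 2V_jk` for a single anchor k). This propagates the
anchor's own sampling noise: without it the statistic has variance
`1 + Var(c)/se_j²` under the null and the criterion-based methods
over-reject by roughly a factor two (measured: ~9% at m = 20, n = 250
versus ~2% with the anchored variance). The anchor item itself is
reported with `t = 0, p = 1` (its restricted variance is zero and its
aligned difference exactly zero). Uncertainty in the *selection* of the
anchor (point or set) is not propagated — the anchor is treated as fixed
once chosen. `wald_test` called with a bare shift and no anchor set uses
the sum-to-zero diagonals, which is appropriate only for an externally
fixed shift.

## Classic anchor heuristics

Three baselines operate on the same fitted objects (no refitting; single-
anchor statistics are `t_{j,k} = (d_j − d_k)/se_j` with `d = b1 − b2`):

* **allother** — each item tested against the mean of all others; the
  four items with smallest |t| form the anchor.
* **mpt4** — from all single-anchor analyses, item j collects its m−1
  p-values; the threshold is the grand mean of all collected p-values;
  items are scored by how many of their p-values exceed it; top four win
  (ties: larger mean p, then lower index).
* **forward** — items ranked ascending by mean |t| over single-anchor
  analyses; the anchor grows along this ranking until it is longer than
  the number of currently significant non-anchor items.

The published descriptions of the latter two are sketches; the threshold
and stopping rule above are explicit deterministic operationalisations,
so baseline rates should be read as *this package's* versions of those
methods. All ties break by secondary score and then by lowest item index
for reproducibility. The anchor length of the constant methods is fixed
at four.

## Synthetic data

`generate_study1` emulates additive DIF: abilities standard normal
(focal mean shifted by `−impact`, default 0), difficulties equally spaced
on `[−2.5, 2.5]` by default, focal-group difficulties of DIF items
shifted by `+dif_size` (default 0.6 logits) or alternating `±dif_size`
for balanced DIF, responses Bernoulli under the Rasch model.
`generate_study2` emulates DIF induced by unaccounted multidimensionality:
a compensatory two-dimensional logistic model in which DIF items load
(default 1.0) on a secondary dimension whose focal-group mean exceeds the
reference mean by `secondary_gap` (default 1.0). These defaults are the
package's reference conditions, chosen as typical values in the DIF
simulation literature; they are configuration, not estimates.

Randomness: each replication's generator derives from
`SeedSequence(seed, spawn_key=(rep,))`, split into ability / secondary /
response streams. Consequently all methods see identical data within a
replication (paired comparisons), and the two-dimensional generator with
zero loadings reproduces the unidimensional null generator draw for draw
(a tested identity).

What the generators do **not** emulate: guessing or discrimination
differences (2PL/3PL behaviour), missing responses, local dependence,
polytomous items, or real-data impact/DIF mixtures. Passing simulation
tests therefore demonstrates correctness of the pipeline under the Rasch
/ M2PL generating models, not robustness to their violations.

**Scoring.** False alarm rate = flagged share of truly DIF-free items;
hit rate = flagged share of true DIF items (undefined without DIF items).
Label-switching scoring also evaluates the complementary labelling (DIF
set and complement swapping roles) and keeps whichever has the smaller
total error `FAR + (1 − HIT)`: when a majority item cluster is internally
invariant both alignments are equally valid. Aggregates are means of
per-replication rates with Monte-Carlo standard errors; replications with
failed estimation are logged and counted, never silently dropped.

## Problem sizes

The default runner performs 500 replications per scenario; the type-I
error check runs 500 null replications (20 items, 250 per group) and the
qualitative pattern checks 200 replications per scenario (40 items,
250–1000 per group) — desk-scale choices that keep the whole suite within
a few minutes while leaving Monte-Carlo standard errors of a few tenths
of a percentage point. Raising `reps` toward 10⁴ narrows the Monte-Carlo
error but changes no default behaviour.

## Known limitations

* Only the two-group, dichotomous Rasch case with CML estimation is
  implemented; the alignment literature's 2PL/group-variance machinery
  and multi-group pairwise extensions are out of scope.
* Anchor-selection uncertainty is not propagated into the Wald tests.
* The classic heuristics are faithful operationalisations of published
  sketches, not line-by-line ports; their rates may differ in detail from
  the original implementations.
* Exact numeric reproduction of the published large-scale simulation
  figures would require scenario constants and 10⁴-replication budgets
  beyond the defaults here; the package reproduces the qualitative
  patterns (level-holding under the null, all-other breakdown under
  unbalanced DIF, label-switching recovery under majority DIF).
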