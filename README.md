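# anchorpoint

Anchor point selection for differential item functioning (DIF) analysis in
the Rasch model, using inequality criteria: the **Gini index** and the
**component loss function (CLF)** of the factor-analytic alignment method.

## The problem

Before the item difficulties of two groups of test takers can be compared
item by item, they must be placed on a common scale: the Rasch model fixes
difficulties only up to an additive constant per group. The traditional
remedy is to choose a set of *anchor items* assumed DIF-free and equate
their mean difficulty across groups — but a contaminated anchor inflates
the false alarm rate of every downstream DIF test, and there is no way to
verify an anchor empirically.

`anchorpoint` instead treats the scale link as a continuous *shift* `c`
applied to the second group's estimates and asks at which shift the two
difficulty patterns interlock best. With per-group CML estimates
`b1_j, b2_j` and item-wise absolute distances

```
d_j(c) = | b1_j − b2_j − c |
```

the selected anchor point maximises the **inequality** of `d(c)` rather
than minimising its total size: at a good alignment most items coincide
(distances near zero) while true DIF items stick out. Two criteria are
implemented:

* **Gini index** `GI(c) = 2 Σ_j r_j d_j(c) / (m Σ_j d_j(c)) − (m+1)/m`
  (ranks `r_j` ascending); bounded by `[0, 1 − 1/m]` and scale invariant;
* **CLF criterion** `−Σ_j √(d_j(c)² + ε)`, by default with `ε = 0`,
  i.e. minus the L1 norm of `d(c)`.

Both criteria can attain local maxima only at the *candidate shifts*
`c = b1_j − b2_j` that align a single item exactly, so the search reduces
to a sparse grid of at most `m` points. Secondary local maxima of the
criterion curve are reported as well: they flag alternative alignments,
e.g. an internally invariant cluster of items driven by a secondary
ability dimension.

Given the selected shift (or a classic anchor set), each item is tested
with the anchored Wald statistic
`t_j = (b1_j − b2_j − c) / se_j`, with standard errors taken under the
anchor restriction so that the anchor's own sampling noise is propagated.

The package also ships the three classic anchor heuristics used as
baselines (constant-4 "all-other", constant-4 mean-p-value-threshold,
iterative forward) and a seeded simulation harness measuring false alarm
and hit rates, including the label-switching scoring rule for
majority-DIF designs.

## Worked example

Simulate a 10-item, 500-per-group data set in which item 4 has a
1-logit DIF shift, then run the pipeline from the command line:

```sh
anchorpoint dif responses.csv --criterion gini --out dif_out
```

prints

```
shift: 0.0657074
flagged items: ['I04']
```

and writes `dif_out/curve.tsv` (criterion curve), `dif_out/curve.json`
(candidates and optima) and `dif_out/dif_table.tsv`:

```
item  diff       se        statistic  pvalue       flagged
I01    0.20278   0.26952    0.75237   0.45183      False
...
I04   -0.94728   0.20594   -4.59986   4.22772e-06  True
...
I07    0         0         0          1            False
```

The Gini-optimal shift 0.0657 is the candidate of item 7 (hence its
`t = 0` row: the anchor item is aligned exactly); the aligned difference
of item 4 is −0.95 ≈ the simulated −1.0 and is the only one flagged at
α = 0.05. The same analysis from Python:

```python
from anchorpoint import fit_rasch_cml, select_anchor_point, anchored_test_from_set, read_responses

data = read_responses("responses.csv")
ref, foc = data.split()
f1, f2 = fit_rasch_cml(ref), fit_rasch_cml(foc)
curve = select_anchor_point(f1, f2, criterion="gini")
table = anchored_test_from_set(f1, f2, curve.anchor_items())
print(curve.optimal_shift, table.flagged_items)   # 0.0657... [3]
```

The noise-free behaviour of the criteria is easiest to see on the built-in
toy configuration (10 items, one with DIF +0.75, true parameters):

```
$ anchorpoint toy
gini: optimal shift 0 (criterion value 0.9)
clf: optimal shift 0 (criterion value -0.75)
gini: local optimum at -0.75 (value 0.1, prominence 0.0758929)
```

Both criteria peak at shift 0, where only the DIF item misfits and the
Gini index attains its 10-item maximum 1 − 1/10 = 0.9; the secondary
Gini peak at −0.75 is the complementary alignment in which the DIF item
interlocks and the other nine misfit.

Simulation scenarios run via `anchorpoint simulate` (see `--help`), e.g.
false-alarm/hit-rate tables for any of the methods
`gini, clf, allother, mpt4, forward`.

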