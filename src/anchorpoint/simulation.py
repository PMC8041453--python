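"""Synthetic DIF data generation, scoring and the replication runner.

Two generators mirror the two canonical ways DIF arises:

* Study-I style (:func:`generate_study1`): unidimensional Rasch data in
  which a subset of items has its focal-group difficulty shifted by a fixed
  amount (all in one direction, or alternating for balanced DIF).
* Study-II style (:func:`generate_study2`): compensatory two-dimensional
  logistic data in which DIF items additionally load on a secondary ability
  dimension whose mean differs between the groups -- marginally this
  induces DIF without any difficulty shift.

:func:`run_simulation` replays a design over many replications, fits both
groups by CML, applies anchor-selection methods, scores flagged items
against the simulated truth (optionally under the label-switching rule that
accepts the complementary item clustering as equally correct), and
aggregates false alarm and hit rates with Monte-Carlo standard errors.

Randomness: every replication derives its own generator from
``(seed, rep_index)`` via ``numpy.random.SeedSequence``, split into
separate ability / secondary-dimension / response streams so that all
methods see identical data within a replication and the two-dimensional
generator with zero secondary loading reproduces the unidimensional null
stream draw for draw.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .rasch_cml import ResponseData, EstimationError, fit_rasch_cml
from .criteria import select_anchor_point
from .dif_tests import anchored_test_from_set
from .classic_anchors import allother_constant4, constant4_mpt, iterative_forward_mtt

logger = logging.getLogger(__name__)

__all__ = [
    "SimDesign",
    "SimResult",
    "generate_study1",
    "generate_study2",
    "make_toy",
    "score_run",
    "run_simulation",
    "METHODS",
]

#: anchor-selection methods known to the runner
METHODS = ("gini", "clf", "allother", "mpt4", "forward")


@dataclass
class SimDesign:
    """One simulation scenario.

    Defaults encode the reference conditions used throughout: 40 items with
    difficulties equally spaced on [-2.5, 2.5], 500 persons per group, a
    DIF shift of 0.6 logits on the focal group, no impact (equal ability
    means on the primary dimension).  ``dif_items`` are 0-based indices.
    For the two-dimensional study, DIF items load with ``loading`` on a
    secondary dimension on which the focal-group mean exceeds the reference
    mean by ``secondary_gap``.
    """

    m: int = 40
    n_ref: int = 500
    n_foc: int = 500
    dif_items: tuple = ()
    dif_size: float = 0.6
    direction: str = "unbalanced"
    impact: float = 0.0
    study: int = 1
    loading: float = 1.0
    secondary_gap: float = 1.0
    reps: int = 500
    seed: int = 0
    difficulty_range: tuple = (-2.5, 2.5)

    def __post_init__(self) -> None:
        self.dif_items = tuple(int(j) for j in self.dif_items)
        if self.m < 2:
            raise ValueError("need at least 2 items")
        if self.n_ref < 1 or self.n_foc < 1:
            raise ValueError("group sizes must be positive")
        if any(j < 0 or j >= self.m for j in self.dif_items):
            raise ValueError(f"dif_items out of range 0..{self.m - 1}")
        if self.dif_size < 0:
            raise ValueError("dif_size must be nonnegative")
        if self.direction not in ("unbalanced", "balanced"):
            raise ValueError("direction must be 'unbalanced' or 'balanced'")
        if self.study not in (1, 2):
            raise ValueError("study must be 1 or 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def difficulties(self) -> np.ndarray:
        lo, hi = self.difficulty_range
        return np.linspace(lo, hi, self.m)

    @property
    def truth(self) -> np.ndarray:
        return np.asarray(self.dif_items, dtype=int)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimDesign":
        d = json.loads(text)
        for key in ("dif_items", "difficulty_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _rep_streams(seed: int, rep_index: int):
    """(ability, secondary, response) generators for one replication."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(rep_index),))
    kids = ss.spawn(3)
    return tuple(np.random.default_rng(k) for k in kids)


def _focal_difficulties(design: SimDesign) -> np.ndarray:
    beta = design.difficulties.copy()
    if design.direction == "unbalanced":
        beta[list(design.dif_items)] += design.dif_size
    else:
        for i, j in enumerate(sorted(design.dif_items)):
            beta[j] += design.dif_size if i % 2 == 0 else -design.dif_size
    return beta


def _assemble(design: SimDesign, X_ref, X_foc) -> ResponseData:
    group = np.array(["ref"] * design.n_ref + ["foc"] * design.n_foc)
    return ResponseData(
        responses=np.vstack([X_ref, X_foc]), group=group, levels=("ref", "foc")
    )


def generate_study1(design: SimDesign, rep_index: int = 0) -> tuple[ResponseData, np.ndarray]:
    """Unidimensional Rasch data with additive DIF on the focal group.

    Reference abilities are standard normal; focal abilities are normal
    with mean ``-impact`` and unit variance.  Returns the data set and the
    0-based indices of the true DIF items.
    """
    if design.study != 1:
        raise ValueError("design.study must be 1 for generate_study1")
    rng_ab, _, rng_resp = _rep_streams(design.seed, rep_index)
    theta_ref = rng_ab.normal(0.0, 1.0, design.n_ref)
    theta_foc = rng_ab.normal(-design.impact, 1.0, design.n_foc)
    beta_ref = design.difficulties
    beta_foc = _focal_difficulties(design)
    p_ref = 1.0 / (1.0 + np.exp(-(theta_ref[:, None] - beta_ref[None, :])))
    p_foc = 1.0 / (1.0 + np.exp(-(theta_foc[:, None] - beta_foc[None, :])))
    X_ref = (rng_resp.random((design.n_ref, design.m)) < p_ref).astype(np.int8)
    X_foc = (rng_resp.random((design.n_foc, design.m)) < p_foc).astype(np.int8)
    return _assemble(design, X_ref, X_foc), design.truth


def generate_study2(design: SimDesign, rep_index: int = 0) -> tuple[ResponseData, np.ndarray]:
    """Two-dimensional data in which DIF items tap a secondary dimension.

    All items load 1 on the primary dimension; DIF items additionally load
    ``design.loading`` on a secondary dimension distributed N(0, 1) in the
    reference group and N(secondary_gap, 1) in the focal group.  Responses
    follow the compensatory two-dimensional logistic model
    P = logistic(theta1 + a2_j * theta2 - beta_j).  With all secondary
    loadings zero this reproduces, draw for draw, the unidimensional
    generator without DIF.
    """
    if design.study != 2:
        raise ValueError("design.study must be 2 for generate_study2")
    rng_ab, rng_sec, rng_resp = _rep_streams(design.seed, rep_index)
    theta1_ref = rng_ab.normal(0.0, 1.0, design.n_ref)
    theta1_foc = rng_ab.normal(-design.impact, 1.0, design.n_foc)
    theta2_ref = rng_sec.normal(0.0, 1.0, design.n_ref)
    theta2_foc = rng_sec.normal(design.secondary_gap, 1.0, design.n_foc)
    a2 = np.zeros(design.m)
    a2[list(design.dif_items)] = design.loading
    beta = design.difficulties
    eta_ref = theta1_ref[:, None] + theta2_ref[:, None] * a2[None, :] - beta[None, :]
    eta_foc = theta1_foc[:, None] + theta2_foc[:, None] * a2[None, :] - beta[None, :]
    X_ref = (rng_resp.random((design.n_ref, design.m)) < 1.0 / (1.0 + np.exp(-eta_ref))).astype(np.int8)
    X_foc = (rng_resp.random((design.n_foc, design.m)) < 1.0 / (1.0 + np.exp(-eta_foc))).astype(np.int8)
    return _assemble(design, X_ref, X_foc), design.truth


def generate(design: SimDesign, rep_index: int = 0) -> tuple[ResponseData, np.ndarray]:
    """Dispatch to the generator matching ``design.study``."""
    fn = generate_study1 if design.study == 1 else generate_study2
    return fn(design, rep_index)


def make_toy(
    true_beta: np.ndarray | None = None,
    dif_item: int = 3,
    dif_size: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """True-parameter toy configuration with DIF concentrated in one item.

    Returns a (beta1, beta2) pair where beta2 equals beta1 except that the
    difficulty of ``dif_item`` (0-based; the default 3 is "item 4" in
    1-based reports) is raised by ``dif_size``.  The default beta1 spaces
    ten difficulties evenly on [-2.5, 2.5].  Used for criterion-curve
    illustrations free of sampling noise: the candidate shifts are
    {-dif_size, 0}, with the global optimum of both criteria at 0 and, for
    the Gini index, a secondary local optimum at -dif_size.
    """
    beta1 = (
        np.linspace(-2.5, 2.5, 10)
        if true_beta is None
        else np.asarray(true_beta, dtype=float)
    )
    if not 0 <= dif_item < beta1.size:
        raise ValueError(f"dif_item out of range 0..{beta1.size - 1}")
    beta2 = beta1.copy()
    beta2[dif_item] += dif_size
    return beta1, beta2


def score_run(flags, truth, m: int, mode: str = "plain") -> tuple[float, float]:
    """(false alarm rate, hit rate) of flagged items against the truth.

    FAR is the fraction of truly DIF-free items flagged; HIT the fraction
    of true DIF items flagged (nan when there are none).  Under
    ``label_switching`` the complementary labelling -- the DIF set and its
    complement swapping roles -- is scored too, and the labelling with the
    smaller total error FAR + (1 - HIT) is returned: when a majority item
    cluster is internally invariant, both alignments are equally valid.
    """
    flags = np.unique(np.asarray(list(flags), dtype=int) if not isinstance(flags, np.ndarray) else flags)
    truth = np.unique(np.asarray(list(truth), dtype=int) if not isinstance(truth, np.ndarray) else truth)
    if flags.size and (flags.min() < 0 or flags.max() >= m):
        raise ValueError(f"flagged indices out of range 0..{m - 1}")
    if truth.size and (truth.min() < 0 or truth.max() >= m):
        raise ValueError(f"truth indices out of range 0..{m - 1}")
    if mode not in ("plain", "label_switching"):
        raise ValueError("mode must be 'plain' or 'label_switching'")

    def rates(tr):
        n_null = m - tr.size
        far = (
            np.setdiff1d(flags, tr).size / n_null if n_null else float("nan")
        )
        hit = (
            np.intersect1d(flags, tr).size / tr.size if tr.size else float("nan")
        )
        return far, hit

    far, hit = rates(truth)
    if mode == "plain":
        return far, hit
    alt = np.setdiff1d(np.arange(m), truth)
    far2, hit2 = rates(alt)

    def loss(f, h):
        f = 0.0 if np.isnan(f) else f
        h = 1.0 if np.isnan(h) else h
        return f + (1.0 - h)

    return (far, hit) if loss(far, hit) <= loss(far2, hit2) else (far2, hit2)


def _flags_for_method(method: str, fit_ref, fit_foc, alpha: float) -> np.ndarray:
    if method in ("gini", "clf"):
        # candidate ties (routine for the piecewise-linear CLF when m is
        # even: the whole median interval is optimal) resolve to the
        # smaller |c|; per-replication warnings would drown the aggregate
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            curve = select_anchor_point(fit_ref, fit_foc, criterion=method)
        table = anchored_test_from_set(
            fit_ref, fit_foc, curve.anchor_items(), alpha=alpha
        )
    elif method == "allother":
        sel = allother_constant4(fit_ref, fit_foc, alpha=alpha)
        table = anchored_test_from_set(fit_ref, fit_foc, sel.anchor, alpha=alpha)
    elif method == "mpt4":
        sel = constant4_mpt(fit_ref, fit_foc, alpha=alpha)
        table = anchored_test_from_set(fit_ref, fit_foc, sel.anchor, alpha=alpha)
    elif method == "forward":
        sel = iterative_forward_mtt(fit_ref, fit_foc, alpha=alpha)
        table = anchored_test_from_set(fit_ref, fit_foc, sel.anchor, alpha=alpha)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return table.flagged_items


@dataclass
class SimResult:
    """Aggregated simulation outcome.

    ``rates`` has one row per (method, scoring mode) with mean false alarm
    and hit rates over completed replications and their Monte-Carlo
    standard errors (nan when fewer than two replications completed or the
    quantity is undefined, e.g. the hit rate of a null scenario).
    """

    design: SimDesign
    rates: pd.DataFrame
    per_rep: pd.DataFrame
    n_completed: int
    n_failed: int
    alpha: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "design": asdict(self.design),
                "alpha": self.alpha,
                "n_completed": self.n_completed,
                "n_failed": self.n_failed,
                "rates": self.rates.to_dict(orient="records"),
            },
            indent=2,
        )


def run_simulation(
    design: SimDesign,
    methods=("gini",),
    alpha: float = 0.05,
    modes=("plain", "label_switching"),
) -> SimResult:
    """Replicate a design: generate, fit, select anchors, test and score.

    Within each replication every method sees the same data and the same
    pair of CML fits.  Replications in which estimation fails (e.g. an
    item answered uniformly within one group at small n) are logged,
    counted in ``n_failed`` and excluded from the averages.
    """
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    rows = []
    n_failed = 0
    for rep in range(design.reps):
        data, truth = generate(design, rep)
        X_ref, X_foc = data.split()
        try:
            fit_ref = fit_rasch_cml(X_ref, restriction="sum_zero")
            fit_foc = fit_rasch_cml(X_foc, restriction="sum_zero")
        except EstimationError as exc:
            logger.warning("replication %d failed: %s", rep, exc)
            n_failed += 1
            continue
        for method in methods:
            flagged = _flags_for_method(method, fit_ref, fit_foc, alpha)
            for mode in modes:
                far, hit = score_run(flagged, truth, design.m, mode=mode)
                rows.append(
                    {"rep": rep, "method": method, "mode": mode, "far": far, "hit": hit}
                )
    per_rep = pd.DataFrame(rows, columns=["rep", "method", "mode", "far", "hit"])
    agg_rows = []
    for (method, mode), grp in per_rep.groupby(["method", "mode"], sort=False):
        n_ok = len(grp)
        agg_rows.append(
            {
                "method": method,
                "mode": mode,
                "far": grp["far"].mean(),
                "hit": grp["hit"].mean(),
                "far_se": grp["far"].std(ddof=1) / np.sqrt(n_ok) if n_ok > 1 else float("nan"),
                "hit_se": grp["hit"].std(ddof=1) / np.sqrt(n_ok) if n_ok > 1 else float("nan"),
                "n_reps": n_ok,
            }
        )
    rates = pd.DataFrame(
        agg_rows, columns=["method", "mode", "far", "hit", "far_se", "hit_se", "n_reps"]
    )
    return SimResult(
        design=design,
        rates=rates,
        per_rep=per_rep,
        n_completed=design.reps - n_failed,
        n_failed=n_failed,
        alpha=alpha,
    )
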