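"""Anchor point selection criteria over scale shifts.

Two groups' Rasch difficulty estimates live on scales with arbitrary
origins.  Writing d_j(c) = |b1_j - b2_j - c| for the item-wise absolute
distance after shifting group 2 by c, an anchor point is a shift c* at which
the two parameter patterns interlock "as well as possible".  Rather than
minimising the total amount of misfit, the criteria here maximise the
*inequality* of the distance vector d(c): at a good alignment most items
coincide (tiny distances) while any DIF items stand out (large distances).

Implemented criteria:

* Gini index: GI(c) = 2 sum_j r_j d_j / (m sum_j d_j) - (m+1)/m, where r_j
  ranks d_j ascending.  Bounded by [0, 1 - 1/m]; scale invariant, so it
  measures only how unevenly DIF is spread over items, not its size.
* CLF criterion: -sum_j sqrt(d_j^2 + eps), the negated component loss
  function of the factor-analytic alignment method; with eps = 0 this is
  minus the L1 norm of d(c).

Both criteria, as functions of c, can attain local maxima only at the
"candidate" shifts c = b1_j - b2_j that align a single item exactly, which
reduces the search to a sparse grid of at most m points.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceProfile",
    "CriterionCurve",
    "LocalOptimum",
    "distances",
    "gini_index",
    "clf_criterion",
    "search_interval",
    "candidate_shifts",
    "select_anchor_point",
    "find_local_optima",
]

CRITERIA = ("gini", "clf")

#: two candidate criterion values closer than this are treated as tied
TIE_TOL = 1e-10


def _as_beta(x) -> np.ndarray:
    """Accept a RaschFit or a plain difficulty vector."""
    beta = getattr(x, "beta", x)
    return np.asarray(beta, dtype=float)


@dataclass
class DistanceProfile:
    """Item-wise absolute distances d_j(c) = |b1_j - b2_j - c| at one shift."""

    c: float
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)


def distances(beta1, beta2, c: float = 0.0) -> DistanceProfile:
    """Absolute item-wise distances after shifting group 2 by ``c``."""
    b1, b2 = _as_beta(beta1), _as_beta(beta2)
    if b1.shape != b2.shape:
        raise ValueError(f"length mismatch: {b1.size} vs {b2.size}")
    return DistanceProfile(c=float(c), d=np.abs(b1 - b2 - c))


def gini_index(d) -> float:
    """Gini inequality index of a nonnegative distance vector.

    Uses the rank formulation
    ``GI = 2 sum_j r_j d_j / (m sum_j d_j) - (m+1)/m`` with ranks from an
    ascending sort; the value does not depend on how ties are ordered.
    Returns 0.0 for an all-zero vector (perfect alignment: the degenerate
    no-DIF case).
    """
    d = np.asarray(getattr(d, "d", d), dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    m = d.size
    total = d.sum()
    if total == 0.0:
        logger.info("all distances zero: perfect alignment, Gini index 0")
        return 0.0
    ranks = np.empty(m)
    ranks[np.argsort(d, kind="stable")] = np.arange(1, m + 1)
    return float(2.0 * (ranks @ d) / (m * total) - (m + 1) / m)


def clf_criterion(d, epsilon: float = 0.0) -> float:
    """Negated component-loss-function criterion -sum_j sqrt(d_j^2 + eps).

    ``epsilon`` smooths the kink at zero for gradient-based optimisers; the
    grid search used here needs none, so the default is the simplified form
    -sum_j d_j.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    d = np.asarray(getattr(d, "d", d), dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if epsilon == 0.0:
        return float(-d.sum())
    return float(-np.sum(np.sqrt(d * d + epsilon)))


def search_interval(beta1, beta2) -> tuple[float, float]:
    """Shift interval over which the two parameter ranges safely overlap.

    ``[cmin, cmax] = [min(b1) - max(b2), max(b1) - min(b2)]``: group 2 is
    moved fully past group 1, from the lowest item of group 1 meeting the
    highest item of group 2 to the reverse.
    """
    b1, b2 = _as_beta(beta1), _as_beta(beta2)
    if b1.size == 0 or b2.size == 0:
        raise ValueError("empty parameter vector")
    return float(b1.min() - b2.max()), float(b1.max() - b2.min())


def candidate_shifts(beta1, beta2, tol: float = 1e-12) -> np.ndarray:
    """Sorted unique single-item shifts {b1_j - b2_j}.

    Every local (hence global) maximum of the Gini and CLF criteria lies in
    this set, so optimisation reduces to evaluating at most m shifts.
    Differences closer than ``tol`` are collapsed to one candidate.
    """
    b1, b2 = _as_beta(beta1), _as_beta(beta2)
    if b1.shape != b2.shape:
        raise ValueError(f"length mismatch: {b1.size} vs {b2.size}")
    diffs = np.sort(b1 - b2)
    keep = [diffs[0]]
    for v in diffs[1:]:
        if v - keep[-1] > tol:
            keep.append(v)
    return np.asarray(keep)


def _evaluate(crit: str, b1, b2, shifts, epsilon: float = 0.0) -> np.ndarray:
    fun = gini_index if crit == "gini" else lambda d: clf_criterion(d, epsilon)
    return np.array([fun(np.abs(b1 - b2 - c)) for c in np.atleast_1d(shifts)])


@dataclass
class LocalOptimum:
    """A non-global local maximum of a criterion curve."""

    shift: float
    value: float
    criterion: str
    prominence: float


@dataclass
class CriterionCurve:
    """Criterion values over shifts, candidates and optima for both criteria.

    ``grid``/``values`` trace the curve for plotting; selection uses only
    the sparse ``candidates`` set, where all optima provably lie.
    ``global_opt`` maps each criterion name to its (shift, value) pair.
    """

    grid: np.ndarray
    values: dict[str, np.ndarray]
    candidates: np.ndarray
    candidate_values: dict[str, np.ndarray]
    global_opt: dict[str, tuple[float, float]]
    local_opts: list[LocalOptimum] = field(default_factory=list)
    criterion: str = "gini"
    interval: tuple[float, float] = (0.0, 0.0)
    beta1: np.ndarray | None = None
    beta2: np.ndarray | None = None
    epsilon: float = 0.0

    @property
    def optimal_shift(self) -> float:
        """Globally optimal shift under the curve's primary criterion."""
        return self.global_opt[self.criterion][0]

    def anchor_items(self, criterion: str | None = None, tol: float = 1e-9) -> np.ndarray:
        """0-based items whose single-item shift equals the global optimum.

        Optima occur only at single-item candidate shifts, so this is the
        item (or the tied items) the selected anchor point aligns exactly.
        """
        crit = criterion or self.criterion
        shift = self.global_opt[crit][0]
        return np.flatnonzero(np.abs(self.beta1 - self.beta2 - shift) <= tol)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"shift": self.grid, "gini": self.values["gini"], "clf": self.values["clf"]}
        )

    def to_json(self) -> str:
        payload = {
            "criterion": self.criterion,
            "interval": list(self.interval),
            "candidates": self.candidates.tolist(),
            "candidate_values": {k: v.tolist() for k, v in self.candidate_values.items()},
            "global_opt": {
                k: {"shift": s, "value": v} for k, (s, v) in self.global_opt.items()
            },
            "local_opts": [
                {
                    "shift": o.shift,
                    "value": o.value,
                    "criterion": o.criterion,
                    "prominence": o.prominence,
                }
                for o in self.local_opts
            ],
        }
        return json.dumps(payload, indent=2)


def select_anchor_point(
    fit1,
    fit2,
    criterion: str = "gini",
    grid_size: int = 1001,
    epsilon: float = 0.0,
) -> CriterionCurve:
    """Select the optimal anchor point by sparse-grid criterion maximisation.

    Evaluates the Gini and CLF criteria at every candidate shift inside the
    search interval, takes the maximiser of the requested ``criterion`` as
    the global anchor point, and traces a dense grid (default 1001 points)
    for the criterion plot.  Exact ties between candidates are resolved
    toward the smaller absolute shift, with a warning: a tie signals a
    label-switching situation that deserves inspection.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    b1, b2 = _as_beta(fit1), _as_beta(fit2)
    if b1.shape != b2.shape:
        raise ValueError(f"length mismatch: {b1.size} vs {b2.size}")
    if b1.size < 2:
        raise ValueError("need at least 2 items to select an anchor point")
    cmin, cmax = search_interval(b1, b2)
    cands = candidate_shifts(b1, b2)
    cands = cands[(cands >= cmin - 1e-12) & (cands <= cmax + 1e-12)]
    grid = np.linspace(cmin, cmax, max(int(grid_size), 2))

    cand_vals: dict[str, np.ndarray] = {}
    grid_vals: dict[str, np.ndarray] = {}
    global_opt: dict[str, tuple[float, float]] = {}
    for crit in CRITERIA:
        cv = _evaluate(crit, b1, b2, cands, epsilon)
        cand_vals[crit] = cv
        grid_vals[crit] = _evaluate(crit, b1, b2, grid, epsilon)
        best = cv.max()
        tied = np.where(cv >= best - TIE_TOL)[0]
        if tied.size > 1:
            pick = tied[np.argmin(np.abs(cands[tied]))]
            # adjacent candidates tying is the ordinary median plateau of
            # the piecewise-linear CLF; separated peaks signal label
            # switching and deserve attention
            contiguous = np.all(np.diff(tied) == 1)
            if crit == "clf" and contiguous:
                logger.debug(
                    "clf: median plateau between adjacent candidates %s",
                    np.round(cands[tied], 6).tolist(),
                )
            else:
                warnings.warn(
                    f"{crit}: {tied.size} candidate shifts tie at the optimum "
                    f"({np.round(cands[tied], 6).tolist()}); reporting the one "
                    "closest to zero -- inspect the criterion plot for "
                    "label switching",
                    stacklevel=2,
                )
        else:
            pick = tied[0]
        global_opt[crit] = (float(cands[pick]), float(cv[pick]))

    curve = CriterionCurve(
        grid=grid,
        values=grid_vals,
        candidates=cands,
        candidate_values=cand_vals,
        global_opt=global_opt,
        criterion=criterion,
        interval=(cmin, cmax),
        beta1=b1,
        beta2=b2,
        epsilon=epsilon,
    )
    curve.local_opts = find_local_optima(curve)
    return curve


def find_local_optima(curve: CriterionCurve) -> list[LocalOptimum]:
    """Non-global local maxima of the criterion curves.

    A candidate shift is a local maximum when the criterion value drops on
    both sides of it along the continuous curve; the flanking values are
    taken at the midpoints toward the neighbouring candidates (or toward
    the interval ends for the outermost candidates).  Prominence is the
    height of the candidate above the higher of its two flanking values.
    Secondary peaks mark alternative alignments, e.g. an internally
    invariant DIF item cluster.
    """
    b1, b2 = curve.beta1, curve.beta2
    if b1 is None or b2 is None:
        raise ValueError("curve lacks the parameter vectors needed to probe flanks")
    cands = curve.candidates
    cmin, cmax = curve.interval
    out: list[LocalOptimum] = []
    if cands.size < 1:
        return out
    # flank probe points: midpoints between consecutive candidates, and the
    # midpoints toward the interval ends for the outermost candidates
    left = np.empty(cands.size)
    right = np.empty(cands.size)
    left[1:] = 0.5 * (cands[:-1] + cands[1:])
    right[:-1] = left[1:]
    left[0] = 0.5 * (cmin + cands[0])
    right[-1] = 0.5 * (cands[-1] + cmax)
    for crit in CRITERIA:
        cv = curve.candidate_values[crit]
        gshift, _ = curve.global_opt[crit]
        lv = _evaluate(crit, b1, b2, left, curve.epsilon)
        rv = _evaluate(crit, b1, b2, right, curve.epsilon)
        for i in range(cands.size):
            c = cands[i]
            if abs(c - gshift) <= TIE_TOL:
                continue
            # candidates sitting exactly on an interval end have one flank
            lo = lv[i] if left[i] < c else -np.inf
            hi = rv[i] if right[i] > c else -np.inf
            flank = max(lo, hi)
            if np.isfinite(flank) and cv[i] > lo + TIE_TOL and cv[i] > hi + TIE_TOL:
                out.append(
                    LocalOptimum(
                        shift=float(c),
                        value=float(cv[i]),
                        criterion=crit,
                        prominence=float(cv[i] - flank),
                    )
                )
    return out
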