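"""Conditional maximum likelihood (CML) estimation of Rasch item parameters.

The Rasch model gives P(X_vj = 1) = logistic(theta_v - beta_j) for person v
and item j.  Conditioning on the person raw scores removes the person
parameters theta_v and leaves a likelihood that depends on the item
difficulties beta only through elementary symmetric functions (ESFs) of the
transformed parameters eps_j = exp(-beta_j).  This module provides

* :func:`elementary_symmetric` -- ESFs gamma_r with optional first and second
  derivatives with respect to beta, computed in a rescaled (centered) domain
  so that test lengths up to ~100 items stay inside double precision,
* :func:`fit_rasch_cml` -- Newton--Raphson maximisation of the conditional
  log-likelihood under a scale restriction (``sum_zero`` or ``first_zero``),
  returning estimates, covariance matrix and fit diagnostics.

Persons with extreme raw scores (0 or m) carry no conditional information
and are dropped before estimation; the number of retained persons is
reported in ``n_used``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ResponseData",
    "RaschFit",
    "EstimationError",
    "elementary_symmetric",
    "fit_rasch_cml",
]

RESTRICTIONS = ("sum_zero", "first_zero")


class EstimationError(RuntimeError):
    """Raised when CML estimation is impossible or fails to converge."""


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class ResponseData:
    """A binary person x item response matrix with a two-level group label.

    Parameters
    ----------
    responses : (n, m) array of 0/1 integers.
    group : length-n array of group labels with exactly two levels.
    item_names : optional item column names; defaults to ``I01 .. Im``.
    levels : the (reference, focal) group labels, in that order.  Defaults
        to order of first appearance in ``group``.
    """

    responses: np.ndarray
    group: np.ndarray
    item_names: list[str] = field(default_factory=list)
    levels: tuple = ()

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        self.group = np.asarray(self.group)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        n, m = self.responses.shape
        if m < 2:
            raise ValueError(f"need at least 2 items, got {m}")
        if len(self.group) != n:
            raise ValueError("group labels do not match number of rows")
        vals = np.unique(self.responses)
        if not np.all(np.isin(vals, (0, 1))):
            bad = [v for v in vals.tolist() if v not in (0, 1)]
            raise ValueError(f"responses must be binary 0/1; found {bad}")
        self.responses = self.responses.astype(np.int8)
        seen = list(dict.fromkeys(self.group.tolist()))
        if len(seen) != 2:
            raise ValueError(
                f"group must have exactly two levels, found {len(seen)}: {seen}"
            )
        if not self.levels:
            self.levels = (seen[0], seen[1])
        elif set(self.levels) != set(seen):
            raise ValueError(f"levels {self.levels} do not match data levels {seen}")
        if not self.item_names:
            self.item_names = [f"I{j + 1:02d}" for j in range(m)]
        elif len(self.item_names) != m:
            raise ValueError("item_names length does not match number of items")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def group_matrix(self, level) -> np.ndarray:
        """Response rows belonging to one group level."""
        mask = self.group == level
        if not mask.any():
            raise ValueError(f"no persons in group {level!r}")
        return self.responses[mask]

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(reference, focal) response matrices in ``levels`` order."""
        return self.group_matrix(self.levels[0]), self.group_matrix(self.levels[1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_names)
        df.insert(0, "group", self.group)
        return df


# ---------------------------------------------------------------------------
# elementary symmetric functions
# ---------------------------------------------------------------------------


def _esf_poly(eps: np.ndarray) -> np.ndarray:
    """ESFs as coefficients of prod_j (1 + eps_j t)."""
    m = eps.size
    gamma = np.zeros(m + 1)
    gamma[0] = 1.0
    for j in range(m):
        gamma[1 : j + 2] = gamma[1 : j + 2] + eps[j] * gamma[0 : j + 1]
    return gamma


def _esf_loo(eps: np.ndarray) -> np.ndarray:
    """Leave-one-out ESFs: row j holds gamma^(j)_0..gamma^(j)_{m-1}.

    Built from prefix/suffix generating-polynomial products combined by
    convolution.  All coefficients are nonnegative, so no cancellation
    occurs and the result is accurate to machine precision -- unlike
    deflation (polynomial division) of the full ESF vector.
    """
    m = eps.size
    if m == 1:
        return np.ones((1, 1))
    prefix = [np.array([1.0])]
    for j in range(m - 1):
        nxt = np.zeros(j + 2)
        nxt[: j + 1] += prefix[j]
        nxt[1:] += eps[j] * prefix[j]
        prefix.append(nxt)
    suffix = [np.array([1.0])]
    for j in range(m - 1, 0, -1):
        prev = suffix[-1]
        nxt = np.zeros(prev.size + 1)
        nxt[:-1] += prev
        nxt[1:] += eps[j] * prev
        suffix.append(nxt)
    suffix.reverse()  # suffix[j] = poly of items j+1..m-1
    out = np.empty((m, m))
    for j in range(m):
        out[j] = np.convolve(prefix[j], suffix[j])
    return out


def elementary_symmetric(beta: np.ndarray, order: int = 0):
    """Elementary symmetric functions of eps_j = exp(-beta_j).

    gamma_r = sum over all response patterns x with raw score r of
    prod_j exp(-beta_j x_j); gamma_0 = 1, gamma_m = prod_j exp(-beta_j).

    Parameters
    ----------
    beta : difficulty vector (finite).
    order : 0 returns ``gamma`` (length m+1); 1 additionally returns the
        first derivatives ``d1`` with ``d1[j, r] = d gamma_r / d beta_j``;
        2 additionally returns ``d2`` with
        ``d2[j, k, r] = d^2 gamma_r / d beta_j d beta_k``.

    The computation is carried out with mean-centered beta and rescaled at
    the end, which keeps intermediate values bounded for long tests.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 1 or beta.size < 1:
        raise ValueError("beta must be a non-empty 1-D vector")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    m = beta.size
    shift = beta.mean()
    eps = np.exp(-(beta - shift))
    gamma_c = _esf_poly(eps)
    # gamma_r(beta) = exp(-r * mean(beta)) * gamma_r(beta - mean)
    scale = np.exp(-shift * np.arange(m + 1))
    gamma = gamma_c * scale
    if order == 0:
        return gamma

    loo = _esf_loo(eps)
    # d gamma_r / d beta_j = -eps_j * gamma^(j)_{r-1}, same r-dependent scale
    d1 = np.zeros((m, m + 1))
    d1[:, 1:] = -eps[:, None] * loo
    d1 *= scale[None, :]
    if order == 1:
        return gamma, d1

    d2 = np.zeros((m, m, m + 1))
    for k in range(m):
        # diagonal: second derivative in beta_k is minus the first derivative
        d2[k, k] = -d1[k]
        if m < 2:
            continue
        others = np.concatenate([np.arange(k), np.arange(k + 1, m)])
        ltwo_k = _esf_loo(eps[others])  # rows: gamma^(j,k) for j != k, orders 0..m-2
        d2[others, k, 2:] = eps[others, None] * eps[k] * ltwo_k * scale[None, 2:]
    # enforce exact symmetry (deflation order can differ in the last ulp)
    d2 = 0.5 * (d2 + np.swapaxes(d2, 0, 1))
    return gamma, d1, d2


# ---------------------------------------------------------------------------
# CML fit
# ---------------------------------------------------------------------------


@dataclass
class RaschFit:
    """CML item-parameter estimates for one group.

    ``beta`` satisfies the stated ``restriction``; ``vcov`` is the
    Moore--Penrose inverse of the conditional information mapped to that
    parameterisation (rank m-1).  ``n_used`` counts persons retained after
    removal of extreme raw scores.
    """

    beta: np.ndarray
    vcov: np.ndarray
    restriction: str
    loglik: float
    n_used: int
    item_names: list[str] = field(default_factory=list)
    n_iter: int = 0

    @property
    def n_items(self) -> int:
        return self.beta.size

    def to_restriction(self, restriction: str) -> "RaschFit":
        """Re-express the fit under another scale restriction.

        Switching restrictions shifts every estimate by the same constant
        and transforms the covariance matrix accordingly; the conditional
        log-likelihood is unchanged.
        """
        if restriction not in RESTRICTIONS:
            raise ValueError(f"unknown restriction {restriction!r}")
        if restriction == self.restriction:
            return self
        m = self.n_items
        if restriction == "sum_zero":
            T = np.eye(m) - np.ones((m, m)) / m
        else:  # first_zero
            T = np.eye(m)
            T[:, 0] -= 1.0
        beta = T @ self.beta
        vcov = T @ self.vcov @ T.T
        return replace(self, beta=beta, vcov=vcov, restriction=restriction)


def _conditional_quantities(beta: np.ndarray, need_info: bool):
    """Per-score-group response probabilities pi_{jr} (and the conditional
    information building blocks) at the current beta.

    Returns (loggamma, P, I) where P[j, r-1] = pi_{jr} for r = 1..m-1 and I
    is the full m x m conditional information per single person at each
    score, left as callable pieces for the caller to weight by score counts.
    """
    m = beta.size
    shift = beta.mean()
    eps = np.exp(-(beta - shift))
    gamma = _esf_poly(eps)
    loggamma = np.log(gamma) - shift * np.arange(m + 1)
    loo = _esf_loo(eps)
    # pi[j, r-1] = eps_j gamma^(j)_{r-1} / gamma_r for r = 1..m-1
    P = eps[:, None] * loo[:, 0 : m - 1] / gamma[1:m][None, :]
    if not need_info:
        return loggamma, P, None, None
    # pairwise pi_{jkr} = eps_j eps_k gamma^(j,k)_{r-2} / gamma_r, r = 2..m-1
    PP = np.zeros((m, m, m - 1))
    for k in range(m):
        others = np.concatenate([np.arange(k), np.arange(k + 1, m)])
        ltwo_k = _esf_loo(eps[others])  # (m-1, m-1): orders 0..m-2
        PP[others, k, 1:] = (
            eps[others, None] * eps[k] * ltwo_k[:, 0 : m - 2] / gamma[2:m][None, :]
        )
    return loggamma, P, PP, eps


def _information(P: np.ndarray, PP: np.ndarray, n_r: np.ndarray) -> np.ndarray:
    """Conditional Fisher information summed over score groups.

    For the conditional exponential family the observed and expected
    information coincide: I_jk = sum_r n_r (pi_jkr - pi_jr pi_kr),
    I_jj = sum_r n_r pi_jr (1 - pi_jr).
    """
    m = P.shape[0]
    info = np.einsum("jkr,r->jk", PP, n_r) - (P * n_r) @ P.T
    diag = (P * (1.0 - P)) @ n_r
    info[np.diag_indices(m)] = diag
    return 0.5 * (info + info.T)


def fit_rasch_cml(
    data,
    restriction: str = "sum_zero",
    max_iter: int = 100,
    gtol: float = 1e-8,
) -> RaschFit:
    """Fit Rasch item difficulties by conditional maximum likelihood.

    Parameters
    ----------
    data : (n, m) binary matrix, or a :class:`ResponseData` containing a
        single group's rows (pass ``data.group_matrix(level)`` otherwise).
    restriction : ``"sum_zero"`` (default) or ``"first_zero"``.
    max_iter, gtol : Newton iteration cap and max-abs-gradient tolerance.

    Raises
    ------
    EstimationError
        If an item lacks both response categories among the retained
        persons, or the Newton iteration fails to converge.
    """
    if isinstance(data, ResponseData):
        levels = np.unique(data.group)
        if len(levels) != 1:
            raise ValueError(
                "fit_rasch_cml expects a single group; use data.group_matrix(level)"
            )
        item_names = list(data.item_names)
        X = data.responses
    else:
        X = np.asarray(data)
        item_names = [f"I{j + 1:02d}" for j in range(X.shape[1])]
    if restriction not in RESTRICTIONS:
        raise ValueError(f"unknown restriction {restriction!r}")
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if not np.all(np.isin(np.unique(X), (0, 1))):
        raise ValueError("responses must be binary 0/1")
    X = X.astype(np.int8)
    n, m = X.shape

    scores = X.sum(axis=1)
    keep = (scores > 0) & (scores < m)
    X = X[keep]
    n_used = int(keep.sum())
    if n_used == 0:
        raise EstimationError("no persons left after removing extreme raw scores")
    s = X.sum(axis=0).astype(float)  # item totals
    zero_var = np.where((s == 0) | (s == n_used))[0]
    if zero_var.size:
        names = ", ".join(item_names[j] for j in zero_var)
        raise EstimationError(
            f"item(s) {names} observed in only one response category "
            "after extreme-score removal; CML estimates do not exist"
        )
    scores = X.sum(axis=1)
    n_r = np.bincount(scores, minlength=m + 1)[1:m].astype(float)  # r = 1..m-1

    def loglik(beta):
        lg = _conditional_quantities(beta, need_info=False)[0]
        return -float(s @ beta) - float(n_r @ lg[1:m])

    # moment starting values on the first_zero scale
    logit = np.log((n_used - s) / s)
    beta = logit - logit[0]
    ll = loglik(beta)

    free = slice(1, m)  # beta_1 fixed at 0 during iteration
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        lg, P, PP, _ = _conditional_quantities(beta, need_info=True)
        grad = -s + P @ n_r
        if np.max(np.abs(grad[free])) < gtol:
            break
        info = _information(P, PP, n_r)
        try:
            step = np.linalg.solve(info[free, free], grad[free])
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate data
            raise EstimationError(f"singular conditional information: {exc}") from exc
        # near the optimum the predicted gain 0.5 g's drops below the
        # floating-point noise of the log-likelihood; there the full Newton
        # step is contractive and is taken without a line search
        pred = 0.5 * float(grad[free] @ step)
        noise = 1e-13 * (1.0 + abs(ll))
        if pred <= noise:
            beta[free] = beta[free] + step
            ll = loglik(beta)
            continue
        # damped Newton: halve the step until the likelihood improves
        lam = 1.0
        for _ in range(40):
            cand = beta.copy()
            cand[free] = beta[free] + lam * step
            ll_cand = loglik(cand)
            if ll_cand >= ll - noise:
                beta, ll = cand, ll_cand
                break
            lam *= 0.5
        else:  # pragma: no cover - concave objective, should not happen
            raise EstimationError(
                f"line search failed at iteration {n_iter} (|grad|="
                f"{np.max(np.abs(grad[free])):.3g})"
            )
    else:
        raise EstimationError(
            f"CML did not converge in {max_iter} iterations "
            f"(max |grad| = {np.max(np.abs(grad[free])):.3g})"
        )

    # covariance: Moore-Penrose inverse of the full conditional information,
    # which is exactly the covariance under the sum-to-zero restriction.
    # The information's null space is exactly span(1), so the pseudo-inverse
    # is computed by inverting info + a*11'/m and removing the added part
    # again -- this never mistakes the near-null eigenvalue for signal.
    lg, P, PP, _ = _conditional_quantities(beta, need_info=True)
    info = _information(P, PP, n_r)
    a = np.trace(info) / m
    J = np.full((m, m), 1.0 / m)
    vcov_sz = np.linalg.inv(info + a * J) - J / a
    vcov_sz = 0.5 * (vcov_sz + vcov_sz.T)
    beta_sz = beta - beta.mean()
    fit = RaschFit(
        beta=beta_sz,
        vcov=vcov_sz,
        restriction="sum_zero",
        loglik=ll,
        n_used=n_used,
        item_names=item_names,
        n_iter=n_iter,
    )
    return fit.to_restriction(restriction)
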