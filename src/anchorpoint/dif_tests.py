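"""Anchored item-wise Wald tests for differential item functioning.

Once the two groups' difficulty estimates are on a common scale -- via an
anchor set A whose mean difficulty is equated across groups, or the shift
c implied by a criterion-selected anchor point (which always corresponds
to one or more single anchor items) -- each item is tested with the Wald
statistic

    t_j = (b1_j - b2_j - c) / se_j,    se_j = sqrt(V1_jj + V2_jj),

referred to the standard normal.  The variances are the diagonals of each
group's covariance matrix *re-expressed under the anchor restriction*
(sum of anchor-item parameters fixed at zero): for a single anchor item k
this gives V_jj + V_kk - 2 V_jk, so the sampling noise of the anchor enters
the standard error and the statistic is properly pivotal.  Testing with a
bare shift and no anchor set falls back to the sum-to-zero diagonals.
Anchor items themselves are reported with t = 0 (a single-item anchor is
aligned exactly; its restricted variance is zero).

No correction for the selection of the anchor (point or set) is applied:
the anchor is treated as fixed once chosen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DIFTable", "wald_test", "anchored_test_from_set"]

CORRECTIONS = (None, "bonferroni", "bh")

#: distances below this count as exactly aligned (anchor items at t = 0)
ALIGN_TOL = 1e-9


@dataclass
class DIFTable:
    """Per-item anchored Wald DIF test results.

    ``diff`` holds the aligned differences b1_j - b2_j - c.  ``anchor_set``
    (0-based indices) is set when the shift came from anchor items;
    serialised output labels items 1-based.
    """

    item_names: list[str]
    diff: np.ndarray
    se: np.ndarray
    statistic: np.ndarray
    pvalue: np.ndarray
    flagged: np.ndarray
    shift: float
    alpha: float
    anchor_set: np.ndarray | None = None
    correction: str | None = None

    @property
    def flagged_items(self) -> np.ndarray:
        """0-based indices of items flagged at level alpha."""
        return np.flatnonzero(self.flagged)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.item_names,
                "diff": self.diff,
                "se": self.se,
                "statistic": self.statistic,
                "pvalue": self.pvalue,
                "flagged": self.flagged,
            }
        )

    def to_json(self) -> str:
        payload = {
            "shift": self.shift,
            "alpha": self.alpha,
            "correction": self.correction,
            "anchor_items_1based": None
            if self.anchor_set is None
            else (np.asarray(self.anchor_set) + 1).tolist(),
            "items": [
                {
                    "item": self.item_names[j],
                    "diff": float(self.diff[j]),
                    "se": float(self.se[j]),
                    "statistic": float(self.statistic[j]),
                    "pvalue": float(self.pvalue[j]),
                    "flagged": bool(self.flagged[j]),
                }
                for j in range(len(self.item_names))
            ],
        }
        return json.dumps(payload, indent=2)


def _sum_zero_pair(fit1, fit2):
    f1 = fit1.to_restriction("sum_zero")
    f2 = fit2.to_restriction("sum_zero")
    if f1.n_items != f2.n_items:
        raise ValueError("fits have different numbers of items")
    return f1, f2


def _anchored_variances(vcov: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Diagonal of the covariance under the anchor-sum-zero restriction.

    The restricted estimates are b - mean_A(b), i.e. T b with
    T = I - 1 a^T / |A| (a the anchor indicator), so the diagonal is
    V_jj - (2/|A|) sum_{k in A} V_jk + (1/|A|^2) sum_{k,l in A} V_kl.
    """
    m = vcov.shape[0]
    a = np.zeros(m)
    a[anchor] = 1.0 / anchor.size
    va = vcov @ a
    return np.diag(vcov) - 2.0 * va + float(a @ va)


def wald_test(
    fit1,
    fit2,
    c: float,
    alpha: float = 0.05,
    correction: str | None = None,
    anchor=None,
) -> DIFTable:
    """Item-wise Wald DIF tests at scale shift ``c``.

    When ``anchor`` (0-based item indices) is given, standard errors are
    computed under the corresponding anchor restriction, which propagates
    the anchor items' own sampling variance; without it the sum-to-zero
    diagonals are used (appropriate only for an externally fixed shift).
    No multiple-testing correction is applied by default (per-item level
    alpha); ``correction`` may be ``"bonferroni"`` or ``"bh"``
    (Benjamini--Hochberg), flagging on adjusted p-values.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    f1, f2 = _sum_zero_pair(fit1, fit2)
    m = f1.n_items
    diff = f1.beta - f2.beta - c
    if anchor is not None:
        anchor = np.unique(np.atleast_1d(np.asarray(anchor, dtype=int)))
        if anchor.size == 0:
            raise ValueError("anchor set must be non-empty")
        if np.any((anchor < 0) | (anchor >= m)):
            raise ValueError(f"anchor indices out of range 0..{m - 1}: {anchor.tolist()}")
        var = _anchored_variances(f1.vcov, anchor) + _anchored_variances(f2.vcov, anchor)
    else:
        var = np.diag(f1.vcov) + np.diag(f2.vcov)
    # a zero variance is legitimate only for an exactly aligned anchor item
    degenerate = var <= 0
    bad = degenerate & (np.abs(diff) > ALIGN_TOL)
    if np.any(bad):
        j = int(np.argmax(bad))
        raise ValueError(
            f"zero standard error for item {f1.item_names[j]}; "
            "covariance matrices must come from a proper CML fit"
        )
    se = np.sqrt(np.where(degenerate, np.nan, var))
    t = np.zeros(m)
    ok = ~degenerate
    t[ok] = diff[ok] / se[ok]
    p = 2.0 * stats.norm.sf(np.abs(t))
    p[degenerate] = 1.0
    se = np.where(degenerate, 0.0, se)
    if correction is None:
        flags = p < alpha
    else:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
        flags, p_adj, _, _ = multipletests(p, alpha=alpha, method=method)
        p = p_adj
    return DIFTable(
        item_names=list(f1.item_names),
        diff=diff,
        se=se,
        statistic=t,
        pvalue=p,
        flagged=flags,
        shift=float(c),
        alpha=float(alpha),
        anchor_set=anchor,
        correction=correction,
    )


def anchored_test_from_set(
    fit1, fit2, anchor_set, alpha: float = 0.05, correction: str | None = None
) -> DIFTable:
    """Wald DIF tests anchored on a set of items (0-based indices).

    The shift equating the anchor means, c = mean_A(b1) - mean_A(b2), makes
    the sum of anchor-item parameters equal in both groups; all m items are
    then tested, anchor items included (a single-item anchor {k} reduces to
    the candidate shift b1_k - b2_k, at which t_k = 0).  A = all items
    reproduces the "equal mean" strategy.
    """
    anchor = np.unique(np.atleast_1d(np.asarray(anchor_set, dtype=int)))
    if anchor.size == 0:
        raise ValueError("anchor set must be non-empty")
    f1, f2 = _sum_zero_pair(fit1, fit2)
    m = f1.n_items
    if np.any((anchor < 0) | (anchor >= m)):
        raise ValueError(f"anchor indices out of range 0..{m - 1}: {anchor.tolist()}")
    c = float(f1.beta[anchor].mean() - f2.beta[anchor].mean())
    return wald_test(fit1, fit2, c, alpha=alpha, correction=correction, anchor=anchor)
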