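"""Classical funnel-plot asymmetry detectors.

Three traditional publication-bias tests, implemented from their original
formulations:

* :func:`egger_test` — t-test of the intercept from regressing standardized
  effects ``y_i / s_i`` on precision ``1 / s_i``.
* :func:`begg_test` — Kendall rank correlation between variance-standardized
  deviates from the fixed-effect mean and the study variances, with the
  normal approximation and optional continuity correction.
* :func:`trim_and_fill` — iterative nonparametric estimation of the number
  k0 of suppressed studies on the dominant side of the funnel.  The L0
  rank-sum estimator flags bias whenever k0 > 0; the R0 run-length
  estimator additionally carries an exact null test (the length of the
  outermost same-side run is geometric under symmetry, p = 2^-(R0+1)), and
  flags at p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Method",
    "TestResult",
    "DegenerateDesignError",
    "egger_test",
    "begg_test",
    "trim_and_fill",
    "results_to_csv",
]


class Method(str, Enum):
    EGGER = "egger"
    BEGG = "begg"
    TRIM_FILL = "trim_fill"


class DegenerateDesignError(ValueError):
    """The study design makes the requested statistic undefined."""


@dataclass(frozen=True)
class TestResult:
    method: Method
    statistic: float
    p_value: float | None
    flagged: bool
    k0: int | None = None
    converged: bool = True
    detail: str = ""


def _check(effects, ses, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} studies, got {y.size}")
    if np.any(s <= 0) or not (np.all(np.isfinite(y)) and np.all(np.isfinite(s))):
        raise ValueError("standard errors must be positive and inputs finite")
    return y, s


def egger_test(effects, ses, alpha: float = 0.05) -> TestResult:
    """Egger's regression test for small-study asymmetry.

    OLS of z_i = y_i/s_i on x_i = 1/s_i with intercept; the statistic is the
    intercept t with n-2 degrees of freedom, two-sided.
    """
    y, s = _check(effects, ses, 3)
    n = y.size
    z = y / s
    x = 1.0 / s
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all precisions identical: singular regression")
    res = stats.linregress(x, z)
    t = res.intercept / res.intercept_stderr
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return TestResult(Method.EGGER, float(t), p, flagged=p < alpha,
                      detail=f"intercept={res.intercept:.6g}")


def begg_test(
    effects, ses, alpha: float = 0.05, continuity: bool = True
) -> TestResult:
    """Begg and Mazumdar's rank correlation test.

    Deviates from the fixed-effect pooled mean are standardized by their
    conditional variance ``s_i^2 - (sum 1/s_j^2)^-1`` and Kendall-correlated
    with the study variances; the normal approximation to P - Q gives the
    two-sided p-value.
    """
    y, s = _check(effects, ses, 3)
    n = y.size
    w = 1.0 / s**2
    sw = w.sum()
    mu_fe = (w * y).sum() / sw
    v_cond = s**2 - 1.0 / sw
    if np.any(v_cond <= 0):
        raise DegenerateDesignError(
            "conditional variance s_i^2 - (sum 1/s_j^2)^-1 non-positive"
        )
    t_dev = (y - mu_fe) / np.sqrt(v_cond)
    var = s**2
    p_conc = q_disc = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            prod = (t_dev[i] - t_dev[j]) * (var[i] - var[j])
            if prod > 0:
                p_conc += 1
            elif prod < 0:
                q_disc += 1
    s_stat = p_conc - q_disc
    sd = np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    if continuity and s_stat != 0:
        z = (s_stat - np.sign(s_stat)) / sd
    else:
        z = s_stat / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(Method.BEGG, float(z), p, flagged=p < alpha,
                      detail=f"P={p_conc} Q={q_disc}")


def _rank_sums(deviates: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Ranks of |deviate| plus the rank sums of the two sides."""
    ranks = stats.rankdata(np.abs(deviates))
    right = ranks[deviates > 0].sum()
    left = ranks[deviates < 0].sum()
    return float(right), float(left), ranks


def _run_length(deviates: np.ndarray, ranks: np.ndarray, positive_side: bool) -> int:
    """Length of the outermost run of consecutive top ranks on one side."""
    order = np.argsort(-ranks)  # largest |deviate| first
    run = 0
    for idx in order:
        on_side = deviates[idx] > 0 if positive_side else deviates[idx] < 0
        if on_side:
            run += 1
        else:
            break
    return run


def trim_and_fill(
    effects,
    ses,
    estimator: str = "L0",
    alpha: float = 0.05,
    max_iter: int = 50,
) -> TestResult:
    """Duval and Tweedie's trim-and-fill estimate of suppressed-study count.

    The funnel is centered at the fixed-effect estimate of the k0-trimmed
    data, deviates are ranked by magnitude, and the chosen estimator (L0
    rank-sum or R0 run-length) is iterated until k0 stabilizes.  The side
    assumed to be complete is the one with the larger rank sum at the first
    centering (ties resolve to the positive side).

    Flag rule: L0 flags whenever k0 > 0 (no distribution available); R0
    flags via its exact run-length test at ``alpha``.
    """
    if estimator not in ("L0", "R0"):
        raise ValueError("estimator must be 'L0' or 'R0'")
    y, s = _check(effects, ses, 3)
    n = y.size
    w = 1.0 / s**2

    def fe_mean(mask: np.ndarray) -> float:
        return float((w[mask] * y[mask]).sum() / w[mask].sum())

    mu0 = fe_mean(np.ones(n, dtype=bool))
    right, left, _ = _rank_sums(y - mu0)
    positive_side = right >= left

    k0 = 0
    converged = False
    run = 0
    est_value = 0.0
    for _ in range(max_iter):
        # trim the k0 most extreme studies on the dominant side
        signed = y if positive_side else -y
        order = np.argsort(-signed, kind="stable")
        mask = np.ones(n, dtype=bool)
        mask[order[:k0]] = False
        mu = fe_mean(mask)
        d = y - mu
        right, left, ranks = _rank_sums(d)
        t_dom = right if positive_side else left
        if estimator == "L0":
            est_value = (4.0 * t_dom - n * (n + 1)) / (2.0 * n - 1.0)
            k_new = max(0, int(np.floor(est_value + 0.5)))
        else:
            run = _run_length(d, ranks, positive_side)
            est_value = float(run - 1)
            k_new = max(0, run - 1)
        k_new = min(k_new, n - 2)  # keep at least 2 studies in the trimmed set
        if k_new == k0:
            converged = True
            break
        k0 = k_new

    if estimator == "L0":
        p = None
        flagged = k0 > 0
    else:
        # Under funnel symmetry the outermost run length is geometric(1/2):
        # P(run >= g) = 2^-g, i.e. p = 2^-(R0+1) for the observed R0 = run-1.
        p = float(2.0 ** (-(k0 + 1)))
        flagged = p < alpha
    return TestResult(
        Method.TRIM_FILL,
        float(est_value),
        p,
        flagged=flagged,
        k0=int(k0),
        converged=converged,
        detail=f"side={'right' if positive_side else 'left'}",
    )


def results_to_csv(results: Sequence[tuple[str, TestResult]], path) -> None:
    """Write (cell-id, TestResult) pairs as the benchmark's CSV contract."""
    rows = [
        {
            "cell_id": cid,
            "method": r.method.value,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "k0": r.k0,
            "flagged": int(r.flagged),
        }
        for cid, r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
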