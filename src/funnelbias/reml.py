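"""Random-effects meta-analysis by restricted maximum likelihood.

The normal-normal model ``y_i ~ N(mu, s_i^2 + tau^2)`` is fitted by Fisher
scoring on the restricted log-likelihood of tau^2, with the pooled effect
profiled out as the inverse-variance weighted mean.  Negative tau^2
proposals are truncated at zero and steps are halved whenever a proposal
would decrease the restricted likelihood.  Reaching the iteration cap is a
reportable non-convergence state, not an error: the simulation engine's
regeneration loop consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["REMLFit", "reml_fit", "restricted_loglik", "dersimonian_laird_tau2"]


@dataclass(frozen=True)
class REMLFit:
    """REML fit summary: pooled effect, its SE, tau^2, convergence state."""

    mu_hat: float
    se_mu: float
    tau2_hat: float
    converged: bool
    n_iter: int
    loglik: float

    def __repr__(self) -> str:  # compact, for logs
        return (
            f"REMLFit(mu={self.mu_hat:.4f} ± {self.se_mu:.4f}, "
            f"tau2={self.tau2_hat:.4f}, converged={self.converged}, "
            f"iters={self.n_iter})"
        )


def _validate(effects, ses) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.ndim != 1 or s.shape != y.shape:
        raise ValueError("effects and ses must be 1-d arrays of equal length")
    if y.size < 2:
        raise ValueError("need at least 2 studies")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(s))):
        raise ValueError("non-finite inputs")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    return y, s


def restricted_loglik(tau2: float, effects, ses) -> float:
    """Restricted log-likelihood of tau^2 (intercept-only model), up to a constant."""
    y, s = _validate(effects, ses)
    v = s**2 + tau2
    w = 1.0 / v
    sw = w.sum()
    mu = (w * y).sum() / sw
    return float(-0.5 * (np.log(v).sum() + np.log(sw) + (w * (y - mu) ** 2).sum()))


def dersimonian_laird_tau2(effects, ses) -> float:
    """Method-of-moments tau^2 estimate, truncated at zero (used to initialize)."""
    y, s = _validate(effects, ses)
    w = 1.0 / s**2
    sw = w.sum()
    mu_fe = (w * y).sum() / sw
    q = (w * (y - mu_fe) ** 2).sum()
    denom = sw - (w**2).sum() / sw
    return float(max(0.0, (q - (y.size - 1)) / denom))


def reml_fit(effects, ses, tol: float = 1e-8, max_iter: int = 100) -> REMLFit:
    """Fit the random-effects model by Fisher-scoring REML.

    Convergence is declared when the tau^2 update falls below `tol` within
    `max_iter` iterations; otherwise the fit is returned with
    ``converged=False``.  ``mu_hat`` is always the weighted mean at the
    final tau^2 and ``se_mu = sqrt(1 / sum(1/(s_i^2 + tau2_hat)))``.
    """
    y, s = _validate(effects, ses)
    s2 = s**2
    tau2 = dersimonian_laird_tau2(y, s)
    ll = restricted_loglik(tau2, y, s)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = 1.0 / (s2 + tau2)
        sw = w.sum()
        mu = (w * y).sum() / sw
        w2, w3 = w**2, w**3
        # tr(P) and tr(P^2) for P = V^-1 - V^-1 1 (1' V^-1 1)^-1 1' V^-1
        tr_p = sw - w2.sum() / sw
        tr_pp = w2.sum() - 2.0 * w3.sum() / sw + (w2.sum() / sw) ** 2
        score = -0.5 * tr_p + 0.5 * (w2 * (y - mu) ** 2).sum()
        info = 0.5 * tr_pp
        if info <= 0:
            break
        step = score / info
        proposal = max(0.0, tau2 + step)
        ll_new = restricted_loglik(proposal, y, s)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step *= 0.5
            proposal = max(0.0, tau2 + step)
            ll_new = restricted_loglik(proposal, y, s)
            halvings += 1
        delta = proposal - tau2
        tau2, ll = proposal, ll_new
        if abs(delta) < tol:
            converged = True
            break

    w = 1.0 / (s2 + tau2)
    sw = w.sum()
    return REMLFit(
        mu_hat=float((w * y).sum() / sw),
        se_mu=float(np.sqrt(1.0 / sw)),
        tau2_hat=float(tau2),
        converged=converged,
        n_iter=n_iter,
        loglik=float(ll),
    )
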