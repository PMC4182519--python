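"""Latent permanent-income wealth from dichotomous asset items.

A one-factor binary-probit latent-trait model (the two-parameter normal-ogive
IRT model): household wealth theta ~ N(0, 1), and item m is owned with
probability Phi(a_m + b_m * theta).  For dichotomous items this is exactly
the likelihood of the hierarchical ordered-probit wealth construction used
in asset-index work, so the reduction is implemented directly.

Estimation is marginal maximum likelihood via EM: the E-step computes each
household's posterior over a Gauss-Hermite grid for theta (21 nodes by
default), and the M-step refits every item's (a_m, b_m) by Newton scoring on
posterior-weighted binomial counts aggregated to the quadrature nodes (all
items share the same theta grid, so the M-step is a handful of 2-parameter
concave fits regardless of sample size).  The marginal log-likelihood is
non-decreasing across iterations.  Orientation is fixed by requiring the
loading sum to be positive -- owning items indicates higher wealth.

Household scores are expected-a-posteriori (EAP) latent values, min-max
rescaled to [0, 1] over the sample, matching the unit-interval scale wealth
indices are usually reported on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .survey_stats import weighted_quantile

__all__ = [
    "WealthModel",
    "fit_wealth_model",
    "score_households",
    "quintile_flags",
    "below_dollar_line",
]

_ETA_CLIP = 8.0


def _quad(n_quad: int):
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    theta = np.sqrt(2.0) * x
    wq = w / np.sqrt(np.pi)
    return theta, wq


@dataclass
class WealthModel:
    """Fitted item parameters, quadrature grid and bookkeeping."""

    item_intercepts: np.ndarray
    item_loadings: np.ndarray
    kept_items: np.ndarray  # indices into the original item block
    n_items_input: int
    nodes: np.ndarray
    node_weights: np.ndarray = field(repr=False)
    loglik_path: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    n_iter: int = 0


def _posterior(items, a, b, theta, wq):
    """Posterior over quadrature nodes per household and total log-likelihood."""
    from scipy.special import log_ndtr

    eta = a[:, None] + b[:, None] * theta[None, :]  # items x nodes
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    lp = log_ndtr(eta)
    lq = log_ndtr(-eta)
    ll = items @ (lp - lq) + lq.sum(axis=0)[None, :] + np.log(wq)[None, :]
    m = ll.max(axis=1, keepdims=True)
    e = np.exp(ll - m)
    denom = e.sum(axis=1, keepdims=True)
    post = e / denom
    loglik = float(np.sum(m.ravel() + np.log(denom.ravel())))
    return post, loglik


def _mstep(r1, r0, a, b, theta, n_newton: int = 60):
    """Vectorized Newton (Fisher scoring) probit fits on node-aggregated counts.

    ``r1``/``r0`` are (items x nodes) posterior-weighted success/failure
    counts; each item's 2-parameter probit likelihood is concave, so scoring
    converges rapidly.
    """
    from scipy.special import ndtr
    from scipy.stats import norm

    a = a.copy()
    b = b.copy()
    for _ in range(n_newton):
        eta = np.clip(a[:, None] + b[:, None] * theta[None, :], -_ETA_CLIP, _ETA_CLIP)
        p = np.clip(ndtr(eta), 1e-12, 1 - 1e-12)
        phi = norm.pdf(eta)
        score = phi * (r1 / p - r0 / (1.0 - p))
        ga = score.sum(axis=1)
        gb = (score * theta[None, :]).sum(axis=1)
        w = (r1 + r0) * phi**2 / (p * (1.0 - p))
        haa = w.sum(axis=1)
        hab = (w * theta[None, :]).sum(axis=1)
        hbb = (w * theta[None, :] ** 2).sum(axis=1)
        det = np.maximum(haa * hbb - hab**2, 1e-300)
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        step = np.clip(np.stack([da, db]), -2.0, 2.0)
        a += step[0]
        b += step[1]
        if np.max(np.abs(step)) < 1e-10:
            break
    return a, b


def fit_wealth_model(
    items,
    max_iter: int = 500,
    tol: float = 1e-7,
    n_quad: int = 21,
) -> WealthModel:
    """Fit the one-factor probit model by EM over a Gauss-Hermite grid.

    Items owned by everyone or no one carry no information about the latent
    and are dropped with a warning.  If the log-likelihood change has not
    fallen below ``tol`` after ``max_iter`` EM sweeps, the best iterate is
    returned flagged non-converged.
    """
    y = np.asarray(items, dtype=float)
    if y.ndim != 2:
        raise ValidationError("items must be an n x m binary matrix")
    n, m_in = y.shape
    if n < 200:
        raise ValidationError("need at least 200 households to fit the wealth model")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("items must be binary with no missing values")

    means = y.mean(axis=0)
    keep = (means > 0) & (means < 1)
    if not keep.all():
        dropped = np.flatnonzero(~keep).tolist()
        warnings.warn(
            f"dropping degenerate items (owned by all or none): {dropped}",
            stacklevel=2,
        )
    y = y[:, keep]
    if y.shape[1] < 2:
        raise ValidationError("fewer than 2 informative items")

    theta, wq = _quad(n_quad)
    from scipy.special import ndtri

    a = ndtri(np.clip(y.mean(axis=0), 1e-3, 1 - 1e-3))
    b = np.ones(y.shape[1])

    path = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post, loglik = _posterior(y, a, b, theta, wq)
        path.append(loglik)
        r1 = post.T @ y        # nodes x items
        r0 = post.T @ (1.0 - y)
        a, b = _mstep(r1.T, r0.T, a, b, theta)
        if b.sum() < 0:  # reflection: fix orientation to "owning = wealthier"
            b = -b
        if loglik - prev < tol and it > 1:
            converged = True
            break
        prev = loglik

    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)
    return WealthModel(
        item_intercepts=a,
        item_loadings=b,
        kept_items=np.flatnonzero(keep),
        n_items_input=m_in,
        nodes=theta,
        node_weights=wq,
        loglik_path=np.asarray(path),
        converged=converged,
        n_iter=it,
    )


def score_households(items, model: WealthModel) -> np.ndarray:
    """EAP latent wealth per household, min-max rescaled to [0, 1].

    Scoring is pure: it never refits the model, so a single household can be
    scored against a prefit model.
    """
    y = np.asarray(items, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    if y.shape[1] == model.n_items_input:
        y = y[:, model.kept_items]
    elif y.shape[1] != len(model.kept_items):
        raise ValidationError(
            f"expected {model.n_items_input} (or {len(model.kept_items)} kept) "
            f"item columns, got {y.shape[1]}"
        )
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("items must be binary with no missing values")
    post, _ = _posterior(
        y, model.item_intercepts, model.item_loadings, model.nodes, model.node_weights
    )
    eap = post @ model.nodes
    lo, hi = eap.min(), eap.max()
    if hi == lo:
        return np.full(len(eap), 0.5)
    return (eap - lo) / (hi - lo)


def quintile_flags(scores, weights=None) -> np.ndarray:
    """Flag households at or below the (weighted) lowest wealth quintile.

    Ties at the boundary are all flagged: equal scores get equal treatment.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 5:
        raise ValidationError("need at least 5 households for quintiles")
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    boundary = weighted_quantile(s, w, 0.2)
    return (s <= boundary).astype(np.int8)


def below_dollar_line(
    monthly_income_mzn,
    household_size,
    exchange_rate: float = 30.0,
    line: float = 1.25,
    days_per_month: float = 30.44,
) -> np.ndarray:
    """Flag households below a per-capita USD/day income poverty line.

    Daily per-capita income is monthly income / days per month / household
    size, converted at ``exchange_rate`` MZN per USD (default 30).
    """
    inc = np.atleast_1d(np.asarray(monthly_income_mzn, dtype=float))
    size = np.atleast_1d(np.asarray(household_size, dtype=float))
    if np.any(inc < 0):
        raise ValidationError("monthly income must be non-negative")
    if np.any(size < 1):
        raise ValidationError("household_size must be >= 1")
    if exchange_rate <= 0:
        raise ValidationError("exchange_rate must be > 0")
    daily_pc_usd = inc / days_per_month / size / exchange_rate
    return (daily_pc_usd < line).astype(np.int8)
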