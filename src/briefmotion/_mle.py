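"""Batched maximum-likelihood machinery for conjoint 2AFC logistic fits.

The model for one condition pair (small/large grating) is

    p_i = gamma + (1 - gamma) * logistic((x_i - mu_{g(i)}) / sigma[_{g(i)}])

with x = log10 duration, gamma the 2AFC guess rate (0.5), lapse rate 0,
group g(i) in {0: small, 1: large}, and either a shared scale sigma
(3 free parameters) or one per group (4).  sigma is optimized on the log
scale to keep it positive.  Estimation is Fisher scoring (expected-Hessian
Newton) with step halving, vectorized over a leading batch axis so that
thousands of parametric-bootstrap refits run as a handful of array
operations.

Log-likelihoods omit the binomial combinatorial constant throughout; all
uses (LRT, deviance, comparisons) depend only on differences.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

# parameter layout: shared  -> (mu0, mu1, log sigma)
#                   free    -> (mu0, mu1, log sigma0, log sigma1)


def n_params(share_slope: bool) -> int:
    return 3 if share_slope else 4


def _unpack(theta, grp, share_slope):
    """Per-observation location and scale from a (..., P) parameter array."""
    mu = np.where(grp == 0, theta[..., [0]], theta[..., [1]])
    if share_slope:
        log_s = theta[..., [2]]
        sigma = np.exp(log_s) * np.ones_like(mu)
    else:
        sigma = np.where(
            grp == 0, np.exp(theta[..., [2]]), np.exp(theta[..., [3]])
        )
    return mu, sigma


def prob_correct(theta, x, grp, share_slope, guess=0.5):
    mu, sigma = _unpack(theta, grp, share_slope)
    return guess + (1.0 - guess) * expit((x - mu) / sigma)


def loglik(theta, x, k, n, grp, share_slope, guess=0.5):
    """Binomial log likelihood (no combinatorial constant), batched."""
    p = prob_correct(theta, x, grp, share_slope, guess)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.sum(k * np.log(p) + (n - k) * np.log1p(-p), axis=-1)


def saturated_loglik(k, n):
    """Log likelihood of the saturated model (p_hat = k/n), 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = np.where(n > 0, k / np.maximum(n, 1), 0.0)
        t1 = np.where(k > 0, k * np.log(np.where(phat > 0, phat, 1.0)), 0.0)
        t2 = np.where(
            n - k > 0, (n - k) * np.log(np.where(phat < 1, 1 - phat, 1.0)), 0.0
        )
    return np.sum(t1 + t2, axis=-1)


def _score_fisher(theta, x, k, n, grp, share_slope, guess):
    """Score vector and Fisher information, batched over leading axes."""
    mu, sigma = _unpack(theta, grp, share_slope)
    eta = (x - mu) / sigma
    lam = expit(eta)
    dp_deta = (1.0 - guess) * lam * (1.0 - lam)
    p = guess + (1.0 - guess) * lam
    p = np.clip(p, guess + 1e-12, 1.0 - 1e-12)
    v = p * (1.0 - p)
    u = (k - n * p) / v * dp_deta  # dLL/deta per observation
    w = n * dp_deta**2 / v  # Fisher weight per observation
    in0 = (grp == 0).astype(float)
    in1 = 1.0 - in0
    cols = [-in0 / sigma, -in1 / sigma]
    if share_slope:
        cols.append(-eta)
    else:
        cols.extend([-eta * in0, -eta * in1])
    J = np.stack(np.broadcast_arrays(*cols), axis=-1)  # (..., m, P)
    score = np.einsum("...m,...mp->...p", u, J)
    info = np.einsum("...m,...mp,...mq->...pq", w, J, J)
    return score, info


def fisher_scoring(
    theta0,
    x,
    k,
    n,
    grp,
    share_slope,
    guess=0.5,
    max_iter=100,
    grad_tol=1e-7,
    step_tol=1e-11,
):
    """Maximize the batched log likelihood by damped Fisher scoring.

    Parameters are shaped ``(..., P)``; ``k`` may carry matching leading
    batch axes while ``x``, ``n`` and ``grp`` are shared across the batch.
    Returns ``(theta, ll, converged, n_iter)`` where ``converged`` flags
    batch elements whose score is (near) zero at a finite optimum.
    """
    theta = np.array(theta0, float)
    single = theta.ndim == 1
    if single:
        theta = theta[None, :]
        k = np.asarray(k, float)
    P = theta.shape[-1]
    ll = loglik(theta, x, k, n, grp, share_slope, guess)
    converged = np.zeros(theta.shape[:-1], bool)
    eye = np.eye(P)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        score, info = _score_fisher(theta, x, k, n, grp, share_slope, guess)
        trace = np.einsum("...ii->...", info)
        ridge = (1e-9 * trace / P + 1e-12)[..., None, None] * eye
        try:
            step = np.linalg.solve(info + ridge, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum(
                "...pq,...q->...p", np.linalg.pinv(info + ridge), score
            )
        step = np.nan_to_num(step, nan=0.0, posinf=0.0, neginf=0.0)
        # cap huge steps (separable data push mu/log-sigma to infinity)
        norm = np.max(np.abs(step), axis=-1, keepdims=True)
        step = np.where(norm > 10.0, step * (10.0 / norm), step)
        scale = np.ones(theta.shape[:-1])
        for _ in range(30):
            cand = theta + scale[..., None] * step
            ll_new = loglik(cand, x, k, n, grp, share_slope, guess)
            bad = ll_new < ll - 1e-10
            if not np.any(bad):
                break
            scale = np.where(bad, scale * 0.5, scale)
        theta = theta + scale[..., None] * step
        ll_new = loglik(theta, x, k, n, grp, share_slope, guess)
        gmax = np.max(np.abs(score), axis=-1)
        smax = np.max(np.abs(scale[..., None] * step), axis=-1)
        converged = (gmax < grad_tol * (1.0 + np.abs(ll_new))) | (smax < step_tol)
        ll = ll_new
        if converged.all():
            break
    if single:
        return theta[0], float(ll[0]), bool(converged[0]), n_iter
    return theta, ll, converged, n_iter


def moment_start(x, k, n, grp, share_slope, guess=0.5):
    """Moment-based starting values: locations from the interpolated
    0.75 crossing of the empirical proportions, scale from the data span."""
    x = np.asarray(x, float)
    span = max(x.max() - x.min(), 1e-3)
    mus = []
    for g in (0, 1):
        m = grp == g
        xs, ks, ns = x[m], k[m], n[m]
        order = np.argsort(xs)
        xs, ps = xs[order], (ks / np.maximum(ns, 1))[order]
        target = guess + (1 - guess) / 2.0  # 0.75 for 2AFC
        above = np.nonzero(ps >= target)[0]
        if above.size == 0:
            mus.append(xs[-1] + 0.25 * span)
        elif above[0] == 0:
            mus.append(xs[0] - 0.25 * span)
        else:
            i = above[0]
            frac = (target - ps[i - 1]) / max(ps[i] - ps[i - 1], 1e-9)
            mus.append(xs[i - 1] + frac * (xs[i] - xs[i - 1]))
    sigma0 = 0.2 * span
    if share_slope:
        return np.array([mus[0], mus[1], np.log(sigma0)])
    return np.array([mus[0], mus[1], np.log(sigma0), np.log(sigma0)])


def at_boundary(theta, x, share_slope):
    """Flag parameter vectors at an effective boundary of the model.

    Separable or monotone-degenerate data drive the scale toward 0 or
    infinity and/or the location far outside the sampled range; such fits
    are reported as non-converged rather than silently returned.
    """
    theta = np.asarray(theta, float)
    x = np.asarray(x, float)
    span = max(x.max() - x.min(), 1e-3)
    mu = theta[..., :2]
    log_s = theta[..., 2:]
    mu_bad = np.any(
        (mu < x.min() - 3.0 * span) | (mu > x.max() + 3.0 * span), axis=-1
    )
    sig = np.exp(log_s)
    sig_bad = np.any((sig < 1e-3 * span) | (sig > 10.0 * span), axis=-1)
    return mu_bad | sig_bad
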