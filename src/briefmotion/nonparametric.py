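"""Nonparametric psychometric-function smoothing and thresholds.

A flexibility check on the logistic fits: the proportion correct is
smoothed by a kernel-weighted local-linear binomial fit on the link scale
(the guess-rate-adjusted logit, mapping [0.5, 1) onto the real line), with
the kernel bandwidth chosen from a grid by leave-one-out deviance.  The
threshold is the smallest duration at which the smoothed curve crosses
the 75%-correct criterion.  Because the local fit maximizes a weighted
binomial likelihood rather than transforming observed proportions, it
tolerates below-chance cells (the short-duration "reversals" some
observers show) that would be undefined on the link scale.

This estimator plays the same role as the local-linear fits of the R
``modelfree`` tradition: a model-agnostic cross-check whose thresholds
should closely match the logistic ones whenever the logistic model is
adequate.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .exceptions import DegenerateDataError
from .fitting import GUESS_RATE, ConditionCounts

__all__ = ["LocalLinearPsychometric", "nonparametric_threshold"]


def _local_fit(x, k, n, w, guess, max_iter=60):
    """Maximize sum w_i [k log p + (n-k) log(1-p)] for p = g + (1-g)expit(a + b x).

    2-parameter Fisher scoring with step halving; x is already centered on
    the evaluation point.  Returns (a, b, converged).
    """
    wk, wn = w * k, w * n
    tot_n = wn.sum()
    if tot_n <= 0:
        return 0.0, 0.0, False
    pbar = np.clip(wk.sum() / tot_n, guess + 1e-3, 1.0 - 1e-3)
    a = float(logit((pbar - guess) / (1.0 - guess)))
    b = 2.0
    theta = np.array([a, b])

    def ll(t):
        p = guess + (1 - guess) * expit(t[0] + t[1] * x)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(w * (k * np.log(p) + (n - k) * np.log1p(-p))))

    cur = ll(theta)
    converged = False
    for _ in range(max_iter):
        lam = expit(theta[0] + theta[1] * x)
        p = guess + (1 - guess) * lam
        p = np.clip(p, guess + 1e-12, 1 - 1e-12)
        dp = (1 - guess) * lam * (1 - lam)
        v = p * (1 - p)
        u = w * (k - n * p) / v * dp
        fw = w * n * dp**2 / v
        Z = np.column_stack([np.ones_like(x), x])
        score = Z.T @ u
        info = (Z * fw[:, None]).T @ Z + 1e-10 * np.eye(2)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -20, 20)
        scale = 1.0
        for _ in range(30):
            new = ll(theta + scale * step)
            if new >= cur - 1e-12:
                break
            scale *= 0.5
        theta = theta + scale * step
        new = ll(theta)
        if np.max(np.abs(score)) < 1e-8 * (1 + abs(new)) or abs(new - cur) < 1e-12:
            cur = new
            converged = True
            break
        cur = new
    return float(theta[0]), float(theta[1]), converged


class LocalLinearPsychometric(BaseEstimator):
    """Kernel local-linear binomial smoother on log10 duration.

    Parameters
    ----------
    bandwidth : float or None
        Gaussian kernel SD in log10-duration units; None selects from
        ``bandwidth_grid`` by leave-one-out deviance.
    bandwidth_grid : sequence of float or None
        Candidate bandwidths; defaults to multiples (1, 1.5, 2.25, 3.4, 5)
        of the median grid spacing.
    guess_rate : float, default 0.5
    n_grid : int, default 201
        Evaluation points for the smoothed curve and threshold search.
    """

    def __init__(
        self,
        bandwidth: float | None = None,
        bandwidth_grid=None,
        guess_rate: float = GUESS_RATE,
        n_grid: int = 201,
    ):
        self.bandwidth = bandwidth
        self.bandwidth_grid = bandwidth_grid
        self.guess_rate = guess_rate
        self.n_grid = n_grid

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float)
        n = (
            np.ones_like(y)
            if sample_weight is None
            else np.asarray(sample_weight, float)
        )
        keep = n > 0
        x, y, n = x[keep], y[keep], n[keep]
        if len(np.unique(x)) < 4:
            raise DegenerateDataError("need at least 4 distinct durations")
        order = np.argsort(x)
        self._x_, self._n_ = x[order], n[order]
        self._k_ = (y * n)[order]
        if self.bandwidth is not None:
            self.bandwidth_ = float(self.bandwidth)
        else:
            grid = self.bandwidth_grid
            if grid is None:
                spacing = float(np.median(np.diff(np.unique(self._x_))))
                grid = spacing * np.array([1.0, 1.5, 2.25, 3.4, 5.0])
            self.bandwidth_ = float(min(grid, key=self._loo_deviance))
        self.loo_deviance_ = self._loo_deviance(self.bandwidth_)
        return self

    def _loo_deviance(self, h: float) -> float:
        x, k, n = self._x_, self._k_, self._n_
        dev = 0.0
        for j in range(len(x)):
            w = np.exp(-((x - x[j]) ** 2) / (2 * h**2))
            w[j] = 0.0
            a, b, _ = _local_fit(x - x[j], k, n, w, self.guess_rate)
            p = np.clip(
                self.guess_rate + (1 - self.guess_rate) * expit(a), 1e-12, 1 - 1e-12
            )
            phat = k[j] / n[j]
            sat = 0.0
            if k[j] > 0:
                sat += k[j] * np.log(phat)
            if n[j] - k[j] > 0:
                sat += (n[j] - k[j]) * np.log(1 - phat)
            fit_ll = k[j] * np.log(p) + (n[j] - k[j]) * np.log1p(-p)
            dev += 2.0 * (sat - fit_ll)
        return float(dev)

    def predict(self, X):
        """Smoothed probability correct at the given log10 durations."""
        xq = np.atleast_1d(np.asarray(X, float)).reshape(-1)
        out = np.empty(len(xq))
        for i, x0 in enumerate(xq):
            w = np.exp(-((self._x_ - x0) ** 2) / (2 * self.bandwidth_**2))
            a, _, _ = _local_fit(
                self._x_ - x0, self._k_, self._n_, w, self.guess_rate
            )
            out[i] = self.guess_rate + (1 - self.guess_rate) * expit(a)
        return out

    def threshold(self, criterion: float = 0.75) -> float:
        """Smallest duration (s) at which the smoothed curve reaches ``criterion``.

        Returns NaN (a distinguished no-threshold value, not an exception)
        when the curve never reaches the criterion within the sampled
        range.  A curve already above criterion at the shortest duration
        yields that duration.
        """
        if not self.guess_rate < criterion < 1.0:
            raise ValueError(f"criterion must be in ({self.guess_rate}, 1)")
        grid = np.linspace(self._x_[0], self._x_[-1], self.n_grid)
        p = self.predict(grid)
        if p[0] >= criterion:
            return float(10.0 ** grid[0])
        above = np.nonzero(p >= criterion)[0]
        if above.size == 0:
            return float("nan")
        i = above[0]
        frac = (criterion - p[i - 1]) / max(p[i] - p[i - 1], 1e-12)
        return float(10.0 ** (grid[i - 1] + frac * (grid[i] - grid[i - 1])))


def nonparametric_threshold(
    counts: ConditionCounts,
    bandwidth_grid=None,
    criterion: float = 0.75,
) -> float:
    """Nonparametric 75%-correct threshold for one condition's counts."""
    est = LocalLinearPsychometric(bandwidth_grid=bandwidth_grid)
    est.fit(
        counts.log10_durations,
        counts.k / np.maximum(counts.n, 1),
        sample_weight=counts.n,
    )
    return est.threshold(criterion)
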