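"""Mean-variance modeling of normalized signal intensities.

Log-count data carry a strong dependence of variance on mean intensity, so
raw variances of different regions are not comparable.  The mean-variance
curve (MVC) f(mu) is fitted by local likelihood under a gamma observation
family with a log link: at each evaluation point the locally linear
log-predictor eta(u) = b0 + b1*(u - x0) maximizes the tricube-weighted gamma
log-likelihood over the span-nearest neighbors, and f(x0) = exp(b0).  The
per-region test statistic is the scaled variance t_hat / f(mu_hat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_SPAN = 0.5
GRID_SIZE = 1000


@dataclass
class MeanVarianceTable:
    """Observed per-region moments and (once scaled) test statistics.

    ``z`` is the natural-log scaled variance; rows with zero observed
    variance carry a ``-inf`` sentinel there.
    """

    mu_hat: pd.Series
    t_hat: pd.Series
    m: int
    scaled: pd.Series | None = None
    z: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"mu_hat": self.mu_hat, "t_hat": self.t_hat}
        if self.scaled is not None:
            cols["scaled_var"] = self.scaled
            cols["z"] = self.z
        return pd.DataFrame(cols)


@dataclass
class MeanVarianceCurve:
    """Fitted MVC tabulated on an ascending grid; interpolated on demand."""

    grid_mu: np.ndarray
    grid_f: np.ndarray
    span: float

    def __post_init__(self):
        self.grid_mu = np.asarray(self.grid_mu, dtype=float)
        self.grid_f = np.asarray(self.grid_f, dtype=float)
        if np.any(np.diff(self.grid_mu) <= 0):
            raise ValueError("grid_mu must be strictly ascending")
        if np.any(self.grid_f <= 0) or not np.all(np.isfinite(self.grid_f)):
            raise ValueError("fitted variances must be positive and finite")

    def __call__(self, mu) -> np.ndarray:
        return predict_variance(self, mu)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.grid_mu, "f": self.grid_f})

    @classmethod
    def from_function(cls, f, mu_min: float, mu_max: float, n: int = GRID_SIZE):
        """Tabulate a known variance function (e.g. a simulator's truth)."""
        grid = np.linspace(mu_min, mu_max, n)
        return cls(grid, np.asarray(f(grid), dtype=float), span=np.nan)


def mean_variance(x: pd.DataFrame) -> MeanVarianceTable:
    """Row means and unbiased (divisor m-1) row variances."""
    m = x.shape[1]
    if m < 2:
        raise ValueError("at least two samples are required")
    vals = x.to_numpy(dtype=float)
    mu = vals.mean(axis=1)
    t = vals.var(axis=1, ddof=1)
    return MeanVarianceTable(
        mu_hat=pd.Series(mu, index=x.index, name="mu_hat"),
        t_hat=pd.Series(t, index=x.index, name="t_hat"),
        m=m,
    )


def _local_gamma_fit(t: np.ndarray, u: np.ndarray, w: np.ndarray) -> float:
    """Maximize sum w*(-t*exp(-eta) - eta) over eta = b0 + b1*u; return b0.

    This is the gamma log-likelihood with log link up to the shape constant.
    The Hessian is negative definite for positive t, so damped Newton steps
    converge; on failure the caller falls back to the weighted mean.
    """
    b = np.array([np.log(np.average(t, weights=w)), 0.0])
    X = np.column_stack([np.ones_like(u), u])
    for _ in range(50):
        eta = X @ b
        r = t * np.exp(-np.clip(eta, -700, 700))
        grad = X.T @ (w * (r - 1.0))
        H = (X * (w * r)[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise FloatingPointError("singular local Hessian")
        # damp oversized steps to keep exp() in range
        nrm = np.max(np.abs(step))
        if nrm > 10:
            step *= 10 / nrm
        b = b + step
        if np.max(np.abs(grad)) < 1e-10 or np.max(np.abs(step)) < 1e-12:
            break
    if not np.all(np.isfinite(b)):
        raise FloatingPointError("non-finite local fit")
    return float(b[0])


def fit_mvc(
    table: MeanVarianceTable, span: float = DEFAULT_SPAN, grid_size: int = GRID_SIZE
) -> MeanVarianceCurve:
    """Fit the MVC on regions with positive observed variance.

    At each of ``grid_size`` uniform evaluation points over the mu_hat range,
    the span-nearest neighbors receive tricube weights and a locally linear
    gamma log-link model is maximized; non-converged points fall back to the
    tricube-weighted mean of t_hat with a warning.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    mu = table.mu_hat.to_numpy(dtype=float)
    t = table.t_hat.to_numpy(dtype=float)
    pos = t > 0
    if pos.sum() < 50:
        raise ValueError(
            f"need >= 50 regions with positive variance, got {int(pos.sum())}"
        )
    mu_p, t_p = mu[pos], t[pos]
    order = np.argsort(mu_p, kind="stable")
    mu_s, t_s = mu_p[order], t_p[order]
    n = mu_s.size
    k = min(n, max(2, int(np.ceil(span * n))))
    grid = np.linspace(mu.min(), mu.max(), grid_size)
    fitted = np.empty(grid_size)
    fallbacks = 0
    for gi, x0 in enumerate(grid):
        lo = int(np.searchsorted(mu_s, x0)) - k // 2
        lo = min(max(lo, 0), n - k)
        # slide window edges toward the k nearest neighbors of x0
        while lo > 0 and x0 - mu_s[lo - 1] < mu_s[lo + k - 1] - x0:
            lo -= 1
        while lo + k < n and mu_s[lo + k] - x0 < x0 - mu_s[lo]:
            lo += 1
        win = slice(lo, lo + k)
        u = mu_s[win] - x0
        h = np.max(np.abs(u))
        if h == 0:
            w = np.ones(k)
        else:
            w = (1 - np.minimum(np.abs(u) / h, 1.0) ** 3) ** 3
            w = np.maximum(w, 1e-12)
        try:
            fitted[gi] = np.exp(_local_gamma_fit(t_s[win], u, w))
        except FloatingPointError:
            fallbacks += 1
            fitted[gi] = np.average(t_s[win], weights=w)
    if fallbacks:
        warnings.warn(
            f"local gamma fit fell back to weighted mean at {fallbacks} grid points"
        )
    return MeanVarianceCurve(grid, fitted, span)


def predict_variance(curve: MeanVarianceCurve, mu) -> np.ndarray:
    """Piecewise-linear interpolation of f, clamped beyond the fitted range."""
    return np.interp(
        np.asarray(mu, dtype=float), curve.grid_mu, curve.grid_f
    )


def scaled_variances(
    table: MeanVarianceTable, curve: MeanVarianceCurve
) -> MeanVarianceTable:
    """Attach scaled variances t_hat / f(mu_hat) and their natural logs."""
    f = predict_variance(curve, table.mu_hat.to_numpy())
    scaled = table.t_hat.to_numpy() / f
    with np.errstate(divide="ignore"):
        z = np.where(scaled > 0, np.log(np.maximum(scaled, 1e-300)), -np.inf)
    return MeanVarianceTable(
        mu_hat=table.mu_hat,
        t_hat=table.t_hat,
        m=table.m,
        scaled=pd.Series(scaled, index=table.mu_hat.index, name="scaled_var"),
        z=pd.Series(z, index=table.mu_hat.index, name="z"),
    )
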