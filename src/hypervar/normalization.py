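"""MA normalization of log2 read counts against a pseudo-reference profile.

Raw counts are transformed as Y_ij = log2(K_ij + 0.5).  A pseudo-reference
profile P_i averages Y over the samples occupying each region.  Each sample j
is then linearly rescaled, X_ij = alpha_j + beta_j * Y_ij, with (alpha_j,
beta_j) chosen so that over the regions occupied by the sample

* the M values (X - P) have zero mean, and
* the M values are uncorrelated with the A values ((X + P) / 2),

i.e. the global signal difference and the M-A trend against the baseline are
simultaneously removed.  The closed-form solution is
beta_j = sd_occ(P) / sd_occ(Y) (positive root) and
alpha_j = (sum_occ P - beta_j * sum_occ Y) / n_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateSampleError(ValueError):
    """A sample has too few occupied regions or zero spread over them."""


@dataclass
class NormalizationCoefficients:
    """Per-sample affine coefficients (beta_j > 0 always)."""

    alpha: pd.Series
    beta: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"alpha": self.alpha, "beta": self.beta})


def log_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Y = log2(K + 0.5); raises on negative counts."""
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    return pd.DataFrame(
        np.log2(vals + 0.5), index=counts.index, columns=counts.columns
    )


def pseudo_reference(logs: pd.DataFrame, occ: pd.DataFrame) -> pd.Series:
    """Occupancy-weighted per-region mean of Y; 0 where no sample occupies.

    The zero branch is notational only: such regions are occupied by no
    sample, so their P_i never enters any sample's fit.
    """
    if logs.shape != occ.shape:
        raise ValueError("log-count and occupancy shapes differ")
    o = occ.to_numpy(dtype=float)
    y = logs.to_numpy(dtype=float)
    denom = o.sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(denom > 0, (o * y).sum(axis=1) / np.maximum(denom, 1), 0.0)
    return pd.Series(p, index=logs.index, name="pseudo_reference")


def fit_sample_normalization(
    y_j: np.ndarray, o_j: np.ndarray, ref: np.ndarray
) -> tuple[float, float]:
    """Solve the two-constraint system for one sample; returns (alpha, beta).

    Sample statistics use the same divisor n_j in numerator and denominator,
    so the variance convention cancels; computed with plain sums.
    """
    mask = np.asarray(o_j, dtype=bool)
    n_j = int(mask.sum())
    if n_j < 2:
        raise DegenerateSampleError(f"only {n_j} occupied regions")
    y = np.asarray(y_j, dtype=float)[mask]
    p = np.asarray(ref, dtype=float)[mask]
    ss_y = np.sum((y - y.mean()) ** 2)
    ss_p = np.sum((p - p.mean()) ** 2)
    if ss_y <= 0 or ss_p <= 0:
        raise DegenerateSampleError("zero spread over occupied regions")
    beta = float(np.sqrt(ss_p / ss_y))
    alpha = float((p.sum() - beta * y.sum()) / n_j)
    return alpha, beta


def normalize_all(
    counts: pd.DataFrame, occ: pd.DataFrame
) -> tuple[pd.DataFrame, NormalizationCoefficients]:
    """Normalize every sample against the pseudo-reference.

    The fitted affine map is applied to *all* cells of a sample, occupied or
    not (the unoccupied cells are needed downstream by the variance model).
    """
    y = log_transform(counts)
    ref = pseudo_reference(y, occ).to_numpy()
    alphas, betas = {}, {}
    x = np.empty(y.shape, dtype=float)
    for j, sample in enumerate(y.columns):
        try:
            a, b = fit_sample_normalization(
                y.iloc[:, j].to_numpy(), occ.iloc[:, j].to_numpy(), ref
            )
        except DegenerateSampleError as err:
            raise DegenerateSampleError(f"sample {sample!r}: {err}") from None
        alphas[sample], betas[sample] = a, b
        x[:, j] = a + b * y.iloc[:, j].to_numpy()
    coeffs = NormalizationCoefficients(
        alpha=pd.Series(alphas, name="alpha"),
        beta=pd.Series(betas, name="beta"),
    )
    return pd.DataFrame(x, index=y.index, columns=y.columns), coeffs


def ma_residuals(
    x: pd.DataFrame, occ: pd.DataFrame, ref: pd.Series
) -> pd.DataFrame:
    """Per-sample diagnostics: mean of M and covariance of (M, A) over the
    occupied regions.  Both are ~0 (to floating point) after normalization."""
    rows = {}
    refv = ref.to_numpy()
    for j, sample in enumerate(x.columns):
        mask = occ.iloc[:, j].to_numpy(dtype=bool)
        m = x.iloc[:, j].to_numpy()[mask] - refv[mask]
        a = (x.iloc[:, j].to_numpy()[mask] + refv[mask]) / 2.0
        rows[sample] = {
            "mean_M": float(m.mean()),
            "cov_MA": float(np.mean((m - m.mean()) * (a - a.mean()))),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
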