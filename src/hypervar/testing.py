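"""Significance testing of scaled variances and comparator rankers.

Under the fitted model the scaled variance of a null region follows
gamma * F_{m-1, d0}, so the hypervariable-region (HVR) p-value is the upper
tail of F_{m-1, d0} evaluated at scaled / gamma, and the lowly-variable
(LVR) p-value is the complementary lower tail.  d0 = inf degenerates the
null to chi2_{m-1} / (m-1).  Multiple testing uses Benjamini-Hochberg;
strata (proximal/distal) are adjusted separately by the pipeline.

Also provided are the simpler variability rankers commonly used in place of
a model-based test (raw variance, MAD, IQR, the min-rank heuristic, and
quantile-normalized log2-CPM variance with a large offset), for benchmarking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimation import ModelFit
from .mvc import MeanVarianceTable

HVR = "HVR"
LVR = "LVR"
NEITHER = "neither"

COMPARATORS = ("variance", "mad", "iqr", "min_rank", "large_offset")


@dataclass
class RegionTestResult:
    """Per-region test table (one stratum)."""

    table: pd.DataFrame  # mu_hat, t_hat, scaled_var, p_hvr, q_hvr, p_lvr, q_lvr, call
    stratum: str = "unassigned"


def _null_sf(scaled_over_gamma: np.ndarray, d1: int, d0: float) -> np.ndarray:
    if math.isinf(d0):
        return stats.chi2.sf(scaled_over_gamma * d1, d1)
    return stats.f.sf(scaled_over_gamma, d1, d0)


def hvr_pvalues(table: MeanVarianceTable, fit: ModelFit) -> pd.Series:
    """Upper-tail p-values of gamma * F_{m-1, d0} at the scaled variances.

    Regions with zero observed variance cannot be hypervariable and get p=1.
    """
    if fit.m != table.m:
        raise ValueError("sample counts of table and fit disagree")
    if table.scaled is None:
        raise ValueError("table lacks scaled variances; run scaled_variances first")
    s = table.scaled.to_numpy(dtype=float)
    p = np.ones_like(s)
    posmask = s > 0
    p[posmask] = _null_sf(s[posmask] / fit.gamma, fit.m - 1, fit.d0)
    # zero scaled variance: upper tail at 0 is 1 by convention
    return pd.Series(p, index=table.scaled.index, name="p_hvr")


def lvr_pvalues(table: MeanVarianceTable, fit: ModelFit) -> pd.Series:
    """Lower-tail p-values: 1 - p_hvr for t_hat > 0, else exactly 0."""
    p_h = hvr_pvalues(table, fit).to_numpy()
    t = table.t_hat.to_numpy(dtype=float)
    p = np.where(t > 0, 1.0 - p_h, 0.0)
    return pd.Series(p, index=table.t_hat.index, name="p_lvr")


def bh_adjust(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_regions(
    table: MeanVarianceTable, fit: ModelFit, stratum: str = "unassigned"
) -> RegionTestResult:
    """Assemble the full per-region result table for one stratum."""
    p_h = hvr_pvalues(table, fit)
    p_l = lvr_pvalues(table, fit)
    df = table.to_frame()
    df["p_hvr"] = p_h
    df["q_hvr"] = bh_adjust(p_h.to_numpy())
    df["p_lvr"] = p_l
    df["q_lvr"] = bh_adjust(p_l.to_numpy())
    df["call"] = NEITHER
    return RegionTestResult(table=df, stratum=stratum)


def call_regions(result: RegionTestResult, cutoff: float = 0.1) -> RegionTestResult:
    """Call HVR/LVR by strict q < cutoff (a region cannot be both for
    cutoff <= 0.5)."""
    df = result.table.copy()
    call = np.full(len(df), NEITHER, dtype=object)
    call[df["q_hvr"].to_numpy() < cutoff] = HVR
    call[df["q_lvr"].to_numpy() < cutoff] = LVR
    both = (df["q_hvr"].to_numpy() < cutoff) & (df["q_lvr"].to_numpy() < cutoff)
    if both.any():  # possible only for cutoff > 0.5; keep the larger tail
        call[both] = np.where(
            df["q_hvr"].to_numpy()[both] <= df["q_lvr"].to_numpy()[both], HVR, LVR
        )
    df["call"] = call
    return RegionTestResult(table=df, stratum=result.stratum)


def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Column-wise quantile normalization against the mean sorted profile.

    Ties within a column receive the mean of the reference quantiles they
    span (average-tie rule).
    """
    order_stats = np.sort(x, axis=0)
    reference = order_stats.mean(axis=1)
    out = np.empty_like(x, dtype=float)
    n = x.shape[0]
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[np.minimum(hi, n - 1)])
    return out


def rank_comparators(
    x: pd.DataFrame | None,
    counts: pd.DataFrame | None,
    method: str,
    offset: int = 5,
) -> pd.Series:
    """Per-region 'hypervariability' scores under the simpler schemes.

    variance / mad / iqr: the row statistic of the normalized matrix (MAD is
    unscaled; IQR uses linear-interpolation quantiles).  min_rank: the
    minimum of the 1-based ascending ranks of the row mean and row variance
    (regions strong in both score high).  large_offset: row variance of
    quantile-normalized log2 counts-per-million with a moderately large
    prior count.  Higher score = more hypervariable in every scheme.
    """
    if method not in COMPARATORS:
        raise ValueError(f"unknown method {method!r}; choose from {COMPARATORS}")
    if method == "large_offset":
        if counts is None:
            raise ValueError("large_offset requires raw counts")
        k = counts.to_numpy(dtype=float)
        lib = k.sum(axis=0)
        # prior count scaled per library, mirroring the usual log-CPM recipe
        pc = offset * lib / lib.mean()
        logcpm = np.log2((k + pc) / (lib + 2 * pc) * 1e6)
        qn = _quantile_normalize(logcpm)
        score = qn.var(axis=1, ddof=1)
        return pd.Series(score, index=counts.index, name=method)
    if x is None:
        raise ValueError(f"{method} requires the normalized matrix")
    vals = x.to_numpy(dtype=float)
    if method == "variance":
        score = vals.var(axis=1, ddof=1)
    elif method == "mad":
        med = np.median(vals, axis=1, keepdims=True)
        score = np.median(np.abs(vals - med), axis=1)
    elif method == "iqr":
        q75, q25 = np.quantile(vals, [0.75, 0.25], axis=1)
        score = q75 - q25
    else:  # min_rank
        mean_rank = stats.rankdata(vals.mean(axis=1), method="average")
        var_rank = stats.rankdata(vals.var(axis=1, ddof=1), method="average")
        score = np.minimum(mean_rank, var_rank)
    return pd.Series(score, index=x.index, name=method)
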