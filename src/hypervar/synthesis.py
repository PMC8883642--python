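"""Synthetic data with the exact statistical structure of the variance model.

The generator draws, for each region, a latent mean intensity mu_i and a
latent variance sigma2_i whose reciprocal follows a scaled chi-square:
1/sigma2 ~ (1/f(mu)) * chi2_{d0} / d0 (d0 = inf pins sigma2 = f(mu)).
Normalized signals are then X_ij ~ Normal(mu_i, gamma * sigma2_i), i.i.d.
across samples, so that scaled variances t_hat / f(mu) follow
gamma * F_{m-1, d0} exactly.  Contamination flags a chosen fraction of
regions as hypervariable (variance multiplied by hvr_fold) or lowly variable
(multiplied by lvr_shrink), with placement either uniform or enriched at
high intensities (sampling probability proportional to the rank of mu).

A separate count-level generator produces Poisson read counts with
per-sample sequencing depths for exercising the normalization front end,
and a label/genotype generator builds fixtures for the clustering and QTL
analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import occupancy_from_counts


def default_mvc(a: float = 0.05, b: float = 1.0):
    """Decreasing variance trend f(mu) = a + b * 2^(-mu): small log-counts
    have larger variances, the shape typical of log count data."""
    def f(mu):
        return a + b * np.power(2.0, -np.asarray(mu, dtype=float))
    return f


@dataclass
class SimulationConfig:
    """Study conditions for the model-faithful simulator.

    Defaults mirror the standard evaluation setting used throughout the
    package's tests: 20000 regions, 10 samples, d0 = 5, gamma = 1.2, 5%
    HVRs with 4x variance placed preferentially at high intensities.
    """

    n_regions: int = 20000
    m: int = 10
    mvc: object = field(default_factory=default_mvc)
    mu_range: tuple[float, float] = (2.0, 8.0)
    d0_true: float = 5.0
    gamma_true: float = 1.2
    hvr_fraction: float = 0.05
    hvr_fold: float = 4.0
    lvr_fraction: float = 0.0
    lvr_shrink: float = 0.25
    intensity_bias: str = "high"  # "uniform" | "high"
    seed: int | None = None

    def validate(self) -> None:
        if self.n_regions < 1 or self.m < 2:
            raise ValueError("need n_regions >= 1 and m >= 2")
        if not (0 <= self.hvr_fraction < 1 and 0 <= self.lvr_fraction < 1):
            raise ValueError("fractions must lie in [0, 1)")
        if self.hvr_fraction + self.lvr_fraction >= 1:
            raise ValueError("contamination fractions must sum to < 1")
        if self.hvr_fraction > 0 and self.hvr_fold <= 1:
            raise ValueError("hvr_fold must exceed 1")
        if self.lvr_fraction > 0 and not 0 < self.lvr_shrink < 1:
            raise ValueError("lvr_shrink must lie in (0, 1)")
        if self.intensity_bias not in ("uniform", "high"):
            raise ValueError("intensity_bias must be 'uniform' or 'high'")
        if self.d0_true <= 0 or self.gamma_true <= 0:
            raise ValueError("d0_true and gamma_true must be positive")
        lo, hi = self.mu_range
        probe = np.linspace(lo, hi, 64)
        if np.any(np.asarray(self.mvc(probe)) <= 0):
            raise ValueError("f(mu) must be positive over mu_range")


@dataclass
class SimulationTruth:
    """Ground truth per region: latent moments and contamination flags."""

    mu: np.ndarray
    sigma2: np.ndarray
    is_hvr: np.ndarray
    is_lvr: np.ndarray


def _flag_regions(
    rng: np.random.Generator, mu: np.ndarray, frac_hvr: float,
    frac_lvr: float, bias: str
) -> tuple[np.ndarray, np.ndarray]:
    n = mu.size
    n_hvr = int(round(frac_hvr * n))
    n_lvr = int(round(frac_lvr * n))
    is_hvr = np.zeros(n, dtype=bool)
    is_lvr = np.zeros(n, dtype=bool)
    if n_hvr:
        if bias == "high":
            w = np.argsort(np.argsort(mu)) + 1.0  # rank(mu)
            p = w / w.sum()
        else:
            p = None
        idx = rng.choice(n, size=n_hvr, replace=False, p=p)
        is_hvr[idx] = True
    if n_lvr:
        pool = np.flatnonzero(~is_hvr)
        idx = rng.choice(pool, size=n_lvr, replace=False)
        is_lvr[idx] = True
    return is_hvr, is_lvr


def simulate_normalized(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw a normalized region x sample matrix from the variance model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_regions, config.m
    lo, hi = config.mu_range
    mu = rng.uniform(lo, hi, size=n)
    f_mu = np.asarray(config.mvc(mu), dtype=float)
    if math.isinf(config.d0_true):
        sigma2 = f_mu.copy()
    else:
        sigma2 = f_mu * config.d0_true / rng.chisquare(config.d0_true, size=n)
    is_hvr, is_lvr = _flag_regions(
        rng, mu, config.hvr_fraction, config.lvr_fraction, config.intensity_bias
    )
    sigma2 = sigma2 * np.where(
        is_hvr, config.hvr_fold, np.where(is_lvr, config.lvr_shrink, 1.0)
    )
    x = rng.normal(
        loc=mu[:, None],
        scale=np.sqrt(config.gamma_true * sigma2)[:, None],
        size=(n, m),
    )
    ids = [f"chr1:{1000 * i}-{1000 * (i + 1)}" for i in range(n)]
    samples = [f"s{j + 1}" for j in range(m)]
    return (
        pd.DataFrame(x, index=ids, columns=samples),
        SimulationTruth(mu=mu, sigma2=sigma2, is_hvr=is_hvr, is_lvr=is_lvr),
    )


def simulate_counts(
    n_regions: int = 2000,
    m: int = 6,
    depth_factors=None,
    mean_log_abundance: float = 5.0,
    sd_log_abundance: float = 1.5,
    occupancy_threshold: int = 10,
    zero_fraction: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Poisson read counts K_ij ~ Poisson(depth_j * lambda_i).

    Per-region abundances lambda_i are log-normal; a ``zero_fraction`` of
    regions has zero abundance (hence zero counts and occupancy).  Returns
    (counts, occupancy, latent abundances) with BED-addressable region ids.
    """
    rng = np.random.default_rng(seed)
    if depth_factors is None:
        depth_factors = np.ones(m)
    depth = np.asarray(depth_factors, dtype=float)
    if depth.size != m or np.any(depth <= 0):
        raise ValueError("need m positive depth factors")
    lam = np.exp(rng.normal(mean_log_abundance, sd_log_abundance, size=n_regions))
    n_zero = int(round(zero_fraction * n_regions))
    if n_zero:
        lam[rng.choice(n_regions, size=n_zero, replace=False)] = 0.0
    k = rng.poisson(lam[:, None] * depth[None, :])
    ids = [f"chr1:{1000 * i}-{1000 * (i + 1)}" for i in range(n_regions)]
    samples = [f"s{j + 1}" for j in range(m)]
    counts = pd.DataFrame(k, index=ids, columns=samples)
    occ = occupancy_from_counts(counts, threshold=occupancy_threshold)
    return counts, occ, pd.Series(lam, index=ids, name="abundance")


def simulate_labels_and_genotypes(
    x: pd.DataFrame,
    group_sizes: tuple[int, int],
    effect_rows: list[str] | None = None,
    effect_size: float = 0.0,
    qtl_rows: list[str] | None = None,
    qtl_effect: float = 0.0,
    alt_fraction: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Inject subgroup and genotype effects into a normalized matrix.

    Samples are split into two classes of the given sizes; ``effect_rows``
    get a mean shift of ``effect_size`` (in units of the row's standard
    deviation) in the second class.  Each ``qtl_rows`` entry becomes a SNP
    whose alt carriers (a random ``alt_fraction`` of samples) get a shift of
    ``qtl_effect`` row-SDs.  Returns (labels, genotype table, modified X).
    """
    n1, n2 = group_sizes
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    if n1 + n2 != x.shape[1]:
        raise ValueError("group sizes must sum to the sample count")
    rng = np.random.default_rng(seed)
    labels = pd.Series(
        ["A"] * n1 + ["B"] * n2, index=x.columns, name="class"
    )
    out = x.copy()
    if effect_rows is not None and effect_size != 0.0:
        missing = [r for r in effect_rows if r not in out.index]
        if missing:
            raise ValueError(f"effect rows outside matrix: {missing[:5]}")
        rows = out.loc[effect_rows].to_numpy(dtype=float)
        sd = rows.std(axis=1, ddof=1, keepdims=True)
        rows[:, n1:] += effect_size * sd
        out.loc[effect_rows] = rows
    geno_rows = {}
    if qtl_rows is not None:
        missing = [r for r in qtl_rows if r not in out.index]
        if missing:
            raise ValueError(f"QTL rows outside matrix: {missing[:5]}")
        n_alt = max(1, int(round(alt_fraction * out.shape[1])))
        for gi, region in enumerate(qtl_rows):
            alt = rng.choice(out.shape[1], size=n_alt, replace=False)
            geno = np.array(["ref"] * out.shape[1], dtype=object)
            geno[alt] = "alt"
            if qtl_effect != 0.0:
                row = out.loc[region].to_numpy(dtype=float)
                row[alt] += qtl_effect * row.std(ddof=1)
                out.loc[region] = row
            geno_rows[f"snp{gi + 1}"] = geno
    genotypes = pd.DataFrame(
        geno_rows, index=x.columns
    ).T if geno_rows else pd.DataFrame(columns=x.columns)
    return labels, genotypes, out
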