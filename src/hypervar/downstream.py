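"""Sample-structure analyses built on called hypervariable regions.

Once HVRs are called, their normalized signals are z-scaled per region and
used as features for: principal-component summaries, Ward hierarchical
clustering of samples (with the adjusted Rand index for comparison against
known labels), per-motif transcription-factor activity scores with
class-specific t-tests, a genotype-association (QTL) scan, and a
resampling-based feature-enrichment test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .regions import RegionSet
from .testing import bh_adjust


def zscale_regions(x: pd.DataFrame) -> pd.DataFrame:
    """Per-region standardization Z = (X - mean) / sd with the m-1 divisor.

    Rows with zero spread are dropped with a warning — a constant row cannot
    be hypervariable in the first place.
    """
    vals = x.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-spread region(s)")
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(z, index=x.index[keep], columns=x.columns)


def activity_scores(z: pd.DataFrame, hits: pd.DataFrame) -> pd.DataFrame:
    """Motif activity S_mj = mean over hit HVRs of (Z_ij - colmean_j(Z)).

    The column mean runs over *all* HVR rows of Z (it adjusts for
    sample-specific biases), so a motif hitting every HVR scores exactly 0.
    Motifs with zero hits get NaN scores.
    """
    if set(hits.columns) != set(z.index):
        raise ValueError("motif hit columns must match the HVR rows of Z")
    zc = z.to_numpy(dtype=float) - z.to_numpy(dtype=float).mean(axis=0, keepdims=True)
    h = hits[z.index].to_numpy(dtype=float)  # motif x HVR, aligned to z rows
    n_hits = h.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (h @ zc) / n_hits[:, None]
    s[n_hits == 0] = np.nan
    return pd.DataFrame(s, index=hits.index, columns=z.columns)


def class_specific_tests(
    s: pd.DataFrame, labels: pd.Series, target_class
) -> pd.DataFrame:
    """Welch t-test of each motif's activity: target class vs all others.

    Returns a table (t, p, rank) sorted as given, with rank 1 = largest t,
    i.e. the motif most specifically active in the target class.
    """
    labels = labels.reindex(s.columns)
    in_class = (labels == target_class).to_numpy()
    if in_class.sum() < 2 or (~in_class).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    a = s.to_numpy(dtype=float)[:, in_class]
    b = s.to_numpy(dtype=float)[:, ~in_class]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    out = pd.DataFrame({"t": t, "p": p}, index=s.index)
    out["rank"] = stats.rankdata(-out["t"].to_numpy(), method="ordinal")
    return out


def pca_features(z: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Scores of samples on the top-k principal axes of the HVR signals.

    The HVR x sample matrix is transposed to sample x HVR, centered, and
    decomposed by SVD.  Signs are fixed by making each component's
    largest-magnitude loading positive, so results are deterministic.
    """
    a = z.to_numpy(dtype=float).T  # samples x HVRs
    n, d = a.shape
    kmax = min(n, d)
    if k > kmax:
        warnings.warn(f"k={k} clipped to {kmax}")
        k = kmax
    a = a - a.mean(axis=0, keepdims=True)
    u, sv, vt = np.linalg.svd(a, full_matrices=False)
    scores = u[:, :k] * sv[:k]
    for c in range(k):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            scores[:, c] *= -1
    return pd.DataFrame(
        scores, index=z.columns, columns=[f"PC{c + 1}" for c in range(k)]
    )


def explained_variance_ratio(z: pd.DataFrame) -> np.ndarray:
    """Fraction of total variance carried by each principal component."""
    a = z.to_numpy(dtype=float).T
    a = a - a.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(a, compute_uv=False)
    return sv**2 / np.sum(sv**2)


def ward_cluster_cut(features: pd.DataFrame, k: int) -> pd.Series:
    """Agglomerative Ward clustering on unsquared Euclidean distances.

    The Lance-Williams Ward update is applied directly to the plain
    Euclidean distances (the classic variant, matching R hclust's
    ``ward.D``), and the tree is cut into k groups.
    """
    x = features.to_numpy(dtype=float)
    n = x.shape[0]
    if k > n or k < 1:
        raise ValueError(f"cannot cut {n} samples into {k} clusters")
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    sizes = np.ones(n)
    active = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    while len(active) > k:
        sub = d[np.ix_(active, active)]
        flat = np.argmin(sub)
        ai, aj = np.unravel_index(flat, sub.shape)
        i, j = active[ai], active[aj]
        if i > j:
            i, j = j, i
        ni, nj = sizes[i], sizes[j]
        for l in active:
            if l in (i, j):
                continue
            nl = sizes[l]
            d_new = (
                (ni + nl) * d[i, l] + (nj + nl) * d[j, l] - nl * d[i, j]
            ) / (ni + nj + nl)
            d[i, l] = d[l, i] = d_new
        sizes[i] = ni + nj
        members[i].extend(members.pop(j))
        active.remove(j)
        d[j, :] = d[:, j] = np.inf
    ids = np.empty(n, dtype=int)
    for cid, root in enumerate(sorted(active)):
        ids[members[root]] = cid
    return pd.Series(ids, index=features.index, name="cluster")


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement of two partitions (1 = identical,
    expectation 0 under random labeling)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


def qtl_scan(
    x: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp_regions: pd.Series,
    min_group: int = 5,
    cutoff: float = 0.1,
) -> pd.DataFrame:
    """Association of SNP genotypes with the enclosing region's signal.

    ``genotypes`` is SNP x sample with entries 'ref'/'alt'; ``snp_regions``
    maps SNP id -> enclosing region id (NaN = no enclosing region, skipped
    with a warning).  SNPs with fewer than ``min_group`` carriers of either
    genotype are filtered before testing; the rest get a Welch t-test of
    ref vs alt signals, BH adjustment across tested SNPs, and a significance
    flag at q < cutoff.
    """
    rows = []
    skipped = 0
    for snp in genotypes.index:
        region = snp_regions.get(snp)
        if region is None or (isinstance(region, float) and np.isnan(region)):
            skipped += 1
            continue
        if region not in x.index:
            skipped += 1
            continue
        geno = genotypes.loc[snp].reindex(x.columns)
        ref_mask = (geno == "ref").to_numpy()
        alt_mask = (geno == "alt").to_numpy()
        if ref_mask.sum() < min_group or alt_mask.sum() < min_group:
            continue
        sig = x.loc[region].to_numpy(dtype=float)
        t, p = stats.ttest_ind(sig[ref_mask], sig[alt_mask], equal_var=False)
        rows.append({"snp": snp, "region": region, "t": float(t), "p": float(p)})
    if skipped:
        warnings.warn(f"skipped {skipped} SNP(s) without an enclosing region")
    if not rows:
        return pd.DataFrame(columns=["region", "t", "p", "q", "significant"])
    out = pd.DataFrame(rows).set_index("snp")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < cutoff
    return out


def resampling_enrichment(
    target: RegionSet | list[str],
    universe: RegionSet | list[str],
    feature_counts: pd.Series,
    n_iter: int = 1000,
    seed: int | None = None,
) -> tuple[float, np.ndarray, float]:
    """Are features (e.g. somatic variants) enriched in the target regions?

    The observed total feature count over the target is compared with totals
    over ``n_iter`` random draws of equally many regions from the universe
    (uniform, without replacement).  The empirical p-value uses the +1
    correction: p = (1 + #{null >= observed}) / (n_iter + 1).
    """
    t_ids = target.ids if isinstance(target, RegionSet) else list(target)
    u_ids = universe.ids if isinstance(universe, RegionSet) else list(universe)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(t_ids) > len(u_ids):
        raise ValueError("target larger than universe")
    if not set(t_ids) <= set(u_ids):
        raise ValueError("target must be a subset of the universe")
    counts = feature_counts.reindex(u_ids).fillna(0).to_numpy(dtype=float)
    observed = float(feature_counts.reindex(t_ids).fillna(0).sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.choice(len(u_ids), size=len(t_ids), replace=False)
        null[it] = counts[idx].sum()
    p = (1.0 + float(np.sum(null >= observed))) / (n_iter + 1.0)
    return observed, null, p
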