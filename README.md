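# hypervar

Statistical detection of **hypervariable regions (HVRs)** — and their
opposites, lowly variable regions (LVRs) — across cohorts of ChIP-seq or
ATAC-seq samples.

Large epigenomic studies profile tens to hundreds of individuals and ask an
unsupervised question: *at which genomic regions does the signal vary most
across samples?* Those regions carry the cohort's substructure — cancer
subtypes, developmental stages, genotype effects. Ranking regions by a raw
variability index is misleading for count data, because after a log
transformation low-intensity regions are intrinsically noisier than
high-intensity ones. `hypervar` is for computational biologists who want a
calibrated, model-based answer: per-region p-values for excess (or
deficient) variability, corrected for the mean-intensity trend and usable
with standard FDR control.

## The model

Let `K_ij` be the read count at region `i` in sample `j`, with a binary
occupancy indicator `O_ij` marking peak regions. The workflow:

1. **Normalization.** `Y_ij = log2(K_ij + 0.5)` is rescaled per sample,
   `X_ij = α_j + β_j Y_ij`, against a pseudo-reference profile
   `P_i = Σ_j O_ij Y_ij / Σ_j O_ij`. The coefficients solve two
   constraints over the regions occupied by the sample: the M values
   (`X − P`) have zero mean, and zero covariance with the A values
   (`(X + P)/2`) — i.e. MA-plot normalization with
   `β_j = sd(P)/sd(Y)`, `α_j = mean(P) − β_j mean(Y)`.
2. **Mean-variance curve (MVC).** With `μ̂_i`, `t̂_i` the sample mean and
   (unbiased) sample variance of `X_i·`, a curve `f(μ)` is fitted by local
   gamma-family regression (log link, tricube weights, locally linear
   predictor) of `t̂` on `μ̂`. The **scaled variance** `t̂_i / f(μ̂_i)` is
   the test statistic.
3. **Null distribution.** Assuming `X_ij | σ_i² ~ N(μ_i, γσ_i²)` with
   `1/σ_i² ~ (1/f(μ_i)) · χ²_{d0}/d0`, the scaled variances follow
   `γ·F_{m−1, d0}` under the null, where `m` is the number of samples,
   `d0` (prior degrees of freedom) measures how tightly variances hug the
   curve, and `γ` is a global scale factor.
4. **Estimation.** `(d0, γ)` come from matching the first two moments of
   winsorized log scaled variances (`p_l = 0.01`, `p_u = 0.1`) against the
   theoretical moments of `log γ + log win(F_{m−1,d0})` (Gauss–Legendre
   quadrature; bisection in `d0`), using only the 10% of regions with the
   smallest `μ̂` — where genuine HVRs are scarce — so that true HVRs do not
   depress `d0` and destroy power.
5. **Testing.** HVR p-values are upper-tail probabilities of the null;
   LVR p-values lower-tail; Benjamini–Hochberg within each stratum
   (promoter-proximal vs distal, split at 5 kb to the nearest TSS);
   calls at `q < 0.1` by default.

Downstream, called HVRs feed per-region z-scaling, PCA features, Ward
(`ward.D`-style, unsquared distances) clustering with the adjusted Rand
index, motif activity scores with class-specific Welch t-tests, a
genotype-association (QTL) scan, and a resampling enrichment test.

## Worked example

`examples/02_parameter_recovery.py` draws 20000 regions × 10 samples from
the generative model (`d0 = 5`, `γ = 1.2`, 5% HVRs at 4× variance placed
preferentially at high intensities) and compares three estimator variants:

```
true parameters:            d0 = 5.0, gamma = 1.2
plain moment matching:      d0 = 4.24, gamma = 1.245
lowest-10% selection:       d0 = 5.03, gamma = 1.173
selection + winsorization:  d0 = 5.35, gamma = 1.183
```

The plain estimator reads the contaminating HVRs as a smaller `d0`
(a heavier null tail, hence weaker tests); restricting estimation to
low-intensity regions removes most of that bias. `examples/01_…` runs the
whole count-matrix pipeline and calls 217 HVRs at `q < 0.1`, recovering
all 200 injected hypervariable rows; `examples/03_…` recovers a 2×
distal/proximal variability ratio via the fixed-`d0` γ comparison; and
`examples/04_…` clusters two sample subgroups perfectly (ARI = 1) from the
top-ranked HVRs and flags the motif whose hits coincide with them.

A thin CLI mirrors the pipeline stages
(`hypervar run|prep-regions|normalize|comparator|simulate|gamma-compare`);
see `hypervar --help`.

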