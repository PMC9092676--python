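# Methods

## Model

One risk gene is assumed per GWAS locus (the 2-Mb window centered on an
index SNP). Writing `g_l` for the gene selected at locus `l`, the sampler
targets the joint assignment whose per-locus conditional is

    P(g_l = g | g_{-l}) ∝ prior_l(g; g_{-l}) · BF(g)

- `BF(g) = exp(-Σ_i ln p_i(g))` is the Fisher's-product evidence over the
  gene's available p-values (whitened regulatory features, differential
  expression, gene-level methylation). Missing p-values are skipped, not
  imputed as 1: imputing would conflate "no data" with "null evidence". A
  per-gene `df` column records how many p-values were combined, so the null
  distribution of `2·log BF` is χ² with `2·df` degrees of freedom.
- `prior_l(g)` is the RWR score of `g` seeded on the current selections at
  the other loci, normalized within the locus with a floor ε:
  `prior(g) = (s(g) + ε) / Σ_{g'} (s(g') + ε)`. The Gibbs conditional only
  needs prior × evidence up to a locus constant, so the normalized form is
  equivalent to literal prior odds.

Because the conditionals are defined through a prior that itself depends on
the other loci's selections, a compatible joint density is not guaranteed;
correctness is therefore stated — and tested — against the stationary
distribution of the systematic-scan chain itself (`exact_stationary_oracle`
builds the one-sweep transition matrix over all joint configurations and
extracts the eigenvector for eigenvalue 1).

## Methylation score

CpG-level (p, log2FC) pairs from promoter-annotated probes are converted to
signed z-scores and combined per gene by Stouffer's method:

    Z_CpG = sign(log2FC) · Φ⁻¹(1 − p/2),   Z_M = Σ Z_CpG / √k,
    p_gene = 2·(1 − Φ(|Z_M|)).

The magnitude is computed as `−Φ⁻¹(p/2)`, which is algebraically identical
but stays finite for p below ~1e-16. The sign-inverted variant
`sign(log2FC)·Φ⁻¹(p/2)` (which makes significant hypermethylation negative)
is available via `convention="literal"`; the corrected form is the default
because the sampler needs large |Z| for strong evidence regardless of
direction. Input p-values of exactly 0 are clipped to 1e-300 before the
inverse CDF; log2FC of exactly 0 contributes z = 0.

## Feature whitening

`decorrelate_features` estimates the mean and covariance from complete
rows, standardizes each column, and applies the symmetric inverse square
root of the *correlation* matrix. Working on the correlation scale keeps
the transform well-conditioned when features live on wildly different
scales (base pairs next to O(1) linkage scores); the output sample
covariance over complete rows is the identity either way. A genuinely
singular correlation (min eigenvalue ≤ 1e-10) is ridge-regularized with
λ = 1e-6·trace/m and logged; constant columns are dropped with a warning.
Rows with any missing entry whiten to all-NaN, because the transform mixes
columns; their p-values are then skipped by the Fisher product. One-sided
tail p-values are taken in the configured evidence direction: larger is
evidence for FANTOM5-like and Hi-C scores, smaller is evidence for distance
to TSS. Whitening is fit genome-wide over all candidates (per-locus fitting
would leave too few rows per fit at ~30 candidates).

## Sampler settings

- Systematic (sorted-locus) scan per sweep; random scan behind a flag.
- Initial state: argmax log BF per locus; ties to the smallest gene id.
- Counts accumulate after `burn_in` = 500 sweeps; every `check_every` = 100
  sweeps the full (locus, candidate) frequency vector is compared with the
  previous check and the run stops when the sum of squared differences drops
  below 0.01 (the convergence threshold of the procedure), or at
  `max_sweeps` = 20,000 with `converged = False`. Only the 0.01 threshold is
  prescribed; burn-in, check interval and cap are implementation defaults
  sized so the reference study converges in seconds.
- Frequencies come from cumulative post-burn-in counts, not a sliding
  window.
- RWR is evaluated through the precomputed fundamental matrix
  `F = r(I − (1−r)W)⁻¹`: the fixed point is linear in the restart vector, so
  scores for any seed set are a column average of F. This is exact (tested
  against power iteration at 1e-8) and makes per-step prior updates O(n·|S|).
  Conditional distributions are memoized per (locus, seed set).
- restart_prob defaults to 0.5 and results are checked for robustness over
  {0.3, 0.5, 0.7}; ε defaults to 1e-6/|nodes|, which effectively hard-masks
  candidates disconnected from every seed while keeping them reachable. The
  oracle-equivalence tests use ε = 0.05 so the target distribution is
  interior (with the tiny default ε a sparse test graph collapses to a point
  mass and the comparison would be trivial).

## Mendelian randomization

Instruments are cis-eQTL with raw p < 1e-4, greedily LD-clumped: keep the
smallest-p SNP, drop others with r² > 0.001 within 10 Mb, repeat. Missing
LD entries count as r² = 1 within the window (conservative). Harmonization
flips the outcome effect sign when alleles are swapped and drops palindromic
SNPs (A/T, C/G) with exposure allele frequency in [0.42, 0.58] — standard
two-sample-MR practice; the exact harmonization defaults of upstream
workflows are not restated anywhere, so these are committed choices. One
surviving instrument → Wald ratio `β_out/β_exp` with first-order delta
standard error `se_out/|β_exp|`; two or more → fixed-effect IVW
(weighted regression through the origin, weights `1/se_out²`).
Benjamini-Hochberg adjustment (via statsmodels) is applied within each
tissue's batch; cross-tissue correction is available by flag.

## Synthetic data

The generators emulate the statistical shape of a GWAS-plus-multi-omics
study, not any particular cohort:

- Genome: `n_genes` genes over `n_chrom` chromosomes, gene lengths
  5-60 kb, spacing calibrated so a 2-Mb window holds about
  `candidates_per_locus_target` genes. TSS = start (+) or end (−).
- Loci: index SNPs placed near randomly chosen planted genes with
  *disjoint* 2-Mb windows, so exactly one planted gene sits in each window.
- Signal: planted genes draw p ~ Beta(1/effect_strength, 1) — Uniform at
  strength 1, concentrating at 0 as strength grows; a one-parameter family
  in which the expected planted p-value is monotone in the strength. Feature
  scores use the matching normal quantile. Planted CpGs share a per-gene
  fold-change sign so Stouffer combination does not cancel the signal.
- Network: planted pairs connect with probability 0.3, background pairs
  with 0.01; weights Uniform(0.5, 1.5).
- MR: 10 instruments per gene with eQTL |z| in [6, 15] (all pass the
  p < 1e-4 filter), outcome effects θ·β_exp plus noise scaled to the outcome
  SE; LD per gene is an AR(1) correlation squared to r² (positive
  semi-definite by construction), with adjacent r = 0.02 by default so
  clumping is exercised without removing instruments.
- Single cell: negative binomial with dispersion 0.5 (the exact value is
  immaterial to the tests), gene base means log-normal; marker genes have
  their mean multiplied by 2^marker_log2fc = 4 in their own type only. The
  first cell type's marker set is seeded with the planted risk genes so the
  end-to-end demo has a disease-relevant cell type.

What the generators do **not** emulate: realistic effect-size spectra, LD
beyond a single AR(1) block per gene, tissue sharing of eQTL, doublets or
ambient RNA in the counts, or correlated evidence across omics layers.
Passing tests therefore demonstrate correctness of the machinery and
recovery under a clean, favorable signal model — not expected performance
on real cohorts.

## Problem sizes

The reference study is 20 loci × ~30 candidates over 1,200 genes, 1,000
cells in 5 types, 200 genes or seeds per Monte-Carlo batch, and 50,000
sweeps for oracle-equivalence runs; these sizes make every property check
sharp while the full suite and the acceptance script each finish in well
under a minute of compute per stage.

## Known limitations

- The method selects exactly one gene per locus and cannot say how many
  risk genes a locus truly harbors.
- The evidence direction ("larger is evidence") per feature is an input
  assumption; a mis-specified orientation silently inverts that feature's
  contribution.
- Posterior "probabilities" are sampling frequencies of a chain whose
  conditionals need not be mutually compatible; they are reproducible and
  well-calibrated against the chain's own stationary law, but they are not
  posterior probabilities under an explicit joint model.
- With the default ε the network prior is strong: candidates disconnected
  from all other selected genes are effectively excluded unless their
  evidence is overwhelming.
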