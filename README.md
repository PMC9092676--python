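# prgene

Bayesian prioritization of GWAS risk genes from multi-omics evidence, with
two validation stages: two-sample Mendelian randomization (MR) and
single-cell cell-type-specificity enrichment (CSEA).

## The problem

A genome-wide association study points at index SNPs, not genes: the 2-Mb
window centered on an index SNP typically holds dozens of candidate genes.
`prgene` picks one risk gene per locus by combining, for every candidate:

- **Evidence** — per-gene p-values from regulatory features (FANTOM5-like
  enhancer linkage, Hi-C contact, distance from index SNP to TSS; whitened
  with the Mahalanobis decorrelation so each feature is a standard-normal
  tail test), differential expression, and a gene-level DNA-methylation
  score, combined by Fisher's product. The log evidence
  `log BF(g) = -Σ_i ln p_i(g)` acts as a Bayes-factor surrogate.
- **A network prior** — proximity of the candidate to the genes currently
  selected at all *other* loci, measured by a random walk with restart
  (RWR) on a weighted gene network: `s = r·e + (1-r)·W·s`, with `W` the
  column-normalized adjacency and `e` uniform over the seed genes.

A systematic-scan Gibbs sampler draws one gene per locus per sweep from
`P(g | rest) ∝ prior(g) · BF(g)`; sampling frequencies after burn-in are the
reported posterior probabilities, and the run stops when the sum of squared
frequency differences between checks falls below 0.01. The top-frequency
gene per locus is the prioritized risk gene.

The gene-level methylation score converts CpG-level statistics via signed
z-scores, `Z_CpG = sign(log2FC) · Φ⁻¹(1 - p/2)`, combined per gene by
Stouffer's method `Z_M = Σ Z_CpG / √k` and reversed to a two-sided p-value.

Validation: per gene × tissue, cis-eQTL instruments (p < 1e-4) are
LD-clumped (r² > 0.001 within 10 Mb), harmonized, and the causal effect of
expression on outcome is estimated by the Wald ratio (one instrument) or
fixed-effect IVW (several), with Benjamini-Hochberg FDR per tissue. CSEA
filters genes with >95% zero counts, builds per-cell-type specificity
panels (top 5% by Welch t of the type's cells vs the rest on log1p
library-normalized counts), and tests a gene set against each panel with a
one-sided Fisher's exact test.

Every input can be generated synthetically with planted ground truth (known
risk gene per locus, true causal effect, marker cell types), so the whole
pipeline is testable offline.

## Worked example

```bash
prgene run-all --config configs/demo.yaml --outdir results/run
# or step by step:
python analysis/01_simulate.py
python analysis/02_prioritize.py
python analysis/03_mendelian_randomization.py
python analysis/04_cell_type_enrichment.py
```

With the demo configuration (seed 42: 20 loci, ~30 candidates per 2-Mb
window, planted signal strength 10) the drivers print:

```
converged: True after 200 recorded sweeps
planted gene is the top-frequency candidate at 20/20 loci

20 gene x tissue MR estimates; 20 significant at FDR < 0.05
mean causal-effect estimate 0.494 (true theta = 0.5)

strongest enrichment: CT1 (overlap 20, p_raw = 3.12e-28)
```

i.e. the sampler recovers the planted risk gene at every locus, MR recovers
the planted causal effect of 0.5, and the prioritized gene set is specific
to the cell type that carries it as markers. Outputs are TSV tables
(`posterior.tsv`, `prgenes.tsv`, `mr_results.tsv`, `enrichment.tsv`) plus a
run manifest with checksums; reruns with the same seed are byte-identical.

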