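# cpgflex

Predicting gene-body methylation from sequence alone, and asking what
it means for how flexibly genes are expressed.

In species without bisulfite data, the normalized CpG content of a
transcript is a robust proxy for germline gene-body methylation:
methylated cytosines deaminate to thymine over evolutionary time, so
historically methylated genes are depleted in CpG dinucleotides. For
each gene,

    CpG_O/E = n_CpG / (n_C · n_G) · l² / (l − 1),

where `l` is the number of unambiguous bases. Across a transcriptome
this statistic is typically a two-component Gaussian mixture — a
low-CpG (hypermethylation-biased) and a high-CpG component — and the
crossing point of the two weighted component densities,
λ₁·N(x|μ₁,σ₁) = λ₂·N(x|μ₂,σ₂), gives an objective threshold for
assigning genes to components.

`cpgflex` implements that analysis as a tested, reusable pipeline for
transcriptome studies with a 2-population × 2-treatment RNA-seq
design (e.g. thermal-origin ecotypes under experimental warming):

- per-gene CpG_O/E profiling from FASTA;
- 1- vs 2-component Gaussian fits (EM, unequal variances, multiple
  seeded starts), BIC/log-likelihood comparison, analytic density
  intersection, low/high classification;
- GO-slim mapping by `is_a` ancestor closure and Fisher-exact
  enrichment of each component (BH-corrected);
- simplified negative-binomial differential expression (CPM filter →
  TMM normalization → moment dispersions → conditional exact test →
  BH) for four contrasts;
- quantile-bin analyses relating CpG_O/E to DEG frequency and
  expression magnitude, with component t-tests and population slope
  comparison;
- a synthetic-data generator that emulates the whole study from one
  seed, with ground truth returned for recovery testing.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the full pipeline on a self-contained synthetic study (10,000
genes, seed 7):

```bash
cpgflex run-all config.yaml -o out/
```

with `config.yaml`:

```yaml
seed: 7
simulate:
  n_genes: 10000
```

which prints

```
threshold: 0.7131
origin: 310 DEGs (3.1% of expressed)
treatment_all: 296 DEGs (2.96% of expressed)
treatment_cold: 203 DEGs (2.03% of expressed)
treatment_warm: 179 DEGs (1.79% of expressed)
```

Reading the output: the fitted two-component mixture beats the single
Gaussian by BIC, and the component densities cross at CpG_O/E ≈ 0.71
— the 8,443 genes below it form the low-CpG (predicted
hypermethylated) component, the 1,557 above it the high-CpG
component. About 3% of expressed genes respond to the (simulated)
population origin, and the per-bin DEG frequency rises with CpG_O/E
(`bins_origin_frequency.tsv`; Pearson r = 0.91 across 25 bins,
p < 1e-9), recovering the planted link between weak methylation and
expression flexibility. `out/summary.json` holds every statistic;
per-stage TSVs (CpG profile, mixture report, classification,
enrichment, DE and bin tables) sit alongside it.

Each stage is also callable on its own (`cpgflex cpg`, `fit-mixture`,
`classify`, `enrich`, `de`, `flexibility`, `simulate`), or from
Python:

```python
from cpgflex import read_fasta, profile_transcriptome, fit_mixture_em
import numpy as np

records, _ = profile_transcriptome(read_fasta("transcripts.fasta"))
fit = fit_mixture_em(np.array([r.cpg_oe for r in records]), k=2, seed=0)
print(fit.mu, fit.sigma, fit.lambda_)
```

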