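# mitocoherence

Does an individual with mitochondria-rich muscle also have mitochondria-rich
brain, heart and liver?  That assumption — inter-tissue *coherence* of
mitochondrial biology — underlies much of how organism-level energetics is
discussed, yet it is rarely tested.  `mitocoherence` is a Python toolkit for
testing it: it computes transcriptome-based indices of mitochondrial
investment for every subject–tissue combination, quantifies the inter-tissue
correlation structure of any mitochondrial feature (transcript indices,
enzymatic activities, mtDNA copy number, protein abundance), relates
mitochondrial expression to energy-sensing regulators and proliferative
activity, and identifies subgroups of individuals with distinct multi-tissue
mitochondrial distribution patterns.

It is written for researchers analysing multi-tissue molecular datasets
(GTEx-style human transcriptomes, multi-organ animal panels) who want a
tested, reproducible implementation of these analyses, together with a
synthetic-cohort generator whose ground truth makes every pipeline stage
verifiable.

## The indices and statistics

For a sample with TPM-like abundances $x_g$ and a gene catalog partitioning
genes into mtDNA-encoded ($M$), nuclear mitochondrial ($N$, a Mitocarta-style
list) and other nuclear genes:

- **mtDNA%** $= 100 \cdot \sum_{g \in M} x_g \big/ \sum_g x_g$ — the share of
  the whole transcriptome encoded on the mitochondrial genome, a proxy for
  mitochondrial content;
- **mito-nDNA%** $= 100 \cdot \sum_{g \in N} x_g \big/ \sum_{g \notin M} x_g$
  — the share of the *nuclear* transcriptome devoted to mitochondrial genes,
  a proxy for nuclear investment in mitochondrial biogenesis.  The same
  construction gives PGC-1α% (gene *PPARGC1A*), ISR% (*ATF4*, *ATF5*,
  *DDIT3*, *GDF15* summed), and profiles for *NRF1*, *NRF2*, *TFAM*, *POLG*;
- **proliferation score** — mean abundance of *KI67*, *TOP2A*, *RRM2*.

Coherence of a feature between tissues $s$ and $t$ is the Spearman rank
correlation $r_{st}$ across the subjects observed in both tissues (pairs
need ≥ 10 shared subjects; tissues must form eligible pairs with > 50% of
other tissues; samples are filtered at RIN ≥ 5.5 and cell lines removed).
Pairs are stratified into brain–brain, body–body and brain–body classes;
summaries report per-class medians, sign and significance breakdowns
(uncorrected two-sided p < 0.05), and an r ≥ 0.2 threshold network.
Within-tissue regulator associations, the across-tissue meta-correlation of
mtDNA%↔mito-nDNA% coupling with proliferation, and k-means phenotyping on
z-scored log₂ inter-tissue ratio features (with PCA variance, two-way type-II
ANOVA, Hedges' g with $J = 1 - 3/(4\,\mathrm{df} - 1)$, and clinical
z-score enrichment) complete the pipeline.

The synthetic generator draws, per subject $i$ and tissue $t$,
$\operatorname{logit} f_{it} = \operatorname{logit}\mu_t + \lambda_t z_i +
\mathrm{shift}(c_i, t) + \varepsilon_{it}$ with a standard-normal subject
trait $z_i$, archetype $c_i$ and noise SD $\sigma_t$, so the expected
between-tissue Pearson correlation is
$\rho_{st} = \lambda_s\lambda_t \big/ \sqrt{(\lambda_s^2+\sigma_s^2)(\lambda_t^2+\sigma_t^2)}$
and the expected Spearman correlation is $(6/\pi)\arcsin(\rho_{st}/2)$ —
an analytic oracle every estimate can be checked against.

## Worked example

```python
import mitocoherence as mc

cohort = mc.generate_cohort(mc.CohortConfig(
    n_subjects=300, n_other=2000, n_mito_nuclear=300, seed=7))
table = mc.build_index_table(cohort.expression, cohort.samples, cohort.catalog)
brain = {t.name for t in cohort.truth.config.tissues if t.tissue_class == "brain"}

results = mc.CoherenceAnalysis(table, "mtdna_pct", brain, min_shared=10).fit()
print(results.summary().per_class[["n_pairs", "median_r", "pct_positive", "pct_ns"]].round(3))
```

```
             n_pairs  median_r  pct_positive  pct_ns
pair_class
brain_brain     10.0     0.197       100.000   0.000
body_body       21.0     0.027        71.429  90.476
brain_body      35.0     0.104        91.429  51.429
all             66.0     0.090        86.364  56.061
```

The default cohort plants a shared-trait loading of 0.5 on the five brain
regions and weaker, mostly idiosyncratic investment in body tissues — and
the fitted structure recovers exactly that: brain–brain pairs show the
highest median coherence (r = 0.197, all positive), body–body pairs are
mostly indistinguishable from zero, and brain regions top the per-tissue
mean-coherence ranking.  Continuing with the regulator and proliferation
stages:

```python
prof = mc.RegulatorAssociation(table, "PPARGC1A_pct").fit()
print(prof.profile.head(2))          # strongest positive tissues
coup = mc.ProliferationCoupling(table).fit()
print(coup.meta_r, coup.meta_p)
```

```
              tissue     r   p    n
heart_left_ventricle 0.548 0.0  300
    colon_transverse 0.419 0.0  300

proliferation meta-correlation: r=0.84, p=0.00064
```

The per-tissue PGC-1α profile recovers the planted effect signs (positive
in heart and colon, negative in adrenal gland and adipose, β = +0.6 … −0.4),
and the mtDNA%↔mito-nDNA% coupling rises with tissue proliferation exactly
as generated.  The same analyses are available from the shell:

```sh
mitocoherence simulate --out sim --n-subjects 300 --seed 7
mitocoherence run --expression sim/expression.tsv --samples sim/samples.tsv \
    --catalog sim/catalog.tsv --out results
```

Externally measured feature tables (mtDNA copy number, enzymatic
activities, protein percentages) enter through the same carrier:
`mitocoherence coherence --table features.tsv --feature mtdnacn ...`.

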