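# dupli-td

Transcriptional divergence of duplicate genes under a carbon-source shift.

Budding yeast retains two classes of gene duplicates: ohnologs from the
whole-genome duplication (WGD pairs) and small-scale duplicates (SSD pairs).
When a population is moved from glucose (YPD) to ethanol (YPE) as carbon
source, the question is whether duplicates — and specifically duplicates whose
two copies are expressed at different levels — carry a disproportionate share
of the transcriptional response. `dupli-td` implements that analysis as a
reusable, fully tested pipeline:

- **Differential expression** between media on a gene × sample count matrix:
  median-of-ratios normalization, negative-binomial dispersions
  (method-of-moments shrunk toward a Pearson-χ² common value), a Wald test on
  the log₂ fold change, Benjamini–Yekutieli FDR, and trinary calls at
  FC > 1.25 and FDR < 0.005.
- **TD statistics**: for each duplicate pair, the transcriptional-divergence
  ratio TD = (higher copy mean)/(lower copy mean) in a reference background;
  a pair is *TD* when TD > τ (default 1.25). Responding copies are labelled
  high-/low-TDC, pairs fall into five response categories, and enrichment is
  tested with exact binomial and Fisher tests, resampling nulls of means and
  category counts (sampling without replacement, empirical p with the +1
  correction), a Pearson correlation of TD with expression plasticity, and a
  τ sensitivity sweep from 1× to 4×.
- **Duplicate catalogs**: WGD pair lists (two-column TSV), SSD candidates by
  reciprocal best hits from all-vs-all BLASTP tabular output
  (E ≤ 10⁻⁵, ≥ 50 bits), filtered to a synonymous-divergence window matching
  the WGD dS distribution. dS is Nei–Gojobori (1986) counting with
  equal-weight pathway averaging and the Jukes–Cantor correction
  dS = −(3/4)·ln(1 − (4/3)·pS).
- **Growth curves**: logistic fits N(t) = K / (1 + ((K−N0)/N0)·e^(−rt)) to
  OD₆₀₀ series (μ_max = r, carrying capacity K), group comparisons by
  Wilcoxon rank-sum, and serial-transfer generation arithmetic
  (passages × log₂(1/bottleneck)).
- **Over-representation**: upper-tail hypergeometric tests of gene sets
  against a term → gene map, BH-adjusted at 0.01.
- **Synthetic data**: a generator that emulates the whole study — singletons
  plus WGD/SSD pairs with planted copy-wise divergence, condition effects,
  NB count noise, codon pairs with tunable dS, OD curves — so every stage is
  testable without sequencing data.

## Worked example

```python
import numpy as np
import dupli_td as dt
from dupli_td.simulate import default_design
from dupli_td.td import pair_expression, td_table, binomial_td_enrichment

cfg = dt.SimConfig(n_singletons=1000, n_wgd_pairs=300, n_ssd_pairs=300,
                   frac_de=0.2, de_td_coupling=4.0, frac_td_pairs=0.5,
                   td_log_ratio_sd=1.0, de_lfc_sd=1.5, seed=11)
catalog, truth = dt.simulate_catalog(cfg)
design = default_design(cfg.n_replicates, timepoints=("t0",))
counts = dt.simulate_counts(catalog, truth, cfg, design)

de = dt.NBExpressionModel(dt.CountMatrix(counts, design)).fit("t0")
print(de.summary())

expr = pair_expression(counts, design, truth.pairs, background=("t0", "YPD"))
pairs = td_table(expr, tau=1.25)
defined = pairs[np.isfinite(pairs["td_ratio"])]
gene_td = {}
for _, r in defined.iterrows():
    gene_td[r["gene_a"]] = gene_td[r["gene_b"]] = bool(r["is_td"])
up = [g for g in gene_td if de.table.loc[g, "call"] == "up"]
k, p0 = sum(gene_td[g] for g in up), defined["is_td"].mean()
res = binomial_td_enrichment(k, len(up), p0, alternative="greater")
print(f"TD pairs: {int(defined['is_td'].sum())}/{len(defined)}")
print(f"up-called duplicate genes: {len(up)}; from TD pairs: {k}")
print(f"binomial enrichment p = {res.p:.3g}")
```

prints

```
NB differential expression, YPE vs YPD at t0
genes tested:      2200
upregulated:       160  (FC > 1.25, BY FDR < 0.005)
downregulated:     147
median |lfc|:      0.393
TD pairs: 354/600
up-called duplicate genes: 129; from TD pairs: 98
binomial enrichment p = 3.95e-05
```

Read: of 600 duplicate pairs, 354 are transcriptionally diverged in the
glucose background; 129 duplicate genes are up-called in ethanol and 98 of
them belong to TD pairs — far more than the pool fraction 354/600 predicts,
so the planted coupling between copy divergence and responsiveness is
detected (upper-tail exact binomial p ≈ 4 × 10⁻⁵).

The same analysis runs from the shell:

```
dupli-td simulate --out run/ --seed 11
dupli-td dge --counts run/counts.tsv --design run/design.tsv --timepoint t0 --out run/de.tsv
dupli-td all --seed 11 --out run/      # full pipeline + summary.json
```

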