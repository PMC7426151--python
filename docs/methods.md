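# Methods

## The question and the quantities

A duplicate gene pair is *transcriptionally diverged* (TD) in a background
(a timepoint in a medium, glucose/YPD by default) when the ratio of the
higher- to the lower-expressed copy exceeds a threshold τ:

    TD ratio = max(m_a, m_b) / min(m_a, m_b),     TD ⇔ ratio > τ,  τ = 1.25

where m is the mean of normalized counts across the background's replicates
plus a pseudocount of 0.5 (the summarization is a package choice; means with
a pseudocount keep the ratio finite when one copy is silent, and pairs with
both copies at zero raw counts are excluded and counted). The strict
inequality means a pair at exactly 25% difference is *not* TD. TD is
background-dependent by design — the same pair can be TD in the ancestral
population and not in an evolved one — so the background is an explicit
parameter everywhere.

Within a TD pair, a copy that responds to the medium shift (an up or down
call) is labelled **high-TDC** if it is the higher-expressed copy and
**low-TDC** otherwise. The two copies' calls map each pair onto one of five
response categories (both up, both down, discordant, one up/one unchanged,
one down/one unchanged) plus "both unchanged"; the mapping is symmetric in
the copies.

The central enrichment question — do responding duplicates come from TD
pairs more often than chance predicts? — is answered with an exact binomial
test: k of n responding duplicate genes belong to TD pairs, against the pool
TD fraction p0. One-sided tails are exact sums; the two-sided p follows the
minimum-likelihood convention (sum of point probabilities no larger than the
observed one), which is what R's `binom.test` reports and what reproduces
the reference analysis' printed value for (k=274, n=312, p0=867/1090):
p = 1.846 × 10⁻⁴. The two-sided value is what that analysis printed; the
upper tail alone gives 8.6 × 10⁻⁵, so the convention matters and both are
exposed via `alternative=`.

## Differential expression

Counts are modelled NB with variance μ + φμ². The stage is deliberately a
simplified two-group pipeline (per-timepoint YPE vs YPD contrast, no
covariates):

1. **Size factors** — median-of-ratios against the geometric-mean reference
   gene profile, rescaled to geometric mean 1; falls back to library-size
   factors when no gene is expressed everywhere.
2. **Dispersions** — per-gene method of moments, (s²−m)/m² on normalized
   counts pooled across conditions (df-weighted), floored at 0, then shrunk
   toward a common dispersion with weight n_prior/(n_prior + df_g),
   n_prior = 10. The common value solves the Pearson-χ² equation
   Σ (x−m)²/(m + φm²) = residual df. The Pearson root was chosen over the
   median of the per-gene estimates because the per-gene moment estimates at
   3 replicates are noisy and right-skewed: their median underestimates a
   shared φ by ~20%, which makes the Wald test anti-conservative, while the
   χ² root weights every gene's standardized residuals equally and is nearly
   unbiased. Null simulations (φ = 0.1, 3v3, 2000 genes) put the raw-p
   false-positive rate at ~0.06 at α = 0.05.
3. **Wald test** — lfc = log₂((m_YPE + 0.5)/(m_YPD + 0.5)); the SE comes
   from the NB variance of each sample's normalized count propagated through
   the log by the delta method; two-sided normal p-values. Genes identical
   in both groups get p = 1.
4. **FDR** — Benjamini–Yekutieli by default (BH available); BY = BH × Σ 1/i.
5. **Calls** — up iff linear FC > 1.25 *and* FDR < 0.005, both strict; down
   symmetric with 1/1.25.

The exact NB conditional test is an intentional non-feature: the stage is
validated by simulation calibration (type-I error, FDR control, power on
planted lfc = 2), not by equivalence to any specific external tool.

## Resampling nulls

Mean-level questions ("is the mean fold change of TD responders higher than
TD duplicates at large?") use a null of means built by drawing subsets of
the same size from the pool *without replacement*, 10,000 iterates by
default, with the +1-corrected empirical p: (1 + #{null ≥ observed})/(n+1).
Category-count questions permute the pooled vector of per-copy calls across
duplicate genes (preserving genome-wide up/down/unchanged totals) and
recount categories per iterate. The normal overlays sometimes drawn over
such nulls are descriptive; the empirical p is the decision statistic. The
direction of each one-sided test follows the sign of the observed deviation
and is reported alongside the p.

## Duplicate catalogs

WGD pairs are ingested from a two-column list (unordered, deduplicated,
self-pairs rejected, conflicting pairings an error). SSD candidates are
reciprocal best hits from all-vs-all BLASTP tabular output after dropping
self-hits and hits failing E ≤ 10⁻⁵ or < 50 bits; a query's best hits are
the maximal-bit-score ones (ties kept), and mutual-best candidate pairs are
resolved to a matching greedily by descending pair score (min bit score,
then min E, then lexicographic ids), so the output is deterministic and no
gene appears in two pairs.

Candidates are then filtered to the central [2.5%, 97.5%] quantile window of
the WGD dS distribution, so retained SSDs have synonymous divergence of the
same epoch as the WGD pairs; a two-sample KS statistic between retained-SSD
and WGD dS is reported as a diagnostic. A quantile window (rather than a
distribution test per pair) is a declared operationalization — "similar
distribution" admits many readings — and the window is configurable.

dS is NG86: per-codon fractional synonymous sites from the standard code
(changes to stop codons count as nonsynonymous), differences at
multi-difference codons averaged with equal weight over all orderings of
single steps (pathways through stops excluded unless all are blocked),
S averaged over the two sequences, and Jukes–Cantor correction
dS = −(3/4)·ln(1−(4/3)·pS), undefined (saturated) at pS ≥ 3/4. The
implementation is validated codon-by-codon against an independent exact-
fraction brute-force enumerator.

## Growth

OD₆₀₀ series are fitted by least squares to the logistic
N(t) = K/(1 + ((K−N0)/N0)e^(−rt)), initialized at K = max OD, N0 = first
positive OD, and r from the log-OD slope over the early quartile of the time
range. μ_max is reported as the fitted r (the convention of standard
growth-curve tools), not a numerical-derivative maximum. OD values are
floored at 10⁻⁴ before log operations; an optional blank (mean of
uninoculated control wells) is subtracted first. Fits that fail, or land
outside K > N0 > 0, r > 0, are flagged and their parameters withheld;
flagged fits are excluded (and counted) from group comparisons.
Serial-transfer generations are passages × log₂(1/bottleneck fraction),
reported raw and rounded (nearest integer; two significant figures from 100
upward, matching how such counts are quoted).

## Synthetic data: what it does and does not emulate

The generator produces the study-shaped inputs. Defaults describe a
yeast-like genome: 4000 singletons, 555 WGD pairs, 560 SSD pairs; 80% of
pairs carry copy-wise divergence (the analysis pool shows 867/1090);
3 replicates per medium/timepoint; NB dispersion 0.1 and lognormal library
factors (sd 0.2 in logs) around a 2-million-read scale — typical
bulk-RNA-seq biological-replicate values. Both copies of a pair share one
baseline mean; the planted divergence is a lognormal factor
(log-ratio ~ N(0, td_log_ratio_sd)) applied to one randomly chosen copy, so
copies are treated symmetrically. DE status is Bernoulli with probability
sigmoid(logit(frac_de) + de_td_coupling·[gene in TD pair]); the coupling
parameter plants (or nulls) the TD–responsiveness association, and log₂
effects are N(de_lfc_mean, de_lfc_sd) applied in YPE. CDS pairs descend
from a stop-free ancestor by single-nucleotide synonymous events (repeated
hits allowed, so back-substitution and JC correction are exercised);
realized dS tracks the target within a few percent at dS ≤ 0.5. Growth
curves are exact logistic values plus Gaussian noise floored at 0.

Not emulated: read-level data (alignment and counting are upstream of
scope), multi-factor expression designs, codon-usage bias or rate
heterogeneity in the CDS model, diauxic or multi-phase growth. Passing
tests therefore demonstrate that the estimators recover the planted
statistical structure under NB noise — not that any particular biological
dataset satisfies these models.

### Calibration conditions used by the acceptance tests

- Type-I rate of the DE caller: frac_de = 0, 2000 genes, 3v3, 50 seeds;
  fraction of raw p < 0.05 within 0.05 ± 0.02.
- Uniformity of the TD-enrichment p requires responders whose calls are
  driven by real condition effects: with no effects at all, the only
  "responders" are noise calls, and the same YPD replicate noise that
  produces a false call also inflates that gene's pair TD ratio (the TD
  background shares the YPD samples with the DE contrast), skewing the p
  left no matter how the test is implemented. The uniformity check therefore
  runs with DE effects present (frac_de = 0.2) and coupling = 0, over 200
  datasets of 2000 genes.
- Planted coupling: de_td_coupling = 4, frac_td_pairs = 0.5,
  td_log_ratio_sd = 1.0, de_lfc_sd = 1.5 — a strong, well-separated plant
  (P(DE|TD pair) ≈ 0.93 vs 0.2 elsewhere, planted ratios ~2-fold) so the
  power property is a property of the method, not of a borderline effect
  size.
- Problem sizes throughout (2000-gene calibrations, 600–1115-pair TD pools,
  100-codon oracle comparisons, 312-point growth grids) were chosen as the
  smallest sizes at which the statistical assertions are stable across
  seeds.

## Numerical and edge-case choices

- Strict inequalities at every threshold (τ, FC, FDR, ORA cutoff).
- Pseudocount 0.5 in lfc and in TD expression means.
- Pairs with both copies at zero raw counts: TD undefined, excluded, counted.
- High/low copy labels are undefined (null) when copy means tie exactly.
- Empirical p never below 1/(n_iter+1); every stochastic routine takes an
  explicit seed and is reproducible bit-for-bit.
- Fisher odds ratio uses the sample cross-product with Haldane's 0.5 added
  to all cells when any cell is zero.
- Rank-sum tests switch from exact enumeration to the tie-corrected normal
  approximation above a combined n of 12 (or whenever ties are present).
- The ORA universe defaults to the expressed genes (the count matrix), not
  all annotated genes; configurable.

## Known limitations

- The DE stage is two-group only; no GLM covariates, no TMM, no exact test.
- dS assumes aligned, equal-length, in-frame CDS; no codon-model ML dS.
- The TD measurement at 3 replicates is noisy (an equal-expression pair has
  a ~40% chance of a measured ratio > 1.25), which attenuates TD-based
  contrasts; conclusions should rest on the enrichment statistics, which
  account for the pool composition, not on individual pair flags.
- Growth fitting assumes a single logistic phase; flagged fits must be
  inspected rather than silently dropped from reports.
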