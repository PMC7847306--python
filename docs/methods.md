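# Methods

## The statistical model

All testing is done per metabolite with an ordinary Gaussian linear
model on log2-scale intensities; "Gaussian GLM" and OLS coincide here,
so the group coefficient has an exact two-sided t-test on the residual
degrees of freedom. With no covariates this reproduces the pooled
two-sample t-test, and with the pair covariate the paired t-test, to
numerical precision (both equivalences are asserted in the test suite
at 1e-10). Pair (same animal) and batch (independent experiment) enter
as fixed-effect indicator blocks with drop-first coding; the design
matrix is checked for rank and a collinear block is reported by name.
The fit is QR-based and vectorised across metabolites, so a 200 × 15
table is tested in one pass.

The reported fold change is 2^β where β is the fitted group
coefficient — a ratio of geometric means on the raw scale. This keeps
the fold change consistent with the model actually tested, rather than
a ratio of arithmetic means computed off-model.

Two front-ends run this model:

- **Above-background calling** compares cell samples to sheath-fluid
  blanks on log2(x + 1)-transformed data with *no* imputation and *no*
  normalization: blanks are legitimately near zero, and normalizing
  them would destroy the very signal being measured. A metabolite is
  above background when 2^β > 2 and BH-FDR < 0.05.
- **Differential abundance** between two cell populations first imputes
  zeros at half the per-metabolite minimum nonzero value (computed
  across all samples of the comparison, not per group), then normalizes
  by relative log expression, then log2-transforms. Imputation precedes
  normalization so that the RLE geometric means are defined without
  discarding rows. The testing universe should be the union of the
  above-background sets of the two conditions; BH runs over that
  universe only.

### Multiple testing and thresholds

The FDR method is Benjamini–Hochberg step-up (delegated to
statsmodels; an independent brute-force implementation of the step-up
definition lives in the tests). All significance thresholds are strict
inequalities — FC > 2, FDR < 0.05, enrichment FDR < 0.01 — and the
comparisons carry a relative guard of 1e-9 so that a fitted fold change
of exactly the cutoff (which lands an ulp off 2.0 after 2^β) is still
excluded, as a strict inequality on real numbers demands. The ppm and
RT windows in library matching are inclusive (|ppm| = 5.000 accepts)
with the same guard on the other side.

### Degenerate fits

When the residual variance is numerically zero (identical values within
groups) the t-statistic is undefined; the convention is p = 1 when the
group effect is also zero (no evidence of a difference) and p = 0 when
it is not, and such rows are flagged `degenerate` in the output.

## Normalization

RLE size factors are the per-sample median of value / (row geometric
mean across samples), over rows with no zeros, rescaled so the factors'
geometric mean is 1 (so the overall intensity scale is preserved). An
alternative normalization, `mean_equalize`, scales each sample so its
mean intensity over the above-background metabolites equals the grand
mean; both are exposed and RLE is the default for differential testing.
RLE assumes most metabolites do not change between samples; when a
large majority of the signal truly shifts, its factors absorb part of
the biology, which is the standard caveat of median-of-ratios methods.

## Library matching

Mass error is 10⁶·(observed − theoretical)/theoretical. Theoretical
m/z of protonated adducts uses the proton mass (1.007276 Da), so the
electron is accounted for. Isotopologue envelopes are predicted from an
embedded table of natural abundances (IUPAC 2021 representative values;
C, H, N, O, P, S, Cl, Na, K) by convolving each element's single-atom
distribution over nominal mass shifts up to the requested M+k —
truncated convolution is exact for the leading coefficients — and
normalising to the monoisotopic peak. Agreement between an observed and
predicted envelope is scored by cosine similarity with an acceptance
minimum of 0.95; the criterion "intensity increases with cell number"
for library inclusion is operationalised as Spearman ρ ≥ 0.8 between
cell count and intensity, and retention-time reproducibility as a
max–min RT spread within the RT tolerance (0.5 min default). These
three numeric choices are configuration, not constants: the qualitative
criteria they implement (pattern matches, signal scales with input,
peaks align) do not come with published cutoffs.

`match_feature` reports near-misses (up to 4× outside the windows) with
rejection reasons rather than silently dropping them, because manual
review of borderline annotations is how low-abundance libraries are
actually curated.

## Pathway enrichment

One-sided hypergeometric over-representation (Fisher exact upper tail)
of the significant set within the detected universe, with pathway
membership intersected with the universe first and pathways holding
fewer than 2 universe members skipped as degenerate. The universe is
the detected (above-background) metabolites of the comparison, not the
whole library — testing against metabolites that could never have been
called inflates enrichment.

## The simulator

`simulate_experiment` draws per-metabolite baselines log-uniformly over
10⁴–10⁹ ion counts, multiplies in lognormal biological noise with CV
0.25 (σ_log2 = sqrt(ln(1 + CV²))/ln 2), plants a configurable fraction
of differential metabolites with log-uniform fold changes (signs
random), adds batch and pair effects additively on the log2 scale, and
gives blanks signal only on a random 30% of metabolites at 5% of the
cell level — mirroring the observation that sheath-fluid background is
concentrated in particular contaminant peaks rather than a uniform
floor. Detection is Bernoulli with a logistic probability in log10
intensity (midpoint 10⁴ counts, slope 2 per decade), which produces
zeros concentrated at low intensities, exactly the missingness that
half-minimum imputation targets. Defaults (200 metabolites, 5
replicates per condition, 5 blanks) match the scale of a typical
sorted-cell experiment.

What the simulator does *not* emulate: retention-time drift between
runs, correlated metabolite panels (covariance is diagonal on the log
scale), heavy-tailed technical outliers, and ion suppression as a
function of co-eluting salt. Passing tests therefore demonstrate the
pipeline's statistical behaviour under a clean generative model, not
robustness to every instrument artefact.

`simulate_titration` makes feature intensities proportional to cell
number with multiplicative noise (plus optional flat contaminant
features), and `simulate_blank_contamination` scales the blank signal
across ordered "drying" levels with the contaminant metabolite set held
fixed, so that the effect of background growth on detection counts is
isolated from resampling noise.

## Operating characteristics and problem sizes

The acceptance suite and `scripts/acceptance.py` run the pipeline as a
user would: above-background calling per condition, union as the
testing universe, then differential testing. On null simulations (20
runs, 200 metabolites each) the average share of metabolites called
significant stays below 0.07; planted 8-fold effects (n = 5 per group,
CV 0.25, 5 runs) are recovered with sensitivity ≥ 0.9 among the
metabolites that enter the universe and a median |log2FC| error well
under 0.5. Effects planted on metabolites whose shifted intensity falls
below the simulated detection limit are excluded by the universe the
same way undetectable metabolites are excluded in a real experiment;
that detection-limit censoring, not the test, is what bounds
sensitivity. The split-protocol concordance scenario uses 10 replicates
per group split into two pseudo-protocols and a 45% differential
fraction, emulating a comparison of two genuinely distinct cell types
measured twice. These sizes keep the whole suite in the low seconds on
one CPU while leaving Monte-Carlo margins comfortably away from the
asserted bounds.

## Data model conventions

Zeros in intensity tables mean "not detected"; empty cells in input
files are read as 0 with a warning (imputation targets zeros, and NaN
would silently fall out of every mean). The canonical orientation is
metabolites × samples with a flag for transposed files. XLSX input is
restricted to the first worksheet. Blanks never participate in
normalization. Result tables round-trip through delimited text at
1e-9 relative precision.

## Known limitations

- Fixed-effect pairing assumes complete pairs; incomplete pairs are an
  error, not a drop-with-warning.
- No variance shrinkage or moderated statistics: with n = 3 per group
  the per-metabolite variance estimate is noisy, and power is
  correspondingly lower than limma-style approaches would give.
- Enrichment assumes metabolite identifiers in results, universe and
  GMT sets already agree; no ontology translation is attempted.
- The isotope table covers C, H, N, O, P, S, Cl, Na, K; formulas with
  other elements are rejected rather than approximated.
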