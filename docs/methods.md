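# Methods

## The limitation statistics

Five hydrolytic extracellular enzyme activities per sediment sample are
pooled into acquisition sums — C = BG + CBH, N = NAG + LAP, P = AP — and
reduced to investment proportions x = C/(C+P) and y = C/(C+N). The
limitation vector of the point (x, y) has length `VL = √(x²+y²)`
(relative carbon limitation) and angle `VA = degrees(arctan(y/x))`
measured from the x-axis in the first quadrant. The angle convention is
load-bearing: with this orientation `VA > 45°` is equivalent to
P-investment exceeding N-investment (P limitation) and `VA < 45°` to
N limitation, and x = y gives exactly 45°. Spreadsheet-style
`ATAN2(x, y)` notation denotes the same quantity (the angle of the point
(x, y)); implementing the other argument order would silently invert the
N/P classification.

Assumptions: activities enter only through ratios, so the statistics are
invariant under uniform rescaling of all five activities and agnostic to
assay units. Samples with a zero denominator (no C-acquisition activity)
have no defined vector; they are excluded from summaries and logged, not
imputed. Exact 45° ties (within 1e-9°) are reported as BALANCED rather
than forced into either class, since the classification rule is defined
by strict inequalities.

An optional natural-log scale (`ln_transform`) takes ln of each pooled
sum before forming the proportions, for comparability with analyses that
work on log-converted activity ratios. On that scale the proportions are
only well defined when each pooled sum exceeds 1 in the working units;
out-of-range samples are marked undefined. The raw-proportion scale is
the default and the flag used is recorded in the run manifest.

The cohort C:N:P acquisition ratio is reported as a ratio of means
(robust to small per-sample denominators); the mean of per-sample ratios
is emitted alongside as a secondary column because published "mean ratio"
phrasings do not always distinguish the two.

## Diversity and community comparison

Alpha diversity is the Shannon index in nats, H = −Σ pᵢ ln pᵢ (base is a
parameter). Beta diversity is Bray–Curtis dissimilarity on raw counts,
Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ). The Hellinger transformation √(countᵢⱼ/rowᵢ) is
exposed as the standard pre-step for linear ordination but is not applied
before Bray–Curtis. Rarefaction subsamples each community without
replacement (multivariate hypergeometric) to a common depth — by default
the minimum positive sample depth — with a fixed seed recorded in the
manifest; samples below the depth are dropped with a warning. Rarefaction
to the minimum retained depth is a documented operational choice, not a
claim about any particular field protocol.

## Driver screening

Pearson correlations (pairwise deletion of missing values, two-sided
t-based p), OLS with adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) and Gaussian
AIC (via statsmodels), and classic one-way ANOVA relate the limitation
statistics to physicochemistry; with two groups F equals the pooled t².
The Mantel test correlates the upper triangles of two distance matrices
(Pearson), builds the null by jointly permuting rows and columns of the
second matrix, and reports the one-tailed (greater) add-one p-value
(1 + #{r_perm ≥ r_obs})/(1 + n_perm); 999 permutations by default.
Pearson-on-distances was chosen over Spearman to match the linear-model
framing of the community analyses.

Model selection is greedy forward stepwise by AIC: starting from the
intercept-only model, the candidate that most lowers AIC is added (ties
broken by column order) until no candidate lowers it. Note a property of
plain forward-AIC worth knowing: an irrelevant predictor enters whenever
its incremental F exceeds ≈ 2, so with several pure-noise candidates the
selected set is often non-empty — but its adjusted R² stays near zero and
its AIC is never worse than the intercept-only model. Variable
attribution uses model-agnostic permutation importance: the mean increase
in MSE after shuffling one predictor's column, averaged over `n_rep`
shuffles and normalised to percentage contributions. This is the same
permute-and-score quantity that tree-ensemble importances estimate,
computed here around the fitted linear model so it is exactly
reproducible from its definition.

## The synthetic survey generator

The generator emulates a 30-site, two-region survey: a small basin
(SXK, 10 sites) that is shallow, solute-rich and carbon-rich, and a large
basin (LXK, 20 sites) that is deeper and more dilute. Defaults encode the
field pattern the pipeline targets: sediment TC/TN/TP means 18.06/1.78/
0.73 g·kg⁻¹ (SXK) and 5.43/0.69/0.44 g·kg⁻¹ (LXK); BG 3× higher, N-enzymes
1.2× higher, and AP 4× lower in SXK; pooled C:N:P acquisition
stoichiometry 1:0.58:1.51; dominant phylum means of 33.03% Proteobacteria
(bacteria) and 53.23% Ascomycota (fungi).

Strictly positive quantities are log-normal with a 30% coefficient of
variation (published tables give only means, so every dispersion is a
generator choice; 30% CV is typical of activity and concentration data);
pH and temperature are normal. Enzyme activities follow

    ln A_e = ln(base_e) + ln(mult_{e,region}) + Σᵢ β_{e,i} zᵢ + ε_e

where zᵢ are the log covariates depth, TDS, water conductivity and
sediment TC, standardised with *analytic* pooled moments of the two-region
mixture (never data moments, so the calibration stays closed-form), and
ε_e is Gaussian with the same 30% CV. Default βs give the C-enzymes
positive loadings on TDS/conductivity/TC and a negative loading on depth,
and AP the opposite signs, reproducing the qualitative driver pattern:
VL rises with dissolved solids and falls with depth, VA the reverse.

Calibration is exact in expectation, not tuned: using
E[lognormal] = exp(μ + σ²/2), the regional conditional mean of each
enzyme is base·mult·exp(β·a + ½β²b² + ½σ²) with (a, b) the per-region
moments of z, so the SXK multiplier that realises a target regional mean
ratio and the base level that realises the pooled stoichiometry target
are solved directly. Region weights use the config's own n_sxk:n_lxk.
A structural consequence of the encoded contrasts: with AP ¼× and
N-enzymes 1.2× in SXK under the pooled 1:0.58:1.51 constraint, the SXK
regional mean N pool exceeds its P pool, so small-basin sites trend
N-limited and the cohort-wide P-limited fraction settles near the LXK
share (~0.73, i.e. 22 of 30 sites) — the large basin itself is >85%
P-limited.

Communities are Dirichlet-multinomial: per-sample phylum proportions are
Dirichlet with concentration 200 around the configured means (optionally
tilted along the standardised conductivity gradient by a coupling
coefficient, default 0.25, with sign-alternating loadings on the
non-dominant phyla so that beta diversity tracks the limitation
gradient), within-phylum OTU weights are one stick-breaking draw per
cohort (Beta(1, 5)), and counts are multinomial at a read depth of
10,000. With coupling 0 the Mantel correlation between community
dissimilarity and limitation differences is centred on zero.

What the generator does *not* emulate: spatial autocorrelation between
neighbouring sites, covariance among chemistry variables beyond the
region split and the planted enzyme couplings, taxon-level ecological
structure (OTU weights are exchangeable within phylum), sequencing error
or compositional artefacts. Tests passing on this cohort therefore
demonstrate correctness of the estimators and the stated calibration, not
robustness to those features of real surveys.

## Numerical choices and problem sizes

Calibration checks use n = 10,000 cohorts (3,334 + 6,666, or 10,000
single-region for the sediment-carbon check), chosen so that Monte-Carlo
error (≈0.01 on the pooled ratios) is well inside the ±0.02 assertion
bands and calibration error is separable from sampling noise; community
checks use the default 30-sample survey. Mantel calibration uses 500 null
replicates at n = 20 with 999 permutations. Distance-matrix symmetry is
enforced at 1e-12; numeric payloads are serialised at 12 significant
digits, making write→read round trips lossless at that precision and
same-seed reruns byte-identical. All random draws flow from explicit
seeds through numpy Generators; nothing consumes wall-clock entropy.

## Known limitations

The stepwise procedure is forward-only with AIC; backward or
p-value-threshold variants can select different sets on collinear field
data. Permutation importance around a linear model understates importance
for predictors whose effect is nonlinear. Bray–Curtis on raw counts is
sensitive to sequencing depth; the pipeline rarefies first, which
discards reads and adds sampling noise. The ln-transform investment scale
is undefined for pooled activities ≤ 1 working unit, so its results
depend on the unit convention, unlike the default raw-proportion scale.
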