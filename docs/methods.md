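# Methods

This note records the statistical procedures the package implements, the
defaults it ships with and why, the numerical choices that matter, and what
the synthetic-data generator does and does not emulate.

## Data model

The unit of analysis is a compound record: six in-silico descriptors
(MW in g/mol, NRB, HBD, HBA counts, TPSA in Å², polarizability α in Å³), an
in-silico log BB response, and the measured chromatographic lipophilicity
log k_w,IAM. The 126-compound study table is packaged as CSV with values
stored exactly as printed (Unicode minus normalised to ASCII on ingest; no
re-rounding). Class labels (I–XVI) and the provenance footnotes are carried
as metadata and never enter any computation. Missing values are rejected —
the study has none, and silently imputing descriptors would invalidate the
leverage arithmetic downstream.

## Retention extrapolation

Isocratic retention factors k = (t_r − t_0)/t_0 require t_r > t_0 > 0;
non-retained solutes are a domain error, not a zero. All logarithms are
base 10 (chromatographic convention). log k_w is the intercept of the OLS
line log k = log k_w − s·φ; the slope is reported negated so s is the
positive solvent-strength parameter. Two distinct φ levels are the hard
minimum (a warning is emitted below three; the study design used four:
φ ∈ {0.2, 0.3, 0.4, 0.5}). Replicate injections at the same φ are averaged
on the log k scale before fitting by default — the alternative (fit all
replicates as points) is selectable, and with balanced replication both give
the same line. Dead time is always an input (measured from unretained-marker
peaks), never estimated.

## Descriptor chemometrics

PCA operates on the correlation matrix (i.e. standardized variables, n−1
denominator): the descriptors differ in units by orders of magnitude, and
correlation-matrix loadings are bounded by 1, matching the reported loading
magnitudes. Components are deterministically oriented so each component's
largest-magnitude loading is positive; reported loadings elsewhere may be
globally flipped per component, so cross-checks compare magnitudes where
signs disagree.

Variable similarity is expressed as a percentage of Pearson correlation.
The default convention, 100·(1+r)/2, is the similarity scale of a dendrogram
built on correlation distance d = 1 − r with maximum distance 2; it was
calibrated by computing both candidate conventions (the other being 100·|r|)
on the bundled panel and keeping the one that reproduces the reported
size-pair similarity (MW vs α = 92.57%) exactly. The reported polarity-pair
value (95.48%) is *not* reproduced by either convention — the table yields
95.86% under the default — and the package makes no attempt to match it;
the discrepancy is assumed to be an artefact of the original software or a
dataset revision. Clustering linkage defaults to single linkage, which on
the bundled panel reproduces the reported dendrogram merge levels (NRB joins
the size cluster at 74.04%, and the final merge with the polarity cluster is
at 68.98%); average and complete linkage are selectable, and merge levels at
the NRB step are linkage-sensitive. HBD and HBA enter chemometrics only as
their sum HB_total.

## Model fitting and statistics

OLS is solved by QR decomposition (via statsmodels), not normal equations;
tests verify agreement with an explicit (XᵀX)⁻¹Xᵀy oracle on
well-conditioned designs. A design whose reciprocal condition number falls
below 1e-10 is rejected with the offending columns named — the size pair
(MW, α) and polarity pair (TPSA, HB_total) must never co-enter a model
silently.

The full statistic set on every fit: coefficient standard errors, two-sided
t-tests with n−p−1 degrees of freedom, the ANOVA F = (SSR/p)/MSE with its
upper-tail p-value, R², adjusted R², the leave-one-out PRESS via the
hat-matrix identity PRESS = Σ(e_i/(1−h_ii))², predicted
R² = 1 − PRESS/SS_total, per-predictor VIFs from auxiliary regressions, and
the hat diagonal itself. The coefficient uncertainties quoted in parentheses
after each coefficient in the reported equation are standard errors (they
match the computed SEs at printed precision; they do not match p-values),
and the package reports them as such. "SS" in the reported statistics is the
corrected total sum of squares of log BB — the only reading under which
R²_pred = 1 − PRESS/SS holds at printed precision, which a consistency test
asserts rather than assumes. A fit whose SSE vanishes to numerical precision
is flagged perfect: F is reported infinite with p = 0, and residual
standardization (needed by the Williams plot) is refused.

Candidate-model enumeration fits the eight admissible blocks — lipophilicity
always, one of {MW, α}, one of {TPSA, HB_total}, optionally NRB — and ranks
by adjusted R² with PRESS as tie-breaker, subject to a parsimony rule: a
model outranks a nested smaller one only by exceeding its adjusted R² by
more than a threshold (default 0.005; the principle is standard, the number
is a package choice). On the bundled panel this ranking places the α-size
block first (adjusted R² 0.9568 vs 0.9326): the published preference for MW
over α was motivated by ease of application (α requires commercial software
to compute), not by fit statistics, so the package keeps the MW block as its
*default* predictor set while the enumeration reports the statistical
ranking honestly. NRB never improves any block by more than the parsimony
threshold.

### Prediction at reported precision

Predictions can be made either from the full-precision coefficient vector or
from the equation rounded to its reported 4-decimal precision
(`coef_precision=4`). The published modeled-log BB values for named compound
subsets (e.g. the hydrazide set spanning −1.241…−1.014) were evidently
computed from the rounded equation: the rounded form reproduces them exactly
at 3 decimals while full precision gives −1.229…−1.002. Reproduction paths
therefore use the rounded form; ordinary prediction defaults to full
precision.

## Cross-validation

Leave-30%-out validation uses a nominal holdout of ceil(0.30·n) = 38
compounds. The default grouped-folds scheme shuffles once (seeded) and
partitions into ceil(n/38) = 4 folds of 31–32 compounds, so every compound
is predicted exactly once from a model refitted without it and PRESS_cv
accumulates n squared errors — the same scale as the 126-prediction LOO
PRESS. The alternative repeated-random-splits scheme draws independent
38-compound holdouts (default 100) and rescales the mean per-prediction
error to n. Q²_cv = 1 − PRESS_cv/SS uses the full-response corrected total
SS as denominator, matching the reporting arithmetic of the fit statistics;
per-fold training-mean denominators are not used. All randomness flows from
one integer seed; identical seed and configuration give bit-identical
results. Note that any honest held-out scheme trains on fewer points than
leave-one-out and therefore cannot produce a PRESS_cv below the LOO PRESS;
reported cross-validation figures elsewhere that equal the fit R² exactly
should be read as tolerance-level agreement, not a reproducible identity.

## Applicability domain

Warning leverage h* = 3(p+1)/n (0.095 for p = 3, n = 126). Standardized
residuals default to e_i/√MSE (plain standardization); internally
studentized residuals e_i/√(MSE(1−h_ii)) are available via an option since
the "±3 SD" convention does not specify which. Flags partition compounds
into in-domain, high-leverage (h > h*), response-outlier (|z| > 3) and both.
Query compounds are assessed against the training moment matrix (XᵀX)⁻¹ and
never update it; query leverage is computed through the training design's R
factor for stability. The Williams output is a table; plotting is a
convenience with no contract.

## Prediction categories and rule filters

Category thresholds: predicted log BB > 0.3 → readily crosses; < −1 →
poorly distributed; the closed interval [−1, 0.3] is one merged
limited-or-moderate band (no finer published bounds exist). Boundary values
fall in the merged band.

Drug-likeness filters: Lipinski Ro5 (MW < 500, HBD < 5, HBA ≤ 10, log P < 5),
Ghose (160 ≤ MW ≤ 480), Clark (MW ≤ 480), van de Waterbeemd (MW ≤ 450 and
TPSA ≤ 90), Kelder (TPSA ≤ 70, with an annotation when the stricter 60 Å²
bound of the 60–70 band is exceeded), Ajay (200 ≤ MW ≤ 400, HBA ≤ 4,
HBD ≤ 3, NRB ≤ 7, log P ≤ 5.2). The HBA bound follows Lipinski's original
"not more than 10": two bundled compounds have exactly 10 acceptors and are
drug-like by the rule. log P is optional input; rules referencing it report
the sub-criterion as skipped when absent — never silently passed — and the
package does not estimate log P.

## Synthetic data

The generator emulates only the statistical structure the pipeline relies
on: a latent size factor loading on MW and α (target corr 0.90, split evenly
as √0.9 each), a latent polarity factor loading on TPSA and the
hydrogen-bond counts (target 0.92), a weak size–polarity factor correlation
(0.15, near the empirical MW–TPSA correlation), log k_w,IAM loading 0.70 on
the size factor, and the response generated from the fitted study
coefficients with Gaussian noise of SD √0.01355 (the study-model residual
SD), so synthetic fits land in the same R² regime as the real panel.
Counts are made discrete by rounding/thresholding latent Gaussians into the
observed support (HBA in 4…10, HBD in {0, 3}, NRB in 0…7) and continuous
descriptors are clipped to the observed ranges; clipping is mild (≲3 SD) so
target correlations survive within ±0.05 at large n. Randomness flows from
one seed through spawned child streams, so descriptor structure, response
noise and retention noise are independent and individually reproducible.

What the generator does **not** emulate: compound classes and chemistry,
heteroscedastic or non-Gaussian measurement error, the bimodal clustering of
real descriptor values within chemical series, or any active-transport
signal. Passing recovery tests on synthetic panels therefore demonstrates
correctness of the estimators under the model's own assumptions, not
robustness to real-data pathologies.

The retention generator uses the study design (φ ∈ {0.2, 0.3, 0.4, 0.5},
3 replicates, log k noise SD 0.02) and can emit either log k values or
(t_r, t_0) time pairs that invert exactly through the retention-factor
computation.

## Problem sizes and determinism

Everything runs at desk scale: the headline analyses are deterministic
recomputations on the 126-row panel; Monte-Carlo assertions use 20–200
seeded replicates (coefficient-coverage: 200 fits; CV stability: 50 seeds;
retention SE calibration: 1000 four-point fits), sizes chosen so the whole
suite completes in well under a minute while keeping Monte-Carlo error small
relative to the asserted tolerances. Every stochastic component takes a
single integer seed, and pipeline outputs embed the configuration hash and
seed; identical configuration and seed reproduce outputs byte-identically.

## Known limitations

- The model covers passive diffusion only; actively transported or effluxed
  compounds fall outside its applicability by construction.
- Descriptors are taken as given; no structure handling or descriptor
  computation (including log P) is provided.
- The merged limited-or-moderate category is coarse because no finer
  published thresholds exist.
- The reported polarity-pair similarity (95.48%) and the reported F (578)
  are not exactly reproducible from the bundled table (the package computes
  95.86% and 577.3 respectively); both discrepancies are documented above
  and surfaced, not patched over.
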