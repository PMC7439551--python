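# Methods

## Model and assumptions

The imputer is a donor-based nearest-neighbour method for longitudinal
clinical registers. Its single substantive assumption is that subjects with
a similar disease course over a short observation window share similar
feature values, so observed values of similar subjects are plausible
estimates for a subject's missing ones. Being fully non-parametric, it
requires no distributional model of the features and no missingness
mechanism beyond the existence of some relationship between the feature
with the missing value and the others; imputed numeric values are always
inside the range of the donor values actually used, and imputed discrete
values are always admissible levels.

A register is a schema (each feature static or dynamic; continuous, ordinal
or categorical; discrete features with explicit levels) plus per-patient
static values and time-stamped visits, times in months re-based so every
patient's first visit is at 0. Missingness is a single sentinel at the data
model level; no magic numbers enter feature space.

### Sample construction

The query vector binds the `p` static values to one block of `m` dynamic
values per visit in the `[0, window_end]` window (`window_end = 2.0`
months, i.e. the first three calendar months; both window ends inclusive).
Candidates are temporally mapped over the query: for each query visit time
the candidate visit minimising `|Δt|` subject to `|Δt| ≤ tolerance`
(`tolerance = 1.0` month, inclusive) fills the corresponding block.
Candidate visits up to `window_end + tolerance` are searched, one candidate
visit may fill several blocks, and a candidate with any unmatched query
time is excluded. Two conventions the construction needs but the procedure
itself does not fix: equidistant candidate visits resolve to the **earlier**
visit (deterministic, and favours information closer to baseline), and the
tolerance comparison is inclusive, mirroring the closed window intervals.

### Distance

Continuous and ordinal entries are min–max normalised to `[0, 1]` per base
feature over the pooled query + all candidate samples (pre-filter; a
constant pooled feature maps to 0 and contributes nothing). The distance is
the pairwise-complete mixed-type metric described in the README: absolute
difference for numeric entries, 0/1 mismatch for categorical ones, static
contributions and the static comparable-count both multiplied by the query
visit count `n` so that statics and the `n`-fold repeated dynamics weigh
comparably, everything divided by the visit-adjusted number of shared
observed entries. Candidates sharing fewer than 90% of the query's own
visit-adjusted observed entries are dropped
(`comparability_threshold = 0.9`).

In the MI-weighted variant every entry is additionally weighted by the
mutual information between its base feature and the feature currently being
imputed, so neighbourhoods are target-specific. The diagonal entry
(a feature's own entropy) is kept: when a dynamic feature is missing at the
target visit but observed at another, those observed copies legitimately
contribute with weight `H(f)`.

### Mutual information estimation

MI is the frequentist plug-in estimate in nats over pairwise-complete
observations. Continuous features are discretised into `i = N^(1/3)`
equal-width intervals (banker's rounding on the bin count, floored at 2 so
the table is never degenerate; the maximum lands in the last bin). Row
units: static–static pairs are estimated on one row per patient (patients
with many visits would otherwise be over-weighted); any pair involving a
dynamic feature uses one row per in-window visit with statics repeated,
because dynamic values only exist per visit. The matrix is estimated once
per donor pool and cached. In external mode the query subjects are not in
the pool; in self mode a subject's own rows stay in the pooled estimate —
excluding them would force a per-subject re-estimate for a change that is
negligible at register scale. By default only in-window visits feed the
estimate (the data the distance actually sees); `window_end=None` switches
to all visits.

### Aggregation

The `k` nearest eligible donors (eligible = holding an observed value at
the target entry and passing the comparability filter; distance ties broken
by candidate id for cross-platform determinism) are aggregated on their
**raw** values — normalisation exists only inside the distance.
Continuous/ordinal: donors outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
(linear-interpolation quartiles) are trimmed — skipped if trimming would
empty the set — then an inverse-distance weighted mean with weights
`1/max(d, 1e-9)`, so exact-duplicate donors dominate without division by
zero. Ordinal results are rounded half-up to the nearest admissible level
(the error quantisation of 0–4 items in practice implies integer
imputations); `round_ordinal=False` disables this. Categorical: unweighted
mode; ties resolve to the category holding the single closest donor, then
to level order.

Within a subject, every query reads from an immutable snapshot of the
original record: previously imputed values are never reused. In self mode
each subject's donors are all other patients of the dataset; in external
mode only the donor pool donates and held-out subjects never see each
other. Only visits inside the window are imputed.

### Random-neighbour baseline

`method="krn"` runs the identical pipeline but draws `k` donors uniformly
(seeded) from the eligible candidates and weighs them equally in
aggregation. Sampling eligible candidates — not all patients — isolates the
effect of neighbour *choice*, which is what the baseline exists to measure.

## Evaluation harness

Masking experiments remove, per subject and per feature, all that feature's
observed window values at once, re-impute them from untouched donors, and
compare with the held-back truth. Per feature the score is nRMSD
(continuous/ordinal) or PFC (categorical); per cell the nAE supports paired
Wilcoxon signed-rank tests (zero-inclusive "pratt" ranking, since nAE on
0–4 items is quantised and heavily tied) and McNemar's exact test for
categorical features — both delegated to scipy/statsmodels. The normalising
range in nRMSD and nAE is the range of the **true values of the evaluated
cells**, exactly what the formulas divide by, not a whole-dataset range;
this affects comparability across experiments and is therefore fixed here
once. Class averages are plain feature means. Neighbour-count selection
partitions patients into folds (default 10), scores each `k` of the grid
(default {5, 10, 15, 20, 25}) with out-of-fold donors, and picks the `k`
minimising the simple average of the numeric-class mean nRMSD and the
categorical-class mean PFC. The presets encode the selected operating
points: k=20 for the MI-weighted method, k=10 for the unweighted one.

The train/test splitter is patient-level and approximately stratified
"over all variables": among R seeded random splits (default 1000) it keeps
the one minimising the summed absolute train–test differences of
per-feature summary statistics (means for numeric features, level
frequencies for categorical). The achieved balance score is what the
implementation reports; no exact-marginal algorithm is claimed.

## Survival samples

For the downstream survival classification task each labellable patient is
condensed to `p + 3·m` entries: the statics plus, for every dynamic
feature, the minimum, maximum and least-squares slope (value against time
in months, ≥ 2 observations at distinct times required, binary features
encoded 0/1) over the window — 53 entries under the packaged 25-feature
schema. The label answers "survives more than 36 months from the first
visit": death at exactly the horizon counts as *short* (strict "more
than"), censoring at or after the horizon counts as alive-at-horizon
(*long*), and patients censored before the horizon are excluded as
unanswerable; both horizon conventions are configurable. Dataset variants
for probing imputation impact: native-missing, complete cases, complete
features, and one variant per supplied imputer applied before sample
construction. A downstream classifier is deliberately out of scope: the
samples are plain DataFrames any scikit-learn estimator can consume.

## Synthetic cohort generator

The generator emulates the structure of an ALS screening register, not its
clinical calibration: per-subject visit schedules (1–4 roughly monthly
visits in the window, follow-up visits to ~8 months that only serve donor
matching), 12 ordinal 0–4 items declining as
`clip(round(4 − severity − rate·t − offset_j − site_shift_j + ε), 0, 4)`
with a per-subject severity latent (sd 0.8) inducing positive inter-item
correlation, a gamma-distributed progression rate, item noise sd 0.5, and
onset-site-specific item shifts (bulbar onset depresses the bulbar items,
limb onset the limb items). NIV/PEG switch on monotonically when cumulative
decline crosses thresholds. Statics carry real epidemiological
dependencies: familiality and FTD track the genetics feature (familial
cases mostly carry a known mutation; FTD is enriched in C9orf72 carriers),
FVC declines with rate and severity, and survival time decreases with the
progression rate under independent uniform censoring.

Two deliberate design choices make the planted structure identifiable by a
k-NN method at desk scale (200 subjects): BMI at diagnosis is a
deterministic shift of premorbid BMI, whose uniform support keeps donor
density even at the extremes (normal tails would starve the neighbourhood
there and bias any k-NN estimate inward), and a configurable set of columns
is never masked — mirroring real registers, where sex, onset site, age at
onset and the onset/diagnosis timing variables are recorded for everyone —
which keeps the tie's source and the MAR covariate observed. Missingness is
MCAR (independent Bernoulli per maskable cell, default rate 0.1) or MAR
(logistic shift of the masking log-odds for male subjects; sex is never
masked, so the probability depends only on observed data). Only static
cells and in-window dynamic cells are maskable — the windowed imputer's
responsibility. MNAR generation is intentionally absent from the defaults;
the mask interface accepts user-supplied mechanisms.

What passing tests on this generator do **not** show: performance on real
registers with informative visit schedules, MNAR missingness, measurement
error structure, or clinically calibrated marginals. The generator's role
is to separate a working implementation from a broken one under known
ground truth, not to predict register-scale error levels.

## Numerical choices and degenerate inputs

Type-7 (linear-interpolation) quantiles everywhere quartiles appear;
distance epsilon 1e-9; zero-range nRMSD/nAE reported as undefined and
excluded from averages; a feature with no observed values gets a zero MI
row with a warning; a candidate sharing zero observed entries is
incomparable (a structured outcome, not an error); entries with no eligible
donor stay missing and are logged. All randomness flows from explicit
seeds; identical configurations give bit-identical cohorts, imputations and
reports.

## Problem sizes

The reference scenario used by the test suite and the acceptance script is
200 subjects with 10% MCAR missingness — large enough for the planted
relationships to be learnable and for the method-versus-baseline gap to be
stable across seeds, small enough to iterate on freely. The
method-dominance check aggregates 20 seeded replicates of that scenario.

## Known limitations

Only the first-window visits are imputed (sliding-window extension over the
full history is future work); single imputation only (no repeated draws to
propagate imputation uncertainty); the plug-in MI estimator is biased
upward at small samples — acceptable here because weights enter relatively —
with no shrinkage or continuous (k-NN/KSG) estimator provided; the
approximate stratified splitter optimises marginal balance only.
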