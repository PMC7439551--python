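# wknnmi

Adaptive mutual-information-weighted k-nearest-neighbour imputation for
clinical registers that mix **static** features (sex, age at onset, BMI, …)
with **dynamic** ones re-measured at every visit (functional-scale items,
intervention indicators), each of which may be continuous, ordinal or
categorical — and all of which may be missing.

The package targets longitudinal disease registers such as ALS screening
registers: one row per patient visit, visit times in months re-based to the
first visit, and a declared schema of 11 static + 14 dynamic variables
(the 12 ALSFRS-R items scored 0–4 plus NIV/PEG intervention flags among
them). Because such registers are typically not shareable, a synthetic
cohort generator with known ground truth is a first-class part of the
package: every claim the test suite makes is checked against data it can
regenerate.

## The method

For a query subject *i*, the imputer flattens the static block and one
dynamic block per visit in the `[0, 2]`-month window into a feature vector
of length `p + n·m`. Every candidate donor *j* is temporally mapped onto the
query's schedule: for each query visit time, the donor's closest visit
within one month supplies that block (a donor visit may serve several query
visits; a donor with an unmatched query time is excluded). After min–max
normalisation of continuous/ordinal entries over the pooled samples, the
distance between the vectors **v**, **u** is

```
d(v, u) = [ n · Σ_static w_l δ_l  +  Σ_dynamic w_l δ_l ] / [ n·N_stat(v,u) + N_dyn(v,u) ]
```

where `δ_l = |v_l − u_l|` for continuous/ordinal entries, the 0/1 mismatch
indicator for categorical ones, only entries observed in *both* vectors
contribute, `N_stat`/`N_dyn` count those shared entries, and the factor *n*
re-balances the statics against the *n*-fold repeated dynamics. With unit
weights `w_l = 1` this is the plain adaptive k-NN distance; the MI-weighted
variant sets `w_l = MI(f, l)`, the plug-in mutual information (nats, with
cube-root equal-width discretisation of continuous features) between the
feature *f* being imputed and the base feature behind entry *l* — so the
neighbourhood adapts to the target feature. Donors sharing fewer than 90%
of the query's (visit-adjusted) observed entries are dropped; the `k`
nearest eligible donors are aggregated by an inverse-distance weighted mean
after 1.5·IQR outlier trimming (continuous/ordinal; ordinal results rounded
to an admissible level) or the mode (categorical). A subject's previously
imputed values are never reused for its remaining entries.

Imputation quality is scored by masking experiments: per feature,
range-normalised RMSD (nRMSD) for continuous/ordinal features and the
proportion of falsely classified (PFC) for categorical ones, plus a
per-cell normalised absolute error (nAE) for paired significance tests
(Wilcoxon signed-rank with zero-inclusive ranking; McNemar for
categorical). A seeded k-random-neighbours baseline (identical pipeline,
random donors) calibrates how much the neighbour choice itself contributes.

## Worked example

```python
import wknnmi as wk

# a synthetic ALS-like register: 200 subjects, 10% MCAR missingness
gt = wk.inject_missingness(wk.generate_cohort(wk.SyntheticConfig(seed=1)))
ds = gt.masked_dataset()

imputer = wk.WKNNImputer(k=20, weighting="mutual_info").fit(ds)
imputed = imputer.transform(ds)          # self-mode: donors = other patients

report = wk.score_against_truth(imputed, gt)
print(report.class_averages(ds.schema))
```

prints (the masked cells scored exactly against the ground truth)

```
{'continuous': 0.21404260819737428, 'ordinal': 0.21492037190067012, 'categorical': 0.0740704828940123}
```

— the mean per-feature nRMSD of the continuous and ordinal classes and the
mean PFC of the categorical class; zero would be perfect recovery. The same
scenario imputed with random donors (`weighting="random"`) scores roughly
0.35 / 0.27 / 0.16, which is the gap the MI-weighted neighbourhood buys.

The same operations are scriptable from a shell:

```sh
wknnmi simulate --seed 1 --out cohort.csv --truth truth.csv --mask mask.csv --schema-out schema.yaml
wknnmi impute cohort.csv --schema schema.yaml --method wknn-mi --k 20 --out imputed.csv
wknnmi evaluate cohort.csv --schema schema.yaml --methods wknn-mi,krn --out report.json
wknnmi select-k cohort.csv --schema schema.yaml --k-grid 5,10,20
wknnmi survival-features truth.csv --schema schema.yaml --out survival.csv
```

`wknnmi survival-features` builds the fixed-length survival samples (the
static block plus min/max/slope of each dynamic feature over the window —
53 entries under the packaged schema) labelled by survival beyond 36 months,
with patients censored before the horizon excluded.

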