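# fcstage

Stage-of-therapy classification from seed-based resting-state
functional connectivity (rs-FC).

`fcstage` is for researchers analyzing within-participant, two-stage
neuroimaging designs — each participant scanned before and after an
intervention — who want to know whether the two stages are separable
from whole-brain connectivity, and which connections, seeds and
networks drive the separation. It implements the complete group-level
chain as a tested library with a CLI, plus a synthetic cohort generator
with planted ground truth so every stage of the method can be validated
without scan data.

## Method

Each scan's S seed time series (S = 236 in the packaged 13-network
template) are reduced to the Pearson correlation matrix **R** ∈
[−1, 1]^{S×S}; the C(S, 2) unique coefficients r_ij (i < j) form the
scan's FC vector — 27,730 features for S = 236. Across the cohort:

1. **Robust screen** — drop any feature where some participant's value
   lies more than 3 scaled MADs (MAD × 1.4826) from the feature median,
   in either stage;
2. **Selection** — Kolmogorov–Smirnov normality filter on the paired
   differences, then a two-sided paired t-test per feature; keep
   p < α (default 0.05);
3. **Transformation** — mean-centered PCA on the stacked selected
   features; keep the smallest k components whose cumulative explained
   variance exceeds 85%; standardize the component scores;
4. **Classification** — binary linear-kernel soft-margin SVM on the
   standardized scores, evaluated by leave-one-*participant*-out CV
   (both scans of the held-out subject predicted per fold, so twinned
   scans never straddle the split), with optional Bayesian optimization
   of the misclassification cost and kernel scale (GP + expected
   improvement, 30 evaluations);
5. **Attribution** — component loadings (optionally SVM-back-projected)
   score each selected connection; half of each connection's weight
   goes to each endpoint seed; connections are partitioned into
   strengthened/weakened (sign of the group-mean change) × motor/
   non-motor (endpoint in a somatomotor network).

Two CV protocols are exposed: `pooled` fits the feature chain
once on the full cohort (the common published protocol — optimistically
biased, since held-out data inform selection), and `nested` refits the
entire chain inside every training fold (the honest estimate). The
package measures the difference rather than hiding it: on effect-free
cohorts nested LOOCV sits at chance while the pooled fit reaches ~80%.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
synthetic cohort (20 participants × 2 stages, 231 time points, 30
seeds, 12 planted connectivity increases of +0.4, 0.2% injected extreme
FC values; seed 2018), writing tables under `results/`:

```sh
cd analysis
python 01_simulate_cohort.py
python 02_feature_selection.py
python 03_classification.py
python 04_attribution.py
```

`02_feature_selection.py` prints the staged feature counts:

```
                                 analysis_step  n_features feature_space
                             Original features         435         rs-FC
                         After outlier removal         269         rs-FC
                        After normality filter         269         rs-FC
                    After univariate filtering          22         rs-FC
            After principal component analysis          22       reduced
Chosen principal components for classification           6       reduced

outlier screen removed 38.2% of features (28 extreme values were injected)
selection recovered 8/8 planted connections that survived screening (22 selected in total)
```

435 = C(30, 2) is the full FC dimension; the robust screen removes
about a third of the features (mostly its own conservatism at n = 20 —
see `docs/methods.md` — plus the injected corruption), and every
planted connection that survives screening is found by the paired
t-test. `03_classification.py` then reports perfect separation on this
cohort under both protocols (accuracy 1.0, AUC 1.0 — the planted effect
is strong), and `04_attribution.py` prints the strengthened/weakened ×
motor/non-motor breakdown and the top-weighted seeds, and exports
BrainNet-style `.node`/`.edge` files.

The same chain is scriptable via the CLI (`fcstage simulate`, `fc`,
`select`, `classify`, `attribute`, `run`) or the library API:

```python
from fcstage import CohortConfig, cohort_fc, loocv_by_participant, toy_atlas

cfg = CohortConfig(n_participants=20, n_seeds=30, n_planted=12, effect_size=0.4)
x_pre, x_post, participants, truth = cohort_fc(cfg, toy_atlas(30))
report = loocv_by_participant(x_pre, x_post, participants, mode="nested")
print(report.accuracy, report.auc)
```

## Layout

```
src/fcstage/      library: atlas, synthetic, connectivity, features,
                  classify, attribution, workflow, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property, end-to-end)
scripts/          acceptance script; atlas regeneration
docs/methods.md   model, assumptions, defaults, numerical choices
```
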