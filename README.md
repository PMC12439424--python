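# sdmrisk

Ensemble species distribution modelling and IUCN Red List re-assessment
for narrow-range endemic plants — as a tested, reusable Python library.

Conservation assessments of range-restricted species increasingly combine
correlative habitat models with the IUCN Red List rules: occurrence records
and an environmental raster stack yield a habitat-suitability surface;
thresholding it gives a presence/absence range; projecting it onto future
climate stacks gives loss/gain/stable change maps; and the resulting range
geometry (EOO, AOO) feeds the categorical criteria (B, C2a(i), A3(c)).
`sdmrisk` implements that whole chain for users working in a planar,
equal-area km coordinate frame, and ships a synthetic-landscape module so
every stage runs — and is tested — without any external data.

## The method

* **Ensemble suitability.** Four learners — GLM (unpenalized logistic
  regression), random forest (RF), boosted regression trees (BRT) and a
  Platt-calibrated SVM — are fitted on replicated 70/30 train/test splits
  of presence and background points. The ensemble surface is the cellwise
  weighted mean of the per-model probability maps with weights
  wᵢ = max(TSSᵢ, 0) / Σⱼ max(TSSⱼ, 0), where TSS = sensitivity +
  specificity − 1.
* **MTSS binarization.** The presence/absence threshold is the observed
  score maximizing training sensitivity + specificity (maximum training
  sensitivity plus specificity); suitability classes are low < 0.3,
  moderate 0.3–0.5, high > 0.5.
* **Predictor screening.** Two-phase collinearity filter: pairs with
  |r| ≥ 0.75 are resolved by dropping the higher-VIF member, then
  variables are removed stepwise until every VIF = 1/(1 − R²) ≤ 5.
  Variable importance is permutation-based (1 − r between intact and
  permuted predictions), normalized to percentages.
* **Change accounting.** Binary maps are coded current + 2 × future
  (0 unsuitable, 1 loss, 2 gain, 3 stable); loss% is relative to the
  current suitable area and gain% to current + gain.
* **Red List rules.** EOO is the convex-hull area, AOO is 4 km² per
  occupied 2×2 km cell. Criterion B applies the standard thresholds
  (e.g. EN: EOO < 5,000 km² or AOO < 500 km² plus two of
  {few/fragmented locations, continuing decline, extreme fluctuation});
  C2a(i) covers small declining populations; A3(c) maps projected AOO
  loss under full/limited dispersal to categories (< 15% LC, 15–30 NT,
  30–50 VU, 50–80 EN, ≥ 80 CR).

## A worked example

```python
import sdmrisk as s
from sdmrisk.ensemble import summary_from_counts

# change accounting from a 5,045-cell study area: 198 currently suitable
# cells, of which 24 are lost and 182 gained under a warming scenario
summ = summary_from_counts(n_loss=24, n_gain=182, n_stable=174,
                           study_area_cells=5045)
print(summ.current_km2, summ.future_km2)       # 198.0 356.0
print(summ.rounded()["loss_pct"])              # 12.1
print(summ.rounded()["current_pct_of_area"])   # 3.9

# criterion B: a montane endemic with EOO 880.117 km2, AOO 144 km2,
# two locations, continuing decline
cat, crit = s.criterion_b(
    880.117, 144, 2,
    s.ConditionFlags(continuing_decline=("i", "iii", "iv", "v")))
print(cat, crit)   # EN B1ab(i,iii,iv,v)+2ab(i,iii,iv,v)
```

The species loses 12.1% of its current range (24/198), currently occupies
3.9% of the study area (198/5045), and is Endangered under both the EOO
(B1) and AOO (B2) sub-criteria with conditions a (≤ 5 locations) and b
(continuing decline in extent, habitat, locations and mature individuals).

The `examples/` directory has one short script per capability: landscape
simulation, collinearity filtering, fitting and evaluation, ensembling and
change accounting, and Red List assessment. An end-to-end run is one call:

```python
res = s.run_pipeline(s.RunConfig(seed=1), outdir="run1")
```

or, from a shell, `sdmrisk run --seed 1 --out run1` (also: `simulate`,
`thin`, `assess`).

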