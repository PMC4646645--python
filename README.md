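# riverscale

Species–habitat models for river fish built on *focal* habitat predictors:
hydromorphological variables averaged over the river network up- and
downstream of each sampling site, truncated at impassable barriers.  The
package answers three questions for dendritic river systems:

1. **At which spatial scale does habitat predict fish presence?**
   Habitat variables mapped on ~100 m channel segments are averaged over
   network neighbourhoods of 0, 200, 1000, 2500 and 4000 m (so a 2500 m
   distance class summarises a 5000 m reach), and presence models are
   compared across these distance classes.
2. **Do measured variables beat assessment scores?**  Models built from 35
   quantitatively measured variables are compared with models built from 13
   ordinal deviation-from-reference assessment scores.
3. **Which variable groups matter?**  Per-variable boosted-tree influences
   are pooled into six hydromorphological groups (TOPO, PROFILE, BED, BANK,
   LONG, FLOODPLAIN) with standardised selection frequencies and rank tests.

## Method core

* **Network model** — the river is a directed tree of reaches draining to
  one outlet.  Strahler and Shreve stream orders, distance from mouth, and
  50 m cell discretisation are computed on this graph; barriers are point
  features snapped to cell boundaries.
* **Focal scaling** — for site *s* and distance *d*, the neighbourhood is
  every cell within network distance *d* of the site's cell (entering
  tributaries, stopping at impassable barriers).  Continuous and count-rate
  variables are summarised by the mean, ordinal categories and scores by
  the median.
* **Presence models** — gradient-boosted regression trees (Bernoulli loss,
  tree complexity 3, learning rate ≤ 0.001 halved until ≥ 1000 trees) in a
  three-step frame: global fit, backward elimination by cross-validated
  deviance, final fit.  Quality is the fold-based cross-validated AUC from
  the Mann–Whitney statistic, AUC = U/(n₁·n₂).
* **Scale inference** — a linear mixed model
  `arcsin(√AUC) ~ α + β_D + β_TV + β_AV + a_Species`
  with a species random intercept, REML estimation and parametric-bootstrap
  percentile CIs, plus paired t-tests and a variance-ratio F test.
* **Synthetic data** — dendritic networks, Ornstein–Uhlenbeck habitat
  fields with exponential covariance in network distance, and virtual
  species whose occurrence depends on habitat at a known true scale, so the
  whole chain can be validated against ground truth.

## Worked example

```python
import riverscale as rs

# a synthetic study: ~300 km network, 64 sites, 5 virtual species that
# respond to habitat averaged 2500 m up- and downstream
means = rs.recover_scale(seed=1, distances=(0.0, 2500.0))
print(means)
```

prints

```
distance_m
0.0       0.635245
2500.0    0.772844
Name: cv_auc, dtype: float64
```

the mean cross-validated AUC across species when models see only
site-level habitat (0.64) versus habitat averaged over the species' true
2500 m scale (0.77): the models recover the scale at which the virtual
species actually perceive their habitat.

The published AUC table ships with the package; the mixed-model evaluation
runs on it directly:

```
$ riverscale reproduce-published --bootstrap 1000 --seed 7
parameter       estimate  95% CI
intercept          1.059  1.003 to 1.117
D200               0.006  -0.026 to 0.037
D1000              0.032  0.000 to 0.062
D2500              0.048  0.017 to 0.079
D4000              0.041  0.010 to 0.069
TV                 0.021  -0.000 to 0.040
AV                -0.000  -0.020 to 0.019
a_Species          0.090  0.052 to 0.122
```

Effects are on the arcsine-square-root scale relative to the baseline
(0 m distance class, measured variables, no topology): the 1000–4000 m
distance classes and the inclusion of topological variables significantly
improve model quality, with the largest gain at 2500 m.

The full pipeline is also scriptable from the shell:

```
riverscale simulate --seed 42 --out data/
riverscale focal --network data/edges.csv --barriers data/barriers.csv \
    --segments data/segments.csv --sites data/sites.csv --out focal.csv
riverscale fit --network data/edges.csv --segments data/segments.csv \
    --sites data/sites.csv --records data/records.csv --out run/
riverscale evaluate --auc run/auc_records.csv --out report/
```

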