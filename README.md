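# reefpulse

Coral-bleaching response and community analysis for photo-quadrat reef
surveys, built for reef monitoring programs in regions — like the central
equatorial Pacific — where ENSO-driven year-to-year temperature variability,
not the seasonal cycle, governs heat stress. The package scores bleaching
from benthic point counts, derives heat-stress and climate-variability
metrics from weekly sea-surface temperature (SST), quantifies local human
disturbance, and runs the downstream inference chain used to ask which of
these drivers explains bleaching intensity and community composition.

## What it computes

**Bleaching Response Index (BRI).** Scored coral points fall into seven
ordered severity categories c₁…c₇ (normal, pale, 0–20 %, 20–50 %, 50–80 %,
80–100 % bleached, recently dead), and

    BRI = (0·c₁ + 1·c₂ + 2·c₃ + 3·c₄ + 4·c₅ + 5·c₆ + 6·c₇) / 6  ∈ [0, 1].

**Thermal metrics.** From weekly SST: the maximum monthly mean climatology
(MMM); HotSpot = max(0, SST − MMM); Degree Heating Weeks DHW(t) = Σ of
HotSpots ≥ 1 °C over the trailing 12 weeks (°C-week); per-event maxima and
durations (MaxDHW, WkDHW4/8, Alert-Level-I weeks); and baseline-period
variability metrics (CV_SST, σ_wk, σ_mon, MaxSST_avg, MaxDHW_avg,
WkDHW4/8_avg, fDHW4/8 — the fraction of years whose annual maximum DHW
exceeds 4 or 8 °C-week).

**Disturbance.** A population metric: closest-village population divided by
along-coast distance, standardized to mean 1 across sites.

**Inference.** Shapiro-Wilk-gated Welch/permutation two-sample tests;
Bonferroni-screened univariate regressions of BRI on each predictor;
penalized additive models with cubic shrinkage splines (basis dimension 3),
GCV smoothing selection, AICc and analysis-of-deviance comparison; NMDS on
Bray-Curtis dissimilarities (Kruskal stress-1); sequential (Type-I) SS
PERMANOVA with permutation p-values; and a Monte Carlo analysis of how many
quadrat images are needed for stable cover estimates.

**Synthetic scenarios.** A first-class generator
(`reefpulse.simulate`) emits multi-site scenarios with ENSO-like AR(1)
interannual SST variability decaying away from the equator, planted
heat-stress events, an ordered-categorical bleaching model driven by heat
stress and light and damped by historical stress frequency, and
Dirichlet-multinomial coral communities whose weedy *Porites rus* share
grows with the population metric — so every stage is testable without field
data.

## Worked example

```python
from reefpulse.simulate import gilberts_like, simulate_site_set
from reefpulse import bri
from reefpulse.gam import fit_response_model
from reefpulse.community import bray_curtis, nmds, permanova
from reefpulse.survey import live_coral_taxon_counts, build_community_matrix

world = simulate_site_set(gilberts_like(seed=1))
table = world["site_table"].join(
    bri.bri_table(world["survey"], by_taxon=False).set_index("site_id")["bri"])

fit = fit_response_model(table, "bri", smooth=["PAR", "fDHW4"])
print(fit.deviance_explained, fit.aicc)     # 0.936  -40.9

counts = live_coral_taxon_counts(world["survey"], by_depth=False)
mat = build_community_matrix(counts)        # >0.5 % rare-taxon filter
d = bray_curtis(mat)
print(nmds(d, seed=1).stress)               # 0.064
print(permanova(d, table.loc[d.index,
      ["pop_metric", "fDHW4", "CV_SST", "chl_a"]], n_perm=999, seed=1))
```

The PERMANOVA table prints:

```
            Df  SumsOfSqs  MeanSqs  F.model      r2      p
pop_metric   1     1.4274   1.4274  14.9097  0.4492  0.001
fDHW4        1     0.5230   0.5230   5.4634  0.1646  0.004
CV_SST       1     0.1589   0.1589   1.6595  0.0500  0.204
chl_a        1     0.2067   0.2067   2.1587  0.0650  0.124
Residuals    9     0.8616   0.0957      NaN  0.2712    NaN
Total       13     3.1775      NaN      NaN  1.0000    NaN
```

Reading this: a two-smooth additive model of BRI on boreal-winter light
(PAR, positive effect) and past heat-stress frequency (fDHW4, negative
effect) explains 93.6 % of the deviance — heat stress during the event
itself is a poor predictor when sites differ in climate history.  The
community ordination embeds 14 sites at stress 0.064, and the sequential
PERMANOVA attributes the largest share of community variation (r² = 0.45,
p = 0.001) to the human-population metric, reflecting the planted spread of
*Porites rus* at disturbed sites.

## Command line

```sh
reefpulse simulate --out data/ --seed 1          # emit a synthetic scenario
reefpulse run-all --config config.yaml --out run/ --seed 1
reefpulse cover|bri|climate|screen|nmds|permanova|sufficiency ...
```

`run-all` executes ingest → cover/BRI → thermal metrics → site table →
univariate screen → model comparison → NMDS → PERMANOVA → sufficiency and
writes each stage's table plus a `manifest.yaml` recording the config
snapshot, input digests, seed, and every default the config did not
override.

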