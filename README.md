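# nitroclim

Statistical machinery for asking how climate variability and climate change
move **riverine nitrogen loading** — the annual mass of nitrogen a catchment
exports to its rivers. Excess nitrogen drives eutrophication, algal blooms
and coastal hypoxia, so water-quality managers need to know whether wetter
and warmer futures will raise or lower nitrogen fluxes, and by how much.
`nitroclim` is aimed at environmental biogeochemists and water-quality
modelers who want a tested, fully synthetic-data-driven implementation of
the whole inference chain, from catchment-year records to ensemble
projections with uncertainty.

## The model

Annual total-nitrogen load Q<sub>TN</sub> (kg N yr⁻¹) is modeled as
conditionally lognormal with an additive structure on the log scale — a
Gaussian generalized additive model (GAM):

```
ln Q_TN = β₀ + f(P_annual) + β_E · P_MAM,p>0.95 + β_T · T_annual
        + e_s · ln(N_surplus) + e_l · ln(N_surplus,−1&−2)
        + Σ landuse slopes (LU_D, LU_C, LU_F,SH, L_TD) + ε,   ε ~ N(0, σ²)
```

* `f(·)` is a penalized cubic B-spline smooth (second-order divided-difference
  penalty, GCV-selected smoothing, sum-to-zero constrained); the
  precipitation response saturates above ~1,500 mm yr⁻¹.
* `P_MAM,p>0.95` is springtime (March–May) precipitation falling on days
  exceeding the 1981–2010 95th wet-day percentile.
* `N_surplus = N_dep + N_fert + N_fix + N_man + N_hum − N_crop`
  (kg N ha⁻¹ yr⁻¹), with a two-year lagged term for short-term legacy
  nitrogen.
* `exp(linear predictor)` is the **median** load prediction.

Around this core the package provides:

| stage | module |
|---|---|
| synthetic catchments, weather, surplus, loads, biased GCM-like ensembles | `nitroclim.synth` |
| penalized-spline GAM with EDF and BIC (`LoadGAM`) | `nitroclim.gam` |
| constrained exhaustive BIC covariate selection, ΔBIC > 2 rule (`BICSearch`) | `nitroclim.select` |
| local-slope sensitivities (% per mm, % per °C) | `nitroclim.sensitivity` |
| scaled distribution mapping bias correction (`ScaledDistributionMapper`) | `nitroclim.sdm` |
| covariate derivation, P/T effect decomposition, ensemble agreement & tradeoff classes | `nitroclim.project` |
| equivalent denitrification Q₁₀ from the temperature response | `nitroclim.q10` |
| lognormal Monte-Carlo propagation of residual uncertainty | `nitroclim.mc` |

Everything runs on synthetic data with known ground truth; no external
hydrologic or climate datasets are required.

## Worked example

```python
from nitroclim import (GeneratorConfig, make_training_table,
                       fit_loading_model, TermSpec, average_sensitivity)

table, specs = make_training_table(GeneratorConfig(), seed=42)
terms = [TermSpec("P_annual", "smooth", 10)] + [
    TermSpec(c, "linear")
    for c in ("P_MAM_p95", "T_annual", "ln_Nsurplus", "ln_Nsurplus_lag12",
              "LU_D", "LU_C", "LU_FSH", "L_TD")]
model = fit_loading_model(table, terms)
print(f"n = {model.n_}, EDF = {model.edf_:.1f}, sigma^2 = {model.sigma2_:.3f}")
for cov in ("P_annual", "P_MAM_p95", "T_annual"):
    s = average_sensitivity(model, cov, table)
    print(f"{cov:12s} {s.average:+.3f} %/unit  (range {s.low:+.3f} to {s.high:+.3f})")
```

prints

```
n = 9030, EDF = 17.6, sigma^2 = 0.254
P_annual     +0.170 %/unit  (range +0.019 to +0.305)
P_MAM_p95    +0.109 %/unit  (range +0.109 to +0.109)
T_annual     -6.382 %/unit  (range -6.382 to -6.382)
```

i.e. on this synthetic population, loading rises by ~0.17% per mm of annual
precipitation (with a wide range because the response saturates at high
precipitation), by ~0.11% per mm of springtime extreme precipitation, and
falls by ~6.4% per degree of warming — recovering the generator's calibrated
ground truth (0.17, 0.12, −6.4). Converting the fitted temperature response
into an equivalent denitrification Q₁₀ (`nitroclim.q10.weighted_q10`) on the
same fit gives `Q10 = 1.21 (1.09 at 19 °C to 1.41 at 3 °C)`: the watershed-
scale temperature effect is far weaker than bench-scale denitrification
experiments (Q₁₀ ≈ 2–4), because only part of the excess nitrogen is lost
through denitrification.

The same stages are exposed as a CLI:

```sh
nitroclim simulate --out table.csv
nitroclim fit --table table.csv --out model.json
nitroclim sensitivity --model model.json --table table.csv --out sens.csv
nitroclim select | biascorrect | project | q10 ...   # see --help
```

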