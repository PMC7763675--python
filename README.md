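# relkin

Release-kinetics modelling for nanoparticle drug carriers.

`relkin` is a small scientific Python package for analysing cumulative
drug-release curves R(t) (percent of total load vs time in days) from
spherical nanocarriers — the setting of MOF-based delivery systems such
as paclitaxel adsorbed on Fe-BTC and encapsulated in mPEG-PCL
nanoparticles.  It provides:

- **Forward models** — the exact sphere-diffusion series solution
  R(t) = 100·(1 − (6/π²) Σ exp(−D i²π² t/r²)/i²), its single-term
  approximation R = 100·(1 − A e^(−kt)), and the bimodal two-population
  model R = 100·[φ(1 − e^(−K1 t)) + (1 − φ)(1 − e^(−K2 t))].
- **Fitting and model comparison** — bounded multi-start least squares
  scored by the RMS deviation S = sqrt(Σ(R_model − R_exp)²/N) over the
  non-trivial (R < 99 %) points.
- **Rate ↔ diffusivity conversion** — the linear-driving-force relation
  K = 15 D/r² for a sphere (K in d⁻¹, D in m²/s).
- **Formulation arithmetic** — Solomon–Ciuta intrinsic viscosity,
  Mark–Houwink–Sakurada molecular weight, weight loss, nanoparticle
  yield, drug loading, entrapment efficiency.
- **Pore-passage screening** — tiered geometric classification of a
  triaxial-ellipsoid guest against MOF pore windows and cage cavities.
- **Synthetic data** — seeded generators for study-like release curves,
  since such studies typically publish their curves only as figures.

See `docs/methods.md` for the models, assumptions and numerical
choices.

## Worked example

Fit all three models to a simulated 15-day release curve of the
MOF-in-polymer composite formulation and convert the fitted rate
constants to diffusivities:

```python
import dataclasses
from relkin import compare_models, paper_like_scenarios, simulate_release

spec = {s.name: s for s in paper_like_scenarios()}["mPEG-PCL-Fe-BTC-PTX"]
curve = simulate_release(spec)          # seeded: bit-reproducible
cmp = compare_models(curve, spec.carrier)
for model_id in cmp.ranking:
    print(model_id, round(cmp.results[model_id].s_value, 2))
print(cmp.results["bimodal"].params)
print(cmp.diffusivities["bimodal"])
```

prints

```
bimodal 1.6
series 1.83
single_term 4.31
BimodalParams(phi=0.2965065877689058, k1=1.5550891154451354, k2=0.12031201341890052)
{'D_fast': 6.134262600643822e-21, 'D_slow': 4.745872612660294e-22}
```

The bimodal model wins (S = 1.6 release-%, about the injected noise
level), recovering the generating parameters (φ = 0.29, K1 = 1.74 d⁻¹,
K2 = 0.123 d⁻¹) to within the noise-limited precision; the fitted rate
constants correspond to fast/slow diffusivities of ~6e-21 and
~4.7e-22 m²/s for the 71.5 nm particle radius.  The same workflow from
the shell:

```
relkin simulate --scenario mPEG-PCL-Fe-BTC-PTX --out curve.csv
relkin fit curve.csv --radius-nm 71.5 --out report.json
relkin convert --rate 1.74 --radius-nm 71.5
relkin geometry            # paclitaxel vs the built-in Fe-BTC cage table
```

## Analysis pipeline

The `analysis/` directory holds the end-to-end study reproduction as
numbered drivers, each writing its tables under `results/`:

1. `01_simulate_release_curves.py` — the three formulation scenarios
   as CSV curves (noisy + noiseless).
2. `02_fit_release_models.py` — per-curve model comparison and fit
   reports; the deviation statistic ranks bimodal < series <
   single-term on the desorption-like curve.
3. `03_diffusivity_conversions.py` — published rate constants → the
   four diffusivities, and the fast (+87 %) / slow (+230 %) increases
   caused by routing the drug through the MOF.
4. `04_formulation_metrics.py` — Mark–Houwink molecular weight
   (43,876 g/mol from [η] = 0.68 dL/g) and formulation percentages.
5. `05_pore_passage_screen.py` — paclitaxel vs the Fe-BTC windows
   (oriented passage at 10.8 Å, marginal blockage at 7.3 Å) and
   cavities.

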