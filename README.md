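# biokin

One-compartment biokinetic modelling of nanomaterial uptake and
bioaccumulation in soil and aquatic invertebrates: closed-form models,
genetic-algorithm nonlinear regression, and AICc / Akaike-weight model
selection.

## The problem

Ecotoxicologists quantify how organisms such as *Daphnia magna* or
earthworms accumulate engineered nanomaterials (Ag, Au, TiO2, SiO2,
graphene, C60, ...) by fitting body-burden time series from two-phase
exposure experiments: an **uptake** phase in contaminated medium until time
`t_e`, then **elimination** (depuration) in clean medium. Two nested
first-order models dominate the field:

- **OC** — a single well-mixed compartment with uptake rate constant `k1`
  (L or kg medium per kg organism per time) and elimination rate constant
  `k2` (per time):

  `C(t) = C0 + Cexp (k1/k2) (1 - e^{-k2 t})` during uptake, and
  `C(t) = C0 + Cexp (k1/k2) (e^{-k2 (t - t_e)} - e^{-k2 t})` afterwards.

- **OC-SF** — the same, plus a dimensionless **stored fraction**
  `SF ∈ [0, 1]` of the influx that is sequestered in tissue, accrues
  linearly during uptake (`SF·Cexp·k1·t`) and is never eliminated.

Estimating `(k1, k2)` or `(k1, k2, SF)` from sparse noisy data is a
nonlinear least-squares problem with a ridge-shaped, sometimes multi-modal
RSS surface. `biokin` solves it with a bounded, seeded, real-coded genetic
algorithm (population 1000, steady-fitness stop after 300 unimproved
generations, `k2` searched over [0.001, 100]), then ranks the candidate
models by small-sample Akaike weights
`w_i = exp(-Δ_i/2) / Σ exp(-Δ_k/2)` computed from
`AICc = 2p - 2 ln L + 2p(p+1)/(n-p-1)`, alongside adjusted
`R² = 1 - (n-1)/(n-p)(1 - R²)`.

The package ships a registry of 22 published organism/nanomaterial fits for
instant simulation, a synthetic-data generator for recovery studies, a
scikit-learn-compatible estimator (`KineticRegressor`), and a CLI.

## Worked example

Recover known kinetics from a simulated silver-nanoparticle experiment
(48 h uptake, 48 h depuration, 5% proportional measurement noise):

```python
from biokin import (ExposureScenario, KineticParameters, NoiseSpec,
                    FitConfig, generate_dataset, fit_model, compare_models)

scenario = ExposureScenario(c_exposure=1.0, t_e=48.0, t_total=96.0)
truth = KineticParameters(k1=0.196, k2=0.033)
data = generate_dataset("oc", truth, scenario,
                        noise=NoiseSpec(kind="proportional", sigma=0.05, seed=7))

oc = fit_model(data, "oc", scenario, FitConfig(seed=1))
ocsf = fit_model(data, "ocsf", scenario, FitConfig(seed=1))
print(f"OC:    k1={oc.params.k1:.4f}  k2={oc.params.k2:.4f}  rss={oc.rss:.4f}")
print(f"OC-SF: k1={ocsf.params.k1:.4f}  k2={ocsf.params.k2:.4f}  "
      f"sf={ocsf.params.sf:.4f}  rss={ocsf.rss:.4f}")
cmp = compare_models(data, [oc, ocsf])
for label, w in zip(cmp.labels, cmp.weights):
    print(f"Akaike weight {label}: {w:.3f}")
```

prints

```
OC:    k1=0.1954  k2=0.0332  rss=0.2216
OC-SF: k1=0.1954  k2=0.0332  sf=0.0000  rss=0.2216
Akaike weight oc: 0.802
Akaike weight ocsf: 0.198
```

The fitted `(k1, k2) = (0.1954, 0.0332)` sit within ~1% of the generating
values, the stored fraction of the three-parameter fit collapses to ~0 on
data generated without storage, and the Akaike weights correctly favour the
two-parameter model (the extra parameter buys no RSS, so the AICc penalty
decides).

The same workflow from the shell:

```
biokin fit --data obs.csv --model both --c-exposure 1.0 \
       --t-exposure 48 --t-total 96 --seed 1 --out results/
biokin simulate --scenario dmagna-graphene-aqueous-oc \
       --t-exposure 24 --t-total 48 --dt 1 --out curve.csv
biokin scenarios list
```

`fit` writes a self-contained JSON report (parameters, residuals, R²,
adjusted R², AICc, Akaike weights, seed echo) plus per-model predicted-curve
CSVs and a plot-data CSV.

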