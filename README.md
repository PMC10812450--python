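# strawpoly

Modeling how biotic and abiotic harvest factors shape the polyphenol
content of sugarcane (*Saccharum officinarum*) straw.

Sugarcane straw is a harvest by-product rich in polyphenols —
hydroxybenzoic acids, hydroxycinnamic acids and flavones — whose
concentrations vary strongly with how and when the straw was harvested.
`strawpoly` is for chemometricians and agronomic data scientists who want
to link five harvest factors (collection date, variety, geographic area,
borer-infestation level, ratoon/harvest number) to polyphenol-class
content and antioxidant capacity (ABTS/DPPH IC50), and to find harvest
conditions that maximize extract quality.

## What it computes

**Response-surface regression.** Raw factors are affinely coded onto
[−1, +1] and each response *Y* is fit by ordinary least squares to a
fixed 20-term second-order polynomial

    Y = β₀ + Σᵢ βᵢXᵢ + Σᵢ βᵢᵢXᵢ² + Σᵢ<ⱼ βᵢⱼXᵢXⱼ

with the area quadratic X₃² excluded (a two-level factor's square is
constant). Coefficients carry t-test p-values annotated with the usual
`*`/`**`/`***` thresholds (p ≤ 0.05 / 0.01 / 0.001).

**Derringer desirability.** Each predicted response maps onto [0, 1]
via the one-sided ramp dᵢ = ((y − y_min)/(y_max − y_min))^wᵢ (mirrored
for minimize goals such as IC50); the composite score
D = (Π dᵢ^wᵢ)^(1/Σwᵢ) is maximized by exhaustive search over a grid of
realizable harvest conditions.

**Neural-network regression.** A from-scratch single-hidden-layer
perceptron ("MLP 20-5-5": 20 one-hot/scaled inputs, 3–5 hidden neurons,
5 outputs) trained by BFGS on the sum-of-squares error, with a seeded
70/15/15 train/validation/test split, an automated 20-candidate search
retaining the top 5 by validation Pearson r, and Garson
connection-weight partitioning for factor importance:

    RI_x = Σ_b (|W_xb| / Σ_a |W_ab|)·|V_b|  /  Σ_x Σ_b (·)

**Model comparison.** Shared R²/RMSE definitions produce a
response-by-model report contrasting the polynomial with each retained
network, with pooled and test-partition metrics side by side.

A synthetic-data module generates the 2-area × 7-date × 2-infection
sampling design with known polynomial coefficients plus Gaussian noise
(and an optional non-polynomial distortion), so every stage is testable
against ground truth.

## Worked example

The study tables ship with the package. Aggregating compounds into class
responses and seeding a model from the published coefficients:

```python
import numpy as np
from strawpoly import datamodel as dm, rsm

class_map = dm.load_class_map()
meas = []
for name in ("table2_guariba.csv", "table3_valparaiso.csv"):
    meas += dm.load_compound_table(dm.fixture_path(name), class_map)
conditions, ic50 = dm.load_conditions()
table = dm.aggregate_classes(meas, class_map, ic50=ic50)

print(table.loc["G05", ["hydroxybenzoic", "hydroxycinnamic", "flavones"]])
# hydroxybenzoic      386.6
# hydroxycinnamic     969.6
# flavones            483.5      (µg/g dry extract)

hb = rsm.model_from_coefficients("hydroxybenzoic")
print(rsm.predict(hb, np.zeros(5))[0])   # 157.15 — intercept at the coded origin
```

The mid-July Guariba batch (G05) is one of the richest in
hydroxycinnamic acids; the coded origin of the published
hydroxybenzoic model predicts 157.15 µg/g, the model's intercept.

Longer narratives live in `examples/` (one script per capability:
ingestion, polynomial fit + desirability optimum, network search +
sensitivity, model comparison, full pipeline). A thin CLI mirrors them:

```bash
strawpoly run-all --seed 1 --out-dir run1
strawpoly compare --seed 1 --out-dir run2
```

Reruns with the same seed reproduce every artifact hash in
`manifest.json` byte for byte.

## Layout

- `src/strawpoly/datamodel.py` — schema, fixture readers, class aggregation
- `src/strawpoly/rsm.py` — factor coding, 20-term OLS fit, prediction, surfaces
- `src/strawpoly/desirability.py` — Derringer transform, composite score, grid optimum
- `src/strawpoly/ann.py` — perceptron + BFGS, split, search, Garson sensitivity
- `src/strawpoly/compare.py` — shared metrics, comparison report
- `src/strawpoly/synthetic.py` — synthetic designs and response surfaces
- `src/strawpoly/pipeline.py`, `cli.py` — orchestration and shell front end
- `src/strawpoly/fixtures/` — transcribed study tables (CSV)
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
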