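# entolca

Life-cycle and nutritional assessment of edible-insect food systems:
attributional and consequential LCA of yellow-mealworm (*Tenebrio
molitor*) larvae production and a mealworm-based lasagna, with
qNRF1.10.2 nutrient-profiling functional units and Monte Carlo
uncertainty propagation.

It is written for practitioners of food-system LCA who want the full
modeling chain — multifunctionality allocation, system expansion with
displacement credits, nutritionally adjusted functional units — as
tested, scriptable code rather than spreadsheet formulas inside
proprietary LCA software.

## What it computes

**Foreground systems.** The package ships two foreground inventories:
a mealworm farm normalised to 1 kg of larvae ready for human
consumption (feed production, rearing, killing/blanching, cleaning,
facilities maintenance, waste management, and the drying of surplus
manure and undeveloped worms), and a lasagna meal whose 1.12 kg of
mince is produced by the farm system. Foreground systems are acyclic
process graphs evaluated by topological traversal; a square
technology-matrix solver exists as an independent cross-check.

**Multifunctionality.** Per kilogram of larvae the farm also yields
2.50 kg of frass (sold as organic fertilizer) and 3.18·10⁻² kg of
dried mealworm residue (sold as bird feed). The burdens shared up to
the end of rearing are partitioned by

- economic value (scenario `TM_AE`): fₖ = mₖpₖ / Σ mⱼpⱼ,
- mass (`TM_AM`): fₖ = mₖ / Σ mⱼ,
- or not at all (`TM_AW`, everything to the larvae),

while killing/blanching stays with the larvae and drying with the
coproducts. The consequential scenario (`TM_C`) instead evaluates the
system against marginal background intensities and credits the
coproducts with the burdens of the products they displace (frass →
commercial organic fertilizer on an organic-matter basis, residue →
bird feed on a protein basis): net = gross − Σ amount × ratio ×
intensity(displaced).

**Nutrition.** The qNRF1.10.2 score per 100 g of food is

qNRF = 100·[ min(cap, protein·DIAAS/DRIₚ) + Σᵢ min(cap, nutrientᵢ/DRIᵢ) − Σⱼ Lⱼ/MRIⱼ ]

over ten encouraged nutrients and two discouraged ones (saturated fat,
sodium). Scores drive iso-nutritional substitution (amount_alt =
amount_ref × score_ref/score_alt) and the nutritional functional unit
(impacts per 1000 score units = per-kg impacts × 1000/(10·score)).

**Background data.** Real background databases are proprietary, so a
synthetic intensity table is generated (seeded) and then *calibrated*:
the foreground is linear in the intensities and every background
product is used by a single stage, so matching published scenario
totals and stage shares reduces to a closed-form scaling per
(stage, category) cell. The calibrated table is a fixture — it makes
the shipped systems reproduce the published results and claims nothing
about any real database.

**Uncertainty.** Monte Carlo propagation perturbs every background
intensity with a median-preserving lognormal factor (default geometric
standard deviation 1.2, 1000 iterations, 95 % empirical interval),
re-running the full scenario pipeline per iteration with one
deterministic substream per parameter.

## Worked example

```python
from entolca import (SCENARIOS, allocate, calibrated_tables,
                     nutritional_fu_convert)

fx = calibrated_tables(seed=0)           # fixtures + calibrated background
res = allocate(fx.farm, SCENARIOS["TM_AE"], fx.average, fx.cfs)

print(res.fractions)
# {'yellow mealworm larvae': 0.7815, 'mealworm frass': 0.2157,
#  'dried mealworm residue': 0.0027}
print(res.main.as_dict())
# {'GWP': 1.45, 'FEP': 0.000267, 'MEP': 0.0191,
#  'LU': 164.0, 'WU': 51.8, 'ADPfossil': 18.4}

per_fu = nutritional_fu_convert(res.main, 117.0)
print(round(per_fu["GWP"], 3), round(per_fu["ADPfossil"], 1))
# 1.239 15.7
```

Reading: under economic allocation 78.15 % of the shared farm burdens
fall on the larvae, giving a carbon footprint of 1.45 kg CO₂ eq and a
fossil-resource use of 18.4 MJ per kg; per 1000 qNRF score units
(score 117 per 100 g) those become 1.24 kg CO₂ eq and 15.7 MJ.

The same evaluations are available from the shell:

```
entolca run --scenario TM_AE --system farm
entolca qnrf substitute --ref beef --alt mealworm
entolca mc --iterations 1000 --seed 1
entolca suite --out bundle.json
```

## Layout

- `entolca.core` — impact categories/vectors, products, process graphs,
  scenarios, validation
- `entolca.tables` — background-intensity and characterization tables
- `entolca.engine` — scaling, characterization, stage contributions,
  matrix oracle
- `entolca.allocation` / `entolca.consequential` — the two
  multifunctionality treatments
- `entolca.nutrition` — qNRF scoring, substitution, nutritional FUs
- `entolca.uncertainty` — Monte Carlo propagation
- `entolca.synthetic` — background generation and calibration, nutrient
  profile synthesis
- `entolca.io` / `entolca.reporting` / `entolca.cli` — fixtures,
  serialization, scenario suite, command line

See `docs/methods.md` for modeling assumptions, parameter choices and
known limitations.
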