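# Methods

This note documents the models implemented in `entolca`, the choices
made where the design was genuinely open, and what the synthetic data
can and cannot support.

## Foreground model

A product system is a directed acyclic graph of unit processes, each
normalised to one unit of its primary output. Stage processes of the
farm (feed production, cleaning, facilities maintenance, waste
management) are modeled as unit "services" consumed by the rearing
process; drying is attached to the larvae chain so that the coproducts
(frass, dried residue) ride along with larvae demand. Evaluation is a
linear topological traversal: the reference process is scaled to the
functional unit, scaling propagates to suppliers, and each scaled
background input (emission) is multiplied by its per-unit intensity
(characterization factor). `matrix_solve_oracle` re-derives totals via
the classical square technology matrix A·s = f and exists only as an
independent cross-check; both paths agree to 1e-9 relative tolerance
on randomized systems.

Transport is a background product in km·kg (mass × distance summed
over routes), because the inventory reports distances and masses but
no tonne-kilometre figure. Discarded feed residues are split over four
waste destinations with fixed national shares (recycled 5.67 %,
composted 22.90 %, landfilled 58.15 %, incinerated 13.28 %), each a
background product. Prices are stored in EUR/kg. The characterization
table shipped with the fixtures covers the three rearing emissions
only (N₂O at GWP-100 = 273, CO₂ = 1, NH₃ into marine eutrophication
via its nitrogen content); it is a stand-in, not a regulatory method.

## Multifunctionality

Shared boundary: feed production, rearing, cleaning, facilities
maintenance and waste management are shared among the three sellable
products "until the end of rearing". Killing/blanching is
larvae-specific; drying is coproduct-specific, divided between frass
and residue by dried mass. Allocation fractions are computed at full
precision from masses (1 / 2.50 / 0.0318 kg) and prices (221.0 / 24.4
/ 24.4 EUR/kg); printed four-significant-figure fractions are display
rounding, not inputs. For the meal system the same larvae/frass/residue
split applies to the farm sub-branch, with the meal stages
(ingredients, cooking) following the main chain.

Under no allocation (`TM_AW`) the larvae carry shared plus all
specific burdens, drying included; this makes `TM_AW` coincide with
the gross system total.

## Consequential model

The expansion scenario evaluates the foreground against a *marginal*
intensity table (the suppliers who respond to a demand change differ
from the average mix) and subtracts displacement credits:

- frass → commercial organic fertilizer (NPK 3/2/3, 52.7 % organic
  matter) at ratio 0.80/0.527 ≈ 1.518 kg displaced per kg frass;
- dried residue → bird feed on protein content. "Protein-adjusted"
  displacement is read as protein-content equivalency (DIAAS-unadjusted);
  the basis function is pluggable, so the digestibility-adjusted
  reading is one configuration change. The residue credit is
  negligible either way (< 1 % of gross in every category).

The published phrase that the fertilizer credit "reduces impacts
100 %" in GWP cannot hold together with the positive published net
carbon footprint (1.49 kg CO₂ eq); the fixture therefore fixes the GWP
credit at 50 % of the marginal gross and reads the phrase as "frass
fully displaces the commercial-fertilizer demand". The fossil-resource
credit share is honoured exactly at its published 40.8 %; the
remaining categories carry a 2 % share (organic-fertilizer manufacture
is energy-intensive but land-, water- and nutrient-light).

## Synthetic background and calibration

`generate_background` draws positive uniform intensities per category
within order-of-magnitude ranges typical of food and energy products,
seeded and reproducible, with a paired marginal table differing by a
configurable perturbation.

`calibrate_to_targets` then rescales intensities so the fixtures
reproduce the published results. Per impact category the published
gross (`TM_AW`), economic (`TM_AE`) and — where published — mass
(`TM_AM`) totals identify the shared pool S, the larvae-specific
burden K and the drying burden D from

    TM_AE = f_e·S + K,  TM_AM = f_m·S + K,  TM_AW = S + K + D.

For land and water use, where no mass-allocation total was published,
the category is treated as having no product-specific burden (S =
TM_AW, K = D = 0); the published economic totals agree with this
reading to 0.1 %. The pool is spread across stages using the published
stage-group shares, remainders split equally over stages without a
published share; direct-emission contributions are subtracted before
scaling the background part of a stage. Each background product is
used by exactly one stage, so each (stage, category) cell has one
closed-form scaling factor. Calibration is verified by re-evaluation
in the test suite (0.5 % tolerance), and any relaxed cell is reported
in the bundle's notes list.

Two published meal figures are internally inconsistent with the rest
of the study (the per-kg marine/freshwater eutrophication of the meal
implies a mealworm share far from the published one); the calibration
reconstructs those whole-meal totals from the published mealworm
shares (46.28 % MEP, 24.6 % FEP) instead.

The calibrated tables reproduce study conditions; they do not carry
database-level realism. Passing tests show the *methods* (allocation
arithmetic, expansion accounting, score algebra, uncertainty
machinery) are correct under the study's printed conditions — they say
nothing about real Ecoinvent/Agribalyse magnitudes, regionalized water
scarcity, or inventory completeness.

## Nutrition

qNRF1.10.2 is computed on a percent-of-daily-value basis with
encouraged terms capped at 100 % by default (configurable, including
uncapped); discouraged terms are never capped. The percent basis with
capping is required for published score magnitudes (117–299) to be
attainable, consistent with the NRF family this model extends. DIAAS
is stored as a fraction; a missing DIAAS enters at 1.0 and flags the
result. The shipped reference-intake table is an EFSA-style adult
placeholder and is user-replaceable; all checks against published
scores use those scores as inputs, never the placeholder table.

The published record carries an ambiguity: 117 is used as the mealworm
*ingredient* score in its concluding comparison while 62.9 appears
both as "mealworm" and as the mealworm *lasagna* score. This package
treats 117 as the ingredient score and 62.9 as the meal score; the
conflict is surfaced here rather than resolved. Meal scores are
mass-weighted per-100 g blends scored once after mixing (capping is
concave, so a blend scores at least the weighted average of individual
capped scores). The meal-basis factor behind per-meal functional units
defaults to 10 × the per-100 g score.

Synthetic nutrient profiles are solved by scaling a realistic template
composition with Brent's method until the capped score hits the
published target within 0.1; templates are order-of-magnitude
realistic but synthetic.

## Uncertainty

Default: lognormal multiplicative noise on every background intensity
(median 1, geometric standard deviation 1.2), foreground amounts
unperturbed — conventional in LCA practice, and everything is
overridable. 1000 iterations and a 95 % empirical interval (linear
interpolation of order statistics) are the defaults. Each (product,
category) parameter draws from a substream seeded by the master seed
and a stable hash of its name, so adding a parameter never reshuffles
the others; results are bit-reproducible given a seed. The empirical
2.5/97.5 % quantiles of a one-parameter linear system match the
lognormal closed form within 1 % at 50 000 draws in the test suite.

## Problem sizes and defaults

- Farm system: 7 processes, 23 background products; meal adds 2
  processes and 18 products. All evaluations are closed-form linear
  algebra; the full scenario suite runs in seconds.
- Randomized property tests use systems of up to 20 processes,
  200 replicates for the traversal-vs-matrix equivalence.
- Monte Carlo defaults: 1000 iterations (50 000 in the closed-form
  quantile check), GSD 1.2, CI 0.95.

## Known limitations

- Background realism is calibrated, not measured; absolute
  consequential values are only reproducible via the calibrated
  fixture round-trip.
- Water scarcity is an opaque category (no regionalized AWARE
  modeling), mirroring its exclusion from the study's food
  comparisons.
- No indirect land-use-change modeling, no constrained-market or
  price-elasticity logic in the consequential model.
- The wheat-milling upstream split (89.37 % flour / 10.63 % bran) is
  exposed as documentation of what the "wheat bran" intensity
  represents; milling yields are back-solved from the published
  fractions because they were not reported.
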