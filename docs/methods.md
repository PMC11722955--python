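# Methods

## Model and assumptions

`dietshift` is a static accounting model, not a production or behavioural
model. For each animal-source food it converts annual per-capita
consumption *C* (kg) and protein content *P* (g/100 g) into protein units
*U* = *C*·*P*/10 (100-g blocks of protein per person-year), then prices
those units in land: *U*·*LU*<sub>animal</sub> m² before substitution, and
*U*·*R*·Σ*w*ᵢ·*LU*<sub>vegetal,i</sub> m² for the plant mix that replaces
the fraction *R* of the protein. The reported per-food "final" figure is
initial minus replaced, and the headline per-capita saving equals the
replaced-land total — this is the convention of the scenario tables the
fixture reproduces, and the package keeps it so that its outputs are
directly comparable with them. The *net* land balance of a substitution
(animal land freed minus plant land claimed,
*R*·*LU*<sub>initial</sub> − *LU*<sub>replaced</sub>) is a different
quantity: it is zero for a food whose animal intensity equals the mix's
weighted intensity, and negative when the mix is more land-intensive than
the animal source. The engine flags the negative case with a warning
record on the result and never clips values.

Assumptions worth stating explicitly:

- Protein is the only equivalence dimension. Calories, amino-acid
  profiles, micronutrients and prices are out of scope.
- Substitution is linear in the rate and food categories are independent;
  there is no demand elasticity or cross-substitution.
- Each basket row is an aggregate (milk includes dairy equivalents, meat
  categories include processed equivalents); no disaggregation is
  attempted. Fish/seafood and eggs are treated by the same equations as
  meat.
- Land intensities are national averages; yield variation, land quality
  and reuse of freed land (e.g. reforestation) are not modelled.

## Parameters and defaults

| parameter | units | default | note |
|---|---|---|---|
| replacement rate *R* | fraction | sweep 0.33, 0.5, 1.0 | "33%" is exactly 0.33, not 1/3 (the fixture tables' replaced-protein column confirms this) |
| mix weights *w*ᵢ | fraction, Σ=1 | soy 0.5, peas 0.3, potatoes 0.2 | validated to 1e-9; file readers renormalize only deviations ≤ 1e-6 |
| plant intensities | m²/100 g protein | soy 2.2, peas 3.36, potatoes 5.18 | see calibration below; corn 3.09 and wheat/rye 3.16 are documented alternatives and any source can be configured |
| population | persons | 14,940,830 | the 2021 adult resident population; consumption figures are national per-capita, so the population is an explicit parameter rather than hard-wired |

### Calibrating a missing plant intensity

The fixture's aggregate mix intensity (3.144 m²/100 g protein) is pinned
by the scenario tables themselves (replaced land ÷ replaced protein units
in any row), but only the potato intensity (5.18) is stated per source.
The package fixes soy at 2.2 — a standard land-per-protein reference value
for soybeans — and back-solves peas = (3.144 − 0.5·2.2 − 0.2·5.18)/0.3 =
3.36 via `calibrate_source_intensity`, which inverts the weighted-intensity
formula for exactly one unknown. Calibration refuses a zero-weight unknown
(unidentifiable) and a negative solution (infeasible target). All three
intensities are overridable through mix files.

## Numerical choices

- All computation is double precision; rounding to 2 decimals happens only
  in rendered CSV tables. Totals are plain left-to-right sums in basket
  order — at eight to a few dozen items, summation-order effects are far
  below every tolerance used.
- The fixture tables round intermediates before multiplying (e.g. the
  printed poultry initial land 267.96 vs the full-precision 268.13), so
  reproduction tests use 0.5% relative tolerance per cell with an absolute
  floor of 0.005 (the printed half-ulp, which dominates for cells near
  0.1), and 0.1% on totals.
- Degenerate inputs are errors, not silent defaults: empty baskets, empty
  rate lists, rates outside [0, 1], nonpositive populations, weights that
  do not sum to 1 beyond 1e-6.

### Baseline convention note

The published per-capita baseline total (8164.59 m²) equals the sum of the
published rows *minus the poultry row*; the internally consistent row sum
is 8432.55 m², and the regression suite pins this diagnosis (the gap
matches the poultry row to within 0.01%). The engine always reports the
consistent sum. Savings measured against the 8164.59 m² baseline therefore
differ from this package's savings, while final-state totals and
scenario-to-scenario differences — which do not depend on the baseline —
agree. The `--paper-compat-note` flag appends a markdown note with this
explanation to rendered reports instead of reproducing the omission.

## Synthetic data

The generator draws baskets and mixes with the structure the analysis
assumes: consumption log-uniform over 0.19–599.32 kg/yr (the fixture spans
three orders of magnitude, and a log draw keeps synthetic totals from
being dominated by a uniform tail), protein uniform over 3.3–18.5 g/100 g,
animal intensities uniform over 3.69–184.81 and plant intensities over
2.2–5.18 m²/100 g protein, with mix weights from a symmetric Dirichlet
draw whose last coordinate is closed to make the sum exact. A single
seeded `numpy.random.Generator` is threaded through every draw; there is
no global random state.

What it deliberately does not emulate: correlations between protein
content and land intensity, realistic food-name semantics, survey noise,
or age-structured consumption. Property tests on synthetic data therefore
establish that the *accounting* is correct (conservation, linearity in the
rate, monotonicity when the mix beats every animal intensity, calibration
round-trip, agreement with a bare-scalar oracle) — they say nothing about
the realism of any particular national basket beyond the bundled one.

## Problem sizes

The bundled study is desk-scale: eight foods, three sources, three rates.
The property harness runs 200 seeded random (basket, mix, rate) cases with
five foods each; the full test suite and the reproduction script each
complete in a few seconds.

## Known limitations

- The "final" column inherits the published convention (initial minus
  plant land) rather than a physical end-state land use (remaining animal
  land plus plant land); use the net balance for physical interpretations.
- National extrapolation multiplies adult population by per-capita figures
  derived from whole-population consumption data, as the source study
  does; the population parameter can be changed but no age structure is
  modelled.
- Reference-area ratios are reported to 3 decimals and are a communication
  device, not an allocation claim.
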