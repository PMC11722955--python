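# dietshift

Land-use accounting for dietary protein-substitution scenarios.

Agricultural land demand is dominated by animal-source foods: producing
100 g of protein from beef or sheep takes one to two orders of magnitude
more land than producing it from soy, peas or cereals. `dietshift` models
what happens to a population's per-capita agricultural footprint when a
fraction of its animal-source protein is replaced by a weighted mix of
plant protein sources, and scales the result to a national population. It
is aimed at food-system and sustainability analysts who want a small,
fully inspectable scenario calculator rather than a full LCA stack.

## Model

For each animal-source food with annual per-capita consumption *C* (kg),
protein content *P* (g/100 g) and land intensity *LU*<sub>animal</sub>
(m² per 100 g protein):

- protein units (100-g blocks per person-year): *U* = *C*·*P*/10
- initial land use: *LU*<sub>initial</sub> = *U* · *LU*<sub>animal</sub>
- land claimed by the plant mix at replacement rate *R* ∈ [0, 1]:
  *LU*<sub>replaced</sub> = *U* · *R* · Σᵢ *w*ᵢ · *LU*<sub>vegetal,i</sub>,
  where the *w*ᵢ (Σ*w*ᵢ = 1) weight the plant sources' intensities
- final land use: *LU*<sub>final</sub> = *LU*<sub>initial</sub> − *LU*<sub>replaced</sub>

Totals are column sums over the basket; national figures multiply a
per-capita total by a population count and convert to hectares.

The package ships the Romanian 2021 study inputs as a fixture: an
eight-category basket (poultry, beef, sheep & goat, pig meat, other meat,
fish & seafood, eggs, milk — each including processed equivalents), a
replacement mix of 50% soy, 30% peas and 20% potatoes (intensities
2.2 / 3.36 / 5.18 m² per 100 g protein, weighted 3.144), the adult
resident population (14,940,830), and county UAA reference areas for
communicating savings.

## Worked example

```python
import dietshift as ds

basket, mix, population, references = ds.load_romania_fixture()
results = ds.scenario_sweep(basket, [0.33, 0.5, 1.0], mix)
for r in results:
    nat = ds.national_result(r, population.adult)
    print(f"rate {r.rate:g}: final {r.total_final:.2f} m2/capita, "
          f"national {nat.national_final:,.0f} ha")
```

prints

```
rate 0.33: final 8108.35 m2/capita, national 12,114,554 ha
rate 0.5: final 7941.35 m2/capita, national 11,865,029 ha
rate 1: final 7450.14 m2/capita, national 11,131,131 ha
```

Replacing all animal protein with the soy–pea–potato mix drops the
per-capita final figure from a 8432.55 m² baseline to 7450.14 m²; at the
50% rate the national final land use is ≈11.86 million ha, and moving from
50% to 100% replacement frees a further ≈734,000 ha — roughly two thirds
of the combined utilized agricultural area of two large counties
(1,113,352.75 ha).

The same sweep is available from the shell:

```sh
dietshift run --basket fixture --mix fixture --rates 0.33,0.5,1.0 \
    --population fixture --out out/ --paper-compat-note
```

which writes one CSV table per rate, a JSON summary and, with the flag, a
markdown note documenting a known baseline-convention discrepancy in the
published tables (see `docs/methods.md`). `dietshift synth` generates
random but structurally valid baskets/mixes, and `dietshift calibrate`
back-solves a missing plant intensity from a target weighted intensity.

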