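"""Published Romanian scenario-table values, frozen for regression checks.

Each row: (food, lu_initial, replaced_protein_units, lu_replaced, lu_final),
land figures in m² per capita-year, replaced protein in 100-g units.  The
published tables round every cell to 2 decimals and round intermediates
before multiplying, so reproduction tolerances are 0.5% relative per cell
with an absolute floor at the printed half-ulp (0.005), and 0.1% on totals.
"""

PUBLISHED_ROWS = {
    0.33: [
        ("Poultry", 267.96, 12.53, 39.40, 228.55),
        ("Beef", 1528.39, 3.08, 9.69, 1518.70),
        ("Sheep and goat", 724.47, 1.29, 4.07, 720.40),
        ("Pig meat", 435.50, 13.39, 42.11, 393.39),
        ("Meat other", 2.16, 0.10, 0.32, 1.84),
        ("Fish and seafood", 32.52, 2.91, 9.15, 23.37),
        ("Eggs", 77.63, 4.53, 14.25, 63.38),
        ("Milk", 5363.91, 65.27, 205.20, 5158.72),
    ],
    0.5: [
        ("Poultry", 267.96, 18.99, 59.70, 208.26),
        ("Beef", 1528.39, 4.67, 14.69, 1513.71),
        ("Sheep and goat", 724.47, 1.96, 6.16, 718.30),
        ("Pig meat", 435.50, 20.30, 63.81, 371.69),
        ("Meat other", 2.16, 0.15, 0.48, 1.68),
        ("Fish and seafood", 32.52, 4.41, 13.86, 18.66),
        ("Eggs", 77.63, 6.87, 21.60, 56.04),
        ("Milk", 5363.91, 98.89, 310.90, 5053.01),
    ],
    1.0: [
        ("Poultry", 267.96, 37.98, 119.41, 148.55),
        ("Beef", 1528.39, 9.34, 29.37, 1499.02),
        ("Sheep and goat", 724.47, 3.92, 12.32, 712.14),
        ("Pig meat", 435.50, 40.59, 127.61, 307.89),
        ("Meat other", 2.16, 0.31, 0.96, 1.20),
        ("Fish and seafood", 32.52, 8.82, 27.72, 4.80),
        ("Eggs", 77.63, 13.74, 43.19, 34.44),
        ("Milk", 5363.91, 197.78, 621.81, 4742.11),
    ],
}

#: Published per-capita final totals, m².
PUBLISHED_FINAL_TOTALS = {0.33: 8108.35, 0.5: 7941.34, 1.0: 7450.14}

#: Published per-capita baseline total, m² — equals the row sum *minus*
#: the poultry row; the internally consistent row sum is 8432.54 m².
PUBLISHED_BASELINE = 8164.59

#: Published national figures (adult population 14,940,830), hectares.
PUBLISHED_NATIONAL_FINAL = {0.5: 11_865_024.0, 1.0: 11_131_127.0}
PUBLISHED_NATIONAL_STEP = {(0.33, 0.5): 249_525.0, (0.5, 1.0): 733_898.0}
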