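"""Build and inspect the in vivo-mimetic membrane composition.

Constructs the asymmetric ten-species bilayer recipe (plasma-membrane-like:
sphingolipids and GM3 outside, PS/PIP2 inside, cholesterol in both
leaflets), validates it, and discretizes the mole fractions into molecule
counts for a concrete patch.
"""

import lipidkinetics as lk

comp = lk.build_default_composition()
print("species:", ", ".join(comp.all_species_names()))
print("violations:", lk.validate_composition(comp) or "none")

counts = lk.realize_counts(comp, n_upper=200, n_lower=200)
for leaflet in ("upper", "lower"):
    row = ", ".join(f"{s}:{n}" for s, n in sorted(counts[leaflet].items()))
    print(f"{leaflet:>5} leaflet (200 lipids): {row}")

# Counts follow largest-remainder rounding of the printed percentages, so
# each leaflet sums exactly to the requested total.
print("totals:", sum(counts["upper"].values()), sum(counts["lower"].values()))
print(lk.composition_to_yaml(comp))
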