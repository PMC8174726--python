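"""From forage quality to nitrogen-cycling coefficients.

The default net-energy physiology turns a diet (forage of a given quality
plus 5% agroindustrial byproducts) into the two coefficients that couple
the herd to the cropland: alpha, the plant-available manure N one cow-unit
produces each year, and 1/beta, the forage N it consumes.
"""

from nsafarm import CattleDiet, build_herd, physiology_coefficients

QUALITIES = {
    "high": dict(forage_energy_density=1.32, forage_n_fraction=0.025),
    "medium": dict(forage_energy_density=1.20, forage_n_fraction=0.022),
    "low": dict(forage_energy_density=1.08, forage_n_fraction=0.019),
}

print(f"{'quality':8s} {'intake kgDM/y':>13s} {'alpha kgN/y':>12s} "
      f"{'1/beta kgN/y':>13s} {'beef kg/y':>10s}")
for quality, spec in QUALITIES.items():
    diet = CattleDiet(forage_quality=quality, **spec)
    coeff, beef, detail = physiology_coefficients(diet)
    print(f"{quality:8s} {detail['dry_matter_intake']:13.0f} {coeff.alpha:12.1f} "
          f"{1 / coeff.beta:13.1f} {beef:10.1f}")

profile = build_herd(100.0)
print("\nherd composition per 100 mother cows:")
for category, count in profile.counts.items():
    print(f"  {category:20s} {count:6.1f}")
print("\nPoorer forage means more dry-matter intake per cow-unit (the")
print("energy requirement must still be met) but less N per kg eaten, so")
print("both manure-N output (alpha) and forage-N demand (1/beta) fall")
print("modestly from high to low quality. All quantities are per 'one cow")
print("and her associated animals' and scale linearly with herd size.")
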