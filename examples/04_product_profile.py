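"""Percent-of-total terpene composition from a GC-MS peak table.

Simulates a limonene-synthase assay extract: terpene product peaks at the
published proportions, the 2.5 µM isobutylbenzene internal standard, a
non-terpene artefact peak, and a boiled-enzyme control.  The analysis
subtracts the control background, classifies peaks against the compound
lexicon, and reports percentages over the mono-/sesquiterpene denominator
only.
"""

from tpskit.profiles import classify_peaks, percent_composition, subtract_background
from tpskit.reference import PANEL_PRODUCT_PROFILES
from tpskit.synthetic import gen_boiled_control, gen_peak_table

profile = PANEL_PRODUCT_PROFILES[("CsTPS1SK", "GPP")]
table, _ = gen_peak_table(
    profile, extra_nonterpene={"geranyl methyl ether": 40_000.0},
    seed=3, sample_id="CsTPS1SK", substrate="GPP", normalise=True,
)
control = gen_boiled_control({"pinene hydrate": 8_000.0}, seed=4)

cleaned = subtract_background(table, control, rt_tol_min=0.10)
result = percent_composition(classify_peaks(cleaned))

print(f"{result.sample_id} + {result.substrate}: active = {result.active}")
for compound, pct in sorted(result.composition.items(), key=lambda kv: -kv[1]):
    print(f"  {compound:<22} {pct:6.2f} %")
print("excluded from the denominator:")
for compound, reason in result.excluded:
    print(f"  {compound:<22} ({reason})")
print()
print("Internal-standard and non-terpene peaks never enter the percentage "
      "denominator, so the composition matches the generative profile.")
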