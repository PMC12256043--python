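"""Fit Michaelis-Menten kinetics from a malachite-green endpoint plate.

Simulates a 96-well endpoint plate (13-level 2-fold substrate series,
triplicate wells, Pi standard block, substrate-free backgrounds) at the
published limonene-synthase/GPP parameters with 5% well-to-well noise, then
runs the full reduction: standard curve -> rates -> non-linear fit -> kcat.
"""

from tpskit.kinetics import fit_michaelis_menten, rates_from_plate
from tpskit.reference import PANEL_KINETICS
from tpskit.synthetic import gen_kinetics_plate

km_true, _, vmax_true, _, kcat_pub = PANEL_KINETICS[("CsTPS1SK", "GPP")]
plate, _ = gen_kinetics_plate(
    km_true, vmax_true, noise_cv=0.05, seed=42,
    enzyme_id="CsTPS1SK", substrate="GPP",
)
print(f"plate: {len(plate)} wells "
      f"({(plate.role == 'sample').sum()} samples, "
      f"{(plate.role == 'standard').sum()} standards, "
      f"{(plate.role == 'background').sum()} backgrounds)")

dataset, std_curve = rates_from_plate(plate, enzyme_id="CsTPS1SK", substrate="GPP")
print(f"Pi standard curve: slope {std_curve.slope:.4f} AU/µM, "
      f"r² = {std_curve.r_squared:.4f}")

fit = fit_michaelis_menten(dataset)
print(f"fitted  Km = {fit.km_uM:.3f} µM   (generative {km_true})")
print(f"fitted  Vmax = {fit.vmax_uM_per_s:.4f} µM/s (generative {vmax_true})")
print(f"fitted  kcat = {fit.kcat_per_s:.4f} s⁻¹  (published {kcat_pub})")
print()
print("kcat = Vmax / E0 with the panel's effective enzyme-concentration "
      "divisor of 10; at 5% noise the fit recovers the generative "
      "parameters to within a few percent.")
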