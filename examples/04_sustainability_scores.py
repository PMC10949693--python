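"""Quantitative sustainability metrics for a UV-vis chemometric method.

Carbon footprint (kg CO2 eq per sample), BAGI blueness (practicality,
geometric mean of ten 1-10 criteria on a 10-100 scale), and RGB12 whiteness
(mean of validation/environmental/economic color scores).
"""
from specchem import (
    BagiInput,
    InstrumentUsage,
    Rgb12Input,
    bagi_score,
    carbon_footprint,
    rgb12_whiteness,
)

# a bench spectrophotometer drawing 0.1 kW for a 30-minute batch at a grid
# emission factor of 0.4 kg CO2/kWh
footprint = carbon_footprint([InstrumentUsage(power_kw=0.1, hours=0.5, emission_factor=0.4)])
print(f"carbon footprint: {footprint:.3f} kg CO2 eq per sample "
      "(spectrophotometry needs no solvent production or separation column)")

bagi = bagi_score(BagiInput((10, 10, 9, 9, 10, 8, 10, 10, 7, 9)))
print(f"BAGI blueness: {bagi:.1f} / 100 (scores >= 60 are considered practical)")

white = rgb12_whiteness(
    Rgb12Input(red=(95, 99, 85, 98), green=(95, 92, 90, 95), blue=(90, 95, 92, 85))
)
print(f"RGB12 colors: red {white['red']:.1f} (validation), "
      f"green {white['green']:.1f} (environment), blue {white['blue']:.1f} (economy)")
print(f"whiteness: {white['whiteness']:.1f} / 100 — the closer to 100, the better "
      "the method balances performance, greenness and cost.")
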