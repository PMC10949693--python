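"""Build the structured calibration and validation mixture designs.

The calibration set is a 25-run five-level cyclic design over 10-30 ug/mL
for two analytes (balanced levels, orthogonal coded columns); the validation
set is a 13-stratum Latin hypercube sample (one mixture per stratum per
analyte).
"""
from specchem import DesignSpec, LHSSpec, brereton_design, coverage_diagnostics, lhs_design

cal = brereton_design(DesignSpec())
print("calibration design (first five rows, ug/mL):")
print(cal.concentrations.head(), "\n")

diag = coverage_diagnostics(cal)
print(f"coded-column correlation: {diag['coded_correlation']:.3f} "
      "(0 means the two analytes' levels are orthogonal, so the model can "
      "separate their spectral contributions)")
print(f"min pairwise distance: {diag['min_pairwise_distance']:.1f} ug/mL\n")

val = lhs_design(LHSSpec(n_strata=13, seed=7))
print("validation design (first five rows, ug/mL):")
print(val.concentrations.round(2).head(), "\n")

occ = coverage_diagnostics(val)["stratum_occupancy"]
print("stratum occupancy per analyte (all ones = every concentration band "
      "of the range is probed exactly once):")
for analyte, hist in occ.items():
    print(f"  {analyte}: {hist}")
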