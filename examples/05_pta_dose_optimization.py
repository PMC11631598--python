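"""Monte Carlo PTA and dose-regimen optimization for one subgroup.

For 10-30 kg children with normal renal function (eGFR 90-120), compute
the probability of attaining 70% fT>MIC across the MIC panel for a
common regimen, then search the dose grid for the regimen the clinical
priority rules select at MIC 4 mg/L.
"""

from ceftazppk import (
    FINAL_MODEL_THETA, OmegaMatrix, PDTarget, Regimen, Subgroup,
    optimize_dose, pta,
)

omega = OmegaMatrix(omega2_CL=0.06, omega2_V=0.04)
sub = Subgroup(10, 30, 90, 120)

print("PTA of 30 mg/kg q8h (0.5-h infusion) by MIC:")
for mic in (2, 4, 8, 16):
    r = pta(Regimen(30.0, 8.0, 0.5), sub, PDTarget(mic=mic), FINAL_MODEL_THETA,
            omega, n=1000, seed=1)
    print(f"  MIC {mic:>2} mg/L: PTA {100 * r.pta:5.1f}%  (MC SE {100 * r.mc_se:.1f}%)")

res = optimize_dose(sub, PDTarget(mic=4.0), FINAL_MODEL_THETA, omega, seed=1)
reg = res.regimen
print(f"\nselected regimen at MIC 4: {reg.dose_per_kg:g} mg/kg q{reg.interval:g}h "
      f"({reg.daily_dose_per_kg:g} mg/kg/day), PTA {100 * res.pta:.1f}%")
print(f"search evaluated {len(res.search_log)} regimens")
# PTA decreases with MIC; the optimizer prefers the least frequent
# administration within 100 mg/kg/day, so a q8h or q12h regimen wins
# whenever one attains PTA > 90%.
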