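"""Monte Carlo PTA of the three study regimens and the dosing nomogram.

Compares the label regimen (6 mg/kg), the local fixed-dose protocol
(600 mg) and the intensified regimen (12 mg/kg q12h x5 then QD) in a
moderate-renal-function stratum, then prints the minimum-daily-dose
nomogram over the cohort's IBW x eGFR range.
"""

import numpy as np

from teicopk import CovariateVector, load_regimen_library
from teicopk.simulation import nomogram, pta, simulate_population, stratified_profiles

regimens = load_regimen_library()
stratum = CovariateVector.from_ibw(IBW=60.0, EGFR=45.0, AGE=62.0)

print("PTA in the IBW 60 kg / eGFR 45 mL/min stratum (1000 subjects each):")
print(f"{'regimen':28s} {'72h>=15':>8s} {'ss>=15':>8s} {'ss>=20':>8s}")
for name in ("smpc_6mgkg", "local_600", "intensified_12mgkg"):
    prof = simulate_population(1000, stratum, regimens[name], seed=31)
    p72 = pta(prof, 15.0, "72h").proportion
    pss15 = pta(prof, 15.0, "steady_state").proportion
    pss20 = pta(prof, 20.0, "steady_state").proportion
    print(f"{name:28s} {p72:8.1%} {pss15:8.1%} {pss20:8.1%}")
print("-> only the intensified regimen clears the 90% adequacy line here.")

print("\nIBW-stratified intensified regimen, 90% prediction band at 72 h:")
strat = stratified_profiles([40.0, 60.0, 80.0], regimens["intensified_12mgkg"],
                            seed=32, n=500)
for _, row in strat.iterrows():
    i72 = int(np.searchsorted(row["times"], 72.0))
    flag = "  (extrapolated beyond cohort IBW range)" if row["extrapolated"] else ""
    print(f"  IBW {row['ibw']:4.0f} kg: mean {row['mean'][i72]:5.1f} "
          f"[{row['p5'][i72]:5.1f}-{row['p95'][i72]:5.1f}] mg/L; "
          f">60 mg/L at SS trough in {row['frac_above_safety_ss']:.1%}{flag}")

print("\nminimum once-daily dose (mg/day) for Cmin,ss >= 15 mg/L "
      "(typical individual):")
grid = nomogram(np.linspace(46.25, 77, 4), np.linspace(26, 141, 4))
print(grid.to_frame().round(0).to_string())
print("-> dose requirements rise with both IBW and eGFR; high-IBW patients")
print("   with preserved renal function need >= 1.5 g/day.")
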