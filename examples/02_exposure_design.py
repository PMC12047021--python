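"""Exposure levels, a spiking plan and recovery bookkeeping.

Loads the bundled case-study exposure table, shows the Portuguese
mixture's three levels (MEC / PEC / 5×PEC, mg a.s./kg dry soil), plans
the laboratory spiking of a 25 g jar at PEC, and checks an observed
persistence against the first-order decay its DT50 predicts.
"""

from mixrisk import (
    build_spiking_plan,
    exposure_sets_from_table,
    load_table1,
    pec_from_rate,
    recovery_report,
)

sets = exposure_sets_from_table(load_table1())
pt = sets["PT"]
print("Portugal exposure set (mg a.s./kg dry soil):")
for pest in pt.pesticides:
    print(f"  {pest:<20} MEC {pt.mec[pest]:>6}  PEC {pt.pec[pest]:>6}"
          f"  5PEC {pt.five_pec[pest]:>6}")

# a 4.32 kg/ha application mixed into 5 cm of soil at 1.5 g/cm^3:
print(f"\nPEC from a 4.32 kg/ha rate: {pec_from_rate(4.32):.3f} mg/kg")

plan = build_spiking_plan("PEC", pt.pec, soil_mass_g=25.0)
print(f"\nspiking plan for 25 g dry soil at PEC:")
print(f"  acetone sub-sample: {plan.spiked_submass_g:.1f} g"
      f" + {plan.acetone_volume_ml:.2f} ml acetone")
for pest, mg in plan.masses_mg.items():
    print(f"  {pest:<20} {mg * 1000:8.2f} ug via {plan.carriers[pest]}")

# lambda-cyhalothrin: only 17% left after 28 d despite a 174-day half-life
rec = recovery_report("lambda-Cyhalothrin", nominal=0.1, measured_initial=0.3,
                      measured_final=0.051, dt50_days=174.0)
print(f"\nrecovery {rec.recovery_percent:.0f}% ({rec.category}), "
      f"persistence {rec.persistence_percent:.0f}% vs expected residual "
      f"{rec.expected_residual_fraction:.1%} -> anomaly={rec.anomaly}")
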