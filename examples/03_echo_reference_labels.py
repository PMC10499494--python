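"""Echo reference standard: Devereux LV mass, BSA, LVMI and the LVH label.

Two subjects — one thick-walled male, one normal female — show how the
linear echo dimensions turn into the sex-specific reference label that the
ECG criteria are scored against.
"""

from ecglvh import EchoStudy, lvh_label

subjects = [
    ("thick-walled male", EchoStudy(ivsd_cm=1.4, lvidd_cm=5.4, pwtd_cm=1.4,
                                    height_cm=170, weight_kg=80, sex="male")),
    ("normal female", EchoStudy(ivsd_cm=0.8, lvidd_cm=4.6, pwtd_cm=0.8,
                                height_cm=165, weight_kg=60, sex="female")),
]

for name, study in subjects:
    lab = lvh_label(study)
    print(f"{name}: LV mass {lab.lv_mass_g:6.1f} g, BSA {lab.bsa_m2:.2f} m2, "
          f"LVMI {lab.lvmi_g_per_m2:6.1f} g/m2 "
          f"(cutoff >{lab.cutoff_used_g_per_m2:g}) -> "
          f"{'LVH' if lab.lvh else 'no LVH'}")
# LVMI = Devereux mass / Mosteller BSA; the label is a strict comparison
# against the sex-specific cutoff.
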