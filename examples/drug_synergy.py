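"""Isobologram synergy analysis of a two-drug combination plate.

Fits four-parameter logistic curves to both single agents, inverts them
for the IC85, locates combination dose pairs achieving 85% inhibition and
scores each with the Loewe combination index CI = d1/IC85_1 + d2/IC85_2
(1 = additive, < 1 = synergistic).
"""

from regnomics.simulate import GeneratorConfig, PlateConfig, gen_dose_response
from regnomics.synergy import DoseResponsePlate, isobologram

for psi, label in ((1.0, "additive"), (0.5, "synergistic")):
    cfg = GeneratorConfig(seed=0, plate=PlateConfig(interaction=psi,
                                                    noise_sd=0.0,
                                                    n_replicates=1))
    df, truth = gen_dose_response(cfg)
    plate = DoseResponsePlate("THZ1", "panobinostat", df)
    res = isobologram(plate, level=85)
    cis = res.points["ci"]
    print(f"{label} surface (interaction {psi}):")
    print(f"  IC85 {plate.drug1}={res.ic_drug1:.2f}, "
          f"{plate.drug2}={res.ic_drug2:.2f} "
          f"(closed-form truth {truth['ic85_1']:.2f}, {truth['ic85_2']:.2f})")
    print(f"  {len(cis)} isobologram points, CI range "
          f"[{cis.min():.3f}, {cis.max():.3f}]")
print("-> combination indices cluster at the interaction parameter: 1 on "
      "the additive surface, well below 1 when the drugs synergize.")
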