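"""Competitive-ELISA quantification and faecal recovery.

Simulates the oral-administration experiment: a known dose is fed, faeces
are collected, extracts are read on a competitive ELISA plate against a
standard curve, and the mass balance gives the percentage of the dose that
survived gut passage.
"""

from kstab import elisa, synthetic

plate, meta, truth = synthetic.gen_recovery_scenario(
    administered=2.1, recovery_pct=83.0, noise_sd=0.01, seed=7,
)

curve = elisa.fit_plate(plate)
print(f"Standard curve: logit p = {curve.slope:.2f} * log10 C + "
      f"{curve.intercept:.2f}   (r^2 = {curve.r_squared:.4f})")

preds = elisa.predict_samples(curve, plate).set_index("well")
samples = [
    (preds.loc[m.well, "concentration"], m.extract_volume,
     m.sampled_mass, m.total_mass)
    for _, m in meta.iterrows()
]
res = elisa.recovery_percent(samples, truth["administered"])
print(f"Administered: {res.administered_mass:.2f} mg; recovered "
      f"{res.recovered_mass:.2f} mg -> {res.recovery_percent:.1f}% "
      f"(scenario truth {truth['recovery_pct']:.0f}%)")
print()
print("A recovery close to the administered dose means the protein crossed "
      "the gastrointestinal tract essentially undigested - the behaviour "
      "of a non-digestible, antinutritive storage protein.")
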