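"""IVGTT responses across glucose-tolerance phenotypes.

A 0.36 g/kgBW IV glucose bolus is injected over 3 min and glycemia /
insulinemia are read on the standard 23-point schedule (-30' to 180').
Phenotypes modify insulin sensitivity, hepatic output, and the secretory
meta-parameters multiplicatively; the left-shifted T2DM variant also
moves the threshold distribution to g_1/2 = 4 mM.  Reduced population
(20,000 units) for speed.
"""

import isletsim as isl

meta, env = isl.load_defaults("human")
meta = meta.with_units(20_000)
proto, schedule = isl.make_ivgtt()
bolus_t = schedule[2]

print(f"{'phenotype':12s} {'fasting G':>10s} {'peak G':>8s} {'G(180)':>8s} "
      f"{'fasting I':>10s} {'1st-phase dI':>13s}")
for name in ("NGT", "IFG", "IGT", "IFG+IGT", "T2DM", "T2DM-shift"):
    m, e = isl.apply_phenotype(meta, env, isl.PHENOTYPES[name])
    pop = isl.sample_population(m, seed=1)
    res = isl.simulate_in_vivo(pop, e, proto, duration=float(schedule[-1]) + 1, seed=1)
    samp = res.at_times(schedule)
    fasting_g = samp.glycemia_mM.iloc[:3].mean()
    fasting_i = samp.insulin_pM.iloc[:3].mean()
    post = (res.time > bolus_t) & (res.time <= bolus_t + 10.0)
    first_phase = res.insulin[post].max() - fasting_i
    print(f"{name:12s} {fasting_g:8.2f} mM {samp.glycemia_mM.max():6.1f} {samp.glycemia_mM.iloc[-1]:8.2f} "
          f"{fasting_i:8.0f} pM {first_phase:+11.0f} pM")

print()
print("NGT restores basal glycemia within 3 h with a sharp first-phase insulin")
print("peak; IFG raises fasting glycemia (hepatic overproduction); the")
print("left-shifted T2DM variant loses the first phase because most units are")
print("already recruited at its hyperglycemic baseline.")
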