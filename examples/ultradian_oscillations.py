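"""Slow (ultradian) insulin oscillations and their amplification by feeding.

Closed-loop runs of the whole-body model: the only difference between
the two simulations is a constant enteral glucose input of 0.035
mmol/kgBW/min (90 kcal/h of mixed nutrition for a 60-kg subject).  A
reduced population (20,000 units, total insulin rescaled) keeps the
example quick; the dynamics are unchanged.
"""

import numpy as np

import isletsim as isl

meta, env = isl.load_defaults("human")
meta = meta.with_units(20_000)
duration = 1440.0  # 24 h, ~14 oscillation cycles: enough for the period estimate

pop = isl.sample_population(meta, seed=1)
fed = isl.simulate_in_vivo(pop, env, isl.make_enteral(0.035, duration), duration=duration, seed=1)
pop = isl.sample_population(meta, seed=1)
fasted = isl.simulate_in_vivo(pop, env, None, duration=duration, seed=1)

swing = lambda x: np.percentile(x, 95) - np.percentile(x, 5)
period = isl.estimate_period(fed.insulin, fed.sample_dt, detrend_window=240.0)

print(f"fasted : glycemia {fasted.glycemia.mean():.2f} mM, insulin swing {swing(fasted.insulin):6.1f} pM")
print(f"fed    : glycemia {fed.glycemia.mean():.2f} mM, insulin swing {swing(fed.insulin):6.1f} pM")
print(f"dominant insulin period while fed: {period:.0f} min")
print()
print("Constant feeding amplifies and regularizes the spontaneous slow")
print("oscillation (period ~100 min) generated by the delayed negative")
print("feedback between secreted insulin and glycemia.")
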