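"""Score simulated behavior: exclusions, corrected d-prime, RTs, and the
Bayesian posterior-overlap probability for drift-diffusion contrasts."""

import catrep as cr
from catrep.behavior import behavior_summary

table = cr.generate_behavior(seed=3)
filtered, removed = cr.filter_trials(table)
print(f"excluded trials: {removed}")

# per-task accuracy (log-linear-corrected d') and RT of correct responses
print(behavior_summary(table)[["task", "dprime", "mean_rt_ms"]].to_string(index=False))

# posterior-overlap probability P: the fabricated posteriors are centered on
# the generator's true parameters, so the basic-level drift for non-bird
# animals (v = 1.8) separates cleanly from the superordinate one (v = 3.0):
# P near 1 means the two posteriors barely overlap, 0.5 means they coincide
post = cr.generate_posterior_samples(cr.default_ddm_params(), spread=0.1, seed=0)
p = cr.posterior_overlap_probability(
    post[("superordinate", "nonbird_animal", "v")],
    post[("basic", "nonbird_animal", "v")],
)
print(f"P(v_superordinate > v_basic) for non-bird animals: {p:.3f}")
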