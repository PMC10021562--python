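"""Willingness-to-accept: money compensation for disliked attribute changes.

Refits the model with money as a single continuous per-GMD column (the ratio
is undefined per-GMD under effects-coded money), then reports WTA with
Krinsky-Robb percentile intervals.
"""

import tourpref as tp

design = tp.default_design(seed=1, n_restarts=2)
config = tp.default_generator_config(seed=3, design=design)
dataset = tp.generate_choices(config)

continuous = tp.recode_money_continuous(dataset, design.attributes)
fit = tp.fit_mnl(continuous)
print(f"money coefficient: {fit.beta['money']:.3f} per 1000 GMD\n")

condom = design.attributes[0]
contrasts = [
    tp.level_contrast(condom, condom.levels[0], condom.levels[-1]),
    tp.Contrast("relationship in general: neither -> engage", {"opt_out": -1.0}),
]
for contrast in contrasts:
    est = tp.wta(fit, contrast, n_sim_draws=10_000, seed=0)
    print(f"{est.contrast}")
    print(f"  WTA {est.point:,.0f} GMD  (95% CI {est.ci_lower:,.0f} to {est.ci_upper:,.0f})\n")

# A positive WTA is the compensation a respondent requires to accept the
# change: moving from condoms always used to never used demands several
# thousand dalasi, mirroring the strong condom-use preference.
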