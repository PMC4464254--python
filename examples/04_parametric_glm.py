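"""Build a parametric-modulation design and fit the GLM to a synthetic ROI.

Trial-level risk/reward/entropy estimates become mean-centered impulse
trains convolved with a gamma HRF; the OLS fit recovers the generating
effect sizes and reports z = beta/SE per regressor.
"""

import numpy as np

from riskdeck import ModelParams, build_design, fit_glm, generate_task_sequence
from riskdeck.cohort import simulate_model_agent, simulate_task_bold
from riskdeck.model import trial_modulators

task = generate_task_sequence(180, rng_seed=7)
rng = np.random.default_rng(1)
ds = simulate_model_agent(task, -0.2, rng=rng)
mods = trial_modulators(task, ModelParams(-0.2), ds.choices)

true_betas = {"risk": 1.0, "reward": 0.5, "entropy": 0.3}
series = simulate_task_bold(mods, true_betas, noise_sd=1.0, rng=rng)
print(f"simulated {len(series)} volumes (3 runs x 210 volumes at TR 2 s)")

design = build_design(mods)
print(f"design columns: {design.columns}  (condition number {design.condition_number():.1f})")

res = fit_glm(series, design)
print("\nregressor   true beta   beta_hat     SE        z")
for name, b in true_betas.items():
    c = res.coef(name)
    print(f"{name:<10}  {b:>8.2f}   {c['beta']:>8.3f}  {c['se']:>7.3f}  {c['z']:>7.2f}")
print(
    "\nbeta_hat tracks the generating effect within ~2 SE; z = beta/SE is the"
    "\nsubject-level activation statistic the group analyses correlate with NS."
)
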