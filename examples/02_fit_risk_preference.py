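"""Simulate a softmax agent and recover its risk preference by maximum likelihood.

Also prints the per-trial MLL, the information criteria (group-size
convention), and the argmax prediction accuracy.
"""

import numpy as np

from riskdeck import SearchConfig, fit_risk_preference, generate_task_sequence
from riskdeck.cohort import simulate_model_agent

task = generate_task_sequence(180, rng_seed=7)
rng = np.random.default_rng(42)

l_true = -0.4
dataset = simulate_model_agent(task, l_true, rng=rng)
fit = fit_risk_preference(dataset, SearchConfig(rng_seed=0), group_size=30)

print(f"true risk preference      l  = {l_true:+.3f}")
print(f"fitted risk preference  l_hat = {fit.l_hat:+.3f}")
print(f"per-trial MLL                = {fit.mll:.4f} nats/trial")
print(f"AIC / AICc / BIC (M=30)      = {fit.aic:.3f} / {fit.aicc:.3f} / {fit.bic:.3f}")
print(f"argmax prediction accuracy   = {fit.accuracy:.3f}")
print(
    "\nA single 180-trial dataset estimates l with sd ~ 0.3; averaging fits"
    "\nover many agents recovers the true value (see the recovery tests)."
)
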