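"""Fit GP and BMT models to one simulated agent by cross-validated
maximum likelihood and compare their out-of-sample predictive accuracy.

Fitting is leave-one-round-out over rounds 1-9: parameters are estimated
by differential evolution on 8 rounds and scored on the held-out round.
Predictive accuracy is a pseudo-R^2 (0 = chance, 1 = perfect).
"""

import gridbandits as gb
from gridbandits.fitting import OptimizerConfig

envs = gb.generate_environment_set(4.0, n=40, seed=1)
truth = gb.ParamSet(model="gp", lambda_=1.0, beta=0.5, tau=0.05)
agent = gb.simulate_agent(truth, envs, seed=7)
print(f"agent generated by: {truth}\n")

opt = OptimizerConfig(popsize=10, maxiter=30)
for model in ("gp", "bmt", "random"):
    res = gb.crossvalidate(model, agent, opt=opt, seed=0)
    print(f"{model:7s} out-of-sample logL {res.total_loglik:8.1f}   "
          f"pseudo-R2 {res.pseudo_r2:.3f}   point estimate {res.params}")
print("\nThe GP recovers parameters near the generating values and predicts "
      "held-out choices far better than the non-generalizing BMT.")
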