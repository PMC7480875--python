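"""Out-of-task validation: predict bonus-round judgments from search
behavior.

In the bonus round an agent makes 15 choices and then judges the expected
reward (1-100) and its confidence (0-10) for 10 options it never tried.
Conditioning the GP on those 15 observations predicts both: judged
rewards track the posterior mean, confidence inversely tracks the
posterior variance. The BMT predicts the same value for every unobserved
option, so its prediction-judgment correlation is undefined.
"""

import gridbandits as gb

envs = gb.generate_environment_set(4.0, n=40, seed=1)
gp = gb.ParamSet(model="gp", lambda_=1.0, beta=0.5, tau=0.05)
agent = gb.simulate_agent(gp, envs, seed=42)

preds = gb.bonus_round_predictions(gp, agent)
print(preds.round(2).to_string(index=False))

out = gb.bonus_round_correlations(gp, agent)
print(f"\nPearson r(model prediction, judged reward): "
      f"{out['reward_correlation']:.3f}")
print(f"Spearman rho(confidence, posterior variance): "
      f"{out['confidence_variance_rank_correlation']:.3f}")

bmt = gb.ParamSet(model="bmt", theta_eps2=16.0, beta=0.01, tau=0.03)
bmt_agent = gb.simulate_agent(bmt, envs, seed=43)
bout = gb.bonus_round_correlations(bmt, bmt_agent)
print(f"BMT reward correlation (undefined, constant predictions): "
      f"{bout['reward_correlation']}")
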