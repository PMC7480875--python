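"""Simulate a generalizing (GP-UCB) agent, a mean-tracker (BMT) agent and
a random baseline on the same environments, and compare their rewards.

The GP agent exploits reward correlations to find good options; the BMT
learns each option independently; the random agent sets the chance level.
"""

import numpy as np

import gridbandits as gb

envs = gb.generate_environment_set(4.0, n=40, seed=1)

agents = {
    "GP  (lambda=1, beta=0.2, tau=0.05)":
        gb.ParamSet(model="gp", lambda_=1.0, beta=0.2, tau=0.05),
    "BMT (theta=16, beta=0.01, tau=0.03)":
        gb.ParamSet(model="bmt", theta_eps2=16.0, beta=0.01, tau=0.03),
    "random":
        gb.ParamSet(model="random"),
}

chance = np.mean([e.means.mean() for e in envs]) * 87.5
print(f"chance reward level: {chance:.1f}\n")
for label, params in agents.items():
    rewards, dists = [], []
    for i in range(10):
        ds = gb.simulate_agent(params, envs, seed=100 + i)
        rewards.append(np.mean([r.reward.mean() for r in ds.training_rounds()]))
        dists.append(gb.search_distances(ds).mean_distance)
    print(f"{label:38s} mean reward {np.mean(rewards):5.1f}   "
          f"step distance {np.mean(dists):4.2f} (chance 5.25)")
print("\nThe GP agent earns the most and searches locally; the random agent "
      "sits at chance on both measures.")
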