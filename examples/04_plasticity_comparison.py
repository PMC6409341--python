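"""Pre/post plasticity: compare p_r across two 30-trial epochs.

Mimics the standard presynaptic-plasticity workflow: 30 trials at
baseline, 30 trials after induction (here the simulator doubles the true
release probability), then a two-proportion comparison of the estimates.
"""

from oqa import DetectionConfig, SimParams, call_trials, compare_pr, estimate_pr, simulate_experiment


def epoch_estimate(true_pr, seed):
    params = SimParams(true_pr=true_pr, seed=seed)
    records, _ = simulate_experiment(params, n_trials=30)
    return estimate_pr(call_trials(records, DetectionConfig()))


before = epoch_estimate(0.3, seed=100)   # baseline epoch
after = epoch_estimate(0.6, seed=200)    # 30 min post-induction

cmp = compare_pr(before, after, test="fisher", alpha=0.05)

print(f"baseline:  p_r = {before.pr_hat:.3f} ({before.n_success}/{before.n_trials})")
print(f"post:      p_r = {after.pr_hat:.3f} ({after.n_success}/{after.n_trials})")
print(f"delta p_r = {cmp.delta_pr:+.3f} +- {cmp.se_delta:.3f}")
print(f"Fisher's exact p = {cmp.p_value:.4f} -> {cmp.direction}")
print()
print("A significant positive delta at alpha=0.05 is labeled potentiation;")
print("with 30 trials per epoch only fairly large p_r changes reach")
print("significance, which is why trial planning (example 05) matters.")
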