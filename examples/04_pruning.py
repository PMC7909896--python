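"""Shrink the federation's network with APoZ pruning during training.

Enables validation-set pruning (10% of remaining hidden neurons per loop,
47% total target) inside a 30-loop SCBFL run and prints the neuron count
and the final utility next to an unpruned run. The pruned model keeps
roughly half the weight parameters at a small AUC cost.
"""

from scbfl import FederationConfig, generate_cohort, run_scbfl, split_federation

cohort = generate_cohort(2000, 200, 20, effect_scale=3.0, seed=0)
split = split_federation(cohort, n_clients=5, seed=0)

base = dict(n_clients=5, global_loops=30, alpha=0.30, master_seed=0)
_, plain = run_scbfl(split, FederationConfig(**base))
_, pruned = run_scbfl(split, FederationConfig(pruning_enabled=True, **base))

print("loop  neurons  pruned-AUC")
for rec in pruned.records[::4]:
    print(f"{rec['loop']:4d}  {rec['neurons_remaining']:7d}  {rec['auc_roc']:.4f}")

p, u = pruned.final(), plain.final()
cut = 1 - p["weight_params"] / p["original_weight_params"]
print(f"\nunpruned AUC {u['auc_roc']:.4f} | pruned AUC {p['auc_roc']:.4f}")
print(f"hidden neurons 96 -> {p['neurons_remaining']}; weight parameters cut by {cut:.0%}")
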