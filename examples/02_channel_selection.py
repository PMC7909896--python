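"""Sparsify one local gradient by channel norms.

Trains a small network for one local loop, computes the Euclidean norm of
the weight-delta over every channel (one neuron per layer), keeps the top
30% of channels, and prints how much of the gradient actually survives.
Because channels through the same first-layer neuron share its whole input
column, the fraction of parameters kept exceeds the fraction of channels.
"""

from scbfl import (
    TrainConfig,
    channel_norms,
    generate_cohort,
    init_model,
    process_gradients,
    train_local,
)

cohort = generate_cohort(500, 50, 10, effect_scale=2.0, seed=1)
model = init_model((50, 16, 8, 1), seed=1)
_, gradient = train_local(model, cohort, TrainConfig(seed=1))

tensor = channel_norms(gradient)
print(f"channel-norm tensor shape: {tensor.norms.shape} -> {tensor.n_channels} channels")

pg = process_gradients(gradient, alpha=0.30, mode="positive")
print(f"selected channels: {len(pg.selected_channels)} ({pg.channel_fraction:.0%})")
print(f"parameters uploaded: {pg.parameter_fraction:.1%} of all weight entries")
print("(channel overlap makes the parameter fraction larger than the channel fraction)")
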