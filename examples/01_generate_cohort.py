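"""Generate a synthetic medication/mortality-style cohort and shard it.

Builds a sparse binary cohort (most exposure features are rare), splits it
60/10/30 into train/validation/test and divides the training rows equally
across five clients, then prints the sizes and label prevalences. The
per-shard prevalences should hover near the cohort prevalence because the
shards are IID by default.
"""

import numpy as np

from scbfl import generate_cohort, split_federation

cohort = generate_cohort(
    n_samples=2000, n_features=200, n_informative=20, effect_scale=3.0, seed=0
)
print(f"cohort: {cohort.n_samples} samples x {cohort.n_features} binary features")
print(f"label prevalence (mortality rate): {cohort.labels.mean():.3f}")
print(f"median feature prevalence: {np.median(cohort.features.mean(axis=0)):.4f}")

split = split_federation(cohort, n_clients=5, fractions=(0.6, 0.1, 0.3), seed=0)
print(f"validation {split.validation.n_samples}, test {split.test.n_samples}")
for i, shard in enumerate(split.client_shards):
    print(f"client {i}: {shard.n_samples} samples, prevalence {shard.labels.mean():.3f}")
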