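# Methods

This note records the model, the choices behind its implementation, and
what the synthetic experiments can and cannot show.

## The learning problem and the network

The simulator targets binary outcome prediction from sparse binary
exposure features (the motivating case: in-hospital mortality from
medication indicators). The shared model is a dense feed-forward network —
input width equal to the feature count, hidden layers of 64 and 32 ReLU
units by default, one sigmoid output — trained with plain mini-batch SGD
(no momentum, no weight decay) on binary cross-entropy. Inverted dropout
(default rate 0.5) is applied to the last hidden layer during local
training only. Weights initialise from a zero-mean Gaussian with standard
deviation $1/\sqrt{\text{fan-in}}$; biases start at zero. The loss is the
canonical choice for a sigmoid output; inside it, scores are clipped to
$[10^{-12}, 1-10^{-12}]$, and the sigmoid itself is computed in the
numerically safe branch form.

## Channel-sparse uploads

A channel $(t_1,\dots,t_L)$ names one neuron per layer. Its parameter set
is the full input column feeding $t_1$ plus the single edge
$(t_{l-1}, t_l)$ for each later layer, so the norm tensor has shape
$m_1 \times \cdots \times m_L$ and channels sharing a first-layer neuron
share that input column. This entry-set convention is the one genuinely
open design point of the upload algorithm: the tensor shape fixes the
channel index set but not which input edges a channel owns; we give each
channel the whole column so that input-layer weights are uploadable at all,
which is also why the uploaded *parameter* fraction exceeds the selected
*channel* fraction (observed ≈45–65% of parameters at a 30% update rate on
the default cohort — the overlap is data- and architecture-dependent).

Selection is a descending-rank cutoff: the threshold is the norm at rank
$\lceil \alpha K \rceil$ of the $K$ flattened channel norms, and every
channel with norm ≥ threshold is kept (inclusive ties, deterministic and
order-independent; with distinct norms exactly $\lceil \alpha K \rceil$
channels are selected). "Negative selection" — discarding the channels
below the cutoff — coincides with positive selection under this tie
policy; both modes are exposed for protocol compatibility, positive being
the default. Entries of the processed gradient off every selected channel
are exactly zero; entries on a selected channel are copied verbatim, so an
exact-zero gradient value on a selected channel is "uploaded as zero"
(selection masks, not nonzero support, define what a client revealed).
Bias deltas are never uploaded.

## Server aggregation and synchronisation

Each loop the server adds, at every weight position, `decay` (default 0.8)
times the mean over the clients that *selected* that position; positions
no client selected do not move. Averaging over selectors keeps the update
magnitude independent of the client count; with one client and decay 1 the
rule reduces to literally adding the processed gradient to the server
weights, which is the degenerate case the equivalence tests pin down
(single client + full upload ≡ sequential centralized SGD to 1e-10).
Summing instead of averaging was evaluated and rejected: it ties the
effective step size to the federation size without improving the
utility/communication trade-off on the study cohorts.

Downloads are full (rate 100%): a sync replaces the client's weights with
the server's but keeps the client's own biases. Since biases are never
uploaded, the server's biases carry no learned signal and stay at their
zero initialisation; overwriting a client's trained biases with them every
loop would discard learning. Server evaluation therefore scores a
zero-bias model — an accepted asymmetry of the protocol. The FedAvg
baseline uploads full weight matrices and sets the server weights to their
unweighted mean (shards are equal-sized by construction); it shares the
same sync, logging and pruning hooks.

Rounds are synchronous with full participation and a fixed client order.
Client $c$ trains in loop $t$ with seed `master_seed + c + t·n_clients`,
which makes an entire run a pure function of (cohort seed, config).

## APoZ pruning

APoZ of a hidden neuron is the fraction of validation examples whose
post-ReLU activation is exactly zero (exact comparison — ReLU emits true
zeros; no tolerance), with output dimension $M=1$ for scalar dense
activations. The server computes APoZ on the central validation set after
its update, removes the $k$ globally highest-APoZ neurons across all
hidden layers — $k = \min(\max(1, \lfloor \text{rate} \cdot
\text{remaining}\rfloor), \text{budget})$ with rate 0.10 per loop and a
total budget of $\lfloor 0.47 \cdot \text{original}\rfloor$ neurons — and
broadcasts keep-masks so every client shrinks identically (shape
congruence is what makes the next loop's aggregation well-defined). Global
ranking follows from the criterion being a single redundancy score; a
one-neuron-per-layer floor prevents degenerate architectures, and ties
break by (layer, index) for determinism. Removal is structural (incoming
column, outgoing row, bias deleted) and is verified in tests to reproduce,
bit-exactly, the unpruned forward pass with the neuron's activation forced
to zero. On a 64+32 network the schedule removes 9, 8, 7, 7, 6, 5, 3
neurons over seven loops — 45 of 96, within one of the 47% target. Input
features and the output unit are never pruned.

## Evaluation metrics

Confusion counts use the score ≥ threshold convention throughout. Curves
sweep the distinct scores descending with sentinel endpoints ((0,0) and
(1,1) on the ROC); precision at zero predicted positives is defined as 1.
AUC-ROC is the trapezoidal area over (FPR, TPR) and is tested to equal the
exhaustive pairwise Mann–Whitney statistic (ties counted ½) exactly;
AUC-PR uses the average-precision right-step sum, not trapezoids, because
linear interpolation of precision is biased. Upload accounting counts
nonzero entries of each processed gradient against the model's total
weight entries, cumulated per run.

## Synthetic cohorts

The generator emulates the statistical shape of hospital
medication/mortality data without modelling its clinical content:
per-feature prevalences drawn from Beta(0.3, 3.0) clipped to
[0.001, 0.5] (most exposures rare — median column mean ≈0.03), independent
Bernoulli features, and labels from a logistic-linear model
$y \sim \mathrm{Bern}(\sigma(\beta_0 + x\beta))$ with 20 of 200
coefficients nonzero at magnitude 3 (random signs) and intercept −1.5 by
default. Logistic outcomes keep the ground truth diagnosable: a plain
logistic fit bounds what any model can extract, and the true generating
probabilities give the Bayes ceiling (AUC-ROC ≈0.91–0.93 on the default
cohorts). Not emulated: admission timing, repeat admissions, dosage,
feature correlations, missingness, or any real-data covariate shift
between clients — so passing tests demonstrate protocol correctness and
relative algorithm behaviour, not clinical-grade absolute performance.
Splits are 60/10/30 with flooring on validation/test and the remainder to
training; shards differ by at most one row. A `shard_skew` knob blends
label-sorted with random assignment for non-IID experiments (default 0,
IID).

## Study problem sizes

The default study — also what `scripts/acceptance.py` re-runs — uses
cohorts of n = 2000 with 200 features, five clients, and 30 global loops
of 5 local epochs (batch 32, learning rate 0.01, decay 0.8), three master
seeds. These sizes give stable AUC estimates in seconds per run while
exercising every protocol component; the full-scale setting (tens of
thousands of admissions, thousands of features, 100 loops) is reachable
through the same config fields. At 30 loops both protocols are still short
of saturation: SCBFL at a 10% update rate reaches ≈0.78–0.79 test AUC-ROC,
within ≈0.12 of the cohort's Bayes ceiling, and tracks FedAvg to within
0.05; run-to-saturation behaviour is a matter of loop budget, not of the
upload rule.

## Known limitations

- No transport layer, asynchrony, client sampling or secure aggregation;
  privacy is structural (what is uploaded), with no formal differential-
  privacy accounting.
- Partial downloads are not implemented (`download_rate` is reserved and
  validated at 1.0).
- The server's biases never learn; for architectures where biases matter
  more than they do under ReLU + binary inputs, the protocol would need a
  bias-sharing extension.
- Wall-clock speedups from pruning are not asserted anywhere (hardware-
  bound); parameter counts stand in for model size.
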