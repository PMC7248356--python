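# Methods

## The model

`cannet` implements contextually-adaptive neurons (CANs) as units of a
random neural network (G-network). Each neuron `y` holds a non-negative
integer potential; while the potential is positive the neuron fires as a
Poisson process with rate `r_y`, and each firing decrements its own
potential and either sends a +1 (excitatory) or −1 (inhibitory) impulse to
a target neuron or leaves the network with departure probability `d(y)`.
Weights are *rates*: `w±(y, x) = r_y · p±(y, x)`, so the two weight
matrices plus the departure probabilities determine both the firing rates

    r(y) = (1 − d(y))⁻¹ Σ_x [w+(y, x) + w−(y, x)]

and the transition probabilities, with the conservation identity
`d(y) + Σ_x [p+(y,x) + p−(y,x)] = 1` holding by construction. External
excitatory/inhibitory impulses arrive as Poisson streams of rates `Λ`, `λ`.

In steady state the joint distribution of the potentials has *product
form*: each neuron is geometric with parameter `q_y`, the probability of
being excited, and the `q` vector solves the nonlinear fixed point

    q_y = (Λ_y + Σ_x q_x w+(x, y)) / (r_y + λ_y + Σ_x q_x w−(x, y)).

`q` of the output neuron is the network's analog output. The product form
only exists while every `q_y < 1`; a fixed point at or above 1 is treated
as an error (saturation), never silently clipped.

A CAN's inputs are partitioned into three labeled fields: the driving
receptive field (RF — the noisy primary sensory stream), the local
contextual field (LCF — a correlated parallel stream, e.g. visual
articulator features) and the universal contextual field (UCF — a binary
pattern encoding the surrounding environment). Because excitation enters
the numerator and inhibition the denominator of the fixed point,
contextual inputs act divisively: they can gate (suppress or amplify) the
transmission of the driving field without adding content of their own.

## Architecture

The default network has two sensory streams (RF-driven and LCF-driven) of
3 CAN layers × 2 CANs, 4 RF input neurons, 4 LCF input neurons, 8 UCF
units and 1 output neuron — 29 neurons in total. Structural rules:

* input neurons feed the first-layer CANs of their stream;
* consecutive CAN layers are fully connected within a stream;
* every CAN connects laterally to all CANs of neighboring streams in the
  same layer (for two streams, each is the other's neighbor);
* UCF units broadcast to every CAN in all streams and layers — the UCF is
  a shared steering field, not a processing stream;
* last-layer CANs feed the output neuron(s).

Every structural edge carries an independent excitatory and inhibitory
learnable weight. This includes input edges: contextual fields must be
able to suppress as well as drive their targets, which is what makes
divisive gating of the LCF pathway by the UCF expressible at all.

Feature vectors enter as rate pairs: a feature min-max scaled to
`s ∈ [0, 1]` becomes `(Λ, λ) = (s·ρ, (1−s)·ρ)` with rate scale `ρ = 1`,
so total drive per input is constant and the excitatory/inhibitory
*balance* carries the value. Default encoding bounds are ±4 (features are
generated with unit variance); heavily corrupted values clip, which is a
realistic saturation of a noisy channel. When the feature dimension
exceeds the input-neuron count, features are block-averaged onto the
inputs (the simplest dimension reduction; nothing in the data pipeline
depends on it for the default dimensions).

### Stability by construction

The product-form regime must survive arbitrary encoded inputs. Three
mechanisms enforce a sufficient condition (`Λ_max + incoming excitation ≤
margin · firing rate` for every neuron, which bounds every `q` by the
margin):

* each input neuron's outgoing row is rescaled to a fixed total
  (`input_gain`, default 1.25 = ρ/0.8), so inputs cannot saturate for any
  `ρ ≤ 1`;
* incoming excitation of the output sink is capped below its explicit
  firing rate `r_sink` (default 1.0);
* each CAN receives a *leak*: its departure probability is set to the
  smallest value that keeps its firing rate ahead of its incoming
  excitation (margin 0.8 at build time, 0.95 during training). The leak
  is the G-network expression of homeostatic gain control — a neuron that
  receives more drive fires faster and sheds the excess out of the
  network.

## Learning

The cost is `C = Σ 0.5 (q_out − target)²` per sample; targets live in
[0, 1) because the output is a probability. Gradients are exact: the
fixed point is differentiated implicitly (one linear adjoint solve per
sample), including the dependence of the firing rates on the weights.
Where the homeostatic leak is active the firing rate equals incoming
excitation / margin, so the rate derivative attaches to the incoming
excitatory column instead of the outgoing row; both branches are verified
against central finite differences (relative error < 1e-5, and < 1e-4
through the leak).

Training is per-sample stochastic gradient descent in seeded shuffled
order, optionally RMSProp-scaled (decay 0.9, epsilon 1e-8 — conventional
values), learning rate 0.02, projection to non-negative weights after
every update (weights are rates). After each update the stability
projection above is re-applied; a unit whose outgoing weights all decay
becomes an absorbing sink with an adaptive fallback rate rather than an
ill-defined dead end. A step that still escapes the stable region is
reverted and the step size halved (this is a rarely-used backstop). Same
seed ⇒ bit-identical trajectories.

The homeostatic leak gives the network a useful normalization: while the
leak binds, a CAN's excitation is approximately the margin times the
weighted mean of its sources' activities, damped by inhibition — learning
then shifts *relative* credit between sources, which is the attention-like
behavior the contextual-gating story needs.

## Information decomposition

All quantities are plug-in estimates on discretized joint tables
(equal-width bins over the observed range; `0·log 0 := 0`; base-2 logs).
The four-way interaction term is `I(X;Y) − I(X;Y|Z,U)` anchored on the
queried pair; the other four pairwise-anchored expressions are *not*
equal for general distributions and are reported as diagnostics. The
output-entropy decomposition

    H(Y) = I(Y;X;Z;U) + I(Y;X|Z,U) + I(Y;Z|X,U) + I(Y;U|X,Z) + H(Y|X,Z,U) + residual

is likewise not an identity; the residual equals `I(Y;Z|X) − I(Y;Z|X,U)`
analytically and is always reported (it is −1 bit for Y = Z⊕U, a useful
synergy canary). The φ-weighted objective `F` reads the case table with
φ0 = 1 implied (the only completion under which `F = I(Y;X)` etc. follow).

Practical notes. Equal-width binning over the observed range loses
information to discretization: at correlation 0.9 between Gaussians, 16
bins lose ≈ 0.14 bit of the analytic 1.198 bits, 32 bins ≈ 0.04. The
plug-in conditional MI also carries a strong positive small-sample bias,
so the per-environment modulation analysis subtracts a permutation
baseline (mean CMI over Z-shuffled surrogates, 10 permutations, seeded);
debiased values can dip slightly below zero under the null.

## Synthetic data

The generator emulates the statistical skeleton of audio-visual speech
enhancement in noise; it does not synthesize audio or video. Per
sequence: clean features are independent AR(1) processes with unit
stationary variance (smoothness coefficient 0.9 — smooth filterbank-like
trajectories); the nominal SNR is drawn uniformly over [−12, 12] dB and
the noisy RF stream is the clean sequence plus white noise rescaled to
that exact SNR; the LCF stream is a fixed unit-row-norm random linear map
of the clean features plus Gaussian noise of sd 0.4 *independent of the
acoustic SNR* (visible articulators are unaffected by acoustic noise —
this is precisely why the LCF disambiguates at low SNR, and why its value
fades at high SNR where the RF itself has correlation ≈ 0.97 with the
clean signal versus ≈ 0.93 for the LCF); the target is one clean
coefficient min-max scaled into [0.05, 0.95]. Five equal-width SNR bands
define the environments (restaurant, cafe, public transport, pedestrian
area, home, noisiest to quietest); each maps to a fixed 8-bit UCF
codeword from a first-order Reed–Muller code (pairwise Hamming distance
≥ 4). The framing utility reads a "62.5% increment" as hop = 62.5% of the
frame length (37.5% overlap) and rounds sample counts.

What passing tests on this data do *not* show: robustness to real
filterbank statistics (correlated dimensions, non-Gaussian tails),
temporal context exploitation (the model is applied frame-by-frame), or
any corpus-level error rates.

## Experiment design and problem sizes

The ablation trains RF-only / RF+LCF / RF+LCF+UCF variants (unused input
fields are simply not built; the CAN lattice is identical) on the same
per-seed dataset with an 80/20 split by sequence, and compares held-out
MSE medians over 5 seeds. Default problem sizes — 40 sequences × 10
frames, 30 epochs — were chosen so a full ablation completes in a few
minutes on one core while the field-ordering effect is well clear of seed
noise. LCF influence is measured two ways, since "amplification/
suppression" has no canonical operational metric: debiased conditional
mutual information I(Y;Z|X,U) per environment, and mean absolute output
change per unit perturbation of the scaled LCF inputs (central
difference, half-width 0.05). Both are rank-correlated against band SNR.

## Known limitations

* The stability projection constrains the reachable function class
  (output excitation is bounded by the margin); targets near 1 carry an
  irreducible error.
* Identifiability is not claimed: teacher–student experiments recover the
  input–output map, not the weights.
* The trained 29-neuron network does not develop environment-dependent
  gating at this scale: its LCF sensitivity is nearly flat across SNR
  bands. The network *class* expresses gating (a hand-built gated model
  shows the full effect through the same analysis), but gradient descent
  on the squared error does not discover it — partly because, with an
  SNR-independent LCF of correlation ≈ 0.93, even the Bayesian-optimal
  combiner retains ≈ 0.3 of its low-SNR LCF weight in the quietest band,
  so the attainable error reduction from gating is second-order.
* Trained outputs are biased toward the lower part of the target range:
  the stability margins bound the output excitation by a cascade of
  per-layer caps, so targets near the top of [0, 1) are approached
  slowly. Error *orderings* between model variants are unaffected.
* The event-driven simulator is exact but written for small networks
  (linear event-rate scans); it is an oracle, not a production engine.
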