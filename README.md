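# cannet

Contextually-adaptive spiking networks: a toolkit for modeling how a
neuron should weigh a noisy driving input against its context.

`cannet` is aimed at computational neuroscientists and machine-learning
researchers studying contextual modulation and multisensory fusion. It
implements a network of *contextually-adaptive neurons* (CANs): random
neural network (G-network) units whose inputs are partitioned into three
labeled fields — the driving **receptive field** (RF, e.g. noisy acoustic
features), the modulatory **local contextual field** (LCF, e.g. visual
lip features from a parallel stream) and the **universal contextual
field** (UCF, a binary pattern encoding the surrounding environment).
The package provides:

* the G-network core: product-form steady state, an exact event-driven
  spiking simulator as an independent oracle, and the conservation
  identity `d(y) + Σ_x [p⁺(y,x) + p⁻(y,x)] = 1` for weight-derived
  transition probabilities;
* declarative construction of multi-stream CAN networks (the default
  expands to the 29-neuron reference architecture: 4 RF + 4 LCF + 8 UCF
  + 12 CANs + 1 output);
* gradient-descent learning on the rate weights with exact
  implicit-differentiation gradients of the steady state, minimizing
  `C = Σ 0.5 (q_estimated − q_clean)²`;
* four-variable information decomposition in bits: entropies, conditional
  mutual information `I(Y;X|Z,U)`, the signed interaction term
  `I(X;Y;Z;U) = I(X;Y) − I(X;Y|Z,U)`, the output-entropy decomposition
  with its residual, and the φ-weighted objective `F`;
* a seeded synthetic multimodal data generator (clean AR(1) feature
  sequences, an RF stream mixed at exact SNR in [−12, 12] dB, a
  correlated LCF stream, environment-coded UCF patterns for restaurant /
  cafe / public transport / pedestrian area / home);
* experiment drivers and a CLI for the field-ablation study (RF-only vs
  RF+LCF vs RF+LCF+UCF) and for per-environment LCF-influence analysis.

## The model in brief

Neuron `y` fires Poisson impulses at rate `r(y) = (1 − d(y))⁻¹ Σ_x
[w⁺(y,x) + w⁻(y,x)]`; excitatory impulses raise target potentials,
inhibitory ones lower them, and signals leave the network with
probability `d(y)`. In steady state the excitation probability of each
neuron solves

    q_y = (Λ_y + Σ_x q_x w⁺(x,y)) / (r_y + λ_y + Σ_x q_x w⁻(x,y))

and the joint stationary law is the product `Π_y (1 − q_y) q_y^{k_y}`.
Because inhibition enters the denominator, contextual fields modulate the
driving field divisively — they gate transmission rather than add
content. See `docs/methods.md` for assumptions, stability handling,
parameter defaults and limitations.

## Worked example

```python
import cannet as cn

# a 29-neuron three-field network and a synthetic multimodal dataset
ds = cn.generate_dataset(cn.SyntheticParams(), seed=1)
net, layout, losses, test_mse = cn.train_on_dataset(
    cn.CANNConfig(seed=1), ds, cn.OptimizerSettings(n_epochs=30, seed=1))
print(f"train loss {losses[0]:.4f} -> {losses[-1]:.4f}, held-out MSE {test_mse:.4f}")

report = cn.modulation_analysis(net, layout, ds)
print(report.table[["env", "mean_snr_db", "lcf_sensitivity"]])
```

prints

```
train loss 0.0216 -> 0.0200, held-out MSE 0.0206
                env  mean_snr_db  lcf_sensitivity
0        restaurant         -9.6         0.022026
1              cafe         -4.8         0.025136
2  public transport          0.0         0.027106
3   pedestrian area          4.8         0.026892
4              home          9.6         0.024658
```

The three-field model's held-out MSE (0.0206) lands below the held-out
target variance (0.0221, the error of always predicting the mean),
whereas the single-stream RF-only variant trained identically ends around
0.08 — the contextual streams carry most of the achievable improvement.
The modulation table gives, per environment, the mean absolute change of
the output per unit perturbation of the scaled LCF inputs — the
operational measure of how much the trained network listens to its
visual stream in each noise regime; for this desk-scale model it is
nearly flat across bands (see `docs/methods.md`, Known limitations).

The same studies are scriptable from the shell:

```bash
cannet ablate --seed 0 --out results/ablation      # RF-only / RF+LCF / RF+LCF+UCF
cannet modulate --seed 1 --out results/modulation  # per-environment LCF influence
cannet --help
```

The ablation writes per-seed and median held-out MSEs for the three
variants; on default synthetic data (5 seeds, 30 epochs) the median
error drops strictly as fields are added — 0.083 (RF-only) > 0.078
(RF+LCF) > 0.052 (RF+LCF+UCF) in the run recorded by the acceptance
suite.

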