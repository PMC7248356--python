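"""Gradient-descent learning on G-network rate weights.

The network's estimate for a sample is the steady-state excitation
probability ``q`` of its output neurons; the cost is the half squared
error ``C = Σ_i 0.5 (q_out_i − target_i)²``.  Because ``q`` is defined
implicitly by the fixed point

    q_i = (Λ_i + Σ_j q_j w+(j,i)) / (r_i + λ_i + Σ_j q_j w-(j,i)),

the exact cost gradient with respect to every weight follows from
implicit differentiation: with ``f`` the fixed-point map and
``A = ∂f/∂q``, the adjoint vector ``v`` solves ``(I − Aᵀ) v = ∂C/∂q``
and ``dC/dθ = Σ_i v_i ∂f_i/∂θ``.  Firing rates are themselves functions
of the outgoing weights (``r_i = Σ_j [w+ + w-](i,j) / (1 − d_i)``), and
that dependence is included.

Training is stochastic gradient descent (optionally RMSProp-scaled) with
per-sample updates in seeded shuffled order; weights are projected to
``≥ 0`` after every update because they are rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .arch import CANNLayout, InputEncoding, cann_arrivals
from .gnet import (
    ExternalArrivals,
    GNetwork,
    GNetworkError,
    SteadyState,
    firing_rates,
    solve_steady_state,
)

__all__ = [
    "TrainingSample",
    "OptimizerSettings",
    "GradientResult",
    "TrainingResult",
    "TrainingError",
    "mse_cost",
    "gradient",
    "predict",
    "train",
]


class TrainingError(GNetworkError):
    """Training diverged or became infeasible."""

    def __init__(self, message: str, epoch: int | None = None) -> None:
        super().__init__(message)
        self.epoch = epoch


@dataclass
class TrainingSample:
    """One multimodal training record.

    ``target`` holds the desired excitation levels of the output neurons
    and must lie in ``[0, 1)`` since the model output is a probability.
    """

    rf_features: np.ndarray | None
    lcf_features: np.ndarray | None
    ucf_pattern: np.ndarray | None
    target: np.ndarray

    def __post_init__(self) -> None:
        self.target = np.atleast_1d(np.asarray(self.target, dtype=float))
        if np.any(self.target < 0) or np.any(self.target >= 1):
            raise GNetworkError("targets must lie in [0, 1)")
        for f in (self.rf_features, self.lcf_features, self.ucf_pattern):
            if f is not None and not np.all(np.isfinite(np.asarray(f, dtype=float))):
                raise GNetworkError("features must be finite")


@dataclass
class OptimizerSettings:
    method: str = "rmsprop"          # "plain-gd" or "rmsprop"
    learning_rate: float = 0.02
    rmsprop_decay: float = 0.9
    rmsprop_epsilon: float = 1e-8
    n_epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("plain-gd", "rmsprop"):
            raise GNetworkError(f"unknown optimizer {self.method!r}")
        if self.learning_rate < 0:
            raise GNetworkError("learning_rate must be >= 0")
        if not 0 < self.rmsprop_decay < 1:
            raise GNetworkError("rmsprop_decay must be in (0, 1)")
        if self.rmsprop_epsilon <= 0:
            raise GNetworkError("rmsprop_epsilon must be positive")
        if self.n_epochs < 1:
            raise GNetworkError("n_epochs must be >= 1")


def mse_cost(estimated: np.ndarray, clean: np.ndarray) -> float:
    """Half squared-error cost ``Σ_i 0.5 (estimated_i − clean_i)²``."""
    estimated = np.asarray(estimated, dtype=float)
    clean = np.asarray(clean, dtype=float)
    if estimated.shape != clean.shape:
        raise GNetworkError("estimated and clean vectors must have equal length")
    diff = estimated - clean
    return float(0.5 * np.dot(diff, diff))


@dataclass
class GradientResult:
    """Cost gradient with respect to every weight entry."""

    w_plus: np.ndarray
    w_minus: np.ndarray
    cost: float
    steady_state: SteadyState

    def by_source_field(self, labels: Sequence[str]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Split gradient rows by the field label of the source neuron."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        labels = list(labels)
        for lab in sorted(set(labels)):
            rows = [i for i, l in enumerate(labels) if l == lab]
            out[lab] = (self.w_plus[rows], self.w_minus[rows])
        return out


# Excitation-probability bound maintained during training; the homeostatic
# leak keeps every CAN's firing rate at incoming-excitation / margin when
# the leak is active.
TRAIN_MARGIN = 0.95


def gradient(
    net: GNetwork,
    arrivals: ExternalArrivals,
    target: np.ndarray,
    output_ids: Sequence[int],
    ss: SteadyState | None = None,
    homeostatic_ids: Sequence[int] | None = None,
    margin: float = TRAIN_MARGIN,
) -> GradientResult:
    """Exact gradient of :func:`mse_cost` w.r.t. every ``w+`` and ``w-`` entry.

    Solves the linear adjoint (sensitivity) system of the steady-state
    fixed point; agrees with central finite differences on stable
    networks.  Entries in sink rows carry no rate-derivative term (their
    firing rate is the explicit ``r_sink`` parameter).

    ``homeostatic_ids`` marks neurons whose departure probability is
    maintained as a function of the weights (leak adaptation, see
    :func:`train`): while their leak is active (``d > 0``) their firing
    rate equals ``incoming excitation / margin``, so the rate derivative
    moves from their outgoing row to their incoming excitatory column.
    """
    if ss is None:
        ss = solve_steady_state(net, arrivals)
    if not ss.converged:
        raise TrainingError("gradient undefined: steady state did not converge")
    q = ss.q
    n = net.n_neurons
    target = np.atleast_1d(np.asarray(target, dtype=float))
    output_ids = list(output_ids)
    if len(output_ids) != target.size:
        raise GNetworkError("target length must match number of output neurons")

    r = firing_rates(net)
    D = r + arrivals.lambda_minus + net.w_minus.T @ q  # denominator aggregates
    dead = D <= 0
    if np.any(dead):
        # a zero denominator is only consistent for fully disconnected
        # (pruned) neurons, which sit at q = 0 and contribute nothing
        if np.any(q[dead] != 0.0) or np.any(arrivals.Lambda[dead] != 0.0):
            raise TrainingError("gradient undefined: zero denominator in fixed point")
        D = np.where(dead, 1.0, D)

    # Jacobian of the fixed-point map: A[i, j] = ∂f_i/∂q_j
    A = (net.w_plus.T - q[:, None] * net.w_minus.T) / D[:, None]

    g = np.zeros(n)
    g[output_ids] = q[output_ids] - target
    cost = mse_cost(q[output_ids], target)

    v = np.linalg.solve(np.eye(n) - A.T, g)

    sink = net.is_sink()
    # homeostatic neurons with an active leak: r depends on incoming
    # excitation, not on the outgoing row
    homeo = np.zeros(n, dtype=bool)
    if homeostatic_ids is not None:
        homeo[list(homeostatic_ids)] = True
        homeo &= (net.d > 0) & ~sink
    # rate-derivative factor per source neuron a: ∂f_a/∂r_a · ∂r_a/∂w(a,·)
    rate_term = np.where(sink | homeo, 0.0,
                         v * q / (D * (1.0 - np.where(sink, 0.0, net.d))))
    gw_plus = np.outer(q, v / D) - rate_term[:, None]
    gw_minus = np.outer(q, -v * q / D) - rate_term[:, None]
    # ∂r_b/∂w+(a,b) = 1/margin for homeostatic targets b
    homeo_col = np.where(homeo, v * q / (D * margin), 0.0)
    gw_plus -= homeo_col[None, :]
    np.fill_diagonal(gw_plus, 0.0)
    np.fill_diagonal(gw_minus, 0.0)
    return GradientResult(w_plus=gw_plus, w_minus=gw_minus, cost=cost, steady_state=ss)


def _project_stable(net: GNetwork, input_ids: list[int], can_ids: list[int],
                    rho: float, margin: float = TRAIN_MARGIN, max_sweeps: int = 30) -> None:
    """Keep the network inside a region where the product form provably exists.

    Sufficient condition: for every neuron,
    ``Λ_max,i + Σ_j w+(j,i) ≤ margin · r_i`` (``Λ_max = ρ`` on input
    neurons, 0 elsewhere), which bounds every excitation probability by
    ``margin`` for any encoded input with rate scale ``ρ``.  The condition
    is restored after a weight update by three homeostatic adjustments:
    input-neuron rows are scaled back up when their total rate falls below
    ``ρ/margin``; incoming excitation of sink neurons (whose rate is the
    fixed ``r_sink``) is scaled down to ``margin · r_sink``; and each
    CAN's departure probability — its leak — is recomputed so its firing
    rate keeps pace with its incoming excitation, exactly as at build
    time.  Only the leak adaptation touches non-weight parameters, so the
    learned weight structure is preserved wherever the constraint allows.
    """
    eps = 1e-12
    for _ in range(max_sweeps):
        changed = False
        for i in input_ids:
            need = rho / margin
            row_sum = net.w_plus[i].sum() + net.w_minus[i].sum()
            if row_sum <= 0:
                raise TrainingError("input neuron lost all outgoing weights")
            r_i = row_sum / (1.0 - net.d[i])
            if r_i < need - eps:
                scale = need * (1.0 - net.d[i]) / row_sum
                net.w_plus[i] *= scale
                net.w_minus[i] *= scale
                changed = True
        sink = net.is_sink()
        inexc = net.w_plus.sum(axis=0)
        can_set = set(can_ids)
        for i in np.nonzero(sink)[0]:
            if i in can_set:
                continue  # dead CANs get an adaptive sink rate below
            cap = margin * (net.r_sink[i] if net.r_sink is not None else 0.0)
            if inexc[i] > cap + eps:
                factor = cap / inexc[i] if cap > 0 else 0.0
                net.w_plus[:, i] *= factor
                changed = True
        inexc = net.w_plus.sum(axis=0)
        for i in can_ids:
            s_out = net.w_plus[i].sum() + net.w_minus[i].sum()
            if s_out <= 0:
                # dead unit: absorb its drive through the fallback sink
                # rate rather than rescaling upstream weights, which
                # would fight the input-row floor
                net.r_sink[i] = max(1.0, inexc[i] / margin)
                continue
            d_new = max(0.0, 1.0 - margin * s_out / inexc[i]) if inexc[i] > 0 else 0.0
            if abs(d_new - net.d[i]) > eps:
                net.d[i] = d_new
        if not changed:
            return
    raise TrainingError("stability projection did not converge")


def predict(
    net: GNetwork,
    layout: CANNLayout,
    sample: TrainingSample,
    enc: InputEncoding,
) -> np.ndarray:
    """Model estimate for one sample: steady-state q of the output neurons."""
    arr = cann_arrivals(layout, sample.rf_features, sample.lcf_features,
                        sample.ucf_pattern, enc)
    ss = solve_steady_state(net, arr)
    return ss.q[layout.out_ids]


@dataclass
class TrainingResult:
    net: GNetwork
    epoch_losses: list[float] = field(default_factory=list)

    def losses_frame(self):
        import pandas as pd

        return pd.DataFrame({"epoch": np.arange(len(self.epoch_losses)),
                             "mean_loss": self.epoch_losses})


def train(
    net: GNetwork,
    layout: CANNLayout,
    samples: Sequence[TrainingSample],
    settings: OptimizerSettings,
    enc: InputEncoding | None = None,
) -> TrainingResult:
    """Train a copy of ``net`` by per-sample gradient descent.

    Samples are visited in a freshly shuffled order each epoch (seeded by
    ``settings.seed``); after every update weights are clipped at zero.
    Only structurally present edges (nonzero initial weight in the
    corresponding matrix) are updated, so the declared topology is
    preserved.  Identical inputs, settings and seed give bit-identical
    results.

    The product-form steady state only exists while every neuron's
    excitation probability stays below 1; an update can step outside that
    region.  When it does, the update is reverted and the step scale is
    halved for the rest of the run — a projection onto the stable regime
    rather than a silent clip.  Training raises :class:`TrainingError` if
    the scale collapses or the loss becomes non-finite.
    """
    enc = enc or InputEncoding(rate_scale=1.0, feature_min=-4.0, feature_max=4.0)
    net = net.copy()
    rng = np.random.default_rng(settings.seed)
    mask_p = net.w_plus > 0
    mask_m = net.w_minus > 0
    out_ids = layout.out_ids
    if not out_ids:
        raise TrainingError("network has no output neurons")
    input_ids = layout.rf_ids + layout.lcf_ids + layout.ucf_ids
    can_ids = layout.can_ids
    # normalize the leak to the training margin before the first step so
    # the homeostatic gradient terms match the maintained constraint
    _project_stable(net, input_ids, can_ids, enc.rate_scale)

    arrivals = [
        cann_arrivals(layout, s.rf_features, s.lcf_features, s.ucf_pattern, enc)
        for s in samples
    ]
    lr = settings.learning_rate
    use_rms = settings.method == "rmsprop"
    if use_rms:
        msq_p = np.zeros_like(net.w_plus)
        msq_m = np.zeros_like(net.w_minus)
        beta, eps = settings.rmsprop_decay, settings.rmsprop_epsilon

    losses: list[float] = []
    lr_scale = 1.0
    prev: tuple[np.ndarray, np.ndarray] | None = None
    for epoch in range(settings.n_epochs):
        order = rng.permutation(len(samples))
        total = 0.0
        for idx in order:
            sample = samples[idx]
            try:
                grad = gradient(net, arrivals[idx], sample.target, out_ids,
                                homeostatic_ids=can_ids)
            except GNetworkError as exc:
                # the last update left the stable regime: revert and shrink
                if prev is None or lr_scale < 2.0 ** -20:
                    raise TrainingError(f"epoch {epoch}: {exc}", epoch=epoch) from exc
                net.w_plus, net.w_minus = prev[0].copy(), prev[1].copy()
                lr_scale *= 0.5
                try:
                    grad = gradient(net, arrivals[idx], sample.target, out_ids,
                                homeostatic_ids=can_ids)
                except GNetworkError as exc2:
                    raise TrainingError(f"epoch {epoch}: {exc2}", epoch=epoch) from exc2
            total += grad.cost
            if lr > 0.0:
                prev = (net.w_plus.copy(), net.w_minus.copy())
                gp = np.where(mask_p, grad.w_plus, 0.0)
                gm = np.where(mask_m, grad.w_minus, 0.0)
                if use_rms:
                    msq_p = beta * msq_p + (1 - beta) * gp * gp
                    msq_m = beta * msq_m + (1 - beta) * gm * gm
                    gp = gp / (np.sqrt(msq_p) + eps)
                    gm = gm / (np.sqrt(msq_m) + eps)
                step = lr * lr_scale
                net.w_plus = np.clip(net.w_plus - step * gp, 0.0, None)
                net.w_minus = np.clip(net.w_minus - step * gm, 0.0, None)
                # input neurons must keep a positive outgoing row (their
                # arrival stream has nowhere else to go); floor structural
                # entries so the row-sum floor in the projection can act
                for i in input_ids:
                    net.w_plus[i] = np.where(mask_p[i],
                                             np.maximum(net.w_plus[i], 1e-9),
                                             0.0)
                _project_stable(net, input_ids, can_ids, enc.rate_scale)
        mean_loss = total / max(len(samples), 1)
        if not np.isfinite(mean_loss):
            raise TrainingError(f"training diverged at epoch {epoch}", epoch=epoch)
        losses.append(mean_loss)
    return TrainingResult(net=net, epoch_losses=losses)
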