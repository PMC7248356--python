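"""Random neural network (G-network) core: model, steady state, simulator.

A G-network is a network of spiking neurons that exchange excitatory (+1)
and inhibitory (−1) impulses.  Neuron ``i`` holds a non-negative integer
potential ``k_i``; while ``k_i > 0`` it fires as a Poisson process with rate
``r_i``, each firing decrementing its own potential and sending an impulse
to neuron ``j`` with probability ``p+(i,j)`` (excitatory) or ``p-(i,j)``
(inhibitory), or leaving the network with probability ``d_i``.  External
excitatory/inhibitory impulses arrive as independent Poisson streams of
rates ``Λ_i`` / ``λ_i``.  The stationary distribution has product form:
each neuron is geometrically distributed with parameter ``q_i``, the
probability of being excited, obtained from a nonlinear fixed point.

Weights are *rates*: ``w+(i,j) = r_i · p+(i,j)`` and likewise for ``w-``,
so the weight matrices together with the departure probabilities fully
determine rates and transition probabilities.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RF",
    "LCF",
    "UCF",
    "CAN",
    "OUT",
    "FIELD_LABELS",
    "GNetworkError",
    "InconsistentNetworkError",
    "MissingParameterError",
    "ConvergenceError",
    "SaturationError",
    "DegenerateSimulationError",
    "GNetwork",
    "ExternalArrivals",
    "SteadyState",
    "NetworkState",
    "SimulationResult",
    "firing_rates",
    "transition_probabilities",
    "check_conservation",
    "is_conserving",
    "solve_steady_state",
    "stationary_probability",
    "simulate_network",
    "steady_state_report",
]

# ---------------------------------------------------------------------------
# field labels and errors

RF = "RF"      # receptive field (driving sensory input)
LCF = "LCF"    # local contextual field (modulatory parallel stream)
UCF = "UCF"    # universal contextual field (environment code)
CAN = "CAN"    # contextually-adaptive neuron (hidden unit)
OUT = "OUT"    # output neuron

FIELD_LABELS = (RF, LCF, UCF, CAN, OUT)

CONSERVATION_TOL = 1e-12
SATURATION_MARGIN = 1e-9


class GNetworkError(ValueError):
    """Base class for G-network model errors."""


class InconsistentNetworkError(GNetworkError):
    """The network parameters violate a structural invariant."""


class MissingParameterError(GNetworkError):
    """A required parameter (e.g. a sink firing rate) is absent."""


class ConvergenceError(GNetworkError):
    """The steady-state fixed point did not converge."""

    def __init__(self, message: str, residual: float | None = None) -> None:
        super().__init__(message)
        self.residual = residual


class SaturationError(GNetworkError):
    """A neuron saturated (q >= 1): the network has no product-form regime."""


class DegenerateSimulationError(GNetworkError):
    """The simulation has no events to schedule (all rates zero)."""


# ---------------------------------------------------------------------------
# model containers


@dataclass
class GNetwork:
    """A weighted spiking G-network.

    Parameters
    ----------
    w_plus, w_minus
        ``n × n`` non-negative rate-weight matrices; entry ``(i, j)`` is the
        rate at which neuron ``i`` sends excitatory / inhibitory impulses to
        neuron ``j``.  Diagonals must be zero (no self-loops).
    d
        Length-``n`` departure probabilities in ``[0, 1]``.  For a neuron
        with positive outgoing weight mass ``d < 1`` is required.
    r_sink
        Explicit firing rates for *sink* neurons (zero outgoing weight
        mass), for which the rate cannot be derived from the weights.
        Entries for non-sink neurons are ignored.
    field_label
        Per-neuron label from :data:`FIELD_LABELS`.
    """

    w_plus: np.ndarray
    w_minus: np.ndarray
    d: np.ndarray
    r_sink: np.ndarray | None = None
    field_label: list[str] = field(default_factory=list)

    FORMAT_VERSION = 1

    def __post_init__(self) -> None:
        self.w_plus = np.asarray(self.w_plus, dtype=float)
        self.w_minus = np.asarray(self.w_minus, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.r_sink is not None:
            self.r_sink = np.asarray(self.r_sink, dtype=float)
        if not self.field_label:
            self.field_label = [CAN] * self.n_neurons
        self.validate()

    @property
    def n_neurons(self) -> int:
        return self.w_plus.shape[0]

    def outgoing_mass(self) -> np.ndarray:
        """Total outgoing weight ``Σ_j [w+(i,j) + w-(i,j)]`` per neuron."""
        return self.w_plus.sum(axis=1) + self.w_minus.sum(axis=1)

    def is_sink(self) -> np.ndarray:
        """Boolean mask of neurons with no outgoing weights."""
        return self.outgoing_mass() == 0.0

    def validate(self) -> None:
        n = self.n_neurons
        for name, w in (("w_plus", self.w_plus), ("w_minus", self.w_minus)):
            if w.shape != (n, n):
                raise InconsistentNetworkError(f"{name} must be square {n}x{n}")
            if not np.all(np.isfinite(w)) or np.any(w < 0):
                raise InconsistentNetworkError(f"{name} must be finite and >= 0")
            if np.any(np.diag(w) != 0):
                raise InconsistentNetworkError(f"{name} has self-loops (nonzero diagonal)")
        if self.d.shape != (n,) or np.any(self.d < 0) or np.any(self.d > 1):
            raise InconsistentNetworkError("d must be a length-n vector in [0, 1]")
        if len(self.field_label) != n:
            raise InconsistentNetworkError("field_label length mismatch")
        for lab in self.field_label:
            if lab not in FIELD_LABELS:
                raise InconsistentNetworkError(f"unknown field label {lab!r}")
        mass = self.outgoing_mass()
        if np.any((mass > 0) & (self.d >= 1.0)):
            raise InconsistentNetworkError(
                "neuron with positive outgoing weights has departure probability 1"
            )
        if self.r_sink is not None:
            if self.r_sink.shape != (n,):
                raise InconsistentNetworkError("r_sink must be length n")
            if np.any(~np.isfinite(self.r_sink)) or np.any(self.r_sink < 0):
                raise InconsistentNetworkError("r_sink must be finite and >= 0")

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        """Serialize to a JSON document (bit-exact float round-trip)."""
        doc = {
            "format_version": self.FORMAT_VERSION,
            "n_neurons": self.n_neurons,
            "w_plus": self.w_plus.tolist(),
            "w_minus": self.w_minus.tolist(),
            "d": self.d.tolist(),
            "r_sink": None if self.r_sink is None else self.r_sink.tolist(),
            "field_label": list(self.field_label),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "GNetwork":
        doc = json.loads(text)
        if doc.get("format_version") != cls.FORMAT_VERSION:
            raise GNetworkError(f"unsupported format version {doc.get('format_version')!r}")
        r_sink = doc["r_sink"]
        return cls(
            w_plus=np.array(doc["w_plus"], dtype=float),
            w_minus=np.array(doc["w_minus"], dtype=float),
            d=np.array(doc["d"], dtype=float),
            r_sink=None if r_sink is None else np.array(r_sink, dtype=float),
            field_label=list(doc["field_label"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "GNetwork":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def copy(self) -> "GNetwork":
        return GNetwork(
            w_plus=self.w_plus.copy(),
            w_minus=self.w_minus.copy(),
            d=self.d.copy(),
            r_sink=None if self.r_sink is None else self.r_sink.copy(),
            field_label=list(self.field_label),
        )


@dataclass
class ExternalArrivals:
    """External Poisson arrival rates: excitatory ``Λ`` and inhibitory ``λ``."""

    Lambda: np.ndarray
    lambda_minus: np.ndarray

    def __post_init__(self) -> None:
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.lambda_minus = np.asarray(self.lambda_minus, dtype=float)
        for name, v in (("Lambda", self.Lambda), ("lambda_minus", self.lambda_minus)):
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise GNetworkError(f"{name} must be finite and >= 0")
        if self.Lambda.shape != self.lambda_minus.shape:
            raise GNetworkError("arrival-rate vectors must have equal length")

    @classmethod
    def zeros(cls, n: int) -> "ExternalArrivals":
        return cls(np.zeros(n), np.zeros(n))


@dataclass
class SteadyState:
    """Product-form steady state: excitation probabilities and signal rates.

    ``q[i]`` is the stationary probability that neuron ``i`` is excited
    (potential > 0); ``Q_plus`` / ``Q_minus`` are the aggregate arrival
    rates of positive / negative signals (external plus internal) at each
    neuron, the numerator and the non-rate part of the denominator of the
    fixed point ``q_i = Q+_i / (r_i + Q-_i)``.
    """

    q: np.ndarray
    Q_plus: np.ndarray
    Q_minus: np.ndarray
    converged: bool
    n_iterations: int
    residual: float


@dataclass
class NetworkState:
    """A point state of the network: integer potentials at elapsed time t."""

    k: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k)
        if np.any(self.k < 0) or not np.issubdtype(self.k.dtype, np.integer):
            raise GNetworkError("potentials must be non-negative integers")


# ---------------------------------------------------------------------------
# rates, transition probabilities, conservation


def firing_rates(net: GNetwork) -> np.ndarray:
    """Per-neuron firing rates ``r_i = (1 − d_i)^{-1} Σ_j [w+(i,j) + w-(i,j)]``.

    Sink neurons (no outgoing weights) take their explicit ``r_sink`` rate,
    since the formula above is 0/0 for them.
    """
    mass = net.outgoing_mass()
    sink = mass == 0.0
    r = np.zeros(net.n_neurons)
    if np.any(~sink):
        denom = 1.0 - net.d[~sink]
        if np.any(denom <= 0):
            raise InconsistentNetworkError("d = 1 with positive outgoing weights")
        r[~sink] = mass[~sink] / denom
    if np.any(sink):
        if net.r_sink is None:
            raise MissingParameterError("sink neurons present but r_sink not given")
        r[sink] = net.r_sink[sink]
    return r


def transition_probabilities(net: GNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Probability matrices ``p±(i,j) = w±(i,j) / r_i`` (zero rows for sinks)."""
    r = firing_rates(net)
    sink = net.is_sink()
    bad = (~sink) & (r == 0.0)
    if np.any(bad):
        raise InconsistentNetworkError("zero firing rate with positive outgoing weights")
    safe_r = np.where(r > 0, r, 1.0)
    p_plus = net.w_plus / safe_r[:, None]
    p_minus = net.w_minus / safe_r[:, None]
    p_plus[sink] = 0.0
    p_minus[sink] = 0.0
    return p_plus, p_minus


def check_conservation(net: GNetwork,
                       p_plus: np.ndarray | None = None,
                       p_minus: np.ndarray | None = None) -> np.ndarray:
    """Per-neuron total ``d_i + Σ_j [p+(i,j) + p-(i,j)]``.

    For a network whose transition probabilities derive from its weights
    this equals 1 for every neuron.  Sink neurons fire straight out of the
    network, so their departure probability is effectively 1.  Explicit
    probability matrices may be supplied to diagnose hand-built or
    corrupted parameter sets where the identity need not hold.
    """
    if p_plus is None or p_minus is None:
        p_plus, p_minus = transition_probabilities(net)
    sink = (np.asarray(p_plus).sum(axis=1) + np.asarray(p_minus).sum(axis=1)) == 0.0
    d_eff = np.where(sink, 1.0, net.d)
    return d_eff + p_plus.sum(axis=1) + p_minus.sum(axis=1)


def is_conserving(net: GNetwork, tol: float = CONSERVATION_TOL) -> bool:
    """Whether every neuron's probability mass sums to 1 within ``tol``."""
    return bool(np.all(np.abs(check_conservation(net) - 1.0) <= tol))


# ---------------------------------------------------------------------------
# steady state


def solve_steady_state(
    net: GNetwork,
    arrivals: ExternalArrivals,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    damping: float = 0.5,
    q0: np.ndarray | None = None,
    raise_on_failure: bool = True,
) -> SteadyState:
    """Solve the G-network fixed point by damped successive substitution.

    Iterates ``q_i ← (Λ_i + Σ_j q_j w+(j,i)) / (r_i + λ_i + Σ_j q_j w-(j,i))``
    from ``q = 0`` with damping, clipping iterates into ``[0, 1]``.  The map
    is monotone from 0, so the damped iteration converges whenever the
    network is stable.

    Raises
    ------
    ConvergenceError
        If the residual does not fall below ``tol`` within ``max_iter``.
    SaturationError
        If any ``q_i`` reaches 1 at the fixed point: the product-form
        stationary distribution requires ``q_i < 1``.
    """
    if tol <= 0:
        raise GNetworkError("tol must be positive")
    net.validate()
    r = firing_rates(net)
    n = net.n_neurons
    Lam = arrivals.Lambda
    lam = arrivals.lambda_minus
    if Lam.shape != (n,):
        raise GNetworkError("arrival vectors must have length n_neurons")
    wp_T = np.ascontiguousarray(net.w_plus.T)
    wm_T = np.ascontiguousarray(net.w_minus.T)

    q = np.zeros(n) if q0 is None else np.clip(np.asarray(q0, dtype=float), 0.0, 1.0)
    residual = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        num = Lam + wp_T @ q
        den = r + lam + wm_T @ q
        with np.errstate(divide="ignore", invalid="ignore"):
            q_new = np.where(den > 0, num / den, 0.0)
        q_new = np.clip(q_new, 0.0, 1.0)
        q_next = (1.0 - damping) * q_new + damping * q
        residual = float(np.max(np.abs(q_next - q)))
        q = q_next
        if residual < tol:
            break
    converged = residual < tol
    Q_plus = Lam + wp_T @ q
    Q_minus = lam + wm_T @ q
    ss = SteadyState(q=q, Q_plus=Q_plus, Q_minus=Q_minus,
                     converged=converged, n_iterations=it, residual=residual)
    if not converged and raise_on_failure:
        raise ConvergenceError(
            f"steady state did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})", residual=residual)
    if converged and np.any(q >= 1.0 - SATURATION_MARGIN):
        sat = np.nonzero(q >= 1.0 - SATURATION_MARGIN)[0].tolist()
        raise SaturationError(
            f"neurons {sat} saturated (q >= 1): network outside the product-form regime")
    return ss


def stationary_probability(ss: SteadyState, state: NetworkState | np.ndarray) -> float:
    """Product-form probability ``Π_y (1 − q_y) q_y^{k_y}`` of a joint state."""
    if not ss.converged:
        raise GNetworkError("steady state is not converged")
    k = state.k if isinstance(state, NetworkState) else np.asarray(state)
    if np.any(k < 0):
        raise GNetworkError("potentials must be non-negative")
    return float(np.prod((1.0 - ss.q) * ss.q ** k))


# ---------------------------------------------------------------------------
# event-driven simulator (independent oracle for the fixed point)


@dataclass
class SimulationResult:
    """Empirical statistics from an event-driven CTMC simulation."""

    activation: np.ndarray        # time-weighted fraction with k_i > 0
    activation_se: np.ndarray     # batch-means standard error
    total_time: float
    n_events: int
    histogram: dict[tuple[int, ...], float] | None = None  # state -> time fraction

    def report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron": np.arange(len(self.activation)),
            "activation": self.activation,
            "standard_error": self.activation_se,
        })


def simulate_network(
    net: GNetwork,
    arrivals: ExternalArrivals,
    n_events: int,
    seed: int,
    collect_histogram: bool = False,
    max_histogram_k: int = 50,
    n_batches: int = 20,
) -> SimulationResult:
    """Exact event-driven simulation of the spiking network's Markov chain.

    Competing exponential clocks: external excitatory/inhibitory arrivals at
    rates ``Λ_i`` / ``λ_i``, and firing at rate ``r_i`` for every neuron with
    positive potential.  A firing neuron decrements its own potential and,
    according to the transition probabilities, sends a +1 or −1 impulse to a
    target (negative impulses floor potentials at 0) or departs.  The run is
    terminated after ``n_events`` events, so results are fully reproducible
    from the seed.  Standard errors come from batch means over ``n_batches``
    contiguous segments, which accounts for the autocorrelation of the chain.
    """
    if n_events < 1:
        raise GNetworkError("n_events must be >= 1")
    net.validate()
    n = net.n_neurons
    r = firing_rates(net)
    p_plus, p_minus = transition_probabilities(net)
    Lam = arrivals.Lambda
    lam = arrivals.lambda_minus
    ext_rate = float(Lam.sum() + lam.sum())
    if ext_rate == 0.0 and np.all(r == 0.0):
        raise DegenerateSimulationError("all rates are zero; nothing to simulate")

    rng = random.Random(seed)
    # pre-computed outcome tables: per neuron, cumulative probability over
    # (excite j / inhibit j / depart)
    outcomes: list[list[tuple[float, int, int]]] = []  # (cum, kind, target)
    for i in range(n):
        cum = 0.0
        tab: list[tuple[float, int, int]] = []
        for j in range(n):
            if p_plus[i, j] > 0:
                cum += p_plus[i, j]
                tab.append((cum, +1, j))
        for j in range(n):
            if p_minus[i, j] > 0:
                cum += p_minus[i, j]
                tab.append((cum, -1, j))
        tab.append((math.inf, 0, -1))  # departure
        outcomes.append(tab)

    Lam_l = Lam.tolist()
    lam_l = lam.tolist()
    r_l = r.tolist()
    k = [0] * n

    total_time = 0.0
    active_time = [0.0] * n
    batch_edges = np.linspace(0, n_events, n_batches + 1).astype(int)
    batch_time: list[float] = []
    batch_active: list[list[float]] = []
    bt = 0.0
    ba = [0.0] * n
    next_edge = 1
    hist: dict[tuple[int, ...], float] | None = {} if collect_histogram else None

    rand = rng.random
    exp = rng.expovariate
    for ev in range(n_events):
        rate = ext_rate
        for i in range(n):
            if k[i] > 0:
                rate += r_l[i]
        if rate == 0.0:
            break  # absorbing empty state: no further events can occur
        dt = exp(rate)
        total_time += dt
        bt += dt
        for i in range(n):
            if k[i] > 0:
                active_time[i] += dt
                ba[i] += dt
        if hist is not None:
            key = tuple(min(x, max_histogram_k) for x in k)
            hist[key] = hist.get(key, 0.0) + dt
        # select event
        u = rand() * rate
        acc = 0.0
        done = False
        for i in range(n):
            acc += Lam_l[i]
            if u < acc:
                k[i] += 1
                done = True
                break
        if not done:
            for i in range(n):
                acc += lam_l[i]
                if u < acc:
                    if k[i] > 0:
                        k[i] -= 1
                    done = True
                    break
        if not done:
            for i in range(n):
                if k[i] > 0:
                    acc += r_l[i]
                    if u < acc:
                        k[i] -= 1
                        v = rand()
                        for cum, kind, j in outcomes[i]:
                            if v < cum:
                                if kind > 0:
                                    k[j] += 1
                                elif kind < 0 and k[j] > 0:
                                    k[j] -= 1
                                break
                        done = True
                        break
        if not done:  # numerical edge: attribute to the last positive-rate clock
            for i in range(n - 1, -1, -1):
                if k[i] > 0:
                    k[i] -= 1
                    break
        if ev + 1 == batch_edges[next_edge]:
            batch_time.append(bt)
            batch_active.append(ba)
            bt = 0.0
            ba = [0.0] * n
            if next_edge < n_batches:
                next_edge += 1

    activation = np.array(active_time) / total_time if total_time > 0 else np.zeros(n)
    bt_arr = np.array(batch_time)
    ba_arr = np.array(batch_active)
    ok = bt_arr > 0
    if ok.sum() >= 2:
        fracs = ba_arr[ok] / bt_arr[ok, None]
        se = fracs.std(axis=0, ddof=1) / math.sqrt(ok.sum())
    else:
        se = np.full(n, np.nan)
    if hist is not None:
        hist = {kk: v / total_time for kk, v in hist.items()}
    return SimulationResult(activation=activation, activation_se=se,
                            total_time=total_time, n_events=n_events, histogram=hist)


# ---------------------------------------------------------------------------
# reporting


def steady_state_report(
    net: GNetwork,
    ss: SteadyState,
    sim: SimulationResult | None = None,
) -> pd.DataFrame:
    """One row per neuron: label, q, Q+, Q−, and simulation stats if given."""
    df = pd.DataFrame({
        "neuron": np.arange(net.n_neurons),
        "label": net.field_label,
        "q": ss.q,
        "Q_plus": ss.Q_plus,
        "Q_minus": ss.Q_minus,
    })
    if sim is not None:
        df["empirical_activation"] = sim.activation
        df["standard_error"] = sim.activation_se
    return df
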