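"""Contextually-adaptive network (CANN) construction and input encoding.

A CANN is a G-network whose neurons are organised into parallel sensory
streams of contextually-adaptive neurons (CANs).  Each CAN integrates three
labeled input fields: the driving receptive field (RF, the noisy primary
stream), the local contextual field (LCF, a correlated parallel stream such
as visual articulator features) and the universal contextual field (UCF, a
binary pattern encoding the external environment).  The default
configuration expands to the reference 29-neuron network: 4 RF inputs,
4 LCF inputs, 8 UCF units, 12 CANs (2 sensory streams × 3 layers × 2 CANs)
and 1 output neuron.

Input features enter the network as pairs of external excitatory and
inhibitory Poisson rates ``(Λ, λ)``: a feature scaled to ``s ∈ [0, 1]``
becomes ``Λ = s·ρ`` and ``λ = (1 − s)·ρ`` so that total input drive is
constant and the balance carries the value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .gnet import (
    CAN,
    LCF,
    OUT,
    RF,
    UCF,
    ExternalArrivals,
    GNetwork,
    GNetworkError,
)

__all__ = [
    "CANNConfig",
    "CANNLayout",
    "InputEncoding",
    "InvalidTopologyError",
    "EncodingError",
    "build_cann",
    "encode_features",
    "block_average",
    "cann_arrivals",
]


class InvalidTopologyError(GNetworkError):
    """The configuration expands to an unusable network topology."""


class EncodingError(GNetworkError):
    """A feature vector cannot be encoded as arrival rates."""


@dataclass
class CANNConfig:
    """Declarative CANN topology.

    ``n_streams`` counts the CAN-bearing sensory streams (the acoustic RF
    stream and the visual LCF stream by default).  UCF units form a shared
    broadcast field: they connect to every CAN in all streams and layers
    and carry no CANs of their own, acting as the network's third stream.

    ``init_weight_scale`` sets the upper bound of the uniform ``(0, scale]``
    draw used for initial weights.  ``input_gain`` is the total outgoing
    excitatory rate of each input neuron; it must exceed the encoding rate
    scale ``ρ`` so that input neurons cannot saturate.  ``stability_margin``
    bounds every neuron's excitation probability away from 1 at build time
    by choosing CAN departure probabilities (leak) accordingly.
    """

    n_streams: int = 2
    n_layers: int = 3
    n_rf_inputs: int = 4
    n_lcf_inputs: int = 4
    n_ucf_units: int = 8
    cans_per_stream_layer: int = 2
    n_outputs: int = 1
    lateral_rule: str = "neighboring-streams-same-layer"
    ucf_rule: str = "broadcast-to-all-cans"
    init_weight_scale: float = 0.1
    input_gain: float = 1.25
    output_r_sink: float = 1.0
    stability_margin: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_streams < 1 or self.n_layers < 1:
            raise InvalidTopologyError("need at least one stream and one layer")
        if self.cans_per_stream_layer < 1:
            raise InvalidTopologyError("need at least one CAN per stream/layer")
        if self.n_outputs < 1:
            raise InvalidTopologyError("need at least one output neuron")
        if min(self.n_rf_inputs, self.n_lcf_inputs, self.n_ucf_units) < 0:
            raise InvalidTopologyError("input counts must be non-negative")
        if self.lateral_rule != "neighboring-streams-same-layer":
            raise InvalidTopologyError(f"unknown lateral rule {self.lateral_rule!r}")
        if self.ucf_rule != "broadcast-to-all-cans":
            raise InvalidTopologyError(f"unknown UCF rule {self.ucf_rule!r}")
        if self.init_weight_scale <= 0 or self.input_gain <= 0:
            raise InvalidTopologyError("init_weight_scale and input_gain must be positive")
        if not 0 < self.stability_margin < 1:
            raise InvalidTopologyError("stability_margin must be in (0, 1)")

    @property
    def n_cans(self) -> int:
        return self.n_streams * self.n_layers * self.cans_per_stream_layer

    @property
    def n_neurons(self) -> int:
        return (self.n_rf_inputs + self.n_lcf_inputs + self.n_ucf_units
                + self.n_cans + self.n_outputs)

    # -- config file round-trip -------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CANNConfig":
        return cls(**d)

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CANNConfig":
        path = str(path)
        with open(path) as fh:
            d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def default_file(cls) -> "CANNConfig":
        """The packaged default configuration (29-neuron reference network)."""
        from importlib.resources import files

        text = files("cannet").joinpath("data/default_cann.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class InputEncoding:
    """Feature-to-rate encoding: min-max bounds and the rate scale ρ."""

    rate_scale: float = 1.0
    feature_min: float | np.ndarray = 0.0
    feature_max: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if self.rate_scale <= 0:
            raise EncodingError("rate_scale must be positive")
        lo = np.asarray(self.feature_min, dtype=float)
        hi = np.asarray(self.feature_max, dtype=float)
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise EncodingError("encoding bounds must be finite")
        if not np.all(lo < hi):
            raise EncodingError("feature_min must be < feature_max")


@dataclass
class CANNLayout:
    """Neuron → (field, stream, layer) map for a built CANN.

    Streams are integers for sensory streams; UCF units and output neurons
    use stream −1 (shared).  Inputs sit at layer 0, CAN layers run 1..L,
    outputs at L+1.
    """

    field: list[str]
    stream: list[int]
    layer: list[int]

    def ids(self, label: str) -> list[int]:
        return [i for i, f in enumerate(self.field) if f == label]

    @property
    def rf_ids(self) -> list[int]:
        return self.ids(RF)

    @property
    def lcf_ids(self) -> list[int]:
        return self.ids(LCF)

    @property
    def ucf_ids(self) -> list[int]:
        return self.ids(UCF)

    @property
    def can_ids(self) -> list[int]:
        return self.ids(CAN)

    @property
    def out_ids(self) -> list[int]:
        return self.ids(OUT)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron": np.arange(len(self.field)),
            "field": self.field,
            "stream": self.stream,
            "layer": self.layer,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _neighbor_streams(s: int, n_streams: int) -> list[int]:
    """Adjacent stream indices (non-circular); for 2 streams each is the
    other's neighbor."""
    return [t for t in (s - 1, s + 1) if 0 <= t < n_streams]


def build_cann(config: CANNConfig) -> tuple[GNetwork, CANNLayout]:
    """Expand a :class:`CANNConfig` into a :class:`~cannet.gnet.GNetwork`.

    Structural rules: RF inputs feed the first-layer CANs of stream 0 and
    LCF inputs those of stream 1 (or stream 0 if only one stream exists);
    consecutive CAN layers are fully connected within a stream; every CAN
    projects laterally to all CANs of neighboring streams in the same
    layer; UCF units broadcast to every CAN; last-layer CANs feed the
    output neurons.  Every structural edge carries an independent
    excitatory and inhibitory learnable weight — contextual inputs can
    therefore suppress their targets directly, not only excite them.

    Initial weights are drawn uniformly from ``(0, init_weight_scale]``
    with the config seed, then input rows are rescaled to ``input_gain``
    and CAN departure probabilities are chosen so the network stays inside
    the product-form regime for any encoded input with ``ρ ≤ input_gain ·
    stability_margin`` (0.5 excitation cap at the default ρ = 1).
    """
    if config.n_cans == 0:
        raise InvalidTopologyError("configuration has zero CANs")
    n = config.n_neurons
    rng = np.random.default_rng(config.seed)

    labels: list[str] = []
    stream: list[int] = []
    layer: list[int] = []
    labels += [RF] * config.n_rf_inputs
    stream += [0] * config.n_rf_inputs
    layer += [0] * config.n_rf_inputs
    lcf_stream = min(1, config.n_streams - 1)
    labels += [LCF] * config.n_lcf_inputs
    stream += [lcf_stream] * config.n_lcf_inputs
    layer += [0] * config.n_lcf_inputs
    labels += [UCF] * config.n_ucf_units
    stream += [-1] * config.n_ucf_units
    layer += [0] * config.n_ucf_units
    can_index: dict[tuple[int, int, int], int] = {}
    for s in range(config.n_streams):
        for l in range(1, config.n_layers + 1):
            for c in range(config.cans_per_stream_layer):
                can_index[(s, l, c)] = len(labels)
                labels.append(CAN)
                stream.append(s)
                layer.append(l)
    out_start = len(labels)
    labels += [OUT] * config.n_outputs
    stream += [-1] * config.n_outputs
    layer += [config.n_layers + 1] * config.n_outputs
    layout = CANNLayout(field=labels, stream=stream, layer=layer)

    def draw() -> float:
        # uniform on (0, scale]
        return config.init_weight_scale * (1.0 - rng.random())

    w_plus = np.zeros((n, n))
    w_minus = np.zeros((n, n))

    def cans_of(s: int, l: int) -> list[int]:
        return [can_index[(s, l, c)] for c in range(config.cans_per_stream_layer)]

    # input neurons -> first-layer CANs of their stream; like every other
    # structural connection the edge carries both an excitatory and an
    # inhibitory learnable weight, so contextual fields can suppress as
    # well as amplify their targets
    for i in layout.rf_ids:
        for j in cans_of(0, 1):
            w_plus[i, j] = draw()
            w_minus[i, j] = draw()
    for i in layout.lcf_ids:
        for j in cans_of(lcf_stream, 1):
            w_plus[i, j] = draw()
            w_minus[i, j] = draw()
    # UCF broadcast to every CAN
    for i in layout.ucf_ids:
        for j in layout.can_ids:
            w_plus[i, j] = draw()
            w_minus[i, j] = draw()
    # within-stream feedforward between consecutive CAN layers
    for s in range(config.n_streams):
        for l in range(1, config.n_layers):
            for i in cans_of(s, l):
                for j in cans_of(s, l + 1):
                    w_plus[i, j] = draw()
                    w_minus[i, j] = draw()
    # lateral connections to neighboring streams, same layer
    for s in range(config.n_streams):
        for l in range(1, config.n_layers + 1):
            for t in _neighbor_streams(s, config.n_streams):
                for i in cans_of(s, l):
                    for j in cans_of(t, l):
                        w_plus[i, j] = draw()
                        w_minus[i, j] = draw()
    # last-layer CANs -> outputs
    for s in range(config.n_streams):
        for i in cans_of(s, config.n_layers):
            for o in range(config.n_outputs):
                w_plus[i, out_start + o] = draw()
                w_minus[i, out_start + o] = draw()

    # rescale input rows to a fixed total outgoing rate (> any ρ used by
    # the encoder) so input neurons cannot saturate
    input_ids = layout.rf_ids + layout.lcf_ids + layout.ucf_ids
    for i in input_ids:
        tot = w_plus[i].sum() + w_minus[i].sum()
        if tot > 0:
            w_plus[i] *= config.input_gain / tot
            w_minus[i] *= config.input_gain / tot

    # explicit sink rates: outputs use the configured rate; every other
    # neuron gets a unit fallback so that a unit whose outgoing weights
    # all decay during training becomes a well-defined absorbing sink
    r_sink = np.ones(n)
    for o in range(config.n_outputs):
        r_sink[out_start + o] = config.output_r_sink
        col = out_start + o
        tot = w_plus[:, col].sum()
        limit = config.stability_margin * config.output_r_sink
        if tot > limit:
            scale = limit / tot
            w_plus[:, col] *= scale
            w_minus[:, col] *= scale

    # CAN departure probabilities: leak so that firing rate >= incoming
    # excitation / margin, which bounds q strictly below margin
    d = np.zeros(n)
    incoming_exc = w_plus.sum(axis=0)
    for i in layout.can_ids:
        s_out = w_plus[i].sum() + w_minus[i].sum()
        if s_out <= 0:
            raise InvalidTopologyError(f"CAN {i} has no outgoing connections")
        need = incoming_exc[i] / config.stability_margin
        if need > s_out:
            d[i] = 1.0 - s_out / need

    net = GNetwork(w_plus=w_plus, w_minus=w_minus, d=d, r_sink=r_sink,
                   field_label=labels)

    # reachability: some output must be reachable from some input
    struct = (w_plus + w_minus) > 0
    frontier = set(input_ids) if input_ids else set(layout.can_ids)
    seen = set(frontier)
    while frontier:
        nxt = set()
        for i in frontier:
            for j in np.nonzero(struct[i])[0]:
                if j not in seen:
                    seen.add(int(j))
                    nxt.add(int(j))
        frontier = nxt
    if not any(o in seen for o in layout.out_ids):
        raise InvalidTopologyError("no output neuron is reachable from the inputs")
    return net, layout


# ---------------------------------------------------------------------------
# feature encoding


def encode_features(x: Sequence[float] | np.ndarray, enc: InputEncoding) -> list[tuple[float, float]]:
    """Encode a feature vector as ``(Λ, λ)`` arrival-rate pairs.

    Each feature is min-max scaled to ``s ∈ [0, 1]`` (clipping outside the
    bounds), then ``Λ = s·ρ`` and ``λ = (1 − s)·ρ``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise EncodingError("features must be finite")
    lo = np.asarray(enc.feature_min, dtype=float)
    hi = np.asarray(enc.feature_max, dtype=float)
    s = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    rho = enc.rate_scale
    return [(float(si * rho), float((1.0 - si) * rho)) for si in s]


def block_average(x: np.ndarray, n_blocks: int) -> np.ndarray:
    """Average a feature vector into ``n_blocks`` contiguous blocks.

    Used when the feature dimension differs from the number of input
    neurons (e.g. 22 filterbank coefficients onto 4 RF inputs).
    """
    x = np.asarray(x, dtype=float)
    if n_blocks < 1:
        raise EncodingError("n_blocks must be >= 1")
    if x.size < n_blocks:
        raise EncodingError("fewer features than blocks")
    return np.array([b.mean() for b in np.array_split(x, n_blocks)])


def cann_arrivals(
    layout: CANNLayout,
    rf: np.ndarray | None,
    lcf: np.ndarray | None,
    ucf: np.ndarray | None,
    enc: InputEncoding,
    ucf_enc: InputEncoding | None = None,
) -> ExternalArrivals:
    """Build the full external-arrival vector for one multimodal sample.

    RF and LCF feature vectors are block-averaged onto their input neurons
    and min-max encoded; the binary UCF pattern is encoded with unit bounds.
    Fields whose input neurons are absent may be passed as ``None``.
    """
    n = len(layout.field)
    Lam = np.zeros(n)
    lam = np.zeros(n)

    def place(ids: list[int], x, encoding: InputEncoding) -> None:
        if not ids:
            return
        if x is None:
            raise EncodingError("missing features for present input neurons")
        x = block_average(np.asarray(x, dtype=float), len(ids))
        for idx, (L, l) in zip(ids, encode_features(x, encoding)):
            Lam[idx] = L
            lam[idx] = l

    place(layout.rf_ids, rf, enc)
    place(layout.lcf_ids, lcf, enc)
    place(layout.ucf_ids, ucf, ucf_enc or InputEncoding(rate_scale=enc.rate_scale,
                                                        feature_min=0.0, feature_max=1.0))
    return ExternalArrivals(Lambda=Lam, lambda_minus=lam)
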