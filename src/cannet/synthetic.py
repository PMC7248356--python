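"""Synthetic multimodal datasets emulating audio-visual speech features.

The real task maps noisy acoustic features to clean ones, helped by a
visual (lip-derived) stream and by knowledge of the surrounding
environment.  This module generates feature-space stand-ins with the same
statistical structure:

* a *clean* feature sequence per utterance — independent first-order
  autoregressive processes with unit stationary variance (smooth
  filterbank-like trajectories);
* a noisy *RF* stream: clean features mixed with broadband Gaussian noise
  at a nominal SNR drawn per sequence from the −12…12 dB range;
* a correlated *LCF* stream: a fixed random linear projection of the
  clean features plus Gaussian noise whose level does not depend on the
  acoustic SNR — visible articulators are unaffected by acoustic noise,
  which is exactly what makes the LCF disambiguating at low SNR;
* a binary *UCF* pattern deterministically encoding the environment, which
  is itself determined by the SNR band (restaurant, cafe, public
  transport, pedestrian area, home, from noisiest to quietest);
* a *target*: one chosen clean coefficient, min-max scaled into [0, 1)
  (the network predicts one coefficient at a time).

Framing and SNR-mixing utilities used by real feature pipelines
(frame segmentation at a given rate/length/increment, exact-power SNR
mixing) are included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentSpec",
    "ENVIRONMENTS",
    "UCF_CODEBOOK",
    "SyntheticParams",
    "SyntheticDataset",
    "SyntheticDataError",
    "mix_at_snr",
    "frame_signal",
    "env_for_snr",
    "generate_dataset",
    "grid_corpus_tables",
    "corpus_sentence_totals",
]


class SyntheticDataError(ValueError):
    """Invalid parameters or inputs for synthetic-data generation."""


@dataclass(frozen=True)
class EnvironmentSpec:
    """A named environment: its SNR band and its binary UCF pattern."""

    name: str
    snr_band_db: tuple[float, float]   # half-open [lo, hi); top band closed
    ucf_pattern: tuple[int, ...]

    @property
    def mean_snr_db(self) -> float:
        return 0.5 * (self.snr_band_db[0] + self.snr_band_db[1])


# Five equal-width SNR bands over [−12, 12] dB, ordered from noisiest to
# quietest.  The 8-bit patterns are distinct codewords of a first-order
# Reed–Muller code, pairwise Hamming distance ≥ 4.
UCF_CODEBOOK: dict[str, tuple[int, ...]] = {
    "restaurant": (1, 1, 1, 1, 1, 1, 1, 1),
    "cafe": (0, 0, 0, 0, 1, 1, 1, 1),
    "public transport": (0, 0, 1, 1, 0, 0, 1, 1),
    "pedestrian area": (0, 1, 0, 1, 0, 1, 0, 1),
    "home": (0, 1, 1, 0, 0, 1, 1, 0),
}

ENVIRONMENTS: list[EnvironmentSpec] = [
    EnvironmentSpec("restaurant", (-12.0, -7.2), UCF_CODEBOOK["restaurant"]),
    EnvironmentSpec("cafe", (-7.2, -2.4), UCF_CODEBOOK["cafe"]),
    EnvironmentSpec("public transport", (-2.4, 2.4), UCF_CODEBOOK["public transport"]),
    EnvironmentSpec("pedestrian area", (2.4, 7.2), UCF_CODEBOOK["pedestrian area"]),
    EnvironmentSpec("home", (7.2, 12.0), UCF_CODEBOOK["home"]),
]


def mix_at_snr(clean: np.ndarray, noise: np.ndarray, snr_db: float) -> np.ndarray:
    """Add ``noise`` to ``clean`` rescaled to an exact power-ratio SNR.

    The noise is scaled so that ``10·log10(P_clean / P_noise_scaled)``
    equals ``snr_db`` exactly, then added to the clean signal.
    """
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if clean.shape != noise.shape:
        raise SyntheticDataError("clean and noise must have the same shape")
    p_clean = float(np.mean(clean ** 2))
    p_noise = float(np.mean(noise ** 2))
    if p_clean == 0.0 or p_noise == 0.0:
        raise SyntheticDataError("clean and noise must have non-zero power")
    scale = np.sqrt(p_clean / (p_noise * 10.0 ** (snr_db / 10.0)))
    return clean + scale * noise


def frame_signal(signal: Sequence[float], sample_rate: float, frame_ms: float,
                 increment_pct: float) -> np.ndarray:
    """Segment a 1-D signal into frames.

    Frame length is ``round(sample_rate · frame_ms / 1000)`` samples and
    the hop is ``round(increment_pct/100 · frame_length)`` samples (an
    increment of 62.5% means consecutive frames overlap by 37.5%).  A
    trailing partial frame is discarded.
    """
    if sample_rate <= 0 or frame_ms <= 0 or increment_pct <= 0:
        raise SyntheticDataError("rate, frame length and increment must be positive")
    signal = np.asarray(signal, dtype=float)
    frame_len = round(sample_rate * frame_ms / 1000.0)
    if frame_len < 1:
        raise SyntheticDataError("frame length is zero samples")
    hop = round(increment_pct / 100.0 * frame_len)
    if hop < 1:
        raise SyntheticDataError("hop is zero samples")
    if signal.size < frame_len:
        return np.empty((0, frame_len))
    n_frames = (signal.size - frame_len) // hop + 1
    return np.stack([signal[i * hop:i * hop + frame_len] for i in range(n_frames)])


def env_for_snr(snr_db: float) -> EnvironmentSpec:
    """Deterministic environment lookup for an SNR in [−12, 12] dB.

    Bands are left-closed/right-open except the top band, which includes
    its right edge.
    """
    if not -12.0 <= snr_db <= 12.0:
        raise SyntheticDataError(f"SNR {snr_db} dB outside [-12, 12]")
    for spec in ENVIRONMENTS:
        lo, hi = spec.snr_band_db
        if lo <= snr_db < hi:
            return spec
    return ENVIRONMENTS[-1]  # snr_db == 12.0


@dataclass
class SyntheticParams:
    """Generation parameters for a synthetic multimodal dataset."""

    n_sequences: int = 40
    sequence_length: int = 10
    feature_dim: int = 4
    lcf_dim: int = 4
    ar_coeff: float = 0.9          # temporal smoothness of clean features
    lcf_noise_sd: float = 0.4      # visual-stream noise, SNR-independent
    target_dim: int = 0            # which clean coefficient is predicted
    target_margin: float = 0.05    # targets scaled into [margin, 1 - margin]

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.sequence_length < 1:
            raise SyntheticDataError("need at least one sequence and one frame")
        if self.feature_dim < 1 or self.lcf_dim < 1:
            raise SyntheticDataError("feature dimensions must be positive")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise SyntheticDataError("ar_coeff must be in [0, 1)")
        if self.lcf_noise_sd < 0:
            raise SyntheticDataError("lcf_noise_sd must be >= 0")
        if not 0 <= self.target_dim < self.feature_dim:
            raise SyntheticDataError("target_dim out of range")
        if not 0.0 < self.target_margin < 0.5:
            raise SyntheticDataError("target_margin must be in (0, 0.5)")


@dataclass
class SyntheticDataset:
    """Generated records plus everything needed to reproduce/de-scale them."""

    frame: pd.DataFrame
    params: SyntheticParams
    seed: int
    target_bounds: tuple[float, float]   # raw clean-coefficient min/max
    lcf_map: np.ndarray                  # fixed linear map clean -> LCF

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def rf(self) -> np.ndarray:
        return self.frame[[f"rf_{i}" for i in range(self.params.feature_dim)]].to_numpy()

    def lcf(self) -> np.ndarray:
        return self.frame[[f"lcf_{i}" for i in range(self.params.lcf_dim)]].to_numpy()

    def clean(self) -> np.ndarray:
        return self.frame[[f"clean_{i}" for i in range(self.params.feature_dim)]].to_numpy()

    def ucf(self) -> np.ndarray:
        return self.frame[[f"ucf_{i}" for i in range(8)]].to_numpy()

    def targets(self) -> np.ndarray:
        return self.frame["target"].to_numpy()

    def descale_target(self, scaled: np.ndarray) -> np.ndarray:
        """Map model outputs in [0, 1) back to raw coefficient units."""
        lo, hi = self.target_bounds
        m = self.params.target_margin
        return (np.asarray(scaled) - m) / (1.0 - 2.0 * m) * (hi - lo) + lo

    def to_csv(self, path, sidecar: str | None = None) -> None:
        self.frame.to_csv(path, index=False)
        if sidecar is not None:
            doc = {
                "params": asdict(self.params),
                "seed": self.seed,
                "target_bounds": list(self.target_bounds),
                "lcf_map": self.lcf_map.tolist(),
            }
            with open(sidecar, "w") as fh:
                json.dump(doc, fh)

    @classmethod
    def from_csv(cls, path, sidecar) -> "SyntheticDataset":
        frame = pd.read_csv(path)
        with open(sidecar) as fh:
            doc = json.load(fh)
        return cls(frame=frame, params=SyntheticParams(**doc["params"]),
                   seed=doc["seed"], target_bounds=tuple(doc["target_bounds"]),
                   lcf_map=np.array(doc["lcf_map"]))


def generate_dataset(params: SyntheticParams, seed: int) -> SyntheticDataset:
    """Generate a fully seeded synthetic multimodal dataset.

    Per sequence: a nominal SNR is drawn uniformly over [−12, 12] dB (the
    five equal-width bands therefore occur with equal probability), the
    environment and its UCF pattern follow deterministically, clean
    features evolve as unit-variance AR(1) processes, the RF stream is the
    clean sequence mixed with white noise at exactly the nominal SNR, and
    the LCF stream is a fixed unit-row-norm linear projection of the clean
    features plus Gaussian noise of sd ``lcf_noise_sd``.
    """
    rng = np.random.default_rng(seed)
    p = params
    # fixed linear map with unit-norm rows: each LCF component is a clean
    # projection with correlation 1/sqrt(1 + sd^2) to its noiseless value
    M = rng.standard_normal((p.lcf_dim, p.feature_dim))
    M /= np.linalg.norm(M, axis=1, keepdims=True)

    rows: list[dict] = []
    raw_targets: list[float] = []
    a = p.ar_coeff
    innov_sd = np.sqrt(1.0 - a * a)
    for s in range(p.n_sequences):
        snr = float(rng.uniform(-12.0, 12.0))
        env = env_for_snr(snr)
        clean = np.empty((p.sequence_length, p.feature_dim))
        clean[0] = rng.standard_normal(p.feature_dim)
        for t in range(1, p.sequence_length):
            clean[t] = a * clean[t - 1] + innov_sd * rng.standard_normal(p.feature_dim)
        noise = rng.standard_normal(clean.shape)
        rf = mix_at_snr(clean, noise, snr)
        lcf = clean @ M.T + p.lcf_noise_sd * rng.standard_normal((p.sequence_length, p.lcf_dim))
        for t in range(p.sequence_length):
            row = {"sequence": s, "t": t, "env": env.name, "snr_db": snr}
            for i in range(p.feature_dim):
                row[f"clean_{i}"] = clean[t, i]
                row[f"rf_{i}"] = rf[t, i]
            for i in range(p.lcf_dim):
                row[f"lcf_{i}"] = lcf[t, i]
            for i, b in enumerate(env.ucf_pattern):
                row[f"ucf_{i}"] = b
            rows.append(row)
            raw_targets.append(clean[t, p.target_dim])

    frame = pd.DataFrame(rows)
    raw = np.array(raw_targets)
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        hi = lo + 1.0
    m = p.target_margin
    frame["target"] = m + (1.0 - 2.0 * m) * (raw - lo) / (hi - lo)
    return SyntheticDataset(frame=frame, params=p, seed=seed,
                            target_bounds=(lo, hi), lcf_map=M)


# ---------------------------------------------------------------------------
# corpus bookkeeping worked example (printed per-speaker sentence counts)

_GRID_SENTENCES = pd.DataFrame({
    "speaker": [1, 2, 3, 4, 5],
    "grid_id": ["S1", "S15", "S26", "S6", "S7"],
    "full_sentences": [1000, 1000, 1000, 1000, 1000],
    "full_removed": [11, 164, 16, 9, 11],
    "full_used": [989, 836, 984, 991, 989],
    "aligned_removed": [11, 164, 71, 9, 11],
    "aligned_used": [989, 836, 929, 991, 989],
})

_GRID_SPLITS = pd.DataFrame({
    "speaker": [1, 2, 3, 4, 5],
    "train": [692, 585, 650, 693, 692],
    "validation": [99, 84, 93, 99, 99],
    "test": [198, 167, 186, 199, 198],
    "total": [989, 836, 929, 991, 989],
})

GRID_PRINTED_TOTALS = {"train": 3312, "validation": 474, "test": 948, "total": 4734}


def grid_corpus_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-speaker sentence bookkeeping of the 5-speaker corpus subset."""
    return _GRID_SENTENCES.copy(), _GRID_SPLITS.copy()


def corpus_sentence_totals() -> dict[str, int]:
    """Grand totals computed by summing the per-speaker sentence counts."""
    _, splits = grid_corpus_tables()
    return {c: int(splits[c].sum()) for c in ("train", "validation", "test", "total")}
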