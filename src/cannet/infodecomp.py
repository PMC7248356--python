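"""Four-variable information decomposition for contextual networks.

Quantifies how the output ``Y`` of a contextually-adaptive processor
shares information with its three input fields — receptive field ``X``,
local contextual field ``Z`` and universal contextual field ``U`` — from
a discretized joint probability table.  All quantities are in bits
(``0·log 0 := 0``).

The signed four-way interaction term

    I(X;Y;Z;U) = I(X;Y) − I(X;Y|Z,U)

is negative for synergistic relations (XOR-like) and positive for
redundant ones.  The output-entropy decomposition

    H(Y) ≈ I(Y;X;Z;U) + I(Y;X|Z,U) + I(Y;Z|X,U) + I(Y;U|X,Z) + H(Y|X,Z,U)

is not an identity for general distributions: the residual equals
``I(Y;Z|X) − I(Y;Z|X,U)`` and is reported alongside the terms.  The
weighted objective ``F = φ0·I4 + φ1·I(Y;X|Z,U) + φ2·I(Y;Z|X,U) +
φ3·I(Y;U|X,Z) + φ4·H(Y|X,Z,U)`` selects particular shared-information
terms through its ``φ`` weights (e.g. φ0 = φ1 = 1, rest 0 gives
``F = I(Y;X)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "AXES",
    "JointPMF",
    "ObjectiveWeights",
    "DecompositionReport",
    "InteractionInfo",
    "InfoError",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "four_way_interaction",
    "decompose_output_entropy",
    "estimate_pmf",
]

AXES = ("X", "Z", "U", "Y")
_LN2 = np.log(2.0)


class InfoError(ValueError):
    """Invalid arguments to an information-theoretic operation."""


@dataclass
class JointPMF:
    """Discrete joint probability table over named axes.

    ``table`` is an N-dimensional array of probabilities; ``axes`` names
    each dimension (default ``(X, Z, U, Y)``); ``bin_edges`` stores the
    discretization grid when the table was estimated from samples.
    """

    table: np.ndarray
    axes: tuple[str, ...] = AXES
    bin_edges: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        self.axes = tuple(self.axes)
        if self.table.ndim != len(self.axes):
            raise InfoError("table rank must match number of axis names")
        if np.any(self.table < 0):
            raise InfoError("probabilities must be non-negative")
        if abs(self.table.sum() - 1.0) > 1e-12:
            raise InfoError("probabilities must sum to 1")

    def axis_indices(self, names: Iterable[str]) -> tuple[int, ...]:
        names = list(names)
        for nm in names:
            if nm not in self.axes:
                raise InfoError(f"unknown axis {nm!r}")
        if len(set(names)) != len(names):
            raise InfoError("duplicate axes")
        return tuple(self.axes.index(nm) for nm in names)

    def marginal(self, names: Sequence[str]) -> np.ndarray:
        keep = self.axis_indices(names)
        drop = tuple(i for i in range(self.table.ndim) if i not in keep)
        m = self.table.sum(axis=drop)
        return np.transpose(m, axes=_reorder(keep))

    def to_frame(self) -> pd.DataFrame:
        idx = np.array(list(np.ndindex(*self.table.shape)))
        df = pd.DataFrame(idx, columns=[f"bin_{a}" for a in self.axes])
        df["probability"] = self.table.ravel()
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, axes: tuple[str, ...] = AXES) -> "JointPMF":
        df = pd.read_csv(path)
        cols = [f"bin_{a}" for a in axes]
        shape = tuple(int(df[c].max()) + 1 for c in cols)
        table = np.zeros(shape)
        table[tuple(df[c].to_numpy() for c in cols)] = df["probability"].to_numpy()
        return cls(table=table, axes=axes)


def _reorder(keep: tuple[int, ...]) -> tuple[int, ...]:
    # after summing, remaining dims appear in sorted(keep) order; permute to
    # the caller's requested order
    sorted_keep = sorted(keep)
    return tuple(sorted_keep.index(k) for k in keep)


@dataclass
class ObjectiveWeights:
    """Weights φ0..φ4 of the information objective, each in [−1, 1]."""

    phi0: float = 1.0
    phi1: float = 1.0
    phi2: float = 1.0
    phi3: float = 1.0
    phi4: float = 1.0

    def __post_init__(self) -> None:
        for name in ("phi0", "phi1", "phi2", "phi3", "phi4"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise InfoError(f"{name} must lie in [-1, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.phi0, self.phi1, self.phi2, self.phi3, self.phi4])


def _entropy_of(p: np.ndarray) -> float:
    return float(-xlogy(p, p).sum() / _LN2)


def entropy(pmf: JointPMF, axes: Sequence[str]) -> float:
    """Shannon entropy (bits) of the marginal over the given axes."""
    if not axes:
        raise InfoError("axes must be non-empty")
    return _entropy_of(pmf.marginal(axes))


def conditional_entropy(pmf: JointPMF, target_axes: Sequence[str],
                        given_axes: Sequence[str]) -> float:
    """``H(target | given) = H(target ∪ given) − H(given)`` in bits."""
    t, g = set(target_axes), set(given_axes)
    if t & g:
        raise InfoError("target and conditioning axes must be disjoint")
    if not g:
        return entropy(pmf, target_axes)
    return entropy(pmf, list(target_axes) + list(given_axes)) - entropy(pmf, given_axes)


def mutual_information(pmf: JointPMF, axes_a: Sequence[str],
                       axes_b: Sequence[str]) -> float:
    """``I(A;B) = H(A) − H(A|B)`` in bits (symmetric in A and B)."""
    a, b = set(axes_a), set(axes_b)
    if a & b:
        raise InfoError("axis sets must be disjoint")
    return entropy(pmf, axes_a) - conditional_entropy(pmf, axes_a, axes_b)


def conditional_mutual_information(pmf: JointPMF, axes_a: Sequence[str],
                                   axes_b: Sequence[str],
                                   given_axes: Sequence[str]) -> float:
    """``I(A;B|G) = H(B|G) − H(B|A,G)`` in bits; non-negative."""
    a, b, g = set(axes_a), set(axes_b), set(given_axes)
    if a & b or a & g or b & g:
        raise InfoError("axis sets must be pairwise disjoint")
    return (conditional_entropy(pmf, axes_b, given_axes)
            - conditional_entropy(pmf, axes_b, list(axes_a) + list(given_axes)))


@dataclass
class InteractionInfo:
    """Four-way interaction term with its expression diagnostics.

    ``value`` is the canonical form ``I(X;Y) − I(X;Y|Z,U)``; the five
    pairwise-anchored expressions are not equal for general distributions,
    so ``expressions`` and ``max_discrepancy`` report how far they spread.
    """

    value: float
    expressions: dict[str, float]
    max_discrepancy: float


def four_way_interaction(pmf: JointPMF) -> InteractionInfo:
    """Signed four-way interaction among X, Y, Z, U (bits)."""
    for ax in AXES:
        if ax not in pmf.axes:
            raise InfoError(f"axis {ax!r} missing from pmf")
    pairs = [("X", "Y"), ("X", "Z"), ("X", "U"), ("Y", "Z"), ("Y", "U")]
    exprs: dict[str, float] = {}
    for a, b in pairs:
        rest = [c for c in AXES if c not in (a, b)]
        exprs[f"I({a};{b})-I({a};{b}|{','.join(rest)})"] = (
            mutual_information(pmf, [a], [b])
            - conditional_mutual_information(pmf, [a], [b], rest)
        )
    vals = list(exprs.values())
    spread = max(abs(x - y) for x in vals for y in vals)
    return InteractionInfo(value=vals[0], expressions=exprs, max_discrepancy=spread)


@dataclass
class DecompositionReport:
    """Terms of the output-entropy decomposition plus the objective F."""

    interaction: float           # I(Y;X;Z;U), Y-anchored canonical form
    i_yx_given_zu: float
    i_yz_given_xu: float
    i_yu_given_xz: float
    h_y_given_xzu: float
    h_y: float
    residual: float
    objective: float
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)

    def terms(self) -> dict[str, float]:
        return {
            "I(Y;X;Z;U)": self.interaction,
            "I(Y;X|Z,U)": self.i_yx_given_zu,
            "I(Y;Z|X,U)": self.i_yz_given_xu,
            "I(Y;U|X,Z)": self.i_yu_given_xz,
            "H(Y|X,Z,U)": self.h_y_given_xzu,
            "H(Y)": self.h_y,
            "residual": self.residual,
            "F": self.objective,
        }

    def to_json(self) -> str:
        doc = dict(self.terms())
        doc["phi"] = self.weights.as_array().tolist()
        return json.dumps(doc, indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"quantity": k, "bits": v} for k, v in self.terms().items()
        ])


def decompose_output_entropy(pmf: JointPMF, phis: ObjectiveWeights | None = None) -> DecompositionReport:
    """Decompose H(Y) into interaction, conditional-MI and noise terms.

    The interaction term uses the Y-anchored expression ``I(Y;X) −
    I(Y;X|Z,U)``.  The residual ``H(Y) − (sum of the five terms)`` is
    reported rather than assumed zero; analytically it equals
    ``I(Y;Z|X) − I(Y;Z|X,U)``.
    """
    phis = phis or ObjectiveWeights()
    i4 = (mutual_information(pmf, ["Y"], ["X"])
          - conditional_mutual_information(pmf, ["Y"], ["X"], ["Z", "U"]))
    i_yx = conditional_mutual_information(pmf, ["X"], ["Y"], ["Z", "U"])
    i_yz = conditional_mutual_information(pmf, ["Z"], ["Y"], ["X", "U"])
    i_yu = conditional_mutual_information(pmf, ["U"], ["Y"], ["X", "Z"])
    h_cond = conditional_entropy(pmf, ["Y"], ["X", "Z", "U"])
    h_y = entropy(pmf, ["Y"])
    residual = h_y - (i4 + i_yx + i_yz + i_yu + h_cond)
    w = phis.as_array()
    objective = float(np.dot(w, [i4, i_yx, i_yz, i_yu, h_cond]))
    return DecompositionReport(
        interaction=i4, i_yx_given_zu=i_yx, i_yz_given_xu=i_yz,
        i_yu_given_xz=i_yu, h_y_given_xzu=h_cond, h_y=h_y,
        residual=residual, objective=objective, weights=phis)


def estimate_pmf(x: np.ndarray, z: np.ndarray, u: np.ndarray, y: np.ndarray,
                 n_bins: int = 8) -> JointPMF:
    """Plug-in estimate of the joint (X, Z, U, Y) pmf by equal-width binning.

    Each variable is binned over its observed range; a constant column
    collapses to a single degenerate bin.
    """
    cols = [np.asarray(c, dtype=float).ravel() for c in (x, z, u, y)]
    n = cols[0].size
    if n == 0:
        raise InfoError("need at least one sample")
    if any(c.size != n for c in cols):
        raise InfoError("columns must have equal length")
    if n_bins < 2:
        raise InfoError("n_bins must be >= 2")
    edges = []
    for c in cols:
        lo, hi = float(c.min()), float(c.max())
        if lo == hi:
            edges.append(np.array([lo - 0.5, hi + 0.5]))
        else:
            edges.append(np.linspace(lo, hi, n_bins + 1))
    hist, _ = np.histogramdd(np.column_stack(cols), bins=edges)
    table = hist / hist.sum()
    return JointPMF(table=table, axes=AXES,
                    bin_edges={a: e for a, e in zip(AXES, edges)})
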