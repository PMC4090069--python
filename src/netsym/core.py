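"""Pair decomposition of a weighted directed adjacency matrix and the symmetry measure.

A network of ``N`` neurons without self-edges is described by an ``N x N``
matrix ``W`` of non-negative synaptic efficacies, ``w_ij`` being the strength
of the connection from presynaptic neuron ``j`` onto postsynaptic neuron ``i``
(row = postsynaptic, column = presynaptic; the measure itself is
transpose-invariant so the orientation only matters for the simulator).

Each unordered neuron pair ``(i, j)``, ``i < j``, is mapped to the single
variable

    z = |w_ij - w_ji| / (w_ij + w_ji)

so that ``z = 0`` for a perfectly reciprocal pair and ``z = 1`` for a strictly
one-way pair.  Pairs with both weights zero carry no information (and would be
0/0), so they are excluded and only tallied.  The symmetry measure of the
network is

    s = 1 - (1/P) * sum_k z_k,     P = N(N-1)/2 - n0,

where ``n0`` counts the excluded (0, 0) pairs and ``P`` the pairs with at
least one nonzero connection.  ``s`` is close to 1 for a network dominated by
bidirectional (reciprocal) motifs and close to 0 for unidirectional motifs,
with no weight thresholding and no dependence on the maximal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class ValidationError(ValueError):
    """An input matrix violates the weighted-adjacency invariants."""


class UndefinedMeasureError(ValueError):
    """The symmetry measure is undefined (no pair has a nonzero connection)."""


@dataclass(frozen=True)
class WeightMatrix:
    """Validated non-negative weighted adjacency matrix with zero diagonal.

    Parameters
    ----------
    weights
        ``N x N`` array, ``weights[i, j]`` = efficacy of the connection from
        neuron ``j`` to neuron ``i``.  Entries must lie in ``[0, w_max]`` and
        the diagonal must be exactly zero.
    w_max
        Upper bound on the synaptic efficacy (default 1; the measure is scale
        invariant so this is a convention, not a restriction).
    """

    weights: np.ndarray
    w_max: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"matrix not square: shape {w.shape}")
        if w.shape[0] < 2:
            raise ValidationError("need at least 2 neurons")
        if self.w_max <= 0:
            raise ValidationError("w_max must be positive")
        def _idx(mask: np.ndarray) -> tuple:
            i, j = np.argwhere(mask)[0]
            return (int(i), int(j))

        if not np.all(np.isfinite(w)):
            raise ValidationError(f"non-finite weight at index {_idx(~np.isfinite(w))}")
        if np.any(w < 0):
            raise ValidationError(f"negative weight at index {_idx(w < 0)}")
        if np.any(w > self.w_max):
            raise ValidationError(
                f"weight above w_max={self.w_max} at index {_idx(w > self.w_max)}"
            )
        diag = np.argwhere(np.diag(w) != 0.0)
        if diag.size:
            i = int(diag[0][0])
            raise ValidationError(f"nonzero diagonal entry at index ({i}, {i})")

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_array(cls, w: np.ndarray, w_max: Optional[float] = None) -> "WeightMatrix":
        """Wrap an array, inferring ``w_max`` as max(1, largest entry) if not given."""
        w = np.asarray(w, dtype=float)
        if w_max is None:
            w_max = max(1.0, float(w.max())) if w.size else 1.0
        return cls(weights=w, w_max=w_max)


@dataclass(frozen=True)
class PairDecomposition:
    """Per-pair variables for all unordered neuron pairs with u > 0.

    Arrays ``i, j, u, v, z`` are aligned and hold only the *counted* pairs
    (at least one nonzero weight): ``u = w_ij + w_ji``, ``v = |w_ij - w_ji|``,
    ``z = v/u``.  ``n_zero_pairs`` counts the excluded (0, 0) pairs.
    """

    i: np.ndarray
    j: np.ndarray
    u: np.ndarray
    v: np.ndarray
    z: np.ndarray
    n_zero_pairs: int
    n_counted: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_counted", int(self.z.size))


@dataclass
class SymmetryReport:
    """Result of evaluating (and optionally testing) the symmetry measure."""

    s: float
    n_counted: int
    n_zero_pairs: int
    z_score: Optional[float] = None
    p_value: Optional[float] = None
    verdict: str = "untested"
    alpha: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "s": self.s,
            "n_counted": self.n_counted,
            "n_zero_pairs": self.n_zero_pairs,
            "z_score": self.z_score,
            "p_value": self.p_value,
            "verdict": self.verdict,
            "alpha": self.alpha,
        }


def _as_weight_matrix(W) -> WeightMatrix:
    if isinstance(W, WeightMatrix):
        return W
    return WeightMatrix.from_array(np.asarray(W, dtype=float))


def pair_decompose(W, floor: float = 0.0) -> PairDecomposition:
    """Decompose a weight matrix into its unordered-pair variables.

    Parameters
    ----------
    W
        :class:`WeightMatrix` or array-like (validated on the fly).
    floor
        Detection floor: weights ``<= floor`` are treated as zero before the
        decomposition (default 0, i.e. only exact zeros are excluded).  This
        models the experimental reality that very small efficacies are not
        measurable.
    """
    wm = _as_weight_matrix(W)
    w = wm.weights
    if floor < 0:
        raise ValidationError("floor must be non-negative")
    if floor > 0:
        w = np.where(w <= floor, 0.0, w)
    n = wm.n_neurons
    iu, ju = np.triu_indices(n, k=1)
    a = w[iu, ju]
    b = w[ju, iu]
    u = a + b
    v = np.abs(a - b)
    counted = u > 0
    n_zero = int(np.count_nonzero(~counted))
    z = v[counted] / u[counted]
    return PairDecomposition(
        i=iu[counted],
        j=ju[counted],
        u=u[counted],
        v=v[counted],
        z=z,
        n_zero_pairs=n_zero,
    )


def symmetry_measure(W, floor: float = 0.0) -> SymmetryReport:
    """Compute the symmetry measure ``s`` of a weight matrix.

    Returns a :class:`SymmetryReport` with ``verdict='untested'`` (use
    :func:`netsym.inference.significance_test` to attach a verdict).

    Raises
    ------
    UndefinedMeasureError
        If every pair is (0, 0): the measure is 0/0 and deliberately *not*
        reported as 0 or 1.
    """
    dec = pair_decompose(W, floor=floor)
    if dec.n_counted == 0:
        raise UndefinedMeasureError(
            "undefined measure: all pairs have both weights zero"
        )
    s = 1.0 - float(np.mean(dec.z))
    return SymmetryReport(
        s=s, n_counted=dec.n_counted, n_zero_pairs=dec.n_zero_pairs
    )
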