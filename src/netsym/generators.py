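"""Network ensemble generators: random, symmetric, asymmetric, prescribed-s.

These are the reference ensembles against which the symmetry measure is
calibrated: random i.i.d. networks define the null, mirrored (symmetric) and
shuffled one-way (asymmetric) networks bracket the measure from above and
below, and prescribed-s networks span the whole ``s in (0, 1)`` range to map
the relation between the measure and motif fractions.  Pruning — permanent
removal of individual directed connections with probability ``p`` — is always
applied *after* the structural construction, so it can break symmetry (a
mirrored network appears increasingly asymmetric as ``p`` grows) but cannot
raise the measure of a strictly one-way network.

Every generator accepts either a ``seed`` or a live ``numpy.random.Generator``
(``rng=``), and is deterministic for a given seed.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from netsym.core import ValidationError, WeightMatrix
from netsym.null_stats import ConfigurationError, NullModelSpec, sample_weights

PruningMask = np.ndarray  # boolean N x N, True = connection permanently removed


def _rng(seed: Optional[int], rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def apply_pruning(
    W: WeightMatrix,
    p: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[WeightMatrix, PruningMask]:
    """Prune each off-diagonal connection independently with probability p.

    Returns the pruned matrix and the boolean mask (True = removed; the
    diagonal is True by convention).  The mask is what a simulator must hold
    fixed: a pruned connection's efficacy remains zero at all times.
    """
    if not 0.0 <= p < 1.0:
        raise ConfigurationError("pruning probability must be in [0, 1)")
    g = _rng(seed, rng)
    n = W.n_neurons
    mask = g.random((n, n)) < p
    np.fill_diagonal(mask, True)
    w = W.weights.copy()
    w[mask] = 0.0
    return WeightMatrix(weights=w, w_max=W.w_max), mask


def random_network(
    n: int,
    spec: NullModelSpec,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> WeightMatrix:
    """Fully random network: i.i.d. family draws off-diagonal, then pruning."""
    if n < 2:
        raise ValidationError("need at least 2 neurons")
    g = _rng(seed, rng)
    w = sample_weights(spec, (n, n), g)
    np.fill_diagonal(w, 0.0)
    if spec.prune_p > 0.0:
        mask = g.random((n, n)) < spec.prune_p
        np.fill_diagonal(mask, True)
        w[mask] = 0.0
    return WeightMatrix(weights=w, w_max=spec.w_max)


def symmetric_network(
    n: int,
    spec: NullModelSpec,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> WeightMatrix:
    """Mirrored network: upper triangle drawn from the family, lower = mirror.

    Pruning (if ``spec.prune_p > 0``) acts per directed connection *after*
    mirroring, so it can remove one side of a reciprocal pair — the mechanism
    by which a structurally symmetric network appears asymmetric under
    pruning.
    """
    if n < 2:
        raise ValidationError("need at least 2 neurons")
    g = _rng(seed, rng)
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    vals = sample_weights(spec, iu.size, g)
    w[iu, ju] = vals
    w[ju, iu] = vals
    W = WeightMatrix(weights=w, w_max=spec.w_max)
    if spec.prune_p > 0.0:
        W, _ = apply_pruning(W, spec.prune_p, rng=g)
    return W


def asymmetric_network(
    n: int,
    spec: NullModelSpec,
    eps: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> WeightMatrix:
    """One-way network: per pair one strong family draw, the other side in [0, eps].

    ``eps = 0`` gives strict unidirectionality (s = 0 exactly); a small
    positive ``eps`` reproduces the "one connection set to a small value"
    construction.  Which direction is strong is chosen uniformly at random
    (the shuffle).  Pruning is applied afterwards and cannot raise the
    measure: surviving pairs are still one-sided.
    """
    if n < 2:
        raise ValidationError("need at least 2 neurons")
    if eps < 0 or eps >= spec.w_max:
        raise ConfigurationError("eps must satisfy 0 <= eps < w_max")
    g = _rng(seed, rng)
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    strong = sample_weights(spec, iu.size, g)
    weak = g.uniform(0.0, eps, size=iu.size) if eps > 0 else np.zeros(iu.size)
    flip = g.random(iu.size) < 0.5
    w[iu, ju] = np.where(flip, strong, weak)
    w[ju, iu] = np.where(flip, weak, strong)
    W = WeightMatrix(weights=w, w_max=spec.w_max)
    if spec.prune_p > 0.0:
        W, _ = apply_pruning(W, spec.prune_p, rng=g)
    return W


def prescribed_s_network(
    n: int,
    s_target: float,
    spec: NullModelSpec,
    sigma_z: float = 0.05,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> WeightMatrix:
    """Network whose pair variables are drawn around ``z = 1 - s_target``.

    Per unordered pair: the larger weight ``a`` is drawn from the family, the
    pair variable ``z`` from ``Normal(1 - s_target, sigma_z)`` clipped to
    ``[0, 1]``, and the smaller weight is ``a (1-z)/(1+z)`` (the inversion of
    the z definition), so both weights stay within bounds by construction.
    Drawing the *larger* weight from the family (rather than an arbitrary
    half of the connections) slightly changes the marginals but guarantees
    the bounds; the measured s is marginal-independent.  ``z`` clipped at 1
    gives a strictly one-way pair with the smaller weight exactly 0.
    """
    if not 0.0 < s_target < 1.0:
        raise ConfigurationError("s_target must be strictly inside (0, 1)")
    if sigma_z <= 0:
        raise ConfigurationError("sigma_z must be positive")
    if n < 2:
        raise ValidationError("need at least 2 neurons")
    g = _rng(seed, rng)
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    a = sample_weights(spec, iu.size, g)
    z = np.clip(g.normal(1.0 - s_target, sigma_z, size=iu.size), 0.0, 1.0)
    b = a * (1.0 - z) / (1.0 + z)
    flip = g.random(iu.size) < 0.5
    w[iu, ju] = np.where(flip, a, b)
    w[ju, iu] = np.where(flip, b, a)
    W = WeightMatrix(weights=w, w_max=spec.w_max)
    if spec.prune_p > 0.0:
        W, _ = apply_pruning(W, spec.prune_p, rng=g)
    return W
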