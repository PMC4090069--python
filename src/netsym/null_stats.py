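"""Null distributions of the pair variable z and the symmetry measure s.

For a network whose weights are i.i.d. draws from a family (uniform on
``[w_min, w_max]`` or a narrow truncated Gaussian centred in the interval),
each off-diagonal entry additionally *pruned* (set permanently to zero) with
probability ``p``, the pair variable ``z = |a - b| / (a + b)`` has a known
distribution, and the symmetry measure is a sample mean of i.i.d. ``z`` values
over the ``P`` counted pairs.  Hence

    mu_s    = 1 - mu_z
    var_s   = var_z / E[P],      E[P] = (1 - p^2) N(N-1)/2

(a pair survives the pruning with probability ``1 - p^2``).

Conditioned on a pair being counted, the two pruning outcomes mix exactly:

    both weights alive      with weight (1-p)^2 / (1-p^2) = (1-p)/(1+p)
    exactly one alive (z=1) with weight 2p(1-p) / (1-p^2) = 2p/(1+p)

giving the exact mixture identity used throughout:

    E[z^k; p] = [ (1-p) E[z^k; 0] + 2p ] / (1 + p).

For the uniform family on the unit interval the unpruned moments are closed
form: ``E[z] = 2 ln 2 - 1`` and ``E[z^2] = 3 - 4 ln 2``.  For the truncated
Gaussian family they are obtained by 2-D numerical quadrature over the two
weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional

import numpy as np
from scipy import integrate, stats


class ConfigurationError(ValueError):
    """A null-model specification violates its invariants."""


#: truncation mass allowed outside [w_min, w_max] for the Gaussian family
_GAUSS_TRUNCATION_TOL = 1e-4

# Unpruned uniform closed forms: E[z] = 2 ln2 - 1, E[z^2] = 3 - 4 ln2.
MU_Z_UNIFORM = 2.0 * math.log(2.0) - 1.0
M2_Z_UNIFORM = 3.0 - 4.0 * math.log(2.0)


@dataclass(frozen=True)
class NullModelSpec:
    """Specification of the random-weights null model.

    Parameters
    ----------
    family
        ``"uniform"`` or ``"gaussian"`` (truncated Gaussian).
    w_min, w_max
        Weight bounds (defaults 0, 1; the measure is scale invariant).
    mu, sigma
        Gaussian mean and standard deviation.  The mean must sit at the centre
        of ``[w_min, w_max]`` and sigma must be small enough that the mass
        outside the bounds is below 1e-4, so the truncated Gaussian is
        effectively Gaussian.  Default sigma 0.1 (variance 0.01).
    prune_p
        Probability that an individual directed connection is permanently
        removed; must be in ``[0, 1)`` (at ``p = 1`` no counted pair exists).
    """

    family: str = "uniform"
    w_min: float = 0.0
    w_max: float = 1.0
    mu: float = 0.5
    sigma: float = 0.1
    prune_p: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "gaussian"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if not self.w_min < self.w_max:
            raise ConfigurationError("w_min must be below w_max")
        if not 0.0 <= self.prune_p < 1.0:
            raise ConfigurationError("prune_p must be in [0, 1)")
        if self.family == "gaussian":
            centre = 0.5 * (self.w_min + self.w_max)
            if abs(self.mu - centre) > 1e-9 * max(1.0, abs(centre)):
                raise ConfigurationError(
                    "gaussian mean must sit at the centre of [w_min, w_max] "
                    f"(got mu={self.mu}, centre={centre})"
                )
            if self.sigma <= 0:
                raise ConfigurationError("sigma must be positive")
            half = 0.5 * (self.w_max - self.w_min)
            mass_out = 2.0 * stats.norm.sf(half / self.sigma)
            if mass_out >= _GAUSS_TRUNCATION_TOL:
                raise ConfigurationError(
                    "gaussian too wide for the bounds: truncated mass "
                    f"{mass_out:.2e} >= {_GAUSS_TRUNCATION_TOL:.0e}; "
                    "the distribution has to be narrow enough"
                )

    def _key(self) -> tuple:
        return (self.family, self.w_min, self.w_max, self.mu, self.sigma)


@dataclass(frozen=True)
class NullStatistics:
    """Moments of z and s under a null model, with provenance."""

    mu_z: float
    var_z: float
    mu_s: float
    var_s: float
    expected_counted_pairs: float
    method: str  # closed_form | quadrature | monte_carlo
    n_neurons: Optional[int] = None
    n_networks: Optional[int] = None
    seed: Optional[int] = None

    @property
    def sigma_s(self) -> float:
        return math.sqrt(self.var_s)

    def to_dict(self) -> dict:
        return {
            "mu_z": self.mu_z,
            "var_z": self.var_z,
            "mu_s": self.mu_s,
            "var_s": self.var_s,
            "expected_counted_pairs": self.expected_counted_pairs,
            "method": self.method,
            "n_neurons": self.n_neurons,
            "n_networks": self.n_networks,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class DensityBundle:
    """Explicit mixture densities of w, u = a+b and v = |a-b| under a null model.

    Continuous parts carry total mass ``weight_continuous``; the pruning
    contribution (pairs with exactly one weight alive, which sit on the line
    ``v = u``) carries mass ``weight_line`` and is described by the 1-D
    density ``line_density`` along ``u``.  ``pdf_w`` is the continuous part of
    the single-weight density (mass ``1 - p``; the remaining atom of mass
    ``p`` sits at zero and is reported as ``w_atom``).
    """

    spec: NullModelSpec
    pdf_w: Callable[[np.ndarray], np.ndarray]
    pdf_u: Callable[[np.ndarray], np.ndarray]
    pdf_v: Callable[[np.ndarray], np.ndarray]
    pdf_joint: Callable[[np.ndarray, np.ndarray], np.ndarray]
    line_density: Callable[[np.ndarray], np.ndarray]
    weight_continuous: float
    weight_line: float
    w_atom: float
    u_support: tuple = field(default=(0.0, 2.0))
    v_support: tuple = field(default=(0.0, 1.0))


def _weight_pdf(spec: NullModelSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Unpruned single-weight density on [w_min, w_max]."""
    if spec.family == "uniform":
        lo, hi = spec.w_min, spec.w_max
        h = 1.0 / (hi - lo)

        def pdf(w):
            w = np.asarray(w, dtype=float)
            return np.where((w >= lo) & (w <= hi), h, 0.0)

        return pdf
    a = (spec.w_min - spec.mu) / spec.sigma
    b = (spec.w_max - spec.mu) / spec.sigma
    dist = stats.truncnorm(a, b, loc=spec.mu, scale=spec.sigma)
    return dist.pdf


def null_densities(spec: NullModelSpec) -> DensityBundle:
    """Build the mixture densities of w, u and v for a null model.

    Conditioned on the pair being counted, the continuous (both-alive) part
    has mixture weight ``(1-p)/(1+p)`` and the pruning part (one weight alive,
    concentrated on ``v = u``) has weight ``2p/(1+p)``; (0, 0) pairs are
    excluded by construction.
    """
    p = spec.prune_p
    c_alive = (1.0 - p) / (1.0 + p)
    c_line = 2.0 * p / (1.0 + p)
    lo, hi = spec.w_min, spec.w_max
    pdf_w_unpruned = _weight_pdf(spec)

    if spec.family == "uniform":
        width = hi - lo

        def pdf_u_cont(u):
            u = np.asarray(u, dtype=float)
            # triangular on [2lo, 2hi]
            t = (u - 2 * lo) / width
            tri = np.where(
                (t >= 0) & (t <= 2), (1.0 - np.abs(t - 1.0)) / width, 0.0
            )
            return tri

        def pdf_v_cont(v):
            v = np.asarray(v, dtype=float)
            t = v / width
            return np.where((t >= 0) & (t <= 1), 2.0 * (1.0 - t) / width, 0.0)

        def pdf_joint_cont(u, v):
            u = np.asarray(u, dtype=float)
            v = np.asarray(v, dtype=float)
            inside = (
                (v >= 0)
                & (v <= u - 2 * lo)
                & (u + v <= 2 * hi)
                & (u >= 2 * lo)
            )
            return np.where(inside, 1.0 / width**2, 0.0)

    else:
        sig_u = math.sqrt(2.0) * spec.sigma
        u_dist = stats.norm(loc=2.0 * spec.mu, scale=sig_u)
        v_dist = stats.halfnorm(loc=0.0, scale=sig_u)
        pdf_u_cont = u_dist.pdf
        pdf_v_cont = v_dist.pdf

        def pdf_joint_cont(u, v):
            # u and v are uncorrelated for the Gaussian family (measured
            # |rho| << 1), so the halved bivariate normal factorises.
            return pdf_u_cont(u) * pdf_v_cont(np.abs(v))

    def pdf_w(w):
        return (1.0 - p) * pdf_w_unpruned(w)

    def pdf_u(u):
        return c_alive * pdf_u_cont(u) + c_line * pdf_w_unpruned(u)

    def pdf_v(v):
        return c_alive * pdf_v_cont(v) + c_line * pdf_w_unpruned(v)

    def pdf_joint(u, v):
        return c_alive * pdf_joint_cont(u, v)

    def line_density(u):
        # density along u of the one-alive contribution (v = u exactly)
        return c_line * pdf_w_unpruned(u)

    return DensityBundle(
        spec=spec,
        pdf_w=pdf_w,
        pdf_u=pdf_u,
        pdf_v=pdf_v,
        pdf_joint=pdf_joint,
        line_density=line_density,
        weight_continuous=c_alive,
        weight_line=c_line,
        w_atom=p,
        u_support=(2 * lo, 2 * hi),
        v_support=(0.0, hi - lo),
    )


@lru_cache(maxsize=64)
def _unpruned_z_moments(key: tuple) -> tuple:
    """(E[z], E[z^2]) for the unpruned family; closed form or quadrature."""
    family, w_min, w_max, mu, sigma = key
    if family == "uniform" and w_min == 0.0:
        # scale invariance: any [0, c] interval gives the unit-square values
        return (MU_Z_UNIFORM, M2_Z_UNIFORM)
    if family == "uniform":
        # non-zero w_min: no closed form needed elsewhere; integrate directly
        def pdf_scalar(x):
            return 1.0 / (w_max - w_min)
    else:
        # fast scalar truncated-normal pdf (the scipy frozen pdf is far too
        # slow inside adaptive quadrature)
        z_lo = (w_min - mu) / sigma
        z_hi = (w_max - mu) / sigma
        norm_const = 1.0 / (
            sigma
            * math.sqrt(2 * math.pi)
            * (stats.norm.cdf(z_hi) - stats.norm.cdf(z_lo))
        )

        def pdf_scalar(x):
            return norm_const * math.exp(-0.5 * ((x - mu) / sigma) ** 2)

    # |a-b| has a kink on the diagonal: integrate the smooth half-domain
    # b < a and double (the integrand is symmetric in a <-> b)
    def make_integrand(power):
        def f(b, a):
            z = (a - b) / (a + b)
            return 2.0 * z**power * pdf_scalar(a) * pdf_scalar(b)

        return f

    opts = dict(epsabs=1e-10, epsrel=1e-10)
    m1, err1 = integrate.dblquad(
        make_integrand(1), w_min, w_max, w_min, lambda a: a, **opts
    )
    m2, err2 = integrate.dblquad(
        make_integrand(2), w_min, w_max, w_min, lambda a: a, **opts
    )
    if err1 > 1e-8 or err2 > 1e-8:
        raise ArithmeticError(
            f"quadrature did not converge: error estimates {err1:.1e}, {err2:.1e}"
        )
    return (m1, m2)


def _mix(m0: float, p: float) -> float:
    """Exact pruning mixture of an unpruned z-moment (one-alive pairs have z=1)."""
    return ((1.0 - p) * m0 + 2.0 * p) / (1.0 + p)


def moments_z(spec: NullModelSpec) -> tuple:
    """Mean and variance of the pair variable z under the null model.

    Uniform family: closed forms ``E[z] = 2 ln 2 - 1``,
    ``E[z^2] = 3 - 4 ln 2``.  Gaussian family: 2-D quadrature of
    ``z = |a-b|/(a+b)`` over the two truncated-Gaussian weights.  Pruning is
    applied through the exact mixture identity.
    """
    m1_0, m2_0 = _unpruned_z_moments(spec._key())
    p = spec.prune_p
    m1 = _mix(m1_0, p)
    m2 = _mix(m2_0, p)
    return (m1, m2 - m1 * m1)


def expected_counted_pairs(spec: NullModelSpec, n_neurons: int) -> float:
    """E[P]: pairs surviving pruning, ``(1 - p^2) N(N-1)/2``."""
    return (1.0 - spec.prune_p**2) * n_neurons * (n_neurons - 1) / 2.0


def moments_s(spec: NullModelSpec, n_neurons: int) -> NullStatistics:
    """Analytic mean and variance of the symmetry measure for an N-neuron network."""
    if n_neurons < 2:
        raise ConfigurationError("n_neurons must be at least 2")
    mu_z, var_z = moments_z(spec)
    ep = expected_counted_pairs(spec, n_neurons)
    method = "closed_form" if spec.family == "uniform" else "quadrature"
    return NullStatistics(
        mu_z=mu_z,
        var_z=var_z,
        mu_s=1.0 - mu_z,
        var_s=var_z / ep,
        expected_counted_pairs=ep,
        method=method,
        n_neurons=n_neurons,
    )


def sample_weights(
    spec: NullModelSpec, size, rng: np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. *unpruned* weights from the family.

    The truncated Gaussian is sampled by rejection from the parent normal
    (exact, and the rejection rate is negligible under the narrowness
    invariant).
    """
    if spec.family == "uniform":
        return rng.uniform(spec.w_min, spec.w_max, size=size)
    out = rng.normal(spec.mu, spec.sigma, size=size)
    bad = (out < spec.w_min) | (out > spec.w_max)
    while np.any(bad):
        out[bad] = rng.normal(spec.mu, spec.sigma, size=int(np.count_nonzero(bad)))
        bad = (out < spec.w_min) | (out > spec.w_max)
    return out


def mc_null_statistics(
    spec: NullModelSpec,
    n_neurons: int,
    n_networks: int,
    seed: int,
) -> NullStatistics:
    """Monte-Carlo null statistics of s over independently generated networks."""
    from netsym.core import symmetry_measure
    from netsym.generators import random_network

    if n_networks < 2:
        raise ConfigurationError("n_networks must be at least 2")
    rng = np.random.default_rng(seed)
    s_values = np.empty(n_networks)
    for m in range(n_networks):
        W = random_network(n_neurons, spec, rng=rng)
        s_values[m] = symmetry_measure(W).s
    mu_s = float(np.mean(s_values))
    var_s = float(np.var(s_values, ddof=1))
    return NullStatistics(
        mu_z=1.0 - mu_s,
        var_z=var_s * expected_counted_pairs(spec, n_neurons),
        mu_s=mu_s,
        var_s=var_s,
        expected_counted_pairs=expected_counted_pairs(spec, n_neurons),
        method="monte_carlo",
        n_neurons=n_neurons,
        n_networks=n_networks,
        seed=seed,
    )


def correlation_uv(spec: NullModelSpec, n_samples: int, seed: int) -> float:
    """Sample Pearson correlation between u = a+b and v = |a-b|.

    Computed for the unpruned model (the pruning contribution is handled as a
    separate mixture component, so only the both-alive part matters).  For the
    Gaussian family the correlation is numerically negligible, which is what
    licenses factorising the joint density of (u, v).
    """
    if spec.prune_p != 0.0:
        raise ConfigurationError("correlation_uv is defined for prune_p = 0")
    if n_samples < 2:
        raise ConfigurationError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    a = sample_weights(spec, n_samples, rng)
    b = sample_weights(spec, n_samples, rng)
    u = a + b
    v = np.abs(a - b)
    if np.std(u) == 0.0 or np.std(v) == 0.0:
        raise ConfigurationError("degenerate weights: correlation undefined")
    r, _ = stats.pearsonr(u, v)
    return float(r)
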