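"""Significance testing of an observed symmetry measure, and motif classification.

Over random networks the symmetry measure is a mean of many i.i.d. pair
variables, so its null distribution is well approximated by a Gaussian with
the analytic moments from :mod:`netsym.null_stats`.  The hypothesis test asks
how many standard deviations the observed ``s`` sits away from the null mean
and converts that into a p-value; rejection with ``s`` above the null mean is
read as significantly *symmetric* connectivity, rejection below as
significantly *asymmetric*, and non-rejection as consistent with randomness.

The same null also fixes the motif threshold ``z_bar = 1 - mu_s``: a counted
pair with ``z > z_bar`` behaves like a unidirectional (single-edge) motif, the
rest like bidirectional (reciprocal) motifs, tying the single-parameter
measure back to the classical motif counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from netsym.core import SymmetryReport, UndefinedMeasureError, pair_decompose
from netsym.null_stats import ConfigurationError, NullStatistics


@dataclass(frozen=True)
class MotifSummary:
    """Fractions of unidirectional vs bidirectional motifs among counted pairs."""

    z_threshold: float
    frac_unidirectional: float
    frac_bidirectional: float
    n_counted: int

    def to_dict(self) -> dict:
        return {
            "z_threshold": self.z_threshold,
            "frac_unidirectional": self.frac_unidirectional,
            "frac_bidirectional": self.frac_bidirectional,
            "n_counted": self.n_counted,
        }


def significance_test(
    s_obs: float,
    null: NullStatistics,
    alpha: float = 0.05,
    sided: str = "two",
    n_counted: int = 0,
    n_zero_pairs: int = 0,
) -> SymmetryReport:
    """Test an observed s against a Gaussian null.

    Parameters
    ----------
    s_obs
        Observed symmetry measure.
    null
        Null moments (analytic or Monte-Carlo) for the matching family,
        pruning level and network size.
    alpha
        Significance level (default 0.05).
    sided
        ``"two"`` (default, conservative), ``"greater"`` (test for symmetry)
        or ``"less"`` (test for asymmetry).
    """
    if null.var_s <= 0.0:
        raise ConfigurationError("degenerate null: var_s must be positive")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must be in (0, 1)")
    if sided not in ("two", "greater", "less"):
        raise ConfigurationError(f"unknown sidedness {sided!r}")
    z = (s_obs - null.mu_s) / null.sigma_s
    if sided == "two":
        p = 2.0 * stats.norm.sf(abs(z))
    elif sided == "greater":
        p = float(stats.norm.sf(z))
    else:
        p = float(stats.norm.cdf(z))
    p = min(float(p), 1.0)
    if p < alpha:
        verdict = "symmetric" if s_obs > null.mu_s else "asymmetric"
    else:
        verdict = "random"
    return SymmetryReport(
        s=s_obs,
        n_counted=n_counted,
        n_zero_pairs=n_zero_pairs,
        z_score=float(z),
        p_value=p,
        verdict=verdict,
        alpha=alpha,
    )


def evaluate_matrix(W, null: NullStatistics, alpha: float = 0.05, sided: str = "two") -> SymmetryReport:
    """Convenience: measure a matrix and test it in one call."""
    from netsym.core import symmetry_measure

    rep = symmetry_measure(W)
    return significance_test(
        rep.s, null, alpha=alpha, sided=sided,
        n_counted=rep.n_counted, n_zero_pairs=rep.n_zero_pairs,
    )


def motif_threshold(null: NullStatistics) -> float:
    """Motif threshold ``z_bar = 1 - mu_s`` of the matching null model."""
    return 1.0 - null.mu_s


def classify_motifs(W, z_threshold: float) -> MotifSummary:
    """Classify each counted pair as unidirectional (z > threshold) or bidirectional.

    Ties (``z == z_threshold``) count as bidirectional: the unidirectional
    class requires strict exceedance.
    """
    if not 0.0 <= z_threshold <= 1.0:
        raise ConfigurationError("z_threshold must be in [0, 1]")
    dec = pair_decompose(W)
    if dec.n_counted == 0:
        raise UndefinedMeasureError(
            "undefined motif fractions: all pairs have both weights zero"
        )
    uni = int(np.count_nonzero(dec.z > z_threshold))
    return MotifSummary(
        z_threshold=z_threshold,
        frac_unidirectional=uni / dec.n_counted,
        frac_bidirectional=1.0 - uni / dec.n_counted,
        n_counted=dec.n_counted,
    )
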