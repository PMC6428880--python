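"""Poisson Mixture Model (PMM) for the stationary metabolite distribution.

Under separation of timescales the metabolite, conditioned on the total
enzyme copy number ``n_etot``, relaxes to a Poisson law whose parameter is
the saturating function

    lambda(n_etot) = lambda_inf / (1 + K / n_etot)          (reversible)
    lambda(n_etot) = slope * n_etot                          (irreversible)

so that the full stationary distribution is the mixture

    P(n_p) = sum_n  P(n_etot = n) * Poisson(n_p; lambda(n)).

The first mixture component, Poisson(n_p; 0), is a point mass at zero: the
probability of carrying no enzyme maps exactly onto the probability of an
empty metabolite pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import special, stats

from .params import (
    RateConstants,
    effective_kinetics,
    saturation,
)
from .gene_expression import DiscretePMF, DEFAULT_TRUNCATION_TOL, _finalize

__all__ = [
    "PoissonParameterMap",
    "poisson_parameter",
    "reduced_propensities",
    "pmm_distribution",
]


@dataclass(frozen=True)
class PoissonParameterMap:
    """The map n_etot -> lambda(n_etot) driving the Poisson modes.

    ``mode`` is "reversible" (saturating lambda with parameters
    ``lambda_inf`` and ``K``) or "irreversible" (lambda linear in the
    enzyme number with coefficient ``linear_slope``).  lambda(0) = 0 in
    both modes.
    """

    mode: str
    lambda_inf: Optional[float] = None
    K: Optional[float] = None
    linear_slope: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode == "reversible":
            if not (self.lambda_inf and self.lambda_inf > 0
                    and self.K and self.K > 0):
                raise ValueError("reversible mode requires lambda_inf > 0 and K > 0")
        elif self.mode == "irreversible":
            if not (self.linear_slope and self.linear_slope > 0):
                raise ValueError("irreversible mode requires linear_slope > 0")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_effective(cls, lambda_inf: float, K: float) -> "PoissonParameterMap":
        """Build a reversible map directly from (lambda_inf, K)."""
        return cls(mode="reversible", lambda_inf=lambda_inf, K=K)

    def lam(self, n_etot: Union[int, np.ndarray]) -> Union[float, np.ndarray]:
        """Poisson parameter lambda(n_etot) for integer enzyme numbers."""
        n = np.asarray(n_etot, dtype=float)
        if np.any(n < 0):
            raise ValueError("n_etot must be non-negative")
        if self.mode == "irreversible":
            out = self.linear_slope * n
        else:
            with np.errstate(divide="ignore"):
                out = np.where(n > 0, self.lambda_inf / (1.0 + self.K / np.where(n > 0, n, 1.0)), 0.0)
        if np.isscalar(n_etot) or np.ndim(n_etot) == 0:
            return float(out)
        return out

    __call__ = lam


def poisson_parameter(rc: RateConstants) -> PoissonParameterMap:
    """Poisson-parameter map implied by the rate constants.

    Reversible catalysis (k_rev > 0) gives the saturating map from
    (lambda_inf, K); irreversible catalysis gives the linear map with slope
    k_1 n_s k_cat / ((k_1 n_s + k_m1) k_c).
    """
    if rc.k_rev == 0.0:
        slope = rc.k_1 * rc.n_s * rc.k_cat / ((rc.k_1 * rc.n_s + rc.k_m1) * rc.k_c)
        return PoissonParameterMap(mode="irreversible", linear_slope=slope)
    ek = effective_kinetics(rc)
    return PoissonParameterMap.from_effective(ek.lambda_inf, ek.K)


def reduced_propensities(rc: RateConstants, n_etot: int) -> tuple:
    """Effective birth/death propensities of the reduced metabolite process.

    With substrate binding equilibrated, the conditional means of free
    enzyme and complex are E(n_e) = (1 - epsilon) n_etot and
    E(n_c) = epsilon n_etot with epsilon = k_1 n_s/(k_1 n_s + k_m1); the
    metabolite then follows a birth-death process with

        birth  = k_cat * epsilon * n_etot                  (zeroth order)
        death  = (k_rev * (1 - epsilon) * n_etot + k_c)    (per molecule)

    Returns ``(birth, death_coeff)`` where ``death_coeff`` multiplies the
    current metabolite number.  The stationary law is Poisson with
    parameter ``birth / death_coeff``, which coincides with
    ``poisson_parameter(rc).lam(n_etot)``.
    """
    if n_etot < 0:
        raise ValueError("n_etot must be >= 0")
    eps = saturation(rc)
    birth = rc.k_cat * eps * n_etot
    death_coeff = rc.k_rev * (1.0 - eps) * n_etot + rc.k_c
    return birth, death_coeff


def conditional_enzyme_split(rc: RateConstants, n_etot: int) -> tuple:
    """Quasi-equilibrium conditional means (E(n_e), E(n_c)) given n_etot."""
    eps = saturation(rc)
    return (1.0 - eps) * n_etot, eps * n_etot


def _mode_support_cap(lam_max: float, tol: float) -> int:
    """Upper metabolite support for the largest Poisson mode.

    Per-mode truncation at mean + 12 sqrt(mean) + 30 or at the cumulative
    tolerance, whichever is larger.
    """
    cap = int(lam_max + 12.0 * math.sqrt(lam_max) + 30.0)
    if lam_max > 0:
        cap = max(cap, int(stats.poisson(lam_max).ppf(1.0 - 0.1 * tol)) + 1)
    return cap


def pmm_distribution(enzyme_pmf: DiscretePMF, pmap: PoissonParameterMap,
                     truncation_tol: float = DEFAULT_TRUNCATION_TOL) -> DiscretePMF:
    """Assemble the Poisson mixture P(n_p) from an enzyme pmf and a lambda map.

    The metabolite support is chosen so that the combined truncated mass
    (enzyme tail plus Poisson tails) is below ``truncation_tol``; the
    truncated enzyme tail is reported in the result's ``tail_mass_bound``
    rather than being lumped into the last mode.  The mass at n_p = 0
    includes the enzyme zero-probability exactly.
    """
    if not (0 < truncation_tol < 1):
        raise ValueError("truncation_tol must be in (0, 1)")
    weights = enzyme_pmf.probs
    lams = pmap.lam(np.arange(weights.size))
    cap = _mode_support_cap(float(lams.max()), truncation_tol)
    n_p = np.arange(cap + 1, dtype=float)
    log_fact = special.gammaln(n_p + 1.0)
    probs = np.zeros(cap + 1)
    # Poisson(n_p; 0) is a point mass at zero
    zero_modes = lams == 0.0
    probs[0] += weights[zero_modes].sum()
    active = np.nonzero(~zero_modes)[0]
    # chunked weights @ Poisson-pmf matrix, in log space for the pmf rows
    for start in range(0, active.size, 64):
        idx = active[start:start + 64]
        lam_col = lams[idx][:, None]
        log_pmf = n_p[None, :] * np.log(lam_col) - lam_col - log_fact[None, :]
        probs += weights[idx] @ np.exp(log_pmf)
    out = _finalize(probs, "pmm",
                    {"mode": pmap.mode, "lambda_inf": pmap.lambda_inf,
                     "K": pmap.K, "linear_slope": pmap.linear_slope,
                     "enzyme_provenance": enzyme_pmf.provenance})
    if out.tail_mass_bound > truncation_tol + enzyme_pmf.tail_mass_bound:
        raise AssertionError(
            "metabolite truncation exceeded the requested tolerance; "
            f"tail={out.tail_mass_bound:.3e}"
        )
    return out


def pmm_moments(enzyme_pmf: DiscretePMF, pmap: PoissonParameterMap) -> tuple:
    """Exact (mean, variance) of the mixture by the laws of total moments.

    mean = E[lambda(N)], variance = E[lambda(N)] + Var[lambda(N)] over the
    enzyme distribution; useful as an oracle for the assembled pmf.
    """
    weights = enzyme_pmf.probs
    lams = pmap.lam(np.arange(weights.size))
    m = float(np.dot(weights, lams))
    v = m + float(np.dot(weights, (lams - m) ** 2))
    return m, v
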