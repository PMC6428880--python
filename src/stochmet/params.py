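"""Model parameters, derived effective kinetics and timescale diagnostics.

The model couples a reversible Michaelis-Menten reaction (substrate + enzyme
<-> complex <-> metabolite + enzyme, with first-order metabolite consumption)
to the three-stage gene-expression model (promoter on/off switching,
transcription, translation, mRNA degradation, dilution of enzyme and complex
by growth).  Everything downstream of the stochastic machinery is summarised
by a handful of derived quantities defined here:

* ``EffectiveKinetics`` -- the pair (lambda_inf, K) that parameterises the
  saturating Poisson rate ``lambda(n_etot) = lambda_inf / (1 + K/n_etot)`` of
  the metabolite given total enzyme, plus the enzyme saturation ``epsilon``.
* ``ThreeStageParams`` -- the dimensionless gene-expression parameters
  (gamma, a, b, alpha_plus, alpha_minus) of the stationary protein
  distribution.

All rate constants are in SI seconds (per second, or per second per molecule
for bimolecular steps); copy numbers are molecules per cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "RateConstants",
    "EffectiveKinetics",
    "ThreeStageParams",
    "TimescaleReport",
    "IrreversibleRegimeError",
    "effective_kinetics",
    "three_stage_params",
    "timescale_diagnostics",
    "load_rate_constants",
    "preset",
    "effective_preset",
    "PRESETS",
    "EFFECTIVE_PRESETS",
]

#: Symbol order shared by config files, the SSA kernel and the CME oracle.
PARAM_NAMES = (
    "n_s", "k_1", "k_m1", "k_cat", "k_rev", "k_c",
    "k_tx", "k_tl", "k_on", "k_off", "k_deg", "delta",
)


class IrreversibleRegimeError(ValueError):
    """Raised when (lambda_inf, K) are requested for k_rev = 0.

    With irreversible catalysis the Poisson rate grows linearly in the
    enzyme copy number and the saturating (lambda_inf, K) parameterisation
    does not exist; callers must branch to the linear form instead.
    """


@dataclass(frozen=True)
class RateConstants:
    """Kinetic and gene-expression rate constants plus substrate copy number.

    Parameters
    ----------
    n_s : int
        Substrate copy number, held constant (open system far from
        equilibrium).
    k_1, k_m1 : float
        Substrate-enzyme binding (s^-1 molecule^-1) and complex dissociation
        (s^-1).
    k_cat, k_rev : float
        Forward catalysis (s^-1) and reverse catalysis (s^-1 molecule^-1).
    k_c : float
        First-order metabolite consumption by downstream pathways (s^-1).
    k_tx, k_tl : float
        Transcription (from the active promoter) and translation rates (s^-1).
    k_on, k_off : float
        Promoter activation / deactivation rates (s^-1).
    k_deg : float
        mRNA degradation rate (s^-1); mRNA is removed by degradation only.
    delta : float
        Dilution rate constant of free enzyme and complex by growth (s^-1).
    """

    n_s: int
    k_1: float
    k_m1: float
    k_cat: float
    k_rev: float
    k_c: float
    k_tx: float
    k_tl: float
    k_on: float
    k_off: float
    k_deg: float
    delta: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n_s, (int,)) and self.n_s > 0):
            raise ValueError(f"n_s must be a positive integer, got {self.n_s!r}")
        may_be_zero = {"k_rev", "k_on", "k_off"}
        for name in PARAM_NAMES[1:]:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if name in may_be_zero:
                if value < 0:
                    raise ValueError(f"{name} must be >= 0, got {value!r}")
            elif value <= 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")

    @property
    def doubling_time(self) -> float:
        """Cell doubling time ln(2)/delta in seconds."""
        return math.log(2.0) / self.delta

    @property
    def promoter_activity(self) -> float:
        """Stationary probability of the active promoter state."""
        return self.k_on / (self.k_on + self.k_off)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **changes) -> "RateConstants":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def scaled_binding(self, factor: float) -> "RateConstants":
        """Scale the fast binding/unbinding pair (k_1, k_m1) by 1/factor.

        The joint scaling leaves epsilon, lambda_inf and K (and hence the
        whole Poisson mixture prediction) exactly invariant while reducing
        the rate of the fast reactions; it is used to run long validation
        simulations at reduced timescale separation.
        """
        if factor <= 0:
            raise ValueError("factor must be positive")
        return self.with_(k_1=self.k_1 / factor, k_m1=self.k_m1 / factor)


@dataclass(frozen=True)
class EffectiveKinetics:
    """Effective kinetic summary (lambda_inf, K, epsilon) of the reaction.

    ``lambda_inf`` is the saturated Poisson parameter (molecules/cell),
    ``K`` the enzyme copy number at which the rate reaches half of
    ``lambda_inf`` (molecules/cell), and ``epsilon`` in (0, 1) the enzyme
    saturation k_1 n_s / (k_1 n_s + k_m1).
    """

    lambda_inf: float
    K: float
    epsilon: float


@dataclass(frozen=True)
class ThreeStageParams:
    """Dimensionless parameters of the three-stage expression model.

    gamma = (k_on + k_off)/delta, a = k_tx/delta, b = k_tl/k_deg and
    alpha_plus/alpha_minus are the roots of
    x^2 - (a + gamma) x + a k_on/delta = 0, so that
    alpha_plus * alpha_minus = a k_on/delta and
    alpha_plus + alpha_minus = a + gamma.  With this root product the
    distribution degenerates correctly at the promoter limits: k_on = 0
    gives a point mass at zero and k_off = 0 the negative binomial of an
    always-active gene.
    """

    gamma: float
    a: float
    b: float
    alpha_plus: float
    alpha_minus: float

    @property
    def mean_protein(self) -> float:
        """Stationary mean protein copy number a * b * k_on/(k_on + k_off).

        In terms of the roots: alpha_plus*alpha_minus/gamma equals
        a*k_on/(k_on+k_off), so the mean is b*alpha_plus*alpha_minus/gamma.
        """
        return self.b * self.alpha_plus * self.alpha_minus / self.gamma


def effective_kinetics(rc: RateConstants) -> EffectiveKinetics:
    """Compute (lambda_inf, K, epsilon) from the rate constants.

    lambda_inf = n_s k_cat k_1 / (k_rev k_m1) and
    K = k_c (k_1 n_s + k_m1) / (k_rev k_m1); both exist only for reversible
    catalysis (k_rev > 0).

    Raises
    ------
    IrreversibleRegimeError
        If ``rc.k_rev == 0``; the caller must use the linear (irreversible)
        rate instead.
    """
    if rc.k_rev == 0.0:
        raise IrreversibleRegimeError(
            "k_rev = 0: (lambda_inf, K) are undefined in the irreversible "
            "regime; use the linear Poisson rate instead."
        )
    lam_inf = rc.n_s * rc.k_cat * rc.k_1 / (rc.k_rev * rc.k_m1)
    K = rc.k_c * (rc.k_1 * rc.n_s + rc.k_m1) / (rc.k_rev * rc.k_m1)
    eps = saturation(rc)
    return EffectiveKinetics(lambda_inf=lam_inf, K=K, epsilon=eps)


def saturation(rc: RateConstants) -> float:
    """Enzyme saturation epsilon = k_1 n_s / (k_1 n_s + k_m1)."""
    k1ns = rc.k_1 * rc.n_s
    return k1ns / (k1ns + rc.k_m1)


def three_stage_params(rc: RateConstants) -> ThreeStageParams:
    """Compute (gamma, a, b, alpha_plus, alpha_minus) from the rate constants."""
    if rc.delta <= 0 or rc.k_deg <= 0:
        raise ValueError("delta and k_deg must be positive")
    gamma = (rc.k_on + rc.k_off) / rc.delta
    a = rc.k_tx / rc.delta
    b = rc.k_tl / rc.k_deg
    s = a + gamma
    prod = a * rc.k_on / rc.delta
    disc = s * s - 4.0 * prod
    # The roots are real for any valid parameters: the discriminant equals
    # (a - gamma)^2 + 4 a k_on/delta >= 0.  Clip tiny negative fp error.
    assert disc >= -1e-9 * s * s, "negative discriminant for valid parameters"
    root = math.sqrt(max(disc, 0.0))
    alpha_plus = 0.5 * (s + root)
    # Compute the small root from the product to avoid cancellation.
    alpha_minus = prod / alpha_plus if alpha_plus > 0 else 0.0
    return ThreeStageParams(gamma=gamma, a=a, b=b,
                            alpha_plus=alpha_plus, alpha_minus=alpha_minus)


@dataclass(frozen=True)
class TimescaleReport:
    """Characteristic rate scales of the model and separation flags.

    ``fast`` is the substrate binding/unbinding relaxation rate
    k_1 n_s + k_m1, ``intermediate`` the catalysis-and-consumption scale
    k_cat + k_c and ``slow`` the expression/dilution scale delta.  A flag is
    raised when adjacent scales are separated by less than ``factor``.
    """

    fast: float
    intermediate: float
    slow: float
    factor: float
    fast_over_intermediate: float
    intermediate_over_slow: float
    flags: tuple

    @property
    def ok(self) -> bool:
        return not self.flags


def timescale_diagnostics(rc: RateConstants, factor: float = 10.0) -> TimescaleReport:
    """Check the timescale-separation assumptions behind the mixture model.

    The reduction assumes substrate binding/unbinding is much faster than
    catalysis/consumption, which in turn is much faster than enzyme
    expression and dilution.  ``factor`` (default 10x) is the minimum ratio
    between adjacent scales below which a flag is raised.
    """
    fast = rc.k_1 * rc.n_s + rc.k_m1
    intermediate = rc.k_cat + rc.k_c
    slow = rc.delta
    flags = []
    if fast < factor * intermediate:
        flags.append("fast-binding assumption violated: "
                     f"(k_1 n_s + k_m1)/(k_cat + k_c) = {fast / intermediate:.3g} "
                     f"< {factor:g}")
    if intermediate < factor * slow:
        flags.append("catalysis/expression separation violated: "
                     f"(k_cat + k_c)/delta = {intermediate / slow:.3g} < {factor:g}")
    return TimescaleReport(
        fast=fast, intermediate=intermediate, slow=slow, factor=factor,
        fast_over_intermediate=fast / intermediate,
        intermediate_over_slow=intermediate / slow,
        flags=tuple(flags),
    )


# --------------------------------------------------------------------------
# Config files and named presets
# --------------------------------------------------------------------------

def load_rate_constants(path: Union[str, Path]) -> RateConstants:
    """Read rate constants from a JSON or YAML key/value file.

    The file must contain exactly the keys n_s, k_1, k_m1, k_cat, k_rev,
    k_c, k_tx, k_tl, k_on, k_off, k_deg, delta.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names")
    missing = set(PARAM_NAMES) - set(raw)
    extra = set(raw) - set(PARAM_NAMES)
    if missing or extra:
        raise ValueError(
            f"{path}: missing keys {sorted(missing)}, unknown keys {sorted(extra)}"
        )
    raw = dict(raw)
    raw["n_s"] = int(raw["n_s"])
    return RateConstants(**{k: raw[k] for k in PARAM_NAMES})


def _table1() -> RateConstants:
    return RateConstants(
        n_s=3000, k_1=1.0, k_m1=1000.0, k_cat=3.6, k_rev=0.01, k_c=0.02,
        k_tx=0.0270, k_tl=0.2, k_on=0.0225, k_off=0.0075, k_deg=0.2,
        delta=0.00025,
    )


#: Named rate-constant presets for the reference parameter sets.  The
#: ``fig1c_*`` entries perturb only the promoter switching rates; the
#: ``fig3_*`` entries set the switching rates of the three expression levels
#: (the corresponding kinetics are given as (lambda_inf, K) pairs in
#: EFFECTIVE_PRESETS because only that pair, not the underlying
#: k_cat/k_rev values, is fixed); ``fig4b_enzyme`` is the lowly-abundant-enzyme expression
#: setting of the kinetic regime map.
PRESETS = {
    "table1": _table1(),
    "fig1c_fast_off": _table1().with_(k_on=0.01, k_off=0.03),
    "fig1c_balanced": _table1().with_(k_on=0.01, k_off=0.01),
    "fig1c_slow_off": _table1().with_(k_on=0.01, k_off=0.0001),
    "fig3_low": _table1().with_(k_on=1.56e-4, k_off=9.8e-4),
    "fig3_mid": _table1().with_(k_on=5.9e-4, k_off=9.3e-4),
    "fig3_high": _table1().with_(k_on=20e-4, k_off=8e-4),
    "fig4b_enzyme": _table1().with_(k_on=1.56e-4, k_off=3e-4,
                                    k_tx=0.025, k_tl=0.2),
}

#: (lambda_inf, K) pairs of the regime-map settings; the individual rate
#: constants behind them are not fixed, so the pair is stored directly.
EFFECTIVE_PRESETS = {
    "fig1c": (1080.0, 8.0),
    "fig2_low": (300.0, 0.1333),
    "fig2_mid": (3000.0, 0.1333),
    "fig2_high": (30000.0, 0.1333),
    "fig2b": (500.0, 0.1333),
    "fig3_K_large": (750.0, 10.0400),
    "fig3_K_mid": (750.0, 2.1630),
    "fig3_K_small": (750.0, 0.4660),
}


def preset(name: str) -> RateConstants:
    """Return a named rate-constant preset (see ``PRESETS``)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")


def effective_preset(name: str) -> tuple:
    """Return a named (lambda_inf, K) pair (see ``EFFECTIVE_PRESETS``)."""
    try:
        return EFFECTIVE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown effective preset {name!r}; available: "
            f"{sorted(EFFECTIVE_PRESETS)}"
        )
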