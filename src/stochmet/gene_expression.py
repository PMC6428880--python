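"""Stationary enzyme copy-number distributions.

The total enzyme (free plus substrate-bound) is produced by translation and
removed by dilution only, so on the slow timescale it follows the classical
three-stage gene-expression model exactly.  Its stationary distribution has
the closed form

    P(n) = Gamma(alpha_+ + n) Gamma(alpha_- + n) Gamma(gamma)
           / [Gamma(n+1) Gamma(alpha_+) Gamma(alpha_-) Gamma(gamma + n)]
           * (b/(1+b))^n (1 - b/(1+b))^alpha_+
           * 2F1(alpha_+ + n, gamma - alpha_-; gamma + n; b/(1+b)),

valid when mRNA turnover is fast compared with dilution (k_deg >> delta).
The Gamma-function ratio is evaluated with log-Gamma and the Gauss series of
the hypergeometric factor is summed in log space; for the parameter domain
of the model all series terms are positive (alpha_- <= gamma <= alpha_+), so
the summation involves no cancellation.

The module also builds enzyme distributions from empirical tables and from
fitted Gamma distributions, standing in for measured single-cell data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Tuple, Union

import numpy as np
from scipy import special, stats

from .params import ThreeStageParams

__all__ = [
    "DiscretePMF",
    "PMFNumericsWarning",
    "HypergeometricError",
    "three_stage_pmf",
    "negative_binomial_pmf",
    "empirical_pmf",
    "gamma_discretized_pmf",
    "total_variation",
    "write_pmf",
    "read_pmf",
]

#: Default truncated tail mass for analytic distributions.
DEFAULT_TRUNCATION_TOL = 1e-8

#: Raw-sum deviation above which a pmf is renormalized (and a warning raised).
RENORMALIZE_TOL = 1e-6


class PMFNumericsWarning(UserWarning):
    """Raised when a pmf had to be renormalized beyond floating-point slack."""


class HypergeometricError(RuntimeError):
    """2F1 series failed to converge at the requested precision."""


@dataclass
class DiscretePMF:
    """A normalized probability mass function on 0..support_max.

    ``probs[n]`` is the stationary probability of copy number ``n``;
    ``tail_mass_bound`` bounds the probability beyond ``support_max`` that
    was truncated away.  ``provenance`` is a free-text label recording how
    the distribution was obtained (e.g. "three-stage", "empirical", "pmm",
    "ssa").
    """

    probs: np.ndarray
    tail_mass_bound: float = 0.0
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.size == 0:
            raise ValueError("probs must be a non-empty 1-D array")
        if np.any(self.probs < 0) or not np.all(np.isfinite(self.probs)):
            raise ValueError("probs must be finite and non-negative")
        if self.tail_mass_bound < 0:
            raise ValueError("tail_mass_bound must be >= 0")
        total = self.probs.sum() + self.tail_mass_bound
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mass + tail bound = {total!r} is not 1 within 1e-9; "
                "normalize before constructing a DiscretePMF"
            )

    @property
    def support_max(self) -> int:
        return self.probs.size - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probs.size)

    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    def var(self) -> float:
        m = self.mean()
        return float(np.dot((self.support - m) ** 2, self.probs))

    def __getitem__(self, n: int) -> float:
        if 0 <= n <= self.support_max:
            return float(self.probs[n])
        return 0.0


def _finalize(raw: np.ndarray, provenance: str, meta: dict = None) -> DiscretePMF:
    """Build a DiscretePMF from raw (untruncated-at-1) masses.

    The analytic distributions sum to 1 over the full lattice, so the
    truncated tail bound is 1 minus the computed raw sum.  If floating-point
    error pushes the raw sum above 1 by more than RENORMALIZE_TOL the masses
    are renormalized and a numerical-quality warning is raised.
    """
    raw = np.asarray(raw, dtype=float)
    total = raw.sum()
    if total > 1.0 + RENORMALIZE_TOL:
        warnings.warn(
            f"raw pmf mass {total!r} exceeds 1 by more than {RENORMALIZE_TOL}; "
            "renormalizing", PMFNumericsWarning, stacklevel=2,
        )
        raw = raw / total
        total = 1.0
    tail = max(0.0, 1.0 - total)
    return DiscretePMF(probs=np.clip(raw, 0.0, None), tail_mass_bound=tail,
                       provenance=provenance, meta=dict(meta or {}))


# --------------------------------------------------------------------------
# Hypergeometric evaluation
# --------------------------------------------------------------------------

def _log_hyp2f1_series(A: float, B: float, C: float, z: float,
                       rtol: float = 1e-16, max_terms: int = 2_000_000) -> float:
    """log 2F1(A, B; C; z) by the Gauss series, summed in log space.

    Requires A, B, C > 0 and 0 <= z < 1 so all terms are positive and the
    summation involves no cancellation.  Terms are generated in blocks as
    cumulative sums of log term-ratios and combined with a log-sum-exp; the
    series stops once the geometric bound on the remainder is below ``rtol``
    of the partial sum.
    """
    if z == 0.0 or B == 0.0 or A == 0.0:
        return 0.0
    if not (A > 0 and B > 0 and C > 0 and 0 <= z < 1):
        raise HypergeometricError(
            f"series requires positive parameters and 0<=z<1, got "
            f"A={A}, B={B}, C={C}, z={z}"
        )
    # term ratio r_k = (A+k)(B+k) z / ((C+k)(k+1)) -> z < 1, so the tail is
    # eventually geometric; start from a quadratic estimate of where r_k
    # drops below 1 and extend in blocks if needed.
    guess = int(max(A + B - C, 10.0) * z / (1.0 - z)) + 80
    log_sum = None  # log of partial sum
    log_last = 0.0  # log of last included term
    k0 = 0
    while True:
        block = min(guess, max_terms - k0)
        k = np.arange(k0, k0 + block, dtype=float)
        log_ratios = (np.log(A + k) + np.log(B + k) + math.log(z)
                      - np.log(C + k) - np.log1p(k))
        log_terms = log_last + np.cumsum(log_ratios)
        m = max(float(log_terms.max()), log_sum if log_sum is not None else 0.0)
        acc = float(np.exp(log_terms - m).sum())
        if log_sum is None:
            acc += math.exp(-m)  # k = 0 term
        else:
            acc += math.exp(log_sum - m)
        log_sum = m + math.log(acc)
        log_last = float(log_terms[-1])
        last_ratio = (A + k0 + block) * (B + k0 + block) * z / \
                     ((C + k0 + block) * (k0 + block + 1.0))
        k0 += block
        if last_ratio < 1.0:
            log_rem = log_last + math.log(last_ratio / (1.0 - last_ratio))
            if log_rem < log_sum + math.log(rtol):
                return log_sum
        if k0 >= max_terms:
            raise HypergeometricError(
                f"2F1 series did not converge within {max_terms} terms "
                f"(A={A}, B={B}, C={C}, z={z})"
            )
        guess = max(guess, 256)


def _log_hyp2f1_mpmath(A: float, B: float, C: float, z: float,
                       digits: int = 50) -> float:
    """High-precision fallback via mpmath (optional dependency)."""
    try:
        import mpmath
    except ImportError as exc:  # pragma: no cover - mpmath ships with sympy
        raise HypergeometricError(
            "high-precision fallback requested but mpmath is unavailable"
        ) from exc
    with mpmath.workdps(digits):
        val = mpmath.hyp2f1(A, B, C, z)
        return float(mpmath.log(val))


# --------------------------------------------------------------------------
# Three-stage stationary distribution
# --------------------------------------------------------------------------

def _three_stage_log_pmf(n: np.ndarray, tsp: ThreeStageParams,
                         precision_digits: int = 50) -> np.ndarray:
    """Log of the closed-form stationary pmf at copy numbers ``n``."""
    ap, am, g, b = tsp.alpha_plus, tsp.alpha_minus, tsp.gamma, tsp.b
    z = b / (1.0 + b)
    n = np.asarray(n, dtype=float)
    log_pref = (
        special.gammaln(ap + n) + special.gammaln(am + n) + special.gammaln(g)
        - special.gammaln(n + 1.0) - special.gammaln(ap) - special.gammaln(am)
        - special.gammaln(g + n)
        + n * math.log(z) + ap * math.log1p(-z)
    )
    log_f = np.empty_like(log_pref)
    B = g - am
    for i, ni in enumerate(n):
        try:
            log_f[i] = _log_hyp2f1_series(ap + ni, B, g + ni, z)
        except HypergeometricError:
            log_f[i] = _log_hyp2f1_mpmath(ap + ni, B, g + ni, z,
                                          digits=precision_digits)
    return log_pref + log_f


def negative_binomial_pmf(shape: float, success_prob: float,
                          truncation_tol: float = DEFAULT_TRUNCATION_TOL,
                          provenance: str = "negative-binomial") -> DiscretePMF:
    """Negative binomial pmf NB(shape, success_prob) as a DiscretePMF.

    Parameterised so the pmf at n is
    ``C(shape+n-1, n) success_prob^n (1-success_prob)^shape`` (mean
    ``shape * success_prob/(1-success_prob)``); this is the always-on
    (k_off = 0) limit of the three-stage model with shape a and success
    probability b/(1+b).
    """
    if not (0 < success_prob < 1) or shape <= 0:
        raise ValueError("need shape > 0 and 0 < success_prob < 1")
    mean = shape * success_prob / (1.0 - success_prob)
    var = mean / (1.0 - success_prob)
    hi = int(mean + 12.0 * math.sqrt(var) + 50.0)
    dist = stats.nbinom(shape, 1.0 - success_prob)
    while dist.sf(hi) > truncation_tol:
        hi = int(hi * 1.5) + 50
    raw = dist.pmf(np.arange(hi + 1))
    return _finalize(raw, provenance, {"shape": shape, "success_prob": success_prob})


def three_stage_pmf(tsp: ThreeStageParams,
                    truncation_tol: float = DEFAULT_TRUNCATION_TOL,
                    precision_digits: int = 50) -> DiscretePMF:
    """Stationary total-enzyme pmf of the three-stage expression model.

    Support is extended until the cumulative mass reaches
    ``1 - truncation_tol``; the truncated remainder is reported as the
    ``tail_mass_bound``.  Degenerate promoters short-circuit to closed
    forms: a permanently inactive gene (alpha roots give mean 0, i.e.
    k_on = 0) yields a point mass at zero and a permanently active gene
    (alpha_minus = 0, i.e. k_off = 0) yields the negative binomial limit.
    """
    if not (0 < truncation_tol < 1):
        raise ValueError("truncation_tol must be in (0, 1)")
    # k_on = 0  <=>  alpha_minus == 0 (promoter never activates)
    if tsp.alpha_minus == 0.0 or tsp.alpha_minus < 1e-300:
        return DiscretePMF(probs=np.array([1.0]), tail_mass_bound=0.0,
                           provenance="three-stage",
                           meta={"degenerate": "k_on=0"})
    # k_off = 0  <=>  alpha_plus*alpha_minus == a*gamma (promoter always
    # active; the roots degenerate to {a, gamma} and the negative binomial
    # of an always-on gene is the exact closed form)
    if math.isclose(tsp.alpha_plus * tsp.alpha_minus, tsp.a * tsp.gamma,
                    rel_tol=1e-12):
        pmf = negative_binomial_pmf(tsp.a, tsp.b / (1.0 + tsp.b),
                                    truncation_tol, provenance="three-stage")
        pmf.meta["degenerate"] = "k_off=0"
        return pmf

    mean = tsp.mean_protein
    # conservative spread guess: bursty variance ~ mean*(1+b) plus promoter
    # switching contribution
    spread = math.sqrt(mean * (1.0 + tsp.b) + mean ** 2 + 1.0)
    hi = int(mean + 8.0 * spread + 50.0)
    block_logs = [_three_stage_log_pmf(np.arange(hi + 1), tsp, precision_digits)]
    total = float(np.exp(block_logs[0]).sum())
    while 1.0 - total > truncation_tol:
        new_hi = int(hi * 1.5) + 50
        block = _three_stage_log_pmf(np.arange(hi + 1, new_hi + 1), tsp,
                                     precision_digits)
        block_logs.append(block)
        total += float(np.exp(block).sum())
        hi = new_hi
        if hi > 10_000_000:
            raise HypergeometricError(
                "three-stage support exceeded 1e7 without reaching the "
                "requested cumulative mass"
            )
    raw = np.exp(np.concatenate(block_logs))
    pmf = _finalize(raw, "three-stage",
                    {"gamma": tsp.gamma, "a": tsp.a, "b": tsp.b,
                     "alpha_plus": tsp.alpha_plus, "alpha_minus": tsp.alpha_minus})
    # trim trailing entries beyond the requested tolerance, keeping the bound
    cum = np.cumsum(pmf.probs)
    keep = int(np.searchsorted(cum, 1.0 - truncation_tol)) + 1
    if keep < pmf.probs.size:
        tail = pmf.tail_mass_bound + float(pmf.probs[keep:].sum())
        pmf = DiscretePMF(probs=pmf.probs[:keep], tail_mass_bound=tail,
                          provenance=pmf.provenance, meta=pmf.meta)
    return pmf


# --------------------------------------------------------------------------
# Empirical and Gamma-derived enzyme distributions
# --------------------------------------------------------------------------

def empirical_pmf(table: Iterable[Tuple[int, float]]) -> DiscretePMF:
    """Build a pmf from (copy number, weight) pairs, e.g. measured data.

    Weights are normalized to 1; copy numbers must be unique non-negative
    integers and weights non-negative with at least one positive.
    """
    pairs = list(table)
    if not pairs:
        raise ValueError("empty table")
    ns, ws = zip(*pairs)
    ns = np.asarray(ns)
    ws = np.asarray(ws, dtype=float)
    if np.any(ns != np.asarray(ns, dtype=int)) or np.any(ns < 0):
        raise ValueError("copy numbers must be non-negative integers")
    ns = ns.astype(int)
    if len(set(ns.tolist())) != ns.size:
        raise ValueError("duplicate copy numbers in table")
    if np.any(ws < 0) or not np.all(np.isfinite(ws)):
        raise ValueError("weights must be finite and non-negative")
    total = ws.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    probs = np.zeros(int(ns.max()) + 1)
    probs[ns] = ws / total
    return DiscretePMF(probs=probs, tail_mass_bound=0.0, provenance="empirical")


def gamma_discretized_pmf(shape: float, scale: float,
                          truncation_tol: float = DEFAULT_TRUNCATION_TOL) -> DiscretePMF:
    """Discretize a Gamma(shape, scale) density onto integer copy numbers.

    The mass at n is the Gamma density integrated over [n, n+1), emulating
    protein distributions reported as fitted Gamma laws.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    if not (0 < truncation_tol < 1):
        raise ValueError("truncation_tol must be in (0, 1)")
    dist = stats.gamma(shape, scale=scale)
    hi = int(dist.ppf(1.0 - truncation_tol)) + 1
    edges = np.arange(hi + 2, dtype=float)
    cdf = dist.cdf(edges)
    raw = np.diff(cdf)
    pmf = _finalize(raw, "gamma", {"shape": shape, "scale": scale})
    if pmf.tail_mass_bound > truncation_tol:
        raise AssertionError("gamma tail bound exceeded requested tolerance")
    return pmf


# --------------------------------------------------------------------------
# Distances and pmf table I/O
# --------------------------------------------------------------------------

def total_variation(p: Union[DiscretePMF, np.ndarray],
                    q: Union[DiscretePMF, np.ndarray]) -> float:
    """Total variation distance, half the L1 distance between two pmfs.

    Truncated tail mass (if any) is counted as disagreement, so the result
    is an upper bound on the true distance for truncated distributions.
    """
    pa = p.probs if isinstance(p, DiscretePMF) else np.asarray(p, dtype=float)
    qa = q.probs if isinstance(q, DiscretePMF) else np.asarray(q, dtype=float)
    size = max(pa.size, qa.size)
    pa = np.pad(pa, (0, size - pa.size))
    qa = np.pad(qa, (0, size - qa.size))
    tv = 0.5 * float(np.abs(pa - qa).sum())
    pt = p.tail_mass_bound if isinstance(p, DiscretePMF) else 0.0
    qt = q.tail_mass_bound if isinstance(q, DiscretePMF) else 0.0
    return tv + 0.5 * (pt + qt)


def write_pmf(pmf: DiscretePMF, path: Union[str, Path]) -> None:
    """Write a pmf as a two-column tab-separated table.

    The '#'-prefixed header carries provenance and the truncated tail
    bound; probabilities are printed with 17 significant digits so that a
    read/write round trip is bit-identical.
    """
    path = Path(path)
    lines = [
        f"# provenance\t{pmf.provenance}",
        f"# tail_mass_bound\t{pmf.tail_mass_bound:.17g}",
        "# copy_number\tprobability",
    ]
    lines += [f"{n}\t{p:.17g}" for n, p in enumerate(pmf.probs)]
    path.write_text("\n".join(lines) + "\n")


def read_pmf(path: Union[str, Path]) -> DiscretePMF:
    """Read a pmf table written by :func:`write_pmf`."""
    path = Path(path)
    provenance = ""
    tail = 0.0
    ns, ps = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].strip().split("\t")
            if fields[0] == "provenance" and len(fields) > 1:
                provenance = fields[1]
            elif fields[0] == "tail_mass_bound" and len(fields) > 1:
                tail = float(fields[1])
            continue
        n_str, p_str = line.split("\t")
        ns.append(int(n_str))
        ps.append(float(p_str))
    probs = np.zeros(max(ns) + 1)
    probs[np.asarray(ns)] = ps
    return DiscretePMF(probs=probs, tail_mass_bound=tail, provenance=provenance)
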