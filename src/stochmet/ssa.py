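"""Exact stochastic simulation of the full reaction network and a CME oracle.

The network couples the metabolic reaction to gene expression:

    R1  Substrate + Enzyme <-> Complex              (k_1 n_s n_e, k_m1 n_c)
    R2  Complex <-> Metabolite + Enzyme             (k_cat n_c, k_rev n_e n_p)
    R3  mRNA -> mRNA + Enzyme                       (k_tl n_m)
    R4  DNA_on -> DNA_on + mRNA                     (k_tx)
    R5  DNA_off <-> DNA_on                          (k_on, k_off)
    R6  Metabolite -> 0                             (k_c n_p)
    R7  mRNA -> 0                                   (k_deg n_m)
    R8  Enzyme -> 0                                 (delta n_e)
    R9  Complex -> 0                                (delta n_c)

All reactions follow mass-action kinetics; the substrate copy number n_s is
constant.  Simulation is Gillespie's direct method -- every reaction event
is realised individually (no tau-leaping).  Two entry points are provided:

* :func:`simulate` produces a (optionally grid-thinned) :class:`Trajectory`
  with exponentially sampled waiting times -- the exact SSA in full;
* :func:`run_stationary_histogram` streams time-weighted occupancy
  histograms during the simulation without storing the path, using the
  expected holding time 1/a0 of each visited state as its occupancy weight
  (a Rao-Blackwellised estimator over the exact embedded jump chain; it
  averages out holding-time noise and is what makes hundreds-of-cell-cycle
  validation runs affordable).

A finite-state projection of the chemical master equation
(:func:`cme_stationary`) serves as an independent oracle on truncated state
spaces.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, gmres, spilu, splu

from .params import RateConstants, PARAM_NAMES
from .gene_expression import DiscretePMF

__all__ = [
    "SystemState",
    "Trajectory",
    "EventBudgetExceeded",
    "propensities",
    "STATE_CHANGES",
    "simulate",
    "stationary_histogram",
    "run_stationary_histogram",
    "Reaction",
    "cme_stationary",
    "full_network_reactions",
    "three_stage_reactions",
    "birth_death_reactions",
    "DEFAULT_BURN_IN_CYCLES",
]

#: Default burn-in before stationary statistics, in cell cycles (ln 2/delta).
DEFAULT_BURN_IN_CYCLES = 20.0

#: Default cap on the number of simulated reaction events.
DEFAULT_MAX_EVENTS = 500_000_000_000

#: Species order used throughout: promoter state, mRNA, free enzyme,
#: complex, metabolite.
SPECIES = ("dna_on", "n_m", "n_e", "n_c", "n_p")


class EventBudgetExceeded(RuntimeError):
    """The simulation horizon implies more events than the configured budget."""


@dataclass(frozen=True)
class SystemState:
    """Full state of the network (the substrate count lives in RateConstants)."""

    dna_on: int
    n_m: int
    n_e: int
    n_c: int
    n_p: int

    def __post_init__(self) -> None:
        if self.dna_on not in (0, 1):
            raise ValueError("dna_on must be 0 or 1 (single gene copy)")
        for name in ("n_m", "n_e", "n_c", "n_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_etot(self) -> int:
        """Total enzyme, free plus substrate-bound."""
        return self.n_e + self.n_c

    def as_array(self) -> np.ndarray:
        return np.array([self.dna_on, self.n_m, self.n_e, self.n_c, self.n_p],
                        dtype=np.int64)


ZERO_STATE = SystemState(0, 0, 0, 0, 0)

#: State-change vectors per reaction channel, rows in the order of the
#: propensity vector below (columns follow SPECIES).
STATE_CHANGES = np.array([
    [0, 0, -1, +1, 0],   # R1 forward: substrate + enzyme -> complex
    [0, 0, +1, -1, 0],   # R1 reverse: complex -> substrate + enzyme
    [0, 0, +1, -1, +1],  # R2 forward: complex -> metabolite + enzyme
    [0, 0, -1, +1, -1],  # R2 reverse: metabolite + enzyme -> complex
    [0, 0, +1, 0, 0],    # R3: translation
    [0, +1, 0, 0, 0],    # R4: transcription
    [+1, 0, 0, 0, 0],    # R5 forward: promoter activation
    [-1, 0, 0, 0, 0],    # R5 reverse: promoter deactivation
    [0, 0, 0, 0, -1],    # R6: metabolite consumption
    [0, -1, 0, 0, 0],    # R7: mRNA degradation
    [0, 0, -1, 0, 0],    # R8: enzyme dilution
    [0, 0, 0, -1, 0],    # R9: complex dilution
], dtype=np.int64)


def propensities(state: SystemState, rc: RateConstants) -> np.ndarray:
    """Mass-action propensities of the 12 reaction channels."""
    return np.array([
        rc.k_1 * rc.n_s * state.n_e,
        rc.k_m1 * state.n_c,
        rc.k_cat * state.n_c,
        rc.k_rev * state.n_e * state.n_p,
        rc.k_tl * state.n_m,
        rc.k_tx * state.dna_on,
        rc.k_on * (1 - state.dna_on),
        rc.k_off * state.dna_on,
        rc.k_c * state.n_p,
        rc.k_deg * state.n_m,
        rc.delta * state.n_e,
        rc.delta * state.n_c,
    ])


@dataclass
class Trajectory:
    """Piecewise-constant sample path of the network.

    ``times`` are the recording instants (event times, or a uniform grid
    when thinned) and ``states`` the state after each instant, columns in
    SPECIES order.  ``histograms`` holds exact time-weighted occupancy
    histograms accumulated during simulation (keys "n_p" and "n_etot"),
    which survive thinning.
    """

    times: np.ndarray
    states: np.ndarray
    rc: RateConstants
    seed: int
    t_end: float
    thinned: bool
    burn_in: float = 0.0
    histograms: dict = field(default_factory=dict)
    n_events: int = 0

    @property
    def duration(self) -> float:
        return self.t_end

    def species(self, name: str) -> np.ndarray:
        if name == "n_etot":
            return self.states[:, 2] + self.states[:, 3]
        return self.states[:, SPECIES.index(name)]

    def params_hash(self) -> str:
        payload = ",".join(f"{k}={getattr(self.rc, k)!r}" for k in PARAM_NAMES)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, path: Union[str, Path]) -> None:
        """Write as a tab-separated table with a '#' metadata header."""
        path = Path(path)
        header = [
            f"# seed\t{self.seed}",
            f"# params_sha256\t{self.params_hash()}",
            f"# t_end\t{self.t_end!r}",
            f"# thinned\t{int(self.thinned)}",
            "# time\tdna_on\tn_m\tn_e\tn_c\tn_p",
        ]
        rows = [
            f"{t:.17g}\t" + "\t".join(str(int(v)) for v in row)
            for t, row in zip(self.times, self.states)
        ]
        path.write_text("\n".join(header + rows) + "\n")


# --------------------------------------------------------------------------
# numba kernels (own xorshift64* PRNG for platform-stable reproducibility)
# --------------------------------------------------------------------------

_U = np.uint64
_MULT = _U(2685821657736338717)
_INV64 = 5.421010862427522e-20  # 2^-64 * (1 - 2^-53) guard not needed; < 1


@njit(cache=True, fastmath=True)
def _traj_kernel(params, t_end, seed, grid_dt, max_events, max_records,
                 init_state, burn_in, np_cap, ne_cap):  # pragma: no cover
    (ns, k1, km1, kcat, krev, kc, ktx, ktl, kon, koff, kdeg, delta) = params
    k1ns = k1 * ns
    dna = init_state[0]; m = init_state[1]; e = init_state[2]
    c = init_state[3]; p = init_state[4]
    t = 0.0
    s = _U(seed) * _U(6364136223846793005) + _U(1442695040888963407)
    hist_p = np.zeros(np_cap + 1)
    hist_e = np.zeros(ne_cap + 1)
    times = np.empty(max_records)
    states = np.empty((max_records, 5), dtype=np.int64)
    n_rec = 0
    next_grid = 0.0
    nev = 0
    status = 0  # 0 ok, 1 event budget exceeded, 2 record budget exceeded
    while True:
        a1 = k1ns * e; a2 = km1 * c; a3 = kcat * c; a4 = krev * e * p
        a5 = ktl * m; a6 = ktx * dna; a7 = kon * (1 - dna); a8 = koff * dna
        a9 = kc * p; a10 = kdeg * m; a11 = delta * e; a12 = delta * c
        a0 = a1+a2+a3+a4+a5+a6+a7+a8+a9+a10+a11+a12
        if a0 <= 0.0:
            # absorbing state: record and hold to the end
            while next_grid <= t_end and n_rec < max_records:
                times[n_rec] = next_grid
                states[n_rec, 0] = dna; states[n_rec, 1] = m
                states[n_rec, 2] = e; states[n_rec, 3] = c; states[n_rec, 4] = p
                n_rec += 1
                next_grid += grid_dt
            if t < t_end and t >= burn_in:
                w = t_end - max(t, burn_in)
                if p <= np_cap:
                    hist_p[p] += w
                etot = e + c
                if etot <= ne_cap:
                    hist_e[etot] += w
            t = t_end
            break
        s ^= s >> _U(12); s ^= s << _U(25); s ^= s >> _U(27)
        u1 = np.float64(s * _MULT) * _INV64
        dt = -np.log(1.0 - u1) / a0
        t_next = t + dt
        # record grid points passed during the holding interval
        while next_grid < t_next and next_grid <= t_end:
            if n_rec >= max_records:
                status = 2
                break
            times[n_rec] = next_grid
            states[n_rec, 0] = dna; states[n_rec, 1] = m
            states[n_rec, 2] = e; states[n_rec, 3] = c; states[n_rec, 4] = p
            n_rec += 1
            next_grid += grid_dt
        if status != 0:
            break
        # exact holding-time occupancy over [burn_in, t_end]
        lo = t if t > burn_in else burn_in
        hi = t_next if t_next < t_end else t_end
        if hi > lo:
            w = hi - lo
            if p <= np_cap:
                hist_p[p] += w
            etot = e + c
            if etot <= ne_cap:
                hist_e[etot] += w
        t = t_next
        if t >= t_end:
            break
        s ^= s >> _U(12); s ^= s << _U(25); s ^= s >> _U(27)
        u2 = np.float64(s * _MULT) * _INV64
        r = u2 * a0
        if r < a1: e -= 1; c += 1
        elif r < a1+a2: c -= 1; e += 1
        else:
            r -= a1+a2
            if r < a3: c -= 1; e += 1; p += 1
            elif r < a3+a4: e -= 1; p -= 1; c += 1
            elif r < a3+a4+a5: e += 1
            elif r < a3+a4+a5+a6: m += 1
            elif r < a3+a4+a5+a6+a7: dna = 1
            elif r < a3+a4+a5+a6+a7+a8: dna = 0
            elif r < a3+a4+a5+a6+a7+a8+a9: p -= 1
            elif r < a3+a4+a5+a6+a7+a8+a9+a10: m -= 1
            elif r < a3+a4+a5+a6+a7+a8+a9+a10+a11: e -= 1
            else: c -= 1
        nev += 1
        if nev >= max_events:
            status = 1
            break
    return times[:n_rec], states[:n_rec], hist_p, hist_e, nev, status


@njit(cache=True, fastmath=True)
def _hist_kernel(params, t_end, burn_in, seed, max_events,
                 init_state, np_cap, ne_cap):  # pragma: no cover
    """Streaming occupancy histograms with expected-holding-time weights.

    The embedded jump chain is the exact direct-method chain; each visited
    state contributes its expected holding time 1/a0 both to the histogram
    and to the elapsed clock (Rao-Blackwellisation of the occupancy
    estimator over the exponential waiting times).
    """
    (ns, k1, km1, kcat, krev, kc, ktx, ktl, kon, koff, kdeg, delta) = params
    k1ns = k1 * ns
    dna = init_state[0]; m = init_state[1]; e = init_state[2]
    c = init_state[3]; p = init_state[4]
    t = 0.0
    s = _U(seed) * _U(6364136223846793005) + _U(1442695040888963407)
    hist_p = np.zeros(np_cap + 1)
    hist_e = np.zeros(ne_cap + 1)
    nev = 0
    status = 0
    while t < t_end:
        a1 = k1ns * e; a2 = km1 * c; a3 = kcat * c; a4 = krev * e * p
        a5 = ktl * m; a6 = ktx * dna; a7 = kon * (1 - dna); a8 = koff * dna
        a9 = kc * p; a10 = kdeg * m; a11 = delta * e; a12 = delta * c
        a0 = a1+a2+a3+a4+a5+a6+a7+a8+a9+a10+a11+a12
        if a0 <= 0.0:
            if t >= burn_in:
                w = t_end - t
                if p <= np_cap:
                    hist_p[p] += w
                etot = e + c
                if etot <= ne_cap:
                    hist_e[etot] += w
            break
        dt = 1.0 / a0
        if t >= burn_in:
            if p <= np_cap:
                hist_p[p] += dt
            etot = e + c
            if etot <= ne_cap:
                hist_e[etot] += dt
        t += dt
        s ^= s >> _U(12); s ^= s << _U(25); s ^= s >> _U(27)
        u = np.float64(s * _MULT) * _INV64
        r = u * a0
        if r < a1: e -= 1; c += 1
        elif r < a1+a2: c -= 1; e += 1
        else:
            r -= a1+a2
            if r < a3: c -= 1; e += 1; p += 1
            elif r < a3+a4: e -= 1; p -= 1; c += 1
            elif r < a3+a4+a5: e += 1
            elif r < a3+a4+a5+a6: m += 1
            elif r < a3+a4+a5+a6+a7: dna = 1
            elif r < a3+a4+a5+a6+a7+a8: dna = 0
            elif r < a3+a4+a5+a6+a7+a8+a9: p -= 1
            elif r < a3+a4+a5+a6+a7+a8+a9+a10: m -= 1
            elif r < a3+a4+a5+a6+a7+a8+a9+a10+a11: e -= 1
            else: c -= 1
        nev += 1
        if nev >= max_events:
            status = 1
            break
    return hist_p, hist_e, nev, status


def _pack_params(rc: RateConstants) -> tuple:
    return (float(rc.n_s), rc.k_1, rc.k_m1, rc.k_cat, rc.k_rev, rc.k_c,
            rc.k_tx, rc.k_tl, rc.k_on, rc.k_off, rc.k_deg, rc.delta)


def _estimate_caps(rc: RateConstants) -> tuple:
    """Generous state caps for histogram arrays from coarse stationary means."""
    mean_etot = (rc.k_tx / rc.delta) * (rc.k_tl / rc.k_deg) * rc.promoter_activity
    ne_cap = int(20 + 4.0 * max(mean_etot, 1.0))
    eps = rc.k_1 * rc.n_s / (rc.k_1 * rc.n_s + rc.k_m1)
    lam_top = rc.k_cat * eps * ne_cap / (rc.k_rev * (1 - eps) * max(ne_cap, 1) + rc.k_c)
    np_cap = int(50 + 1.5 * lam_top)
    return np_cap, ne_cap


def simulate(rc: RateConstants, t_end: float, seed: int,
             recording_dt: Optional[float] = None,
             initial_state: SystemState = ZERO_STATE,
             burn_in: float = 0.0,
             max_events: int = DEFAULT_MAX_EVENTS,
             max_records: int = 20_000_000) -> Trajectory:
    """Exact direct-method SSA run of the full network.

    The trajectory is recorded on a uniform grid of spacing ``recording_dt``
    (default: 2000 grid points over the horizon); pass a value smaller than
    any waiting time to record effectively every event.  Time-weighted
    occupancy histograms of the metabolite and of the total enzyme are
    accumulated exactly from the event holding times over
    ``[burn_in, t_end]`` regardless of thinning.

    Raises
    ------
    EventBudgetExceeded
        If the run would exceed ``max_events`` reaction events; shorten the
        horizon, scale down the fast rate constants, or raise the budget.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if recording_dt is None:
        recording_dt = t_end / 2000.0
    n_grid = int(math.floor(t_end / recording_dt)) + 2
    if n_grid > max_records:
        raise ValueError(
            f"recording grid needs {n_grid} records > max_records={max_records}; "
            "increase recording_dt"
        )
    np_cap, ne_cap = _estimate_caps(rc)
    times, states, hist_p, hist_e, nev, status = _traj_kernel(
        _pack_params(rc), float(t_end), int(seed) & 0x7FFFFFFF,
        float(recording_dt), int(max_events), int(n_grid),
        initial_state.as_array(), float(burn_in), np_cap, ne_cap,
    )
    if status == 1:
        raise EventBudgetExceeded(
            f"simulation exceeded the event budget of {max_events:g} events "
            f"after t={times[-1] if len(times) else 0:.3g} s of {t_end:.3g} s; "
            "shorten t_end, reduce the fast binding rates or raise max_events"
        )
    if status == 2:
        raise RuntimeError("recording budget exceeded; increase recording_dt")
    return Trajectory(
        times=times, states=states, rc=rc, seed=int(seed), t_end=float(t_end),
        thinned=True, burn_in=float(burn_in),
        histograms={
            "n_p": hist_p, "n_etot": hist_e,
        },
        n_events=int(nev),
    )


def _normalize_hist(hist: np.ndarray, provenance: str) -> DiscretePMF:
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty histogram (no occupancy after burn-in)")
    probs = hist / total
    nz = np.nonzero(probs)[0]
    probs = probs[: nz[-1] + 1] if nz.size else probs[:1]
    return DiscretePMF(probs=probs / probs.sum(), tail_mass_bound=0.0,
                       provenance=provenance)


def stationary_histogram(traj: Trajectory, burn_in: float,
                         species: str = "n_p") -> DiscretePMF:
    """Time-weighted stationary histogram of one species from a trajectory.

    Weights are the holding times between recorded instants over
    ``[burn_in, t_end]``.  For thinned trajectories the in-run exact
    histograms are used when the requested burn-in matches the one the run
    was performed with; otherwise the histogram is recomputed from the
    recorded (grid) holding times.
    """
    if burn_in >= traj.t_end:
        raise ValueError("burn_in must be smaller than the trajectory duration")
    if species in traj.histograms and math.isclose(burn_in, traj.burn_in):
        return _normalize_hist(traj.histograms[species], f"ssa:{species}")
    values = traj.species(species)
    times = traj.times
    if times.size < 2:
        raise ValueError("trajectory too short")
    ends = np.append(times[1:], traj.t_end)
    starts = np.clip(times, burn_in, traj.t_end)
    ends = np.clip(ends, burn_in, traj.t_end)
    weights = ends - starts
    hist = np.bincount(values.astype(int), weights=weights)
    return _normalize_hist(hist, f"ssa:{species}")


def run_stationary_histogram(rc: RateConstants, t_end: float, seed: int,
                             burn_in: Optional[float] = None,
                             max_events: int = DEFAULT_MAX_EVENTS,
                             initial_state: SystemState = ZERO_STATE) -> dict:
    """Long-run stationary histograms of metabolite and total enzyme.

    Streams the exact embedded chain of the direct method and accumulates
    expected-holding-time occupancy weights; nothing is stored per event.
    Returns ``{"n_p": DiscretePMF, "n_etot": DiscretePMF, "n_events": int}``.
    ``burn_in`` defaults to DEFAULT_BURN_IN_CYCLES cell cycles.
    """
    if burn_in is None:
        burn_in = DEFAULT_BURN_IN_CYCLES * rc.doubling_time
    if burn_in >= t_end:
        raise ValueError("burn_in must be smaller than t_end")
    np_cap, ne_cap = _estimate_caps(rc)
    hist_p, hist_e, nev, status = _hist_kernel(
        _pack_params(rc), float(t_end), float(burn_in),
        int(seed) & 0x7FFFFFFF, int(max_events),
        initial_state.as_array(), np_cap, ne_cap,
    )
    if status == 1:
        raise EventBudgetExceeded(
            f"simulation exceeded the event budget of {max_events:g} events; "
            "shorten t_end, reduce the fast binding rates or raise max_events"
        )
    return {
        "n_p": _normalize_hist(hist_p, "ssa:n_p"),
        "n_etot": _normalize_hist(hist_e, "ssa:n_etot"),
        "n_events": int(nev),
    }


# --------------------------------------------------------------------------
# Finite-state CME oracle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """A reaction channel for the CME oracle.

    ``change`` is the state-change vector and ``rate`` maps an
    (n_states, n_species) integer array of states to propensities.
    """

    change: Tuple[int, ...]
    rate: Callable[[np.ndarray], np.ndarray]
    name: str = ""


def full_network_reactions(rc: RateConstants) -> list:
    """The 12 channels of the full network in SPECIES order."""
    return [
        Reaction((0, 0, -1, +1, 0), lambda S: rc.k_1 * rc.n_s * S[:, 2], "bind"),
        Reaction((0, 0, +1, -1, 0), lambda S: rc.k_m1 * S[:, 3], "unbind"),
        Reaction((0, 0, +1, -1, +1), lambda S: rc.k_cat * S[:, 3], "cat"),
        Reaction((0, 0, -1, +1, -1), lambda S: rc.k_rev * S[:, 2] * S[:, 4], "rev"),
        Reaction((0, 0, +1, 0, 0), lambda S: rc.k_tl * S[:, 1], "translate"),
        Reaction((0, +1, 0, 0, 0), lambda S: rc.k_tx * S[:, 0], "transcribe"),
        Reaction((+1, 0, 0, 0, 0), lambda S: rc.k_on * (1 - S[:, 0]), "on"),
        Reaction((-1, 0, 0, 0, 0), lambda S: rc.k_off * S[:, 0], "off"),
        Reaction((0, 0, 0, 0, -1), lambda S: rc.k_c * S[:, 4], "consume"),
        Reaction((0, -1, 0, 0, 0), lambda S: rc.k_deg * S[:, 1], "deg"),
        Reaction((0, 0, -1, 0, 0), lambda S: rc.delta * S[:, 2], "dilute_e"),
        Reaction((0, 0, 0, -1, 0), lambda S: rc.delta * S[:, 3], "dilute_c"),
    ]


def three_stage_reactions(rc: RateConstants) -> list:
    """Gene expression only (promoter, mRNA, protein), species (dna, m, prot)."""
    return [
        Reaction((+1, 0, 0), lambda S: rc.k_on * (1 - S[:, 0]), "on"),
        Reaction((-1, 0, 0), lambda S: rc.k_off * S[:, 0], "off"),
        Reaction((0, +1, 0), lambda S: rc.k_tx * S[:, 0], "transcribe"),
        Reaction((0, -1, 0), lambda S: rc.k_deg * S[:, 1], "deg"),
        Reaction((0, 0, +1), lambda S: rc.k_tl * S[:, 1], "translate"),
        Reaction((0, 0, -1), lambda S: rc.delta * S[:, 2], "dilute"),
    ]


def birth_death_reactions(birth: float, death_coeff: float) -> list:
    """Constant-birth, linear-death process in one species."""
    return [
        Reaction((+1,), lambda S: np.full(S.shape[0], float(birth)), "birth"),
        Reaction((-1,), lambda S: death_coeff * S[:, 0], "death"),
    ]


def _solve_stationary(A: "sparse.csc_matrix", b: np.ndarray) -> np.ndarray:
    """Solve the normalised stationary system.

    Incomplete-LU preconditioned GMRES first (the generator's LU fill-in on
    multi-species boxes makes a direct factorisation far slower); exact
    sparse LU with the MMD_AT_PLUS_A ordering as fallback.
    """
    n = A.shape[0]
    try:
        ilu = spilu(A, drop_tol=1e-6, fill_factor=30)
        M = LinearOperator((n, n), ilu.solve)
        pi, info = gmres(A, b, M=M, rtol=1e-12, atol=0.0,
                         maxiter=1000, restart=150)
        if info == 0 and np.max(np.abs(A @ pi - b)) < 1e-9:
            return pi
    except RuntimeError:
        pass  # singular ILU pivot; fall through to exact LU
    lu = splu(A, permc_spec="MMD_AT_PLUS_A")
    return lu.solve(b)


def cme_stationary(reactions: Sequence[Reaction], caps: Sequence[int],
                   max_states: int = 2_000_000,
                   boundary_tol: float = 1e-6) -> np.ndarray:
    """Stationary law of the CME truncated to the box prod([0..cap_i]).

    Transitions leaving the box are dropped (reflecting truncation) and the
    stationary distribution of the truncated generator is obtained as the
    solution of pi Q = 0 with normalisation, via a sparse direct solve.
    Returns the distribution reshaped to the box.

    Raises
    ------
    ValueError
        If the box exceeds ``max_states`` states, or if the solution puts
        more than ``boundary_tol`` mass on an outer face of the box (cap
        too small to hold the stationary law).
    """
    dims = tuple(int(c) + 1 for c in caps)
    n_states = int(np.prod(dims))
    if n_states > max_states:
        raise ValueError(f"state space of {n_states} states exceeds cap {max_states}")
    grids = np.indices(dims).reshape(len(dims), -1).T  # (n_states, n_species)
    idx = np.arange(n_states)
    strides = np.array([int(np.prod(dims[i + 1:])) for i in range(len(dims))])

    rows, cols, vals = [], [], []
    diag = np.zeros(n_states)
    for rxn in reactions:
        rates = np.asarray(rxn.rate(grids), dtype=float)
        if rates.shape != (n_states,):
            raise ValueError(f"reaction {rxn.name!r} returned bad rate shape")
        if np.any(rates < 0):
            raise ValueError(f"reaction {rxn.name!r} produced negative rates")
        target = grids + np.asarray(rxn.change)
        inside = np.all((target >= 0) & (target <= np.array(dims) - 1), axis=1)
        live = inside & (rates > 0)
        tgt_idx = target[live] @ strides
        rows.append(tgt_idx)
        cols.append(idx[live])
        vals.append(rates[live])
        diag[idx[live]] -= rates[live]
    rows.append(idx)
    cols.append(idx)
    vals.append(diag)
    Q = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_states, n_states),
    )
    # replace one balance equation by the normalisation sum(pi) = 1
    A = Q.tolil()
    A[0, :] = 1.0
    A = A.tocsc()
    b = np.zeros(n_states)
    b[0] = 1.0
    pi = _solve_stationary(A, b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    pi = pi.reshape(dims)
    # boundary check on genuinely truncated axes: an axis is truncated when
    # some channel at its top face points out of the box with positive rate
    for axis, dim in enumerate(dims):
        face_mask = grids[:, axis] == dim - 1
        truncated = False
        for rxn in reactions:
            if np.asarray(rxn.change)[axis] > 0:
                face_rates = np.asarray(rxn.rate(grids), dtype=float)[face_mask]
                if np.any(face_rates > 0):
                    truncated = True
                    break
        if not truncated:
            continue
        face = np.take(pi, dim - 1, axis=axis).sum()
        if face > boundary_tol:
            raise ValueError(
                f"cap {dim - 1} on axis {axis} too small: boundary mass "
                f"{face:.3e} > {boundary_tol:g}"
            )
    return pi


def cme_marginal(pi: np.ndarray, axis: int) -> np.ndarray:
    """Marginal pmf of one species from a box-shaped stationary law."""
    axes = tuple(i for i in range(pi.ndim) if i != axis)
    return pi.sum(axis=axes)
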