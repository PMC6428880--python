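"""Parameter-space regime maps for metabolite heterogeneity.

Two sweeps reproduce the qualitative analyses of the mixture model:

* :func:`switching_sweep` varies the promoter switching timescale
  (k_on + k_off, log-spaced) and promoter activity (k_on/(k_on + k_off),
  linear) at fixed kinetics, classifying both the enzyme and the metabolite
  distribution at each grid point.  Bimodal metabolite regimes are tagged
  "switching-induced" when the enzyme itself is bimodal and
  "catalytically-induced" when a unimodal enzyme produces a bimodal
  metabolite.
* :func:`kinetic_sweep` varies the effective kinetic parameters
  (lambda_inf, K) at a fixed enzyme distribution.

:func:`kinetic_line` computes the constraint line lambda_inf/K =
epsilon * k_cat / k_c that places measured enzyme turnover numbers in the
(lambda_inf, K) plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .params import RateConstants, three_stage_params
from .gene_expression import DiscretePMF, three_stage_pmf, DEFAULT_TRUNCATION_TOL
from .pmm import PoissonParameterMap, pmm_distribution
from .modality import RegimeLabel, classify, classify_bimodal

__all__ = [
    "GridPoint",
    "RegimeMap",
    "KineticLine",
    "switching_sweep",
    "kinetic_sweep",
    "kinetic_line",
]


@dataclass
class GridPoint:
    """Classification result at one grid point of a regime map."""

    coords: dict
    enzyme_label: Optional[RegimeLabel] = None
    metabolite_label: Optional[RegimeLabel] = None
    regime: str = ""
    error: Optional[str] = None


@dataclass
class RegimeMap:
    """A fully evaluated regime map.

    ``axes`` maps axis names to their grid values; ``points`` is the list
    of evaluated grid points (row-major over the axes); failed points carry
    their error message instead of labels.
    """

    axes: dict
    points: list
    settings: dict = field(default_factory=dict)

    def regimes(self) -> np.ndarray:
        shape = tuple(len(v) for v in self.axes.values())
        return np.array([p.regime for p in self.points]).reshape(shape)

    def to_table(self) -> str:
        """Long-format tab-separated table of the map."""
        axis_names = list(self.axes)
        lines = ["\t".join(axis_names + ["enzyme_label", "metabolite_label",
                                         "regime", "peaks", "error"])]
        for p in self.points:
            peaks = ""
            if p.metabolite_label is not None:
                peaks = ";".join(f"{loc}:{h:.6g}" for loc, h in p.metabolite_label.peaks)
            lines.append("\t".join(
                [f"{p.coords[a]:.10g}" for a in axis_names]
                + [p.enzyme_label.label if p.enzyme_label else "",
                   p.metabolite_label.label if p.metabolite_label else "",
                   p.regime, peaks, p.error or ""]
            ))
        return "\n".join(lines) + "\n"

    def write(self, table_path: Union[str, Path],
              sidecar_path: Optional[Union[str, Path]] = None) -> None:
        Path(table_path).write_text(self.to_table())
        if sidecar_path is not None:
            sidecar = {"axes": {k: list(map(float, v)) for k, v in self.axes.items()},
                       "settings": self.settings}
            Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n")


def _joint_regime(enzyme: RegimeLabel, metabolite: RegimeLabel) -> str:
    e_bimodal = enzyme.label in ("bimodal", "multimodal")
    m_label = metabolite.label
    if m_label == "unimodal":
        return "unimodal"
    if m_label == "multimodal":
        return "multimodal"
    return "switching-induced" if e_bimodal else "catalytically-induced"


def switching_sweep(base: RateConstants,
                    switching_rates: Sequence[float],
                    activities: Sequence[float],
                    lambda_inf: float,
                    K: float,
                    truncation_tol: float = DEFAULT_TRUNCATION_TOL) -> RegimeMap:
    """Regime map over promoter switching timescale and activity.

    ``switching_rates`` is the grid of total switching rates k_on + k_off
    (s^-1, typically log-spaced) and ``activities`` the grid of stationary
    active-state probabilities k_on/(k_on + k_off).  The enzyme pmf is
    evaluated from the three-stage model with the remaining expression
    parameters taken from ``base``; the metabolite pmf from the mixture
    with the given (lambda_inf, K) -- varying lambda_inf corresponds to
    scaling the turnover number k_cat, which leaves K unchanged.

    Numerical failures at individual points are recorded and the sweep
    continues.
    """
    pmap = PoissonParameterMap.from_effective(lambda_inf, K)
    points = []
    for sw in switching_rates:
        for act in activities:
            coords = {"switching_rate": float(sw), "activity": float(act)}
            try:
                rc = base.with_(k_on=float(sw * act), k_off=float(sw * (1.0 - act)))
                enz = three_stage_pmf(three_stage_params(rc), truncation_tol)
                met = pmm_distribution(enz, pmap, truncation_tol)
                e_lab = classify_bimodal(enz)
                m_lab = classify(met)
                points.append(GridPoint(coords, e_lab, m_lab,
                                        _joint_regime(e_lab, m_lab)))
            except Exception as exc:  # per-point failures must not kill the sweep
                points.append(GridPoint(coords, regime="failed", error=str(exc)))
    return RegimeMap(
        axes={"switching_rate": np.asarray(switching_rates, dtype=float),
              "activity": np.asarray(activities, dtype=float)},
        points=points,
        settings={"lambda_inf": lambda_inf, "K": K,
                  "axis_definitions": {
                      "switching_rate": "k_on + k_off (s^-1)",
                      "activity": "k_on / (k_on + k_off)"}},
    )


def kinetic_sweep(enzyme_pmf: DiscretePMF,
                  lambda_inf_grid: Sequence[float],
                  K_grid: Sequence[float],
                  truncation_tol: float = DEFAULT_TRUNCATION_TOL) -> RegimeMap:
    """Regime map over the effective kinetic parameters (lambda_inf, K).

    The enzyme distribution is held fixed across the grid; the mixture
    depends on the kinetics only through (lambda_inf, K).
    """
    points = []
    for li in lambda_inf_grid:
        for K in K_grid:
            coords = {"lambda_inf": float(li), "K": float(K)}
            try:
                pmap = PoissonParameterMap.from_effective(float(li), float(K))
                met = pmm_distribution(enzyme_pmf, pmap, truncation_tol)
                e_lab = classify_bimodal(enzyme_pmf)
                m_lab = classify(met)
                points.append(GridPoint(coords, e_lab, m_lab,
                                        _joint_regime(e_lab, m_lab)))
            except Exception as exc:
                points.append(GridPoint(coords, regime="failed", error=str(exc)))
    return RegimeMap(
        axes={"lambda_inf": np.asarray(lambda_inf_grid, dtype=float),
              "K": np.asarray(K_grid, dtype=float)},
        points=points,
        settings={"enzyme_provenance": enzyme_pmf.provenance},
    )


@dataclass(frozen=True)
class KineticLine:
    """The constraint line lambda_inf = slope * K in the (lambda_inf, K) plane.

    ``slope`` is epsilon * k_cat / k_c; ``band`` optionally holds the
    (low, high) slopes spanned by a k_cat range.
    """

    epsilon: float
    k_cat: float
    k_c: float
    slope: float
    band: Optional[tuple] = None


def kinetic_line(epsilon: float, k_cat: float, k_c: float,
                 k_cat_range: Optional[tuple] = None) -> KineticLine:
    """Constraint line lambda_inf/K = epsilon * k_cat/k_c.

    ``epsilon`` is the enzyme saturation in (0, 1], ``k_cat`` the turnover
    number (s^-1) and ``k_c`` the metabolite consumption rate constant
    (s^-1); an optional (low, high) ``k_cat_range`` produces the band of
    slopes it spans.
    """
    if not (0 < epsilon <= 1) or k_cat <= 0 or k_c <= 0:
        raise ValueError("need 0 < epsilon <= 1, k_cat > 0, k_c > 0")
    slope = epsilon * k_cat / k_c
    band = None
    if k_cat_range is not None:
        lo, hi = k_cat_range
        if not (0 < lo <= hi):
            raise ValueError("k_cat_range must be 0 < low <= high")
        band = (epsilon * lo / k_c, epsilon * hi / k_c)
    return KineticLine(epsilon=epsilon, k_cat=k_cat, k_c=k_c,
                       slope=slope, band=band)
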