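"""Classification of discrete distributions as uni-, bi- or multimodal.

The detection rules operate directly on the probability mass function:

* bimodal -- some pair of peaks has the smaller peak at least 10% as high
  as the larger one AND the trough between them at most 10% of the smaller
  peak's height;
* multimodal -- a bimodal pair exists AND at least one additional peak is
  higher than an absolute threshold of 1e-4 with the trough towards its
  neighbouring peak at most 90% of the smaller of the two neighbouring
  peak heights.

Multimodal takes precedence over bimodal, which takes precedence over
unimodal.  The bimodality rule is scale-free (ratios of heights only); the
multimodality rule is not, because of the absolute 1e-4 peak threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

import numpy as np

from .gene_expression import DiscretePMF

__all__ = [
    "RegimeLabel",
    "find_peaks",
    "classify",
    "classify_bimodal",
    "classify_multimodal",
    "BIMODAL_PEAK_RATIO",
    "BIMODAL_TROUGH_RATIO",
    "MULTIMODAL_PEAK_HEIGHT",
    "MULTIMODAL_TROUGH_RATIO",
]

BIMODAL_PEAK_RATIO = 0.10      # smaller peak >= 10% of larger peak
BIMODAL_TROUGH_RATIO = 0.10    # trough <= 10% of smaller peak
MULTIMODAL_PEAK_HEIGHT = 1e-4  # absolute height for a significant peak
MULTIMODAL_TROUGH_RATIO = 0.90 # trough <= 90% of smaller neighbouring peak
FP_NOISE_FLOOR = 1e-15         # masses below this are treated as zero


@dataclass
class RegimeLabel:
    """Modality label with its peak/trough evidence.

    ``peaks`` and ``troughs`` are (location, height) pairs; ``rule_trace``
    records which thresholds fired (or failed) so alternative rule readings
    can be compared without recomputation.
    """

    label: str
    peaks: List[Tuple[int, float]]
    troughs: List[Tuple[int, float]]
    rule_trace: dict = field(default_factory=dict)

    def __str__(self) -> str:
        return self.label


def _as_probs(pmf: Union[DiscretePMF, np.ndarray, Sequence[float]]) -> np.ndarray:
    if isinstance(pmf, DiscretePMF):
        return pmf.probs
    arr = np.asarray(pmf, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("pmf must be a non-empty 1-D array")
    return arr


def _smooth(probs: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of half-width ``window`` (0 = off).

    Intended for finite-sample simulation histograms, where shot noise
    creates spurious local maxima; analytic pmfs are classified unsmoothed.
    """
    if window <= 0:
        return probs
    kernel = np.ones(2 * window + 1) / (2 * window + 1)
    return np.convolve(probs, kernel, mode="same")


def find_peaks(pmf, smooth_window: int = 0) -> Tuple[list, list]:
    """Locate peaks and the troughs between adjacent peaks.

    An index i is a peak when probs[i] >= probs[i-1] and probs[i] >
    probs[i+1]; a plateau run counts once, at its leftmost index.  Index 0
    is a peak when probs[0] > probs[1]; the last index when it is not below
    its left neighbour.  The trough between two adjacent peaks is the
    minimum mass strictly between them.

    Returns (peaks, troughs) as lists of (location, height); troughs has
    one entry less than peaks.
    """
    probs = _smooth(_as_probs(pmf), smooth_window)
    # kill denormal/underflow chatter in deep tails, which otherwise
    # produces spurious local maxima of vanishing height
    probs = np.where(probs < FP_NOISE_FLOOR, 0.0, probs)
    n = probs.size
    if n == 1:
        return [(0, float(probs[0]))], []
    peaks: List[Tuple[int, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and probs[j + 1] == probs[i]:
            j += 1  # maximal plateau run [i, j]; neighbours differ strictly
        left_ok = (i == 0) or (probs[i] > probs[i - 1])
        right_ok = (j == n - 1) or (probs[i] > probs[j + 1])
        if left_ok and right_ok:
            peaks.append((i, float(probs[i])))
        i = j + 1
    troughs: List[Tuple[int, float]] = []
    for (loc_a, _), (loc_b, _) in zip(peaks, peaks[1:]):
        inner = probs[loc_a + 1:loc_b]
        k = int(np.argmin(inner))
        troughs.append((loc_a + 1 + k, float(inner[k])))
    return peaks, troughs


def classify(pmf, smooth_window: int = 0,
             peak_floor: float = MULTIMODAL_PEAK_HEIGHT) -> RegimeLabel:
    """Classify a pmf as unimodal / bimodal / multimodal.

    Applies the bimodality rule over all candidate peak pairs and then the
    multimodality rule over remaining peaks, with precedence multimodal >
    bimodal > unimodal.  Only peaks higher than ``peak_floor`` count as
    candidates: the absolute significance threshold that the multimodality
    rule states (1e-4) is applied to all peaks, since the detection rules
    compare peak-height ratios and a pmf evaluated in double precision
    carries genuine but negligible local maxima deep in its tails.
    """
    all_peaks, troughs = find_peaks(pmf, smooth_window)
    probs = _smooth(_as_probs(pmf), smooth_window)
    peaks = [pk for pk in all_peaks if pk[1] > peak_floor] or all_peaks[:1]
    trace: dict = {"n_peaks": len(peaks), "peak_floor": peak_floor,
                   "n_peaks_unfiltered": len(all_peaks)}
    label = "unimodal"
    bimodal_pair = None

    if len(peaks) >= 2:
        locs = [p[0] for p in peaks]
        heights = [p[1] for p in peaks]
        # trough between any (not necessarily adjacent) peak pair
        for ia in range(len(peaks)):
            for ib in range(ia + 1, len(peaks)):
                hi, lo = max(heights[ia], heights[ib]), min(heights[ia], heights[ib])
                if lo < BIMODAL_PEAK_RATIO * hi:
                    continue
                trough = float(probs[locs[ia] + 1:locs[ib]].min())
                if trough <= BIMODAL_TROUGH_RATIO * lo:
                    bimodal_pair = (ia, ib)
                    trace["bimodal_pair"] = (locs[ia], locs[ib])
                    trace["bimodal_trough"] = trough
                    break
            if bimodal_pair:
                break
        if bimodal_pair:
            label = "bimodal"

    if bimodal_pair and len(peaks) >= 3:
        ia, ib = bimodal_pair
        extras = []
        for ic, (loc, h) in enumerate(peaks):
            if ic in (ia, ib) or h <= MULTIMODAL_PEAK_HEIGHT:
                continue
            # trough towards the nearest neighbouring peak
            for neigh in (ic - 1, ic + 1):
                if not (0 <= neigh < len(peaks)):
                    continue
                lo_loc, hi_loc = sorted((peaks[ic][0], peaks[neigh][0]))
                trough = float(probs[lo_loc + 1:hi_loc].min())
                smaller = min(h, peaks[neigh][1])
                if trough <= MULTIMODAL_TROUGH_RATIO * smaller:
                    extras.append((loc, h))
                    break
        if extras:
            label = "multimodal"
            trace["extra_peaks"] = extras
    return RegimeLabel(label=label, peaks=peaks, troughs=troughs, rule_trace=trace)


def classify_bimodal(pmf, smooth_window: int = 0) -> RegimeLabel:
    """Apply only the two-peak 10%/10% rule (no multimodality precedence)."""
    full = classify(pmf, smooth_window)
    label = "bimodal" if "bimodal_pair" in full.rule_trace else "unimodal"
    return RegimeLabel(label=label, peaks=full.peaks, troughs=full.troughs,
                       rule_trace=full.rule_trace)


def classify_multimodal(pmf, smooth_window: int = 0) -> RegimeLabel:
    """Full classification with multimodal precedence (alias of classify)."""
    return classify(pmf, smooth_window)
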