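"""MMN feature extraction: amplitude, latency, area under the curve.

Features are measured on the ROI-averaged difference wave.  The MMN peak is
the most negative sample in the 100-250 ms post-stimulus window; its
amplitude is referenced to the nearest local maximum of the wave (searched
outward in time from the peak, preceding side preferred on ties, falling
back to the 0 uV prestimulus baseline when no local maximum exists).  The
area under the curve integrates (reference - wave) over the contiguous
interval around the peak where the wave stays below the reference level,
bounded by the reference-level crossings (linearly interpolated) or the
epoch edges, giving uV*ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evoked import DifferenceWave, polarity_reversal_check
from .paradigm import DEVIANT_KINDS, DeviantKind
from .synthetic_eeg import ChannelLayout

__all__ = ["PeakResult", "MMNFeatureSet", "find_peak", "reference_extremum",
           "area_under_curve", "measure_wave", "extract_features",
           "features_to_table", "MMN_WINDOW_MS"]

MMN_WINDOW_MS: tuple[float, float] = (100.0, 250.0)


@dataclass(frozen=True)
class PeakResult:
    latency_ms: float
    raw_value_uV: float
    reference_level_uV: float = np.nan
    relative_amplitude_uV: float = np.nan


@dataclass(frozen=True)
class MMNFeatureSet:
    subject_id: str
    group: str
    amplitude_uV: dict[DeviantKind, float]
    latency_ms: dict[DeviantKind, float]
    auc_uVms: dict[DeviantKind, float]
    reference_uV: dict[DeviantKind, float]
    reversal_ok: dict[DeviantKind, bool]


def find_peak(roi_wave: np.ndarray, times_ms: np.ndarray,
              window_ms: tuple[float, float] = MMN_WINDOW_MS) -> PeakResult:
    """Most negative sample in the window; earliest time wins ties."""
    mask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} ms contains no samples")
    idx = np.flatnonzero(mask)
    rel = int(np.argmin(roi_wave[idx]))  # argmin returns the first minimum
    i = idx[rel]
    return PeakResult(latency_ms=float(times_ms[i]),
                      raw_value_uV=float(roi_wave[i]))


def _local_maxima(wave: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima (plateau edges count once)."""
    d = np.diff(wave)
    rising = d > 0
    falling = d < 0
    out = []
    last_rise = None
    for i in range(len(d)):
        if rising[i]:
            last_rise = i + 1
        elif falling[i] and last_rise is not None:
            out.append(last_rise if wave[last_rise] >= wave[i] else i)
            last_rise = None
    return np.array(sorted(set(out)), dtype=int)


def reference_extremum(roi_wave: np.ndarray, times_ms: np.ndarray,
                       peak: PeakResult) -> float:
    """Value of the local maximum nearest in time to the MMN peak.

    Searches outward on both sides; on equidistant candidates the preceding
    (earlier) one is used.  Returns 0 uV (the prestimulus baseline level)
    when the wave has no interior local maximum.
    """
    maxima = _local_maxima(roi_wave)
    if maxima.size == 0:
        return 0.0
    peak_idx = int(np.argmin(np.abs(times_ms - peak.latency_ms)))
    dist = np.abs(maxima - peak_idx)
    best = np.min(dist)
    candidates = maxima[dist == best]
    before = candidates[candidates <= peak_idx]
    chosen = int(before.max()) if before.size else int(candidates.min())
    return float(roi_wave[chosen])


def area_under_curve(roi_wave: np.ndarray, times_ms: np.ndarray,
                     peak: PeakResult, reference_level_uV: float) -> float:
    """Area between the reference level and the wave around the MMN peak.

    Integrates ``reference - wave`` with the trapezoidal rule over the
    maximal interval containing the peak on which the wave lies below the
    reference, ending at linearly interpolated reference crossings (or the
    epoch edges).  Returns 0 with a warning when the peak does not lie below
    the reference.
    """
    peak_idx = int(np.argmin(np.abs(times_ms - peak.latency_ms)))
    depth = reference_level_uV - roi_wave  # positive below reference
    if depth[peak_idx] <= 0:
        warnings.warn("MMN peak is not below the reference level; AUC = 0")
        return 0.0

    lo = peak_idx
    while lo > 0 and depth[lo - 1] > 0:
        lo -= 1
    hi = peak_idx
    n = len(roi_wave)
    while hi < n - 1 and depth[hi + 1] > 0:
        hi += 1

    t = list(times_ms[lo:hi + 1])
    d = list(depth[lo:hi + 1])
    if lo > 0:  # interpolate the left crossing (depth goes 0 at t_cross)
        f = depth[lo] / (depth[lo] - depth[lo - 1])
        t.insert(0, times_ms[lo] - f * (times_ms[lo] - times_ms[lo - 1]))
        d.insert(0, 0.0)
    if hi < n - 1:
        f = depth[hi] / (depth[hi] - depth[hi + 1])
        t.append(times_ms[hi] + f * (times_ms[hi + 1] - times_ms[hi]))
        d.append(0.0)
    return float(np.trapezoid(d, t))


def measure_wave(roi_wave: np.ndarray, times_ms: np.ndarray,
                 window_ms: tuple[float, float] = MMN_WINDOW_MS
                 ) -> tuple[PeakResult, float]:
    """Peak + reference + relative amplitude + AUC for one ROI trace."""
    partial = find_peak(roi_wave, times_ms, window_ms)
    ref = reference_extremum(roi_wave, times_ms, partial)
    peak = PeakResult(
        latency_ms=partial.latency_ms, raw_value_uV=partial.raw_value_uV,
        reference_level_uV=ref,
        relative_amplitude_uV=partial.raw_value_uV - ref,
    )
    if peak.raw_value_uV < ref:
        auc = area_under_curve(roi_wave, times_ms, peak, ref)
    else:
        auc = 0.0
    return peak, auc


def extract_features(
    subject_id: str,
    group: str,
    diff_waves: dict[DeviantKind, DifferenceWave],
    layout: ChannelLayout | None = None,
    window_ms: tuple[float, float] = MMN_WINDOW_MS,
) -> MMNFeatureSet:
    """Assemble the per-subject feature set over all deviant classes.

    A missing deviant class yields NaN features (never fabricated values).
    """
    amp: dict[DeviantKind, float] = {}
    lat: dict[DeviantKind, float] = {}
    auc: dict[DeviantKind, float] = {}
    ref: dict[DeviantKind, float] = {}
    rev: dict[DeviantKind, bool] = {}
    for kind in DEVIANT_KINDS:
        dw = diff_waves.get(kind)
        if dw is None:
            amp[kind] = lat[kind] = auc[kind] = ref[kind] = float("nan")
            rev[kind] = False
            continue
        peak, a = measure_wave(dw.roi_trace, dw.times_ms, window_ms)
        amp[kind] = peak.relative_amplitude_uV
        lat[kind] = peak.latency_ms
        auc[kind] = a
        ref[kind] = peak.reference_level_uV
        rev[kind] = bool(polarity_reversal_check(dw, window_ms)["reversed"])
    return MMNFeatureSet(subject_id=subject_id, group=group, amplitude_uV=amp,
                         latency_ms=lat, auc_uVms=auc, reference_uV=ref,
                         reversal_ok=rev)


def features_to_table(feature_sets: list[MMNFeatureSet]) -> pd.DataFrame:
    """Long-format feature table: one row per subject x deviant class."""
    rows = []
    for fs in feature_sets:
        for kind in DEVIANT_KINDS:
            rows.append({
                "subject_id": fs.subject_id, "group": fs.group,
                "deviant_kind": kind.value,
                "amplitude_uV": fs.amplitude_uV[kind],
                "latency_ms": fs.latency_ms[kind],
                "auc_uVms": fs.auc_uVms[kind],
                "reference_uV": fs.reference_uV[kind],
                "reversal_ok": fs.reversal_ok[kind],
            })
    return pd.DataFrame(rows)
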