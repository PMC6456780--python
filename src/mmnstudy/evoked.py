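"""Condition averages, deviant-minus-standard difference waves, ROI collapse.

The MMN is read from the difference wave (deviant evoked minus standard
evoked) averaged over the frontocentral region of interest (F3, F4, Fz,
FC3, FC4, FCz, Cz).  Under a nose reference a genuine auditory MMN reverses
polarity at the mastoids (M1/M2), which is checked explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paradigm import DeviantKind
from .preprocess import EpochSet
from .synthetic_eeg import MASTOID_CHANNELS, ROI_CHANNELS, ChannelLayout

__all__ = ["Evoked", "DifferenceWave", "average_by_condition",
           "difference_wave", "polarity_reversal_check"]


@dataclass(frozen=True)
class Evoked:
    data: np.ndarray  # channels x samples, uV
    times_ms: np.ndarray
    layout: ChannelLayout
    condition: DeviantKind
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("an evoked response needs at least one trial")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("evoked contains non-finite values")


@dataclass(frozen=True)
class DifferenceWave:
    data: np.ndarray  # channels x samples, uV
    times_ms: np.ndarray
    layout: ChannelLayout
    kind: DeviantKind
    roi_trace: np.ndarray
    roi_labels: tuple[str, ...] = ROI_CHANNELS


def average_by_condition(epochs: EpochSet,
                         kinds=None) -> dict[DeviantKind, Evoked]:
    """Arithmetic mean over kept trials, separately per stimulus condition.

    Raises naming the condition if one of the requested kinds has no kept
    trials.
    """
    if kinds is None:
        kinds = sorted({k for k in epochs.kinds}, key=lambda k: k.value)
    out: dict[DeviantKind, Evoked] = {}
    kept = epochs.keep
    kind_arr = np.array([k.value for k in epochs.kinds])
    for kind in kinds:
        sel = kept & (kind_arr == kind.value)
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"no kept trials for condition {kind.value!r}")
        out[kind] = Evoked(
            data=epochs.data[sel].mean(axis=0), times_ms=epochs.times_ms,
            layout=epochs.layout, condition=kind, n_trials=n,
        )
    return out


def roi_average(data: np.ndarray, layout: ChannelLayout,
                roi=ROI_CHANNELS) -> np.ndarray:
    """Unweighted mean over the ROI channels."""
    return data[layout.indices(roi)].mean(axis=0)


def difference_wave(deviant: Evoked, standard: Evoked,
                    roi=ROI_CHANNELS) -> DifferenceWave:
    """Channel-wise deviant-minus-standard wave with its ROI trace."""
    if deviant.data.shape != standard.data.shape or not np.array_equal(
            deviant.times_ms, standard.times_ms):
        raise ValueError("deviant and standard evoked have mismatched axes")
    if deviant.layout.labels != standard.layout.labels:
        raise ValueError("deviant and standard evoked have different layouts")
    diff = deviant.data - standard.data
    return DifferenceWave(
        data=diff, times_ms=deviant.times_ms, layout=deviant.layout,
        kind=deviant.condition, roi_trace=roi_average(diff, deviant.layout, roi),
        roi_labels=tuple(roi),
    )


def polarity_reversal_check(diff: DifferenceWave,
                            window_ms: tuple[float, float] = (100.0, 250.0),
                            windowed_mean: bool = False) -> dict:
    """Mastoid polarity-reversal validity check of an MMN difference wave.

    Finds the ROI negative peak inside ``window_ms`` and reports whether the
    mean of M1 and M2 there has opposite sign to the ROI value.  With
    ``windowed_mean`` the comparison uses window-mean values instead of the
    instantaneous values at the peak latency.
    """
    missing = [c for c in MASTOID_CHANNELS if c not in diff.layout.labels]
    if missing:
        raise ValueError(f"mastoid channels missing: {missing}")
    mask = (diff.times_ms >= window_ms[0]) & (diff.times_ms <= window_ms[1])
    if not mask.any():
        raise ValueError("polarity window outside the epoch")
    m_idx = diff.layout.indices(MASTOID_CHANNELS)
    if windowed_mean:
        roi_val = float(diff.roi_trace[mask].mean())
        mast = float(diff.data[m_idx][:, mask].mean())
    else:
        peak_rel = int(np.argmin(diff.roi_trace[mask]))
        peak_idx = int(np.flatnonzero(mask)[peak_rel])
        roi_val = float(diff.roi_trace[peak_idx])
        mast = float(diff.data[m_idx, peak_idx].mean())
    reversed_ = bool(roi_val * mast < 0)
    m1, m2 = (float(v) for v in (
        diff.data[m_idx[0], mask].mean(), diff.data[m_idx[1], mask].mean())
    ) if windowed_mean else (
        float(diff.data[m_idx[0], peak_idx]), float(diff.data[m_idx[1], peak_idx]))
    return {"reversed": reversed_, "m1_value": m1, "m2_value": m2,
            "roi_value": roi_val}


def evoked_to_frame(ev: Evoked | DifferenceWave) -> pd.DataFrame:
    """Wide CSV-ready table: time column plus one column per channel."""
    df = pd.DataFrame(ev.data.T, columns=list(ev.layout.labels))
    df.insert(0, "time_ms", ev.times_ms)
    return df
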