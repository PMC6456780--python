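"""Forward simulation of oddball EEG with known mismatch-negativity (MMN) truth.

Each subject's recording is a linear superposition on a 31-channel montage
(29 scalp sites, nose reference, plus two EOG channels, 1,024 Hz):

* obligatory N1/P2 Gaussian kernels time-locked to every stimulus,
* an MMN Gaussian on deviant trials only, with per-deviant-class amplitude
  and latency drawn from the subject's group distribution,
* 1/f background noise, posterior-dominant alpha, frontal eye blinks
  mirrored on the EOG channels, and optional 50 Hz line interference.

The MMN topography is frontocentral-negative with polarity reversal at the
mastoids (M1/M2), matching the validation criterion used for real MMN under
a nose reference.  Group amplitude/latency distributions default to the
published cohort means/SDs for normal-control, compensated-tinnitus and
decompensated-tinnitus groups, so that downstream parameter-recovery tests
have exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .paradigm import DEVIANT_KINDS, DeviantKind, TrialEvent, events_to_frame, read_events

__all__ = [
    "SCALP_CHANNELS", "EOG_CHANNELS", "ROI_CHANNELS", "MASTOID_CHANNELS",
    "SAMPLE_RATE_HZ", "ChannelLayout", "ComponentKernel", "NoiseModel",
    "ZERO_NOISE", "SubjectProfile",
    "RawRecording", "GROUPS", "default_group_parameters", "sample_cohort",
    "mmn_topography", "simulate_subject", "write_recording", "read_recording",
]

SAMPLE_RATE_HZ = 1024.0

SCALP_CHANNELS: tuple[str, ...] = (
    "FP1", "FPz", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8", "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8", "P3", "Pz", "P4", "POz", "M1", "M2",
)
EOG_CHANNELS: tuple[str, ...] = ("EOG_lower", "EOG_canthus")
ROI_CHANNELS: tuple[str, ...] = ("F3", "F4", "Fz", "FC3", "FC4", "FCz", "Cz")
MASTOID_CHANNELS: tuple[str, ...] = ("M1", "M2")

GROUPS: tuple[str, ...] = ("control", "compensated", "decompensated")


@dataclass(frozen=True)
class ChannelLayout:
    """Electrode montage: 29 scalp sites plus two EOG channels, nose reference."""

    labels: tuple[str, ...] = SCALP_CHANNELS + EOG_CHANNELS
    reference: str = "nose"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        missing = [c for c in ROI_CHANNELS + MASTOID_CHANNELS if c not in self.labels]
        if missing:
            raise ValueError(f"layout missing required channels: {missing}")

    @property
    def scalp(self) -> tuple[str, ...]:
        return tuple(c for c in self.labels if c not in EOG_CHANNELS)

    @property
    def eog(self) -> tuple[str, ...]:
        return tuple(c for c in self.labels if c in EOG_CHANNELS)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(c) for c in labels])


@dataclass(frozen=True)
class ComponentKernel:
    """Gaussian ERP component: amplitude (signed, uV) at a latency, SD width."""

    name: str
    amplitude_uV: float
    latency_ms: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0 or self.latency_ms <= 0:
            raise ValueError("kernel latency and width must be positive")

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        return self.amplitude_uV * np.exp(
            -0.5 * ((t_ms - self.latency_ms) / self.width_ms) ** 2
        )


@dataclass(frozen=True)
class NoiseModel:
    pink_exponent: float = 1.0
    pink_rms_uV: float = 8.0
    alpha_rms_uV: float = 3.0
    alpha_freq_hz: float = 10.0
    blink_rate_per_min: float = 12.0
    blink_amp_uV: float = 150.0
    line_50hz_rms_uV: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pink_rms_uV", "alpha_rms_uV", "blink_rate_per_min",
                     "line_50hz_rms_uV"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


ZERO_NOISE = NoiseModel(pink_rms_uV=0.0, alpha_rms_uV=0.0,
                        blink_rate_per_min=0.0, line_50hz_rms_uV=0.0)


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str
    mmn_amplitude_uV: dict[DeviantKind, float]
    mmn_latency_ms: dict[DeviantKind, float]
    n1: ComponentKernel = ComponentKernel("N1", -4.0, 100.0, 15.0)
    p2: ComponentKernel = ComponentKernel("P2", 3.0, 180.0, 25.0)
    mmn_width_ms: float = 25.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for k, a in self.mmn_amplitude_uV.items():
            if a > 0:
                raise ValueError(f"MMN amplitude for {k} must be <= 0 (negativity)")
        for k, lat in self.mmn_latency_ms.items():
            if not (100.0 <= lat <= 250.0):
                raise ValueError(f"MMN latency for {k} outside [100, 250] ms")


@dataclass
class RawRecording:
    """Multichannel EEG in uV with event markers."""

    data: np.ndarray  # channels x samples
    sample_rate_hz: float
    layout: ChannelLayout
    events: list[TrialEvent]

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.layout.labels):
            raise ValueError("data rows do not match layout")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        n_s = self.data.shape[1]
        for e in self.events:
            if not (0 <= e.onset_s * self.sample_rate_hz < n_s):
                raise ValueError(f"event at {e.onset_s} s outside recording span")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RawRecording":
        return RawRecording(self.data.copy(), self.sample_rate_hz,
                           self.layout, list(self.events))


# Published cohort parameters: (mean, SD) of MMN amplitude [uV] and latency
# [ms] per deviant class for the three groups (n = 20 per group).
_AMPLITUDE_TABLE = {
    DeviantKind.FREQUENCY_HIGH: {"control": (-5.49, 1.68),
                                 "compensated": (-6.64, 2.08),
                                 "decompensated": (-3.78, 1.55)},
    DeviantKind.FREQUENCY_LOW: {"control": (-3.04, 1.65),
                                "compensated": (-4.02, 1.95),
                                "decompensated": (-3.39, 1.66)},
    DeviantKind.DURATION: {"control": (-3.00, 1.14),
                           "compensated": (-3.70, 1.66),
                           "decompensated": (-2.90, 1.47)},
    DeviantKind.GAP: {"control": (-4.20, 1.16),
                      "compensated": (-4.03, 2.13),
                      "decompensated": (-2.85, 1.53)},
}
_LATENCY_TABLE = {
    DeviantKind.FREQUENCY_HIGH: {"control": (150.27, 7.75),
                                 "compensated": (158.14, 10.67),
                                 "decompensated": (152.35, 18.03)},
    DeviantKind.FREQUENCY_LOW: {"control": (149.64, 16.45),
                                "compensated": (140.45, 17.43),
                                "decompensated": (146.74, 19.74)},
    DeviantKind.DURATION: {"control": (143.60, 15.22),
                           "compensated": (145.83, 15.37),
                           "decompensated": (137.44, 15.63)},
    DeviantKind.GAP: {"control": (143.98, 10.99),
                      "compensated": (151.44, 16.68),
                      "decompensated": (144.92, 17.74)},
}


def default_group_parameters() -> dict[str, dict[DeviantKind, dict[str, float]]]:
    """Cohort MMN distributions per group and deviant class.

    Returns ``{group: {kind: {amplitude_mean, amplitude_sd, latency_mean,
    latency_sd}}}`` with the published subject-level means/SDs.
    """
    out: dict[str, dict[DeviantKind, dict[str, float]]] = {}
    for g in GROUPS:
        out[g] = {}
        for kind in DEVIANT_KINDS:
            am, asd = _AMPLITUDE_TABLE[kind][g]
            lm, lsd = _LATENCY_TABLE[kind][g]
            out[g][kind] = {
                "amplitude_mean": am, "amplitude_sd": asd,
                "latency_mean": lm, "latency_sd": lsd,
            }
    return out


def sample_cohort(
    n_per_group: int,
    seed: int = 0,
    noise: NoiseModel | None = None,
    amplitude_sd_scale: float = 1.0,
    latency_sd_scale: float = 1.0,
) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles from the group distributions.

    Per-subject amplitudes/latencies are independent normal draws from the
    group (mean, SD); amplitudes are clipped at 0 (MMN is a negativity) and
    latencies to [100, 250] ms.  The SD scale factors allow noise-free
    (``0``) cohorts pinned at the group means.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    params = default_group_parameters()
    rng = np.random.default_rng(seed)
    noise = noise if noise is not None else NoiseModel()
    cohort: list[SubjectProfile] = []
    for g in GROUPS:
        for i in range(n_per_group):
            amps, lats = {}, {}
            for kind in DEVIANT_KINDS:
                p = params[g][kind]
                a = rng.normal(p["amplitude_mean"],
                               p["amplitude_sd"] * amplitude_sd_scale)
                lat = rng.normal(p["latency_mean"],
                                 p["latency_sd"] * latency_sd_scale)
                amps[kind] = min(a, 0.0)
                lats[kind] = float(np.clip(lat, 100.0, 250.0))
            cohort.append(SubjectProfile(
                subject_id=f"{g}_{i + 1:02d}", group=g,
                mmn_amplitude_uV=amps, mmn_latency_ms=lats,
                noise=noise, seed=int(rng.integers(2**31 - 1)),
            ))
    return cohort


def mmn_topography(layout: ChannelLayout) -> np.ndarray:
    """Per-channel gain of the frontocentral MMN source.

    ROI channels 1.0, immediate neighbours 0.5, mastoids -0.4 (polarity
    reversal under the nose reference), remaining scalp 0.1, EOG 0.
    """
    neighbours = {"F7", "F8", "FT7", "FT8", "C3", "C4", "CP3", "CPz", "CP4"}
    gains = np.zeros(len(layout.labels))
    for i, ch in enumerate(layout.labels):
        if ch in EOG_CHANNELS:
            gains[i] = 0.0
        elif ch in ROI_CHANNELS:
            gains[i] = 1.0
        elif ch in MASTOID_CHANNELS:
            gains[i] = -0.4
        elif ch in neighbours:
            gains[i] = 0.5
        else:
            gains[i] = 0.1
    return gains


def _obligatory_topography(layout: ChannelLayout) -> np.ndarray:
    # N1/P2 share the frontocentral distribution of the MMN source
    return mmn_topography(layout)


def _blink_topography(layout: ChannelLayout) -> np.ndarray:
    """Frontal-dominant blink field, full amplitude on the EOG channels."""
    frontal = {"FP1": 0.8, "FPz": 0.8, "FP2": 0.8,
               "F7": 0.4, "F3": 0.4, "Fz": 0.4, "F4": 0.4, "F8": 0.4,
               "FT7": 0.15, "FC3": 0.15, "FCz": 0.15, "FC4": 0.15, "FT8": 0.15}
    gains = np.zeros(len(layout.labels))
    for i, ch in enumerate(layout.labels):
        if ch in EOG_CHANNELS:
            gains[i] = 1.0
        else:
            gains[i] = frontal.get(ch, 0.02)
    return gains


def _alpha_topography(layout: ChannelLayout) -> np.ndarray:
    posterior = {"P3": 1.0, "Pz": 1.0, "P4": 1.0, "POz": 1.0,
                 "CP3": 0.6, "CPz": 0.6, "CP4": 0.6, "TP7": 0.5, "TP8": 0.5}
    gains = np.zeros(len(layout.labels))
    for i, ch in enumerate(layout.labels):
        if ch in EOG_CHANNELS:
            gains[i] = 0.0
        else:
            gains[i] = posterior.get(ch, 0.2)
    return gains


def _pink_noise(rng: np.random.Generator, n_ch: int, n_s: int,
                exponent: float, rms: float) -> np.ndarray:
    """Independent 1/f^exponent noise per channel, scaled to target RMS."""
    white = rng.standard_normal((n_ch, n_s))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_s, d=1.0)
    freqs[0] = freqs[1]  # avoid DC blow-up
    spec *= freqs ** (-exponent / 2.0)
    pink = np.fft.irfft(spec, n=n_s, axis=1)
    std = pink.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return pink / std * rms


def _blink_train(rng: np.random.Generator, n_s: int, fs: float,
                 rate_per_min: float, amp: float) -> np.ndarray:
    """Poisson train of ~300 ms Hann-shaped positive blink pulses."""
    out = np.zeros(n_s)
    n_blinks = rng.poisson(rate_per_min * n_s / fs / 60.0)
    width = int(round(0.300 * fs))
    pulse = amp * np.hanning(width)
    for onset in np.sort(rng.integers(0, max(n_s - width, 1), size=n_blinks)):
        out[onset:onset + width] += pulse[: n_s - onset]
    return out


def simulate_subject(
    profile: SubjectProfile,
    events: list[TrialEvent],
    noise: NoiseModel | None = None,
    duration_pad_s: float = 1.5,
    start_pad_s: float = 1.0,
    layout: ChannelLayout | None = None,
    sample_rate_hz: float = SAMPLE_RATE_HZ,
) -> RawRecording:
    """Render one subject's continuous recording for an event schedule.

    Every stimulus evokes the subject's N1 and P2 kernels; deviant trials
    additionally evoke the MMN kernel with that class's amplitude/latency.
    Kernel latencies are measured from stimulus onset.  Channel patterns are
    fixed gain maps (linear instantaneous mixing), so evoked responses add
    and the injected MMN is recoverable exactly in the noise-free case.

    ``start_pad_s`` of recording precedes the first stimulus (event onsets
    are shifted accordingly) so that every epoch has prestimulus support.
    """
    layout = layout or ChannelLayout()
    noise = noise if noise is not None else profile.noise
    if not events:
        raise ValueError("no events to simulate")
    if start_pad_s > 0:
        events = [replace(e, onset_s=e.onset_s + start_pad_s) for e in events]
    fs = sample_rate_hz
    t_end = max(e.onset_s for e in events) + duration_pad_s
    n_s = int(round(t_end * fs))
    n_ch = len(layout.labels)
    rng = np.random.default_rng(profile.seed)

    data = np.zeros((n_ch, n_s))
    topo = mmn_topography(layout)
    kernel_span_ms = 500.0
    n_k = int(round(kernel_span_ms / 1000.0 * fs))
    t_ms = np.arange(n_k) / fs * 1000.0
    oblig = profile.n1.waveform(t_ms) + profile.p2.waveform(t_ms)

    for e in events:
        i0 = int(round(e.onset_s * fs))
        seg = slice(i0, min(i0 + n_k, n_s))
        n_seg = seg.stop - seg.start
        if n_seg <= 0:
            raise ValueError(f"event at {e.onset_s} s past recording end")
        resp = oblig[:n_seg].copy()
        if e.kind is not DeviantKind.STANDARD:
            mmn = ComponentKernel(
                "MMN", profile.mmn_amplitude_uV[e.kind],
                profile.mmn_latency_ms[e.kind], profile.mmn_width_ms,
            )
            resp += mmn.waveform(t_ms[:n_seg])
        data[:, seg] += topo[:, None] * resp[None, :]

    if noise.pink_rms_uV > 0:
        scalp_idx = layout.indices(layout.scalp)
        pink = _pink_noise(rng, len(scalp_idx), n_s,
                           noise.pink_exponent, noise.pink_rms_uV)
        data[scalp_idx] += pink
        # EOG channels carry attenuated background noise of their own
        eog_idx = layout.indices(layout.eog)
        data[eog_idx] += _pink_noise(rng, len(eog_idx), n_s,
                                     noise.pink_exponent, 0.5 * noise.pink_rms_uV)
    if noise.alpha_rms_uV > 0:
        t = np.arange(n_s) / fs
        phase = rng.uniform(0, 2 * np.pi)
        envelope = 1.0 + 0.5 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
        alpha = np.sqrt(2.0) * noise.alpha_rms_uV * np.sin(
            2 * np.pi * noise.alpha_freq_hz * t + phase) * envelope / np.sqrt(1.125)
        data += _alpha_topography(layout)[:, None] * alpha[None, :]
    if noise.blink_rate_per_min > 0 and noise.blink_amp_uV != 0:
        blinks = _blink_train(rng, n_s, fs, noise.blink_rate_per_min,
                              noise.blink_amp_uV)
        data += _blink_topography(layout)[:, None] * blinks[None, :]
    if noise.line_50hz_rms_uV > 0:
        t = np.arange(n_s) / fs
        line = np.sqrt(2.0) * noise.line_50hz_rms_uV * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        data += line[None, :]  # common-mode on all channels

    return RawRecording(data=data, sample_rate_hz=fs, layout=layout,
                        events=list(events))


def write_recording(rec: RawRecording, path: str | Path) -> tuple[Path, Path]:
    """Save a recording as an MNE FIF file plus a sidecar events CSV.

    Data are stored in volts inside the FIF container (MNE convention) and
    converted back to uV on read.  Returns (fif_path, events_path).
    """
    import mne

    path = Path(path)
    if path.suffix != ".fif":
        path = path.with_suffix(".fif")
    ch_types = ["eog" if c in EOG_CHANNELS else "eeg" for c in rec.layout.labels]
    info = mne.create_info(list(rec.layout.labels), rec.sample_rate_hz, ch_types)
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    raw.save(path, overwrite=True, verbose="error")
    events_path = path.with_name(path.stem + "_events.csv")
    events_to_frame(rec.events).to_csv(events_path, index=False)
    return path, events_path


def read_recording(path: str | Path,
                   layout: ChannelLayout | None = None) -> RawRecording:
    """Load a recording written by :func:`write_recording`.

    Raises ``ValueError`` naming any required channel missing from the file.
    """
    import mne

    layout = layout or ChannelLayout()
    path = Path(path)
    raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    missing = [c for c in layout.labels if c not in raw.ch_names]
    if missing:
        raise ValueError(f"recording {path} is missing channels: {missing}")
    data = raw.get_data(picks=list(layout.labels)) * 1e6
    events_path = path.with_name(path.stem + "_events.csv")
    events = read_events(events_path) if events_path.exists() else []
    return RawRecording(data=data, sample_rate_hz=raw.info["sfreq"],
                        layout=layout, events=events)
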