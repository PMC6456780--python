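"""Multifeature auditory oddball paradigm: stimuli and trial sequencing.

The paradigm presents a repeated *standard* tone complex (three summed
sinusoids at 7,500 / 8,000 / 8,500 Hz, 75 ms, 5 ms raised-cosine ramps)
interleaved with four rare *deviant* classes — frequency shifted 10 % up or
down, a shortened 25 ms duration, and a 7 ms silent gap — arranged in four
pseudo-randomised blocks in which every deviant is sandwiched between two
standards and two standards never follow each other after a 10-standard
warm-up run.  Stimulus offset-to-onset interval is 900 ms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "DeviantKind",
    "ToneComplexSpec",
    "StimulusWaveform",
    "TrialEvent",
    "BlockPlan",
    "ParadigmConfig",
    "component_frequencies",
    "synthesize_stimulus",
    "stimulus_duration_ms",
    "generate_block",
    "generate_paradigm",
    "schedule_events",
    "total_span_s",
    "events_to_frame",
    "default_waveforms",
    "export_paradigm",
    "read_events",
]


class DeviantKind(str, enum.Enum):
    """Stimulus classes of the multifeature oddball paradigm."""

    STANDARD = "standard"
    FREQUENCY_HIGH = "frequency_high"
    FREQUENCY_LOW = "frequency_low"
    DURATION = "duration"
    GAP = "gap"


#: The four deviant classes (everything except the standard).
DEVIANT_KINDS: tuple[DeviantKind, ...] = (
    DeviantKind.FREQUENCY_HIGH,
    DeviantKind.FREQUENCY_LOW,
    DeviantKind.DURATION,
    DeviantKind.GAP,
)


@dataclass(frozen=True)
class ToneComplexSpec:
    """A complex tone: summed sinusoids with raised-cosine on/off ramps.

    ``amplitude`` is the per-component linear amplitude (arbitrary units
    standing in for the 85 dB SPL presentation level).
    """

    frequencies_hz: tuple[float, float, float] = (7500.0, 8000.0, 8500.0)
    duration_ms: float = 75.0
    rise_ms: float = 5.0
    fall_ms: float = 5.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.frequencies_hz):
            raise ValueError("tone frequencies must be strictly positive")
        if self.duration_ms <= 0 or self.amplitude <= 0:
            raise ValueError("duration and amplitude must be positive")
        if self.rise_ms < 0 or self.fall_ms < 0:
            raise ValueError("ramp times must be non-negative")
        if self.rise_ms + self.fall_ms > self.duration_ms:
            raise ValueError("rise + fall time exceeds stimulus duration")


@dataclass(frozen=True)
class StimulusWaveform:
    samples: np.ndarray
    sample_rate_hz: float
    kind: DeviantKind


@dataclass(frozen=True)
class TrialEvent:
    onset_s: float
    kind: DeviantKind
    block_index: int  # 1-based
    trial_index_in_block: int  # 1-based
    is_warmup: bool


@dataclass(frozen=True)
class BlockPlan:
    trials: tuple[DeviantKind, ...]
    n_warmup: int
    counts: dict[DeviantKind, int] = field(compare=False)

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class ParadigmConfig:
    """Full description of the oddball experiment.

    Defaults reproduce the study paradigm: 4 blocks x 91 trials with a
    10-standard warm-up, 900 ms offset-to-onset ISI, 10 % frequency shift,
    25 ms duration deviant and a 7 ms central gap with 1 ms edge ramps.
    """

    tone: ToneComplexSpec = field(default_factory=ToneComplexSpec)
    deviant_shift: float = 0.10
    duration_deviant_ms: float = 25.0
    gap_ms: float = 7.0
    gap_edge_ramp_ms: float = 1.0
    isi_ms: float = 900.0  # offset-to-onset
    n_blocks: int = 4
    trials_per_block: int = 91
    n_warmup: int = 10
    audio_sample_rate_hz: float = 44100.0
    ramp_shape: str = "hann"  # "hann" | "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "deviant_shift", "duration_deviant_ms", "gap_ms", "isi_ms",
            "n_blocks", "trials_per_block", "audio_sample_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_warmup < 0 or self.gap_edge_ramp_ms < 0:
            raise ValueError("n_warmup and gap_edge_ramp_ms must be >= 0")
        if self.trials_per_block <= self.n_warmup:
            raise ValueError("trials_per_block must exceed n_warmup")
        nyquist = self.audio_sample_rate_hz / 2.0
        if max(self.tone.frequencies_hz) * (1 + self.deviant_shift) >= nyquist:
            raise ValueError("shifted tone frequency at or above Nyquist")
        if self.ramp_shape not in ("hann", "linear"):
            raise ValueError(f"unknown ramp shape {self.ramp_shape!r}")


def component_frequencies(kind: DeviantKind, config: ParadigmConfig) -> tuple[float, ...]:
    """Sinusoid component frequencies of a stimulus class in Hz.

    Frequency deviants scale all three standard components by
    ``1 +/- deviant_shift``; every other class keeps the standard components.
    """
    base = config.tone.frequencies_hz
    if kind is DeviantKind.FREQUENCY_HIGH:
        return tuple(f * (1.0 + config.deviant_shift) for f in base)
    if kind is DeviantKind.FREQUENCY_LOW:
        return tuple(f * (1.0 - config.deviant_shift) for f in base)
    if isinstance(kind, DeviantKind):
        return base
    raise ValueError(f"unknown stimulus kind {kind!r}")


def stimulus_duration_ms(kind: DeviantKind, config: ParadigmConfig) -> float:
    """Total stimulus duration in ms (only the duration deviant differs)."""
    if kind is DeviantKind.DURATION:
        return config.duration_deviant_ms
    return config.tone.duration_ms


def _ramp_envelope(n: int, n_rise: int, n_fall: int, shape: str) -> np.ndarray:
    env = np.ones(n)
    if n_rise > 0:
        x = np.arange(n_rise) / n_rise
        env[:n_rise] = x if shape == "linear" else 0.5 * (1 - np.cos(np.pi * x))
    if n_fall > 0:
        x = np.arange(n_fall) / n_fall
        ramp = x if shape == "linear" else 0.5 * (1 - np.cos(np.pi * x))
        env[n - n_fall:] = ramp[::-1]
    return env


def synthesize_stimulus(kind: DeviantKind, config: ParadigmConfig) -> StimulusWaveform:
    """Render one stimulus class to an audio waveform.

    The standard is the equal-amplitude sum of the three sinusoids with
    raised-cosine rise/fall ramps.  Frequency deviants shift all components
    by ``+/- deviant_shift``; the duration deviant shortens the complex to
    ``duration_deviant_ms``; the gap deviant silences a central ``gap_ms``
    interval whose edges carry ``gap_edge_ramp_ms`` ramps, leaving exact
    zeros in between.
    """
    kind = DeviantKind(kind)
    rate = config.audio_sample_rate_hz
    freqs = component_frequencies(kind, config)
    if max(freqs) >= rate / 2:
        raise ValueError("component frequency at or above Nyquist")
    dur_ms = stimulus_duration_ms(kind, config)
    rise_ms, fall_ms = config.tone.rise_ms, config.tone.fall_ms
    if rise_ms + fall_ms > dur_ms:
        raise ValueError("ramps longer than stimulus duration")

    n = int(round(dur_ms / 1000.0 * rate))
    t = np.arange(n) / rate
    y = np.zeros(n)
    for f in freqs:
        y += np.sin(2 * np.pi * f * t)
    y *= config.tone.amplitude
    n_rise = int(round(rise_ms / 1000.0 * rate))
    n_fall = int(round(fall_ms / 1000.0 * rate))
    y *= _ramp_envelope(n, n_rise, n_fall, config.ramp_shape)

    if kind is DeviantKind.GAP:
        n_gap = int(round(config.gap_ms / 1000.0 * rate))
        n_edge = int(round(config.gap_edge_ramp_ms / 1000.0 * rate))
        start = (n - n_gap) // 2
        gap_env = np.ones(n)
        # fall into the gap, exact zeros in the middle, rise back out
        x = np.arange(n_edge) / max(n_edge, 1)
        down = 0.5 * (1 + np.cos(np.pi * x)) if config.ramp_shape == "hann" else 1 - x
        gap_env[start:start + n_edge] = down
        gap_env[start + n_edge:start + n_gap - n_edge] = 0.0
        gap_env[start + n_gap - n_edge:start + n_gap] = down[::-1]
        y = y * gap_env

    return StimulusWaveform(samples=y, sample_rate_hz=rate, kind=kind)


def generate_block(config: ParadigmConfig, rng: np.random.Generator) -> BlockPlan:
    """Generate one pseudo-randomised block.

    The first ``n_warmup`` trials are standards; thereafter deviants and
    standards strictly alternate starting with a deviant, so no two
    standards are ever adjacent after the warm-up and every deviant is
    immediately preceded by a standard.  Deviant classes are allocated in
    as-equal-as-possible counts and shuffled.
    """
    n_rest = config.trials_per_block - config.n_warmup
    n_dev = (n_rest + 1) // 2  # alternation starts and ends with a deviant
    base, extra = divmod(n_dev, len(DEVIANT_KINDS))
    counts = {k: base for k in DEVIANT_KINDS}
    for k in rng.choice(len(DEVIANT_KINDS), size=extra, replace=False):
        counts[DEVIANT_KINDS[k]] += 1
    deviants = [k for k in DEVIANT_KINDS for _ in range(counts[k])]
    deviants = [deviants[i] for i in rng.permutation(len(deviants))]

    trials: list[DeviantKind] = [DeviantKind.STANDARD] * config.n_warmup
    for i in range(n_rest):
        trials.append(deviants[i // 2] if i % 2 == 0 else DeviantKind.STANDARD)
    counts[DeviantKind.STANDARD] = len(trials) - n_dev
    return BlockPlan(trials=tuple(trials), n_warmup=config.n_warmup, counts=counts)


def generate_paradigm(config: ParadigmConfig) -> list[BlockPlan]:
    """All blocks of the experiment from the config's seed."""
    rng = np.random.default_rng(config.seed)
    return [generate_block(config, rng) for _ in range(config.n_blocks)]


def schedule_events(blocks: list[BlockPlan], config: ParadigmConfig) -> list[TrialEvent]:
    """Lay the concatenated blocks on a single 0-based timeline.

    onset[i+1] = onset[i] + stimulus_duration(kind_i) + ISI, with the ISI
    read offset-to-onset (SOA = 975 ms for a standard).
    """
    if not blocks:
        raise ValueError("no blocks to schedule")
    events: list[TrialEvent] = []
    t = 0.0
    for b, block in enumerate(blocks, start=1):
        for i, kind in enumerate(block.trials, start=1):
            events.append(TrialEvent(
                onset_s=t, kind=kind, block_index=b,
                trial_index_in_block=i, is_warmup=i <= block.n_warmup,
            ))
            t += (stimulus_duration_ms(kind, config) + config.isi_ms) / 1000.0
    return events


def total_span_s(events: list[TrialEvent], config: ParadigmConfig) -> float:
    """Time from the first onset to the last stimulus offset, in seconds."""
    if not events:
        return 0.0
    last = events[-1]
    return last.onset_s + stimulus_duration_ms(last.kind, config) / 1000.0


def events_to_frame(events: list[TrialEvent]) -> pd.DataFrame:
    return pd.DataFrame({
        "onset_s": [e.onset_s for e in events],
        "kind": [e.kind.value for e in events],
        "block": [e.block_index for e in events],
        "trial": [e.trial_index_in_block for e in events],
        "is_warmup": [int(e.is_warmup) for e in events],
    })


def read_events(path: str | Path) -> list[TrialEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        TrialEvent(
            onset_s=float(r.onset_s), kind=DeviantKind(r.kind),
            block_index=int(r.block), trial_index_in_block=int(r.trial),
            is_warmup=bool(r.is_warmup),
        )
        for r in df.itertuples(index=False)
    ]


def export_paradigm(
    events: list[TrialEvent],
    waveforms: dict[DeviantKind, StimulusWaveform],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write per-kind WAV stimuli and the event table CSV.

    Returns a map of written artifact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for kind, wf in waveforms.items():
        path = out / f"stimulus_{kind.value}.wav"
        wavfile.write(path, int(wf.sample_rate_hz), wf.samples.astype(np.float32))
        written[f"wav_{kind.value}"] = path
    csv_path = out / "events.csv"
    events_to_frame(events).to_csv(csv_path, index=False)
    written["events"] = csv_path
    return written


def default_waveforms(config: ParadigmConfig) -> dict[DeviantKind, StimulusWaveform]:
    return {kind: synthesize_stimulus(kind, config) for kind in DeviantKind}
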