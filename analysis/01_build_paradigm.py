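#!/usr/bin/env python
"""Build the multifeature oddball paradigm: stimuli, blocks, event schedule.

Writes the five stimulus WAV files and the 364-trial event table to
scratch/paradigm/ (audio is binary scratch), copies the event table to
results/, and prints the realized sequencing statistics.
"""

import shutil
from collections import Counter
from pathlib import Path

from mmnstudy.paradigm import (ParadigmConfig, default_waveforms,
                               export_paradigm, generate_paradigm,
                               schedule_events, total_span_s)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "paradigm"


def main() -> None:
    config = ParadigmConfig(seed=0)
    blocks = generate_paradigm(config)
    events = schedule_events(blocks, config)
    written = export_paradigm(events, default_waveforms(config), OUT)
    (ROOT / "results").mkdir(exist_ok=True)
    shutil.copy(written["events"], ROOT / "results" / "paradigm_events.csv")

    counts = Counter(e.kind.value for e in events)
    n_dev = sum(v for k, v in counts.items() if k != "standard")
    span = total_span_s(events, config)
    print(f"blocks: {len(blocks)} x {config.trials_per_block} trials "
          f"({config.n_warmup} warm-up standards each)")
    print(f"trial counts: {dict(sorted(counts.items()))}")
    print(f"deviant share: {n_dev}/{len(events)} = {n_dev / len(events):.1%}")
    print(f"presentation span: {span:.1f} s (~{span / 60:.1f} min)")
    print(f"wrote {len(written)} artifacts to {OUT}")


if __name__ == "__main__":
    main()
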