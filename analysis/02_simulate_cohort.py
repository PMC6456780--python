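#!/usr/bin/env python
"""Simulate a demonstration cohort of oddball EEG recordings.

Renders n-per-group subjects (default 2; pass a number to change) for the
three groups with the published MMN amplitude/latency distributions and
moderate recording noise, and writes FIF recordings + manifest under
scratch/recordings/ (recordings are bulky simulation scratch, not results).
"""

import sys
from pathlib import Path

from mmnstudy.pipeline import RunConfig, simulate_study

ROOT = Path(__file__).resolve().parents[1]
REC_DIR = ROOT / "scratch" / "recordings"


def main() -> None:
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 2
    config = RunConfig(n_per_group=n, seed=0)
    manifest = simulate_study(config, REC_DIR, overwrite=True)
    (ROOT / "results").mkdir(exist_ok=True)
    config.to_yaml(ROOT / "results" / "run_config.yaml")
    print(manifest.to_string(index=False))
    print(f"\nwrote {len(manifest)} recordings to {REC_DIR}")


if __name__ == "__main__":
    main()
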