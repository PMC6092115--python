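#!/usr/bin/env python
"""Generate the synthetic study: 4 subjects x 3 stimulation conditions.

Each subject/condition cell gets 3 walk trials (lumbar acceleration, with
freeze episodes injected for the two freezer subjects), a block of 10
step-initiation trials, and 5 platform-perturbation trials, all with ground
truth recorded beside the data.  Trial CSVs are bulky and reproducible, so
they go under scratch/ (regenerate with this script); every result table is
derived from them by 02_run_pipeline.py.
"""

import sys
from pathlib import Path

from pfk.synth import generate_study

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    data_dir = ROOT / "scratch" / "study"
    cfg = generate_study(data_dir, seed=seed)
    n_files = sum(1 for _ in data_dir.rglob("*.csv"))
    print(f"synthetic study written to {data_dir}")
    print(f"  config: {cfg}")
    print(f"  trial CSVs: {n_files} (4 subjects x 3 conditions x 18 trials)")
    print("  freezer subjects: s02, s03 (s01 and s04 have no freeze episodes)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
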