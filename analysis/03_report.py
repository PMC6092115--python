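#!/usr/bin/env python
"""Report the study outcome: group %change per variable and t-tests vs OFF.

Reads results/study/ produced by 02_run_pipeline.py and prints the group
mean percent change (ON vs OFF) for each outcome variable with the
one-sample t-test against zero.  A positive improvement score always means
better performance (sign flipped for variables where a decrease is better).
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "study"
    if not out.is_dir():
        raise SystemExit("no pipeline outputs found; run analysis/02_run_pipeline.py first")
    pct = pd.read_csv(out / "percent_change.tsv", sep="\t")
    tests = {(r["variable"], r["condition"]): r for r in json.loads((out / "ttests.json").read_text())}

    print(f"{'variable':<14}{'condition':<10}{'mean %change':>13}{'improvement':>13}"
          f"{'t':>9}{'p':>9}  sig")
    group = pct.groupby(["variable", "condition"], sort=True)
    for (variable, condition), rows in group:
        mean_pct = 100.0 * rows["pct_change"].mean()
        mean_imp = 100.0 * rows["improvement"].mean()
        r = tests.get((variable, condition))
        t = f"{r['t']:9.2f}" if r else "      n/a"
        p = f"{r['p']:9.4f}" if r else "      n/a"
        sig = "*" if r and r["significant"] else ""
        print(f"{variable:<14}{condition:<10}{mean_pct:>12.1f}%{mean_imp:>12.1f}%{t}{p}  {sig}")


if __name__ == "__main__":
    main()
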