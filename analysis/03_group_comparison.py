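#!/usr/bin/env python
"""Build the two-group comparison table for the simulated cohort.

Reads the burden/event tables from 02_event_burden.py (recomputing if
absent), runs the normality-routed test battery (Shapiro-Wilk routing
to t-test or Mann-Whitney, Fisher's exact for proportions), and writes
the report table as CSV and markdown.  Prints the rows significant at
the 0.05 level.
"""

import argparse
import importlib.util
import sys
from pathlib import Path

from hypoburden import build_report, cohort_burden
from hypoburden.cohort_compare import report_frame, report_markdown

spec = importlib.util.spec_from_file_location(
    "event_burden", Path(__file__).parent / "02_event_burden.py"
)
event_burden = importlib.util.module_from_spec(spec)
spec.loader.exec_module(event_burden)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort-dir", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    cohort = event_burden.load_cohort(Path(args.cohort_dir), args.seed)
    burdens = cohort_burden(cohort)
    rows = build_report(burdens, cohort.meta)
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ga, gb = cohort.groups
    report_frame(rows, ga, gb).to_csv(outdir / "comparison.csv", index=False)
    (outdir / "comparison.md").write_text(report_markdown(rows, ga, gb))

    print(f"comparison of {ga} (n={sum(b.group == ga for b in burdens)}) vs "
          f"{gb} (n={sum(b.group == gb for b in burdens)}):")
    for r in rows:
        flag = "*" if r.significant else " "
        print(f" {flag} {r.variable}: {r.summary_a} vs {r.summary_b} "
              f"(p={r.p_value:.2g}, {r.test_used})")
    print(f"wrote {outdir}/comparison.csv and {outdir}/comparison.md")


if __name__ == "__main__":
    sys.exit(main())
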