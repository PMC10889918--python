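#!/usr/bin/env python
"""Detect hypotensive events and compute per-patient burden endpoints.

Reads the cohort written by 01_simulate_cohort.py (simulating it first
if absent), detects events below 65 and 50 mmHg (> 1 min), and writes
the per-patient burden table and the per-event table.  Prints the
group medians of the primary endpoint (TWA of MAP < 65 mmHg).
"""

import argparse
from pathlib import Path

import numpy as np

from hypoburden import SyntheticCohortConfig, cohort_burden, read_cohort_csv
from hypoburden.hypotension_burden import burden_frame, events_frame
from hypoburden import simulate_cohort, write_cohort_csv


def load_cohort(cohort_dir: Path, seed: int):
    traces, meta = cohort_dir / "traces.csv", cohort_dir / "meta.csv"
    if not traces.exists():
        cohort_dir.mkdir(parents=True, exist_ok=True)
        cohort = simulate_cohort(SyntheticCohortConfig(seed=seed))
        write_cohort_csv(cohort, traces, meta)
    return read_cohort_csv(traces, meta)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort-dir", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    cohort = load_cohort(Path(args.cohort_dir), args.seed)
    burdens = cohort_burden(cohort)
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    burden_frame(burdens).to_csv(outdir / "patient_burden.csv", index=False)
    ev = events_frame(cohort)
    ev.to_csv(outdir / "events.csv", index=False)

    for g in cohort.groups:
        twa = [b.at(65).twa_mmhg for b in burdens if b.group == g]
        tt = [b.at(65).total_time_below_min for b in burdens if b.group == g]
        print(
            f"{g}: median TWA(65) = {np.median(twa):.2f} mmHg, "
            f"median time below 65 = {np.median(tt):.1f} min, "
            f"{sum(b.at(65).any_event for b in burdens if b.group == g)}"
            f"/{len(twa)} patients with events"
        )
    print(f"wrote {outdir}/patient_burden.csv ({len(burdens)} patients) "
          f"and {outdir}/events.csv ({len(ev)} events)")


if __name__ == "__main__":
    main()
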