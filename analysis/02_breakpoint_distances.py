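#!/usr/bin/env python
"""Breakpoint distances of the benchmark orders to the ancestral arrangement.

Reproduces the two structural facts the distance rests on: a genome
retaining the ancestral order scores 0, and each single rearrangement event
leaves its arithmetic signature (inversion +2; transposition or inverse
transposition +3; a TDRL at most its segment length + 1).  Also tabulates
how the distance saturates with the number of events.  Writes
results/breakpoints.tsv.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from mitorearr import ancestral_order, breakpoint_distance, collapse_duplicates
from mitorearr.synthetic_data import benchmark_suite

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=17)
    args = parser.parse_args()

    anc = ancestral_order()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        suite = benchmark_suite(args.seed)

        rows = [{"taxon": "ancestral", "n_events": 0, "event_type": "-",
                 "breakpoints": breakpoint_distance(anc, anc)}]
        for h in suite.single_event + suite.multi_event:
            o = collapse_duplicates(h.final, anc)
            rows.append({
                "taxon": h.final.taxon,
                "n_events": len(h.events),
                "event_type": h.events[0].type if len(h.events) == 1 else "mixed",
                "breakpoints": breakpoint_distance(o, anc),
            })

    frame = pd.DataFrame(rows)
    out = ROOT / "results" / "breakpoints.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out, sep="\t", index=False)

    print(f"wrote {out} ({len(frame)} rows)")
    print("ancestral vs itself:", int(frame.iloc[0].breakpoints))
    single = frame[frame.n_events == 1]
    for etype, grp in single.groupby("event_type"):
        print(f"  single {etype}: distances {sorted(grp.breakpoints.unique())}")
    multi = frame[frame.n_events > 1]
    print("saturation (mean breakpoints by event count):")
    print(multi.groupby("n_events").breakpoints.mean().round(1).to_string())


if __name__ == "__main__":
    main()
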