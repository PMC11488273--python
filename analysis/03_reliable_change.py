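"""Reliable and clinically significant change tables.

Computes Jacobson–Truax reliable-change thresholds from each scale's
admission SD and reliability, then classifies every complete
admission/stepdown and admission/discharge pair into the five-group
taxonomy, separately for the IP/RES and PHP/IOP admitting groups, and
writes the footnoted change tables (CSV + markdown).
"""

import argparse
import pathlib

import pandas as pd

from edhloc.mixed_models import preprocess
from edhloc.pipeline import SCALE_OUTCOMES, SUBSAMPLES, render_change_table
from edhloc.reliable_change import change_table, default_thresholds


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=pathlib.Path, default="results/cohort")
    ap.add_argument("--out", type=pathlib.Path, default="results")
    args = ap.parse_args()

    data, _ = preprocess(pd.read_csv(args.cohort / "cohort.csv"))
    thresholds = default_thresholds()
    print("reliable-change thresholds (z = 1.96):")
    for name, t in thresholds.items():
        print(f"  {name:6s} RCI {t.rci_threshold:5.2f}   cutoff {t.cs_cutoff:5.2f}")

    args.out.mkdir(parents=True, exist_ok=True)
    adm = data[data["timepoint"] == "admission"].set_index("participant_id")
    for sub, locs in SUBSAMPLES.items():
        pids = adm.index[adm["loc_admit"].isin(locs)]
        tables = {}
        for scale, outcome in SCALE_OUTCOMES.items():
            wide = (data[data["participant_id"].isin(pids)]
                    .pivot_table(index="participant_id", columns="timepoint",
                                 values=outcome, aggfunc="first"))
            for interval, col in [("admit_to_stepdown", "stepdown"),
                                  ("admit_to_discharge", "discharge")]:
                pairs = wide[["admission", col]].rename(
                    columns={"admission": "admit", col: "followup"})
                tables[(scale, interval)] = change_table(
                    pairs, thresholds[scale], interval)
        frame, md = render_change_table(tables, sub)
        frame.to_csv(args.out / f"change_table_{sub}.csv", index=False)
        (args.out / f"change_table_{sub}.md").write_text(md)
        print(f"\n{sub}:")
        print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
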