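"""Sample descriptives and internal consistency.

Reads the simulated cohort, applies the preprocessing filters (first stay
only, implausible episode counts flagged) and writes means/SDs/ranges for
age, length of stay, the three scale scores per timepoint and %EBW (full
sample and AN only), plus Cronbach's alpha per scale and timepoint from the
item matrices.
"""

import argparse
import pathlib

import pandas as pd

from edhloc.mixed_models import preprocess
from edhloc.pipeline import _descriptives
from edhloc.scales import cronbach_alpha

SCALES = ("edeq", "phq9", "gad7")
TIMEPOINTS = ("admission", "stepdown", "discharge")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=pathlib.Path, default="results/cohort")
    ap.add_argument("--out", type=pathlib.Path, default="results")
    args = ap.parse_args()

    data, exclusions = preprocess(pd.read_csv(args.cohort / "cohort.csv"))
    desc = _descriptives(data)
    args.out.mkdir(parents=True, exist_ok=True)
    desc.to_csv(args.out / "descriptives.csv", index=False)
    print(f"preprocessing removed {len(exclusions)} records "
          f"(first-stay rule + count outliers)")
    print(desc.to_string(index=False, float_format="%.2f"))

    rows = []
    for scale in SCALES:
        for tp in TIMEPOINTS:
            path = args.cohort / f"items_{scale}_{tp}.csv"
            if not path.exists():
                continue
            items = pd.read_csv(path, index_col=0)
            rows.append({"scale": scale, "timepoint": tp,
                         "cronbach_alpha": cronbach_alpha(items.to_numpy())})
    rel = pd.DataFrame(rows)
    rel.to_csv(args.out / "reliability.csv", index=False)
    print("\ninternal consistency (listwise complete rows):")
    print(rel.to_string(index=False, float_format="%.3f"))


if __name__ == "__main__":
    main()
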