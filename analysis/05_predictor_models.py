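"""Predictors of treatment-related change (aim 2) and post-hoc region models.

Pooled models with predictor x time interactions: AN binge/purge subtype,
psychiatric comorbidity, simple-coded diagnosis (AN reference), age, and
admission EDE-Q severity. Post-hoc variants add US-census-region dummies
(South reference) and level-of-care indicators. Significance at the
Bonferroni-corrected 0.05/17 threshold.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

from edhloc.mixed_models import bonferroni, preprocess
from edhloc.pipeline import _fit_one, predictor_model_specs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=pathlib.Path, default="results/cohort")
    ap.add_argument("--out", type=pathlib.Path, default="results")
    ap.add_argument("--bootstrap-reps", type=int, default=200)
    args = ap.parse_args()

    data, _ = preprocess(pd.read_csv(args.cohort / "cohort.csv"))
    an_data = data[data["diagnosis4"] == "AN"]
    threshold = bonferroni(0.05, 17)
    rng = np.random.default_rng(args.seed + 3)

    tables = []
    for post_hoc in (False, True):
        for spec in predictor_model_specs(post_hoc_region=post_hoc):
            base = an_data if spec.outcome == "percent_ebw" else data
            table = _fit_one(base, spec, threshold, args.bootstrap_reps, rng)
            tables.append(table)
            if "error" in table.columns:
                print(f"{spec.label}: {table['error'].iloc[0]}")
                continue
            sig = table[table["significant"] & (table["term"] != "intercept")]
            terms = ", ".join(sig["term"]) or "none"
            print(f"{spec.label:20s} significant terms: {terms}")

    args.out.mkdir(parents=True, exist_ok=True)
    out = pd.concat(tables, ignore_index=True)
    out.to_csv(args.out / "predictor_models.csv", index=False)
    print(f"\nwrote {args.out / 'predictor_models.csv'}")


if __name__ == "__main__":
    main()
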