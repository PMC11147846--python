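#!/usr/bin/env python
"""Per-network prediction errors of the group-average predictor.

Computes log(1 - r) per parcel (r = correlation between the parcel's row
of the prediction and of the empirical FC), aggregated over the seven
canonical functional systems. Networks whose FC deviates most from the
group template (limbic, then frontoparietal/default-mode) are predicted
worst — a pattern that needs no model of polysynaptic communication, only
network-dependent individual variability.

Requires scratch/cohort_dk/ from 01_simulate_cohort.py.
"""

import json
from pathlib import Path

import pandas as pd

from fcbench import avg_predictor, make_folds, network_error_map
from fcbench.io import read_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 1


def main():
    cohort = read_cohort(SCRATCH / "cohort_dk")
    folds = make_folds(len(cohort), 10, seed=SEED)
    errs = network_error_map(avg_predictor(cohort, folds), cohort)
    table = pd.DataFrame(
        sorted(errs.items(), key=lambda kv: kv[1], reverse=True),
        columns=["network", "log_one_minus_r"],
    )
    table.to_csv(OUT / "04_network_errors.tsv", sep="\t", index=False)
    (OUT / "04_network_errors.json").write_text(json.dumps(errs, indent=2))
    print(table.to_string(index=False))
    print("\nhigher (less negative) = worse prediction; ordering follows the "
          "generator's network deviation scales")


if __name__ == "__main__":
    main()
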