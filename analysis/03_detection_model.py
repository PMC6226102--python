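"""Stage 1: choose the detection model.

Fits each candidate set of nightly survey covariates with intercept-only
occupancy and ranks by WAIC.  The winner's covariates are fixed and
carried into every occupancy model in stage 2 — detection and occupancy
effects are never selected jointly.

Reads:  results/study/, results/covariates/
Writes: results/selection/detection_model_comparison.tsv
"""

from pathlib import Path

import pandas as pd

from batscape.occupancy import McmcConfig
from batscape.pipeline import detection_candidates, select_detection_model

STUDY = Path("results/study")
OUT = Path("results/selection")
SEED = 20_150_103

# desk-scale schedule: 3 chains x 1,200 post-burn-in iterations, thin 4
CONFIG = McmcConfig(n_chains=3, n_burnin=400, n_sampling=1_200, thin=4, seed=SEED)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    detections = pd.read_csv(STUDY / "detections.tsv", sep="\t")
    cov_std = pd.read_csv("results/covariates/cell_covariates_std.tsv", sep="\t")

    terms, comparison = select_detection_model(
        detections, cov_std, detection_candidates(), CONFIG)
    comparison.table.round(4).to_csv(OUT / "detection_model_comparison.tsv",
                                     sep="\t", index=False)

    top = comparison.table.head(3)[["model", "waic", "delta_waic", "weight"]]
    print("detection model ranking (top 3):")
    print(top.round(2).to_string(index=False))
    print(f"carrying detection covariates {list(terms) or ['(intercept only)']} "
          "into all occupancy models")


if __name__ == "__main__":
    main()
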