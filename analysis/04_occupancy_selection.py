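"""Stage 2: fit and rank the a priori occupancy models.

Fits the 11 ecological candidate models plus null and global with the
stage-1 detection covariates, ranks by WAIC with relative likelihoods and
weights, flags closely competing models (dWAIC <= 2.0), and computes
5-fold cross-validated AUC for every model performing at least as well as
the null.

Reads:  results/study/, results/covariates/, results/selection/
Writes: results/selection/{model_comparison,top_model_posterior,
        top_model_mean_psi}.tsv
"""

from pathlib import Path

import pandas as pd

from batscape.landscape import pearson_screen
from batscape.occupancy import McmcConfig
from batscape.pipeline import run_candidate_set
from batscape.selection import partition_folds

STUDY = Path("results/study")
OUT = Path("results/selection")
SEED = 20_150_104

CONFIG = McmcConfig(n_chains=3, n_burnin=400, n_sampling=1_200, thin=4, seed=SEED)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    detections = pd.read_csv(STUDY / "detections.tsv", sep="\t")
    covariates = pd.read_csv(STUDY / "cell_covariates.tsv", sep="\t")
    det_comp = pd.read_csv(OUT / "detection_model_comparison.tsv", sep="\t")
    det_terms = () if det_comp["model"].iloc[0] == "null" \
        else (det_comp["model"].iloc[0],)

    regions = covariates.set_index("cell_id")["region"]
    partition = partition_folds(sorted(covariates["cell_id"]), regions, seed=SEED)
    results = run_candidate_set(
        detections, covariates, det_terms, CONFIG,
        screen=pearson_screen(covariates), partition=partition, cv_config=CONFIG)

    table = results["comparison"].table
    table.round(4).to_csv(OUT / "model_comparison.tsv", sep="\t", index=False)
    top = results["top_model"]
    results["summaries"][top].table.round(4).to_csv(
        OUT / "top_model_posterior.tsv", sep="\t")
    results["summaries"][top].mean_psi_by_year.round(4).to_csv(
        OUT / "top_model_mean_psi.tsv", sep="\t", index=False)

    shown = table[table["waic"] <= table.set_index("model").loc["null", "waic"]]
    print("occupancy models performing at least as well as the null:")
    print(shown[["model", "waic", "delta_waic", "weight", "mean_auc"]]
          .round(2).to_string(index=False))
    print(f"\ncompeting set (dWAIC <= 2): {results['comparison'].competing_models()}")
    sig = results["summaries"][top].table.query("significant")
    print(f"top model {top!r}: significant effects "
          f"{sig.index.tolist() or '(none)'}")


if __name__ == "__main__":
    main()
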