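"""Statewide predictions and turnover from the top-ranked model.

Refits the top occupancy model from stage 2, projects it onto a larger
cell universe (emulating prediction over every 10 x 10 km cell in the
state) with the fitting set's standardization, and summarizes annual
turnover: colonization, extinction, and the combined fraction of cells
whose latent state changed between years.

Reads:  results/study/, results/selection/
Writes: results/predictions/{predictions,turnover}.tsv
"""

from pathlib import Path

import pandas as pd

from batscape.landscape import standardize
from batscape.occupancy import McmcConfig, ModelSpec, fit_mcmc
from batscape.pipeline import occupancy_candidates
from batscape.products import predict_occupancy_grid, turnover_summary
from batscape.synthetic import build_survey_design, generate_cell_covariates

STUDY = Path("results/study")
OUT = Path("results/predictions")
SEED = 20_150_105
N_GRID = 200  # prediction universe; the field program spans 893 statewide cells

CONFIG = McmcConfig(n_chains=3, n_burnin=400, n_sampling=1_200, thin=4, seed=SEED)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    detections = pd.read_csv(STUDY / "detections.tsv", sep="\t")
    covariates = pd.read_csv(STUDY / "cell_covariates.tsv", sep="\t")
    comparison = pd.read_csv("results/selection/model_comparison.tsv", sep="\t")
    det_comp = pd.read_csv("results/selection/detection_model_comparison.tsv", sep="\t")

    top_name = comparison["model"].iloc[0]
    det_terms = () if det_comp["model"].iloc[0] == "null" \
        else (det_comp["model"].iloc[0],)
    spec = ModelSpec(top_name, occupancy=occupancy_candidates()[top_name],
                     detection=det_terms)

    cov_std, params = standardize(covariates)
    draws = fit_mcmc(detections, cov_std, spec, CONFIG)

    grid_design = build_survey_design(n_cells=N_GRID, seed=SEED + 1)
    grid_cov = generate_cell_covariates(grid_design, seed=SEED + 2)
    predictions = predict_occupancy_grid(draws, grid_cov, standardization=params)
    predictions.round(4).to_csv(OUT / "predictions.tsv", sep="\t", index=False)

    turnover = turnover_summary(draws)
    turnover.to_frame().round(4).to_csv(OUT / "turnover.tsv", sep="\t", index=False)

    by_year = predictions.groupby("year")["psi_mean"]
    print(f"top model {top_name!r} projected onto {N_GRID} cells:")
    print(f"  mean predicted occupancy: "
          f"{ {y: round(v, 3) for y, v in by_year.mean().items()} }")
    print("turnover summary (posterior mean [95% CrI]):")
    for q, row in turnover.table.iterrows():
        print(f"  {q:9s} {row['mean']:.3f} [{row['lo']:.3f}, {row['hi']:.3f}]")


if __name__ == "__main__":
    main()
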