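"""Landscape covariates: raster metrics, the collinearity screen, and
standardization.

Computes percent cover, edge density, and contagion from the example
rasters written by 01, then screens the full simulated covariate table
for Pearson |r| > 0.7 — the pairs that may not co-occur in one model —
and standardizes the continuous columns for fitting.

Reads:  results/study/
Writes: results/covariates/{raster_metrics,correlation_matrix,
        correlated_pairs,cell_covariates_std}.tsv
"""

from pathlib import Path

import pandas as pd

from batscape.landscape import (
    contagion,
    edge_density,
    pearson_screen,
    percent_cover,
    read_ascii_grid,
    standardize,
)

STUDY = Path("results/study")
OUT = Path("results/covariates")

# synthetic rasters use analysis-class codes directly
CLASS_MAP = {0: "Ag", 1: "Dev", 2: "Forest", 3: "F.Wet"}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    rows = []
    for path in sorted(STUDY.glob("rasters/*.asc")):
        raster = read_ascii_grid(path)
        cover = percent_cover(raster, CLASS_MAP)
        rows.append({
            "cell_id": path.stem,
            **{k: round(v, 3) for k, v in cover.items() if k != "other"},
            "F.ED": round(edge_density(raster, [2]), 3),
            "F.Wet.ED": round(edge_density(raster, [3]), 3),
            "Contagion": round(contagion(raster), 3),
        })
    metrics = pd.DataFrame(rows)
    metrics.to_csv(OUT / "raster_metrics.tsv", sep="\t", index=False)
    print(f"raster metrics for {len(metrics)} cells "
          f"(contagion {metrics['Contagion'].min():.1f}-{metrics['Contagion'].max():.1f})")

    covariates = pd.read_csv(STUDY / "cell_covariates.tsv", sep="\t")
    report = pearson_screen(covariates)
    report.r.round(4).to_csv(OUT / "correlation_matrix.tsv", sep="\t")
    flagged = pd.DataFrame(report.flagged, columns=["covariate_a", "covariate_b"])
    flagged.to_csv(OUT / "correlated_pairs.tsv", sep="\t", index=False)
    print(f"{len(flagged)} covariate pairs flagged at |r| > {report.threshold}:")
    for a, b in report.flagged:
        print(f"  {a} ~ {b} (r = {report.r.loc[a, b]:+.2f}) -> never in one model")

    cov_std, params = standardize(covariates)
    cov_std.to_csv(OUT / "cell_covariates_std.tsv", sep="\t", index=False)
    print(f"standardized {len(params.location)} continuous covariates "
          "(location/scale stored for prediction-grid reuse)")


if __name__ == "__main__":
    main()
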