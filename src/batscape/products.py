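"""Predicted-occupancy grids and turnover estimates from a fitted model.

The fitted top model is projected onto the full cell universe (in the
field study, all 893 statewide 10 x 10 km cells): per posterior draw,
first-year occupancy is the logit-linear prediction and second-year
occupancy follows the colonization/extinction recursion
psi2 = psi1 (1 - epsilon) + (1 - psi1) gamma.  Turnover is summarized
three ways — colonization gamma, extinction epsilon, and the combined
fraction of cells whose sampled latent state changed between years — so
any single-number reading of "turnover" is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import Standardization
from .occupancy import PosteriorDraws, build_occupancy_matrix, _sigmoid

__all__ = [
    "TurnoverEstimate",
    "predict_occupancy_grid",
    "derived_second_year_psi",
    "turnover_summary",
]


@dataclass(frozen=True)
class TurnoverEstimate:
    """Posterior mean and 95% CrI of gamma, epsilon, and combined turnover."""

    table: pd.DataFrame  # index: gamma / epsilon / turnover; mean, lo, hi

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index().rename(columns={"index": "quantity"})


def _summary_row(draws: np.ndarray) -> dict:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {"mean": float(draws.mean()), "lo": float(lo), "hi": float(hi)}


def derived_second_year_psi(psi1, gamma, epsilon):
    """psi2 = psi1 (1 - epsilon) + (1 - psi1) gamma (a convex combination,
    so psi2 is always a probability)."""
    psi1, gamma, epsilon = (np.asarray(v, dtype=float) for v in (psi1, gamma, epsilon))
    for name, v in (("psi1", psi1), ("gamma", gamma), ("epsilon", epsilon)):
        if ((v < 0) | (v > 1)).any():
            raise ValueError(f"{name} must lie in [0, 1]")
    return psi1 * (1.0 - epsilon) + (1.0 - psi1) * gamma


def predict_occupancy_grid(
    draws: PosteriorDraws,
    grid_covariates: pd.DataFrame,
    standardization: Standardization | None = None,
) -> pd.DataFrame:
    """Per-cell, per-year posterior occupancy probabilities over a grid.

    ``grid_covariates`` are raw-scale covariates for the prediction cells;
    they are transformed with the fitting set's stored location/scale
    (never re-standardized on the grid itself).  Returns a long table
    (cell_id, year, psi_mean, psi_lo, psi_hi).
    """
    cov = grid_covariates.copy()
    if standardization is not None:
        cov = standardization.apply(cov)
    try:
        X, _ = build_occupancy_matrix(cov, draws.spec.occupancy)
    except KeyError as err:
        raise KeyError(f"prediction grid is missing fitted covariates: {err}") from err
    S = draws.n_draws
    psi = _sigmoid(draws.beta.reshape(S, -1) @ X.T)  # (S, n_grid)
    rows = []
    for t, year in enumerate(draws.data.years):
        if t > 0:
            g = draws.gamma.reshape(S, 1)
            e = draws.epsilon.reshape(S, 1)
            psi = derived_second_year_psi(psi, g, e)
        lo, hi = np.quantile(psi, [0.025, 0.975], axis=0)
        for cid, m, l, h in zip(cov["cell_id"], psi.mean(axis=0), lo, hi):
            rows.append({"cell_id": cid, "year": year, "psi_mean": float(m),
                         "psi_lo": float(l), "psi_hi": float(h)})
    return pd.DataFrame(rows)


def turnover_summary(draws: PosteriorDraws) -> TurnoverEstimate:
    """Posterior summaries of colonization, extinction, and the combined
    turnover (per-draw fraction of cells whose latent state changed
    between consecutive years, from the sampled z)."""
    if draws.data.n_years < 2 or draws.gamma is None:
        raise ValueError("turnover is undefined for single-year data")
    if draws.z is None:
        raise ValueError("turnover needs stored latent-state draws (store_z=True)")
    S = draws.n_draws
    z = draws.z.reshape(S, draws.data.n_cells, draws.data.n_years).astype(float)
    changed = np.abs(np.diff(z, axis=2))        # (S, n, T-1)
    tau = changed.mean(axis=(1, 2))             # per-draw fraction of cells changed
    table = pd.DataFrame(
        {
            "gamma": _summary_row(draws.gamma.reshape(-1)),
            "epsilon": _summary_row(draws.epsilon.reshape(-1)),
            "turnover": _summary_row(tau),
        }
    ).T[["mean", "lo", "hi"]]
    return TurnoverEstimate(table=table)
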