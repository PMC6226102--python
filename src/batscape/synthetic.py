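"""Synthetic acoustic-survey data with the structure the analysis assumes.

Emulates a NABat-style study: ~38 grid cells spread over five physiographic
regions, surveyed in two consecutive summers with up to four stationary
detector-nights and two mobile transect-nights per cell-year.  A latent
occupancy state per cell-year evolves between years by constant
colonization/extinction; nightly detections are Bernoulli conditional on
occupancy with a logit-linear detection model over nine survey covariates.

Everything is seedable and deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import LandscapeRaster

__all__ = [
    "REGIONS",
    "SURVEY_COVARIATES",
    "SurveyDesign",
    "SimulationTruth",
    "build_survey_design",
    "generate_landscape_raster",
    "generate_cell_covariates",
    "simulate_dynamics",
    "simulate_detections",
]

#: U.S. Level III physiographic regions of the study area (alphabetical;
#: the first is the dummy-coding reference level).
REGIONS = [
    "Blue Ridge",
    "Middle Atlantic Coastal Plain",
    "Piedmont",
    "Southeastern Plains",
    "Southern Coastal Plain",
]

#: The nine nightly survey covariates available to the detection model.
SURVEY_COVARIATES = [
    "type", "duration", "clutter", "date", "issue",
    "temperature", "humidity", "wind", "rain",
]

_CONTINUOUS_SURVEY = ["duration", "date", "temperature", "humidity", "wind"]


def _expand_logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SurveyDesign:
    """Which cell was surveyed when, and how.

    ``occasions`` has one row per cell x year x night with a ``method``
    label (``stationary`` or ``mobile``) and an occasion index unique
    within each cell-year.
    """

    cells: list[str]
    regions: pd.Series  # region label per cell, indexed by cell id
    years: list[int]
    occasions: pd.DataFrame  # columns: cell_id, year, occasion, method

    def __post_init__(self):
        occ = self.occasions
        if not set(occ["method"]).issubset({"stationary", "mobile"}):
            raise ValueError("method must be 'stationary' or 'mobile'")
        if occ.duplicated(["cell_id", "year", "occasion"]).any():
            raise ValueError("occasion indices must be unique within cell-year")
        surveyed = occ.groupby("year")["cell_id"].unique()
        for year in self.years:
            missing = set(self.cells) - set(surveyed.get(year, []))
            if missing:
                raise ValueError(f"cells with no occasions in year {year}: {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters and latent states behind a synthetic dataset."""

    beta: pd.Series          # occupancy coefficients, logit scale
    alpha: pd.Series         # detection coefficients, logit scale
    gamma: float             # colonization probability
    epsilon: float           # extinction probability
    psi1: np.ndarray         # initial occupancy probability per cell
    z: np.ndarray            # latent state, shape (n_cells, n_years)

    def __post_init__(self):
        for name, v in (("gamma", self.gamma), ("epsilon", self.epsilon)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("latent states must be binary")


def build_survey_design(
    n_cells: int = 38,
    region_weights: np.ndarray | None = None,
    n_years: int = 2,
    n_stationary: int = 4,
    n_mobile: int = 2,
    seed: int = 0,
    regions: list[str] = REGIONS,
) -> SurveyDesign:
    """Lay out a survey: cells assigned to regions, nights per cell-year.

    Defaults follow the field protocol: four consecutive stationary
    detector-nights plus two mobile transect-nights per cell-year.
    ``n_stationary=0`` or ``n_mobile=0`` emulate cells surveyed with one
    method only.
    """
    if n_stationary > 4 or n_mobile > 2:
        raise ValueError("at most 4 stationary and 2 mobile nights per cell-year")
    if n_stationary + n_mobile < 1:
        raise ValueError("each cell-year needs at least one occasion")
    if n_cells < len(regions):
        raise ValueError(
            f"design infeasible: {n_cells} cells cannot cover {len(regions)} regions"
        )
    rng = np.random.default_rng(seed)
    if region_weights is None:
        region_weights = np.full(len(regions), 1.0 / len(regions))
    region_weights = np.asarray(region_weights, dtype=float)
    region_weights = region_weights / region_weights.sum()

    cells = [f"cell_{i:03d}" for i in range(n_cells)]
    # every region receives >= 1 cell; remainder assigned by weight
    labels = list(regions)
    labels += list(rng.choice(regions, size=n_cells - len(regions), p=region_weights))
    rng.shuffle(labels)
    region_series = pd.Series(labels, index=cells, name="region")

    years = list(range(1, n_years + 1))
    rows = []
    for cell in cells:
        for year in years:
            j = 0
            for _ in range(n_stationary):
                rows.append((cell, year, j, "stationary"))
                j += 1
            for _ in range(n_mobile):
                rows.append((cell, year, j, "mobile"))
                j += 1
    occasions = pd.DataFrame(rows, columns=["cell_id", "year", "occasion", "method"])
    return SurveyDesign(cells=cells, regions=region_series, years=years, occasions=occasions)


def generate_landscape_raster(
    dim: int = 64,
    n_classes: int = 4,
    clustering: int = 2,
    pixel_size: float = 30.0,
    seed: int = 0,
) -> LandscapeRaster:
    """Random categorical raster with tunable spatial aggregation.

    Starts from an iid uniform categorical field and applies ``clustering``
    passes of 3x3 majority smoothing, so larger values yield larger
    same-class patches (higher contagion on average over seeds).
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if n_classes > dim * dim:
        raise ValueError("more classes than pixels")
    rng = np.random.default_rng(seed)
    grid = rng.integers(0, n_classes, size=(dim, dim))
    for _ in range(int(clustering)):
        grid = _majority_smooth(grid, n_classes)
    return LandscapeRaster(grid=grid, pixel_size=pixel_size)


def _majority_smooth(grid: np.ndarray, n_classes: int) -> np.ndarray:
    """One 3x3 majority-filter pass; ties keep the current class if it is
    among the modes, else take the lowest tied code."""
    dim = grid.shape[0]
    counts = np.zeros((n_classes, *grid.shape), dtype=np.int32)
    padded = np.pad(grid, 1, constant_values=-1)
    for di in (0, 1, 2):
        for dj in (0, 1, 2):
            window = padded[di:di + dim, dj:dj + dim]
            for c in range(n_classes):
                counts[c] += window == c
    maxc = counts.max(axis=0)
    is_mode = counts == maxc
    current_is_mode = np.take_along_axis(is_mode, grid[None], axis=0)[0]
    lowest_mode = is_mode.argmax(axis=0)
    return np.where(current_is_mode, grid, lowest_mode)


# Default location/scale of the landscape covariates, loosely matched to a
# southeastern-US mixed forest/agricultural state at the 100 km^2 scale.
_COVARIATE_SCALES = {
    "Ag": (20.0, 10.0), "Dev": (10.0, 7.0), "Forest": (45.0, 15.0),
    "F.Wet": (12.0, 8.0), "Contagion": (55.0, 10.0), "F.ED": (40.0, 20.0),
    "F.Wet.ED": (15.0, 8.0), "Stream": (100.0, 35.0), "Pri": (5.0, 4.0),
    "Sec": (15.0, 7.0), "Ter": (80.0, 30.0), "Qua": (10.0, 6.0),
}
_PERCENT_COLS = ("Ag", "Dev", "Forest", "F.Wet")


def default_covariate_correlation() -> pd.DataFrame:
    """Correlation structure emulating the field covariates: development
    correlated with the primary/secondary/tertiary road classes, secondary
    with tertiary roads, and forested-wetland cover with its edge density."""
    cols = list(_COVARIATE_SCALES)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pairs = {
        ("Dev", "Pri"): 0.80, ("Dev", "Sec"): 0.78, ("Dev", "Ter"): 0.75,
        ("Sec", "Ter"): 0.80, ("F.Wet", "F.Wet.ED"): 0.85,
        ("Pri", "Sec"): 0.63, ("Pri", "Ter"): 0.60,
        ("Forest", "Ag"): -0.40, ("Forest", "F.ED"): 0.30,
    }
    for (a, b), v in pairs.items():
        r.loc[a, b] = r.loc[b, a] = v
    return r


def generate_cell_covariates(
    design: SurveyDesign,
    correlation: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-cell landscape covariate table with a configurable
    correlation matrix (Gaussian copula on the natural scales, truncated to
    physical bounds), bypassing raster generation.

    The default correlation matrix reproduces the collinearity the |r| > 0.7
    screen must catch (roads with development, wetland cover with wetland
    edge density).
    """
    rng = np.random.default_rng(seed)
    if correlation is None:
        correlation = default_covariate_correlation()
    cols = list(correlation.columns)
    corr = correlation.to_numpy(dtype=float)
    # eigen-clip guards user-supplied matrices that are not quite PSD
    w, v = np.linalg.eigh(corr)
    corr = (v * np.clip(w, 1e-9, None)) @ v.T
    d = np.sqrt(np.diag(corr))
    corr = corr / np.outer(d, d)
    latent = rng.multivariate_normal(np.zeros(len(cols)), corr, size=design.n_cells,
                                     method="cholesky")
    table = pd.DataFrame({"cell_id": design.cells})
    table["region"] = design.regions.loc[design.cells].to_numpy()
    for j, col in enumerate(cols):
        mu, sd = _COVARIATE_SCALES.get(col, (0.0, 1.0))
        x = mu + sd * latent[:, j]
        lo, hi = (0.0, 100.0) if col in _PERCENT_COLS or col == "Contagion" else (0.0, np.inf)
        table[col] = np.clip(x, lo, hi)
    # keep composition physically possible: percent covers must sum <= 100
    tot = table[list(_PERCENT_COLS)].sum(axis=1)
    over = tot > 100.0
    if over.any():
        table.loc[over, list(_PERCENT_COLS)] = (
            table.loc[over, list(_PERCENT_COLS)].mul(100.0 / tot[over], axis=0)
        )
    return table


def simulate_dynamics(
    design: SurveyDesign,
    covariates: pd.DataFrame,
    beta: dict[str, float] | pd.Series,
    gamma: float,
    epsilon: float,
    seed: int = 0,
) -> SimulationTruth:
    """Draw latent occupancy states: first-year states from a logit-linear
    model of the (already standardized) covariates, later years by constant
    colonization/extinction — closed within years, open between.

    ``beta`` maps covariate names to logit-scale slopes; ``"intercept"`` is
    the intercept and ``"region:<level>"`` entries are offsets relative to
    the reference region.
    """
    beta = pd.Series(beta, dtype=float)
    if not (0.0 <= gamma <= 1.0 and 0.0 <= epsilon <= 1.0):
        raise ValueError("gamma and epsilon must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cov = covariates.set_index("cell_id").loc[design.cells]
    eta = np.zeros(design.n_cells)
    unmatched = []
    for name, slope in beta.items():
        if name == "intercept":
            eta += slope
        elif name.startswith("region:"):
            eta += slope * (cov["region"] == name.split(":", 1)[1]).to_numpy(float)
        elif name in cov.columns:
            eta += slope * cov[name].to_numpy(float)
        else:
            unmatched.append(name)
    if unmatched:
        raise KeyError(f"beta names with no matching covariate column: {unmatched}")
    psi1 = _expand_logistic(eta)
    z = np.zeros((design.n_cells, design.n_years), dtype=np.int8)
    z[:, 0] = rng.random(design.n_cells) < psi1
    for t in range(1, design.n_years):
        p_occ = np.where(z[:, t - 1] == 1, 1.0 - epsilon, gamma)
        z[:, t] = rng.random(design.n_cells) < p_occ
    return SimulationTruth(
        beta=beta, alpha=pd.Series(dtype=float), gamma=float(gamma),
        epsilon=float(epsilon), psi1=psi1, z=z,
    )


@dataclass(frozen=True)
class SurveyCovariateModel:
    """Distributions of the nightly survey covariates.

    Continuous covariates are normal (unit scale before standardization),
    clutter is a 3-level categorical (none/medium/high), rain and issue are
    Bernoulli.  All knobs overridable.
    """

    clutter_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    rain_prob: float = 0.15
    issue_prob: float = 0.05
    missing_rate: float = 0.0  # occasions lost to weather/malfunction

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        out = pd.DataFrame(index=range(n))
        for col in _CONTINUOUS_SURVEY:
            out[col] = rng.normal(size=n)
        out["clutter"] = rng.choice(3, size=n, p=self.clutter_probs)
        out["rain"] = (rng.random(n) < self.rain_prob).astype(int)
        out["issue"] = (rng.random(n) < self.issue_prob).astype(int)
        return out


def simulate_detections(
    truth: SimulationTruth,
    design: SurveyDesign,
    alpha: dict[str, float] | pd.Series,
    survey_covariate_model: SurveyCovariateModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Nightly Bernoulli detections conditional on the latent states.

    logit(p) = alpha0 + sum_m alpha_m * w_m over the nine survey covariates
    (``"type"`` is an offset for mobile occasions); y = 0 wherever z = 0, so
    the generator never produces false positives.
    """
    alpha = pd.Series(alpha, dtype=float)
    model = survey_covariate_model or SurveyCovariateModel()
    rng = np.random.default_rng(seed)
    det = design.occasions.copy().reset_index(drop=True)
    det = pd.concat([det, model.draw(len(det), rng)], axis=1)
    det["type"] = (det["method"] == "mobile").astype(int)

    eta = np.zeros(len(det))
    unmatched = []
    for name, slope in alpha.items():
        if name == "intercept":
            eta += slope
        elif name in det.columns:
            eta += slope * det[name].to_numpy(float)
        else:
            unmatched.append(name)
    if unmatched:
        raise KeyError(f"alpha names with no matching survey covariate: {unmatched}")
    p = _expand_logistic(eta)

    year_index = {y: t for t, y in enumerate(design.years)}
    cell_index = {c: i for i, c in enumerate(design.cells)}
    z_occ = truth.z[
        det["cell_id"].map(cell_index).to_numpy(),
        det["year"].map(year_index).to_numpy(),
    ]
    det["y"] = ((rng.random(len(det)) < p) & (z_occ == 1)).astype(int)
    if model.missing_rate > 0:
        det = det[rng.random(len(det)) >= model.missing_rate].reset_index(drop=True)
    cols = ["cell_id", "year", "occasion", "method", "y", *SURVEY_COVARIATES]
    return det[cols]
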