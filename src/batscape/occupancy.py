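"""Multi-season Bayesian occupancy model with imperfect detection.

The model treats each grid cell i as a sample unit with a latent binary
occupancy state z[i, t] per year t.  First-year occupancy follows a
logit-linear model of cell covariates, later years evolve by constant
colonization (gamma) and extinction (epsilon) probabilities — populations
closed within years, open between.  Nightly detections y[i, j, t] are
Bernoulli(z[i, t] * p[i, j, t]) with logit(p) linear in nightly survey
covariates, so a species is never detected where it is absent.

Fitting is Metropolis-within-Gibbs: exact Bernoulli full-conditional
updates of each latent state (forced to 1 wherever the cell-year has a
detection), adaptive random-walk Metropolis on the logit-scale occupancy
and detection coefficients, and exact Beta full-conditional draws of
gamma and epsilon (the Uniform(0,1) prior is conjugate given the latent
transition counts).  Priors: Normal(0, sd 10) on all logit-scale
coefficients, Uniform(0,1) on gamma and epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "PreparedData",
    "PosteriorDraws",
    "FitSummary",
    "prepare_data",
    "marginal_cell_loglik",
    "fit_mcmc",
    "rhat",
    "DegenerateChainsError",
    "summarize_posterior",
]

RHAT_THRESHOLD = 1.1


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _log_sigmoid(x):
    # log sigma(x) = -log(1 + e^{-x}), stable both tails
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which covariates act on occupancy and detection.

    ``occupancy`` may contain ``"Region"`` (expanded to dummy variables
    against the alphabetically first region) and continuous covariate
    column names.  ``detection`` names nightly survey covariates
    (``"clutter"`` expands to medium/high dummies).  Dynamics are constant
    colonization/extinction without covariates.  ``fixed_p`` pins the
    detection probability to a known constant instead of estimating it
    (used for perfect-detection checks).
    """

    name: str
    occupancy: tuple[str, ...] = ()
    detection: tuple[str, ...] = ()
    dynamics: str = "constant"
    fixed_p: float | None = None

    def __post_init__(self):
        if self.dynamics != "constant":
            raise ValueError("only constant colonization/extinction dynamics are supported")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler schedule and tuning.

    Defaults follow the analysis protocol: 3 chains, 5,000 burn-in
    iterations, 25,000 post-burn-in iterations thinned by 4 (6,250
    retained per chain, 18,750 total).
    """

    n_chains: int = 3
    n_burnin: int = 5_000
    n_sampling: int = 25_000
    thin: int = 4
    seed: int = 0
    prior_sd: float = 10.0
    target_accept: float = 0.44
    adapt_interval: int = 50
    init_scale: float = 0.5
    flat_psi_prior: bool = False  # standard-logistic prior on an intercept-only psi
    store_z: bool = True

    def __post_init__(self):
        if min(self.n_chains, self.n_burnin, self.n_sampling, self.thin) < 1:
            raise ValueError("all schedule counts must be positive")
        if self.n_sampling % self.thin != 0:
            raise ValueError("thin must divide n_sampling evenly")

    @property
    def retained_per_chain(self) -> int:
        return self.n_sampling // self.thin

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain


@dataclass(frozen=True)
class PreparedData:
    """Model matrices and detection histories in array form."""

    cells: list
    years: list
    X: np.ndarray             # (n_cells, k) occupancy design, intercept first
    beta_names: list[str]
    W: np.ndarray             # (n_records, m) detection design, intercept first
    alpha_names: list[str]
    rec_cell: np.ndarray      # record -> cell index
    rec_year: np.ndarray      # record -> year index
    y: np.ndarray             # record detection 0/1
    detected: np.ndarray      # (n_cells, n_years) any detection

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws, per chain, plus pointwise cell log-likelihoods."""

    beta: np.ndarray            # (chains, draws, k)
    alpha: np.ndarray           # (chains, draws, m)
    gamma: np.ndarray | None    # (chains, draws) or None for single-year data
    epsilon: np.ndarray | None
    z: np.ndarray | None        # (chains, draws, n_cells, n_years) uint8
    loglik: np.ndarray          # (chains*draws, n_cells), latent states marginalized
    data: PreparedData
    spec: ModelSpec
    config: McmcConfig

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def parameter_draws(self) -> dict[str, np.ndarray]:
        """Monitored parameters as name -> (chains, draws) arrays."""
        out = {}
        for j, name in enumerate(self.data.beta_names):
            out[name] = self.beta[:, :, j]
        for j, name in enumerate(self.data.alpha_names):
            out[name] = self.alpha[:, :, j]
        if self.gamma is not None:
            out["gamma"] = self.gamma
            out["epsilon"] = self.epsilon
        return out

    def stacked(self, name_arr: np.ndarray) -> np.ndarray:
        return name_arr.reshape(-1, *name_arr.shape[2:])


@dataclass
class FitSummary:
    """Posterior means, 95% credible intervals, R-hat, and significance."""

    table: pd.DataFrame          # index: parameter; mean, lo, hi, rhat, significant
    mean_psi_by_year: pd.DataFrame
    converged: bool
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Design-matrix construction

def _region_levels(covariates: pd.DataFrame) -> list[str]:
    return sorted(covariates["region"].unique())


def build_occupancy_matrix(covariates: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    """Occupancy design matrix; Region dummy-coded against the
    alphabetically first level."""
    cols = [np.ones(len(covariates))]
    names = ["psi:intercept"]
    missing = []
    for term in terms:
        if term == "Region":
            for level in _region_levels(covariates)[1:]:
                cols.append((covariates["region"] == level).to_numpy(float))
                names.append(f"psi:Region[{level}]")
        elif term in covariates.columns:
            cols.append(covariates[term].to_numpy(float))
            names.append(f"psi:{term}")
        else:
            missing.append(term)
    if missing:
        raise KeyError(f"occupancy covariates not found in cell table: {missing}")
    return np.column_stack(cols), names


def build_detection_matrix(records: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    """Detection design matrix; clutter dummy-coded (none reference)."""
    cols = [np.ones(len(records))]
    names = ["p:intercept"]
    missing = []
    for term in terms:
        if term == "clutter":
            for level, label in ((1, "medium"), (2, "high")):
                cols.append((records["clutter"] == level).to_numpy(float))
                names.append(f"p:clutter[{label}]")
        elif term in records.columns:
            cols.append(records[term].to_numpy(float))
            names.append(f"p:{term}")
        else:
            missing.append(term)
    if missing:
        raise KeyError(f"detection covariates not found in records: {missing}")
    W = np.column_stack(cols)
    if np.isnan(W).any():
        bad = [names[j] for j in np.unique(np.argwhere(np.isnan(W))[:, 1])]
        raise ValueError(f"missing detection covariate values in columns: {bad}")
    return W, names


def prepare_data(
    detections: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: ModelSpec,
) -> PreparedData:
    """Index cells/years and build model matrices for one candidate model.

    ``covariates`` must already be standardized (the pipeline stores the
    fitting set's location/scale for later prediction).
    """
    cells = sorted(detections["cell_id"].unique())
    cov = covariates.set_index("cell_id")
    absent = [c for c in cells if c not in cov.index]
    if absent:
        raise KeyError(f"cells with detections but no covariates: {absent}")
    cov = cov.loc[cells].reset_index()
    years = sorted(detections["year"].unique())
    cell_index = {c: i for i, c in enumerate(cells)}
    year_index = {y: t for t, y in enumerate(years)}

    X, beta_names = build_occupancy_matrix(cov, spec.occupancy)
    if spec.fixed_p is None:
        W, alpha_names = build_detection_matrix(detections, spec.detection)
    else:
        W, alpha_names = np.zeros((len(detections), 0)), []

    rec_cell = detections["cell_id"].map(cell_index).to_numpy()
    rec_year = detections["year"].map(year_index).to_numpy()
    y = detections["y"].to_numpy(int)
    detected = np.zeros((len(cells), len(years)), dtype=bool)
    np.logical_or.at(detected, (rec_cell, rec_year), y.astype(bool))
    return PreparedData(
        cells=cells, years=years, X=X, beta_names=beta_names, W=W,
        alpha_names=alpha_names, rec_cell=rec_cell, rec_year=rec_year,
        y=y, detected=detected,
    )


# ---------------------------------------------------------------------------
# Marginal likelihood (latent states summed out analytically)

def marginal_cell_loglik(
    y_by_year,
    p_by_year,
    psi1: float,
    gamma: float = 0.0,
    epsilon: float = 0.0,
) -> float:
    """Exact log-likelihood of one cell's detection history.

    Sums over all latent occupancy paths by a forward recursion:
    state 1 accumulates the Bernoulli detection product, state 0 admits
    only all-zero histories.  ``y_by_year``/``p_by_year`` are sequences
    (one entry per year) of equal-length arrays; a year with no surveys
    contributes nothing.  Exact — no sampling.
    """
    if not 0.0 <= psi1 <= 1.0:
        raise ValueError("psi1 must lie in [0, 1]")
    a1, a0 = psi1, 1.0 - psi1
    for t, (y, p) in enumerate(zip(y_by_year, p_by_year)):
        y = np.asarray(y, dtype=float)
        p = np.asarray(p, dtype=float)
        if y.shape != p.shape:
            raise ValueError("detection history and probabilities differ in length")
        if np.isnan(p).any():
            raise ValueError(f"missing detection covariates/probabilities in year index {t}")
        if t > 0:
            a1, a0 = a1 * (1.0 - epsilon) + a0 * gamma, a1 * epsilon + a0 * (1.0 - gamma)
        q1 = float(np.prod(np.where(y == 1, p, 1.0 - p)))
        q0 = 0.0 if (y == 1).any() else 1.0
        a1, a0 = a1 * q1, a0 * q0
    lik = a1 + a0
    return math.log(lik) if lik > 0 else -math.inf


def _grouped_sum(values: np.ndarray, flat_idx: np.ndarray, n_groups: int) -> np.ndarray:
    """Sum ``values`` (..., R) by record group along the last axis."""
    out = np.zeros((*values.shape[:-1], n_groups))
    order = np.argsort(flat_idx, kind="stable")
    sorted_idx = flat_idx[order]
    if len(sorted_idx) == 0:
        return out
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_idx) > 0])
    sums = np.add.reduceat(values[..., order], starts, axis=-1)
    out[..., sorted_idx[starts]] = sums
    return out


def pointwise_loglik(
    data: PreparedData,
    beta: np.ndarray,
    alpha: np.ndarray,
    gamma: np.ndarray | None,
    epsilon: np.ndarray | None,
    fixed_p: float | None = None,
    chunk: int = 2_000,
) -> np.ndarray:
    """Marginal per-cell log-likelihood for a batch of parameter draws.

    Returns an (S, n_cells) matrix; entry (s, i) marginalizes the latent
    states analytically (never conditions on sampled z).  Vectorized over
    draws in chunks to bound memory.
    """
    beta = np.atleast_2d(beta)
    S = beta.shape[0]
    n, T = data.n_cells, data.n_years
    flat_idx = data.rec_cell * T + data.rec_year
    q0 = np.where(data.detected, 0.0, 1.0)  # (n, T)
    out = np.empty((S, n))
    for s0 in range(0, S, chunk):
        sl = slice(s0, min(s0 + chunk, S))
        b = beta[sl]
        psi1 = _sigmoid(b @ data.X.T)  # (s, n)
        if fixed_p is not None:
            with np.errstate(divide="ignore"):
                contrib = np.where(
                    data.y == 1, np.log(fixed_p), np.log1p(-fixed_p)
                )[None, :].repeat(b.shape[0], axis=0)
        else:
            eta = np.atleast_2d(alpha)[sl] @ data.W.T  # (s, R)
            contrib = np.where(data.y == 1, _log_sigmoid(eta), _log_sigmoid(-eta))
        logq1 = _grouped_sum(contrib, flat_idx, n * T).reshape(-1, n, T)
        q1 = np.exp(logq1)
        a1 = psi1 * q1[:, :, 0]
        a0 = (1.0 - psi1) * q0[:, 0]
        for t in range(1, T):
            g = gamma[sl][:, None]
            e = epsilon[sl][:, None]
            a1, a0 = (
                (a1 * (1.0 - e) + a0 * g) * q1[:, :, t],
                (a1 * e + a0 * (1.0 - g)) * q0[:, t],
            )
        with np.errstate(divide="ignore"):
            out[sl] = np.log(a1 + a0)
    return out


# ---------------------------------------------------------------------------
# Sampler

class _AdaptiveRW:
    """Componentwise random-walk Metropolis with burn-in scale adaptation."""

    def __init__(self, k: int, config: McmcConfig):
        self.log_scale = np.full(k, np.log(config.init_scale))
        self.accepts = np.zeros(k)
        self.batch = 0
        self.config = config

    def adapt(self):
        self.batch += 1
        rate = self.accepts / self.config.adapt_interval
        self.log_scale += (rate - self.config.target_accept) / np.sqrt(self.batch)
        self.accepts[:] = 0.0


def _coef_loglik_beta(beta, X, z1):
    eta = X @ beta
    return float(np.sum(z1 * eta) - np.sum(np.logaddexp(0.0, eta)))


def _log_prior_beta(beta, config: McmcConfig, flat_psi: bool):
    if flat_psi:
        # standard-logistic density on the lone intercept == flat on psi
        b0 = beta[0]
        return float(_log_sigmoid(b0) + _log_sigmoid(-b0))
    return float(-0.5 * np.sum(beta**2) / config.prior_sd**2)


def _run_chain(data: PreparedData, spec: ModelSpec, config: McmcConfig,
               rng: np.random.Generator):
    n, T = data.n_cells, data.n_years
    k, m = data.X.shape[1], data.W.shape[1]
    flat_psi = config.flat_psi_prior and k == 1
    dynamic = T >= 2

    beta = rng.normal(0.0, 0.1, size=k)
    alpha = rng.normal(0.0, 0.1, size=m)
    gamma = rng.uniform(0.1, 0.9) if dynamic else 0.0
    epsilon = rng.uniform(0.1, 0.9) if dynamic else 0.0
    z = data.detected.astype(np.int8).copy()
    free = ~data.detected
    z[free] = (rng.random(free.sum()) < 0.5).astype(np.int8)

    rw_beta = _AdaptiveRW(k, config)
    rw_alpha = _AdaptiveRW(m, config) if m else None
    flat_idx = data.rec_cell * T + data.rec_year

    n_keep = config.retained_per_chain
    out_beta = np.empty((n_keep, k))
    out_alpha = np.empty((n_keep, m))
    out_gamma = np.empty(n_keep)
    out_eps = np.empty(n_keep)
    out_z = np.empty((n_keep, n, T), dtype=np.uint8) if config.store_z else None

    total = config.n_burnin + config.n_sampling
    keep_ptr = 0
    for it in range(total):
        # --- detection probabilities for this iteration's latent update
        if spec.fixed_p is not None:
            # p == 1 gives q1 = 0: an occupied, surveyed cell-year cannot go undetected
            rec_log1mp = np.full(len(data.y),
                                 np.log1p(-spec.fixed_p) if spec.fixed_p < 1 else -np.inf)
        else:
            eta = data.W @ alpha
            rec_log1mp = _log_sigmoid(-eta)
        logq1 = _grouped_sum(rec_log1mp[None, :], flat_idx, n * T)[0].reshape(n, T)
        q1 = np.exp(logq1)  # P(all y=0 in cell-year | z=1)

        # --- Gibbs update of latent states (sequential over years)
        psi1 = _sigmoid(data.X @ beta)
        for t in range(T):
            if t == 0:
                a = psi1
            else:
                a = np.where(z[:, t - 1] == 1, 1.0 - epsilon, gamma)
            if t < T - 1:
                b1 = np.where(z[:, t + 1] == 1, 1.0 - epsilon, epsilon)
                b0 = np.where(z[:, t + 1] == 1, gamma, 1.0 - gamma)
            else:
                b1 = b0 = 1.0
            f1 = a * q1[:, t] * b1
            f0 = (1.0 - a) * b0
            tot = f1 + f0
            prob1 = np.where(tot > 0, f1 / np.where(tot > 0, tot, 1.0), 0.5)
            draw = (rng.random(n) < prob1).astype(np.int8)
            z[:, t] = np.where(data.detected[:, t], 1, draw)

        # --- occupancy coefficients (componentwise adaptive RW Metropolis)
        z1 = z[:, 0]
        ll_beta = _coef_loglik_beta(beta, data.X, z1)
        lp_beta = _log_prior_beta(beta, config, flat_psi)
        scales = np.exp(rw_beta.log_scale)
        for j in range(k):
            prop = beta.copy()
            prop[j] += scales[j] * rng.normal()
            ll_p = _coef_loglik_beta(prop, data.X, z1)
            lp_p = _log_prior_beta(prop, config, flat_psi)
            if math.log(rng.random()) < (ll_p + lp_p) - (ll_beta + lp_beta):
                beta, ll_beta, lp_beta = prop, ll_p, lp_p
                rw_beta.accepts[j] += 1

        # --- detection coefficients, over records at occupied cell-years
        if m:
            active = z[data.rec_cell, data.rec_year] == 1
            Wa, ya = data.W[active], data.y[active]

            def ll_alpha_fn(a_vec):
                eta = Wa @ a_vec
                return float(np.sum(ya * eta) - np.sum(np.logaddexp(0.0, eta)))

            ll_alpha = ll_alpha_fn(alpha)
            scales_a = np.exp(rw_alpha.log_scale)
            for j in range(m):
                prop = alpha.copy()
                prop[j] += scales_a[j] * rng.normal()
                ll_p = ll_alpha_fn(prop)
                lp = -0.5 * (prop[j] ** 2 - alpha[j] ** 2) / config.prior_sd**2
                if math.log(rng.random()) < (ll_p - ll_alpha) + lp:
                    alpha, ll_alpha = prop, ll_p
                    rw_alpha.accepts[j] += 1

        # --- colonization/extinction (exact Beta full conditionals)
        if dynamic:
            prev, nxt = z[:, :-1], z[:, 1:]
            n01 = int(((prev == 0) & (nxt == 1)).sum())
            n00 = int(((prev == 0) & (nxt == 0)).sum())
            n10 = int(((prev == 1) & (nxt == 0)).sum())
            n11 = int(((prev == 1) & (nxt == 1)).sum())
            gamma = rng.beta(1 + n01, 1 + n00)
            epsilon = rng.beta(1 + n10, 1 + n11)

        in_burnin = it < config.n_burnin
        if in_burnin and (it + 1) % config.adapt_interval == 0:
            rw_beta.adapt()
            if rw_alpha is not None:
                rw_alpha.adapt()
        if not in_burnin:
            s = it - config.n_burnin
            if (s + 1) % config.thin == 0:
                out_beta[keep_ptr] = beta
                out_alpha[keep_ptr] = alpha
                out_gamma[keep_ptr] = gamma
                out_eps[keep_ptr] = epsilon
                if out_z is not None:
                    out_z[keep_ptr] = z
                keep_ptr += 1

    return out_beta, out_alpha, out_gamma, out_eps, out_z


def fit_mcmc(
    detections: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: ModelSpec,
    config: McmcConfig | None = None,
) -> PosteriorDraws:
    """Fit the dynamic occupancy model by MCMC; returns retained draws.

    Covariates must be standardized before fitting.  Deterministic under
    ``config.seed`` (chains use independently spawned substreams).
    """
    config = config or McmcConfig()
    data = prepare_data(detections, covariates, spec)
    ss = np.random.SeedSequence(config.seed)
    chains = [_run_chain(data, spec, config, np.random.default_rng(child))
              for child in ss.spawn(config.n_chains)]
    beta = np.stack([c[0] for c in chains])
    alpha = np.stack([c[1] for c in chains])
    dynamic = data.n_years >= 2
    gamma = np.stack([c[2] for c in chains]) if dynamic else None
    epsilon = np.stack([c[3] for c in chains]) if dynamic else None
    z = np.stack([c[4] for c in chains]) if config.store_z else None

    S = config.retained_total
    loglik = pointwise_loglik(
        data,
        beta.reshape(S, -1),
        alpha.reshape(S, -1),
        gamma.reshape(S) if dynamic else np.zeros(S),
        epsilon.reshape(S) if dynamic else np.zeros(S),
        fixed_p=spec.fixed_p,
    )
    return PosteriorDraws(beta=beta, alpha=alpha, gamma=gamma, epsilon=epsilon,
                          z=z, loglik=loglik, data=data, spec=spec, config=config)


# ---------------------------------------------------------------------------
# Diagnostics and summaries

class DegenerateChainsError(ValueError):
    """All chains constant: within-chain variance is zero, R-hat undefined."""


def rhat(chains: np.ndarray) -> float:
    """Brooks-Gelman-Rubin potential scale reduction factor (unsplit).

    ``chains`` is (m, n) retained draws.  With between-chain variance B
    and mean within-chain variance W:  sqrt(((n-1)/n * W + B/n) / W).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("rhat needs >= 2 chains of >= 2 draws")
    m, n = x.shape
    within = x.var(axis=1, ddof=1)
    W = within.mean()
    if W == 0.0:
        raise DegenerateChainsError("zero within-chain variance in all chains")
    B = n * x.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def _ci(draws: np.ndarray) -> tuple[float, float]:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return float(lo), float(hi)


def summarize_posterior(draws: PosteriorDraws) -> FitSummary:
    """Posterior table with the 95% CrI significance rule and R-hat.

    A covariate effect is significant when its 95% credible interval
    excludes zero.  Convergence declared when R-hat < 1.1 on every
    monitored parameter (coefficients, gamma, epsilon — not latent z);
    failures are recorded as warnings, never raised.
    """
    rows, warnings = [], []
    converged = True
    for name, arr in draws.parameter_draws().items():
        pooled = arr.reshape(-1)
        lo, hi = _ci(pooled)
        try:
            r = rhat(arr)
            if not r < RHAT_THRESHOLD:
                converged = False
                warnings.append(f"R-hat {r:.3f} >= {RHAT_THRESHOLD} for {name}")
        except DegenerateChainsError:
            r = np.nan
            warnings.append(f"degenerate (constant) chains for {name}")
        rows.append({
            "parameter": name, "mean": float(pooled.mean()), "lo": lo, "hi": hi,
            "rhat": r, "significant": bool(lo > 0.0 or hi < 0.0),
        })
    table = pd.DataFrame(rows).set_index("parameter")

    # derived mean occupancy per year: cell-average of psi, per draw
    S = draws.n_draws
    beta = draws.beta.reshape(S, -1)
    psi1 = _sigmoid(beta @ draws.data.X.T)  # (S, n)
    psi_years = [psi1]
    for _ in range(1, draws.data.n_years):
        g = draws.gamma.reshape(S, 1)
        e = draws.epsilon.reshape(S, 1)
        psi_years.append(psi_years[-1] * (1 - e) + (1 - psi_years[-1]) * g)
    recs = []
    for year, psi in zip(draws.data.years, psi_years):
        cell_avg = psi.mean(axis=1)
        lo, hi = _ci(cell_avg)
        recs.append({"year": year, "mean": float(cell_avg.mean()), "lo": lo, "hi": hi})
    return FitSummary(table=table, mean_psi_by_year=pd.DataFrame(recs),
                      converged=converged, warnings=warnings)
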