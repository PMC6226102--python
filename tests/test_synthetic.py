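"""Synthetic-data generator: survey structure, latent dynamics, and the
detection process, checked against binomial/Markov closed forms."""

import numpy as np
import pandas as pd
import pytest

from batscape.landscape import contagion
from batscape.synthetic import (
    REGIONS,
    SurveyCovariateModel,
    build_survey_design,
    generate_cell_covariates,
    generate_landscape_raster,
    simulate_detections,
    simulate_dynamics,
)


def _intercept_design(n_cells, seed=0, n_years=1, **kw):
    return build_survey_design(n_cells=n_cells, n_years=n_years, seed=seed,
                               regions=["only"], region_weights=[1.0], **kw)


class TestSurveyDesign:
    def test_default_study_layout(self):
        design = build_survey_design(n_cells=38, n_years=2, seed=1)
        assert design.n_cells == 38 and design.n_years == 2
        per_cell_year = design.occasions.groupby(["cell_id", "year"]).size()
        assert (per_cell_year == 6).all()  # 4 stationary + 2 mobile nights
        methods = design.occasions.groupby(["cell_id", "year"])["method"].value_counts()
        assert set(methods.unstack()["stationary"]) == {4}
        assert set(methods.unstack()["mobile"]) == {2}
        assert set(design.regions) == set(REGIONS)  # every region seeded

    def test_single_method_designs(self):
        mobile_only = _intercept_design(3, n_stationary=0, n_mobile=2)
        assert set(mobile_only.occasions["method"]) == {"mobile"}
        stationary_only = _intercept_design(3, n_stationary=4, n_mobile=0)
        assert set(stationary_only.occasions["method"]) == {"stationary"}

    def test_single_cell_default_occasions(self):
        design = _intercept_design(1)
        assert len(design.occasions) == 6

    def test_infeasible_when_fewer_cells_than_regions(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_survey_design(n_cells=3, n_years=1, seed=0)

    def test_deterministic_under_seed(self):
        a = build_survey_design(n_cells=20, seed=9)
        b = build_survey_design(n_cells=20, seed=9)
        assert a.regions.equals(b.regions)
        assert a.occasions.equals(b.occasions)


class TestLandscapeRaster:
    def test_single_class_is_uniform(self):
        r = generate_landscape_raster(dim=16, n_classes=1, clustering=3, seed=0)
        assert (r.grid == 0).all()

    def test_deterministic_under_seed(self):
        a = generate_landscape_raster(dim=20, n_classes=3, clustering=2, seed=4)
        b = generate_landscape_raster(dim=20, n_classes=3, clustering=2, seed=4)
        assert (a.grid == b.grid).all()

    def test_too_many_classes_errors(self):
        with pytest.raises(ValueError):
            generate_landscape_raster(dim=2, n_classes=5, seed=0)

    def test_clustering_raises_mean_contagion(self):
        # Monte Carlo over seeds: smoothing passes aggregate patches
        rough, smooth = [], []
        for seed in range(50):
            rough.append(contagion(generate_landscape_raster(24, 2, 0, seed=seed)))
            smooth.append(contagion(generate_landscape_raster(24, 2, 4, seed=seed)))
        assert np.mean(smooth) > np.mean(rough) + 5.0
        assert np.mean(rough) < 10.0  # iid field sits near the interspersed minimum


class TestDynamics:
    def test_frozen_dynamics_keep_states(self):
        design = _intercept_design(200, n_years=3)
        cov = generate_cell_covariates(design, seed=0)
        truth = simulate_dynamics(design, cov, {"intercept": 0.0}, 0.0, 0.0, seed=1)
        assert (truth.z == truth.z[:, [0]]).all()

    def test_certain_extinction_empties_year_two(self):
        design = _intercept_design(100, n_years=2)
        cov = generate_cell_covariates(design, seed=0)
        truth = simulate_dynamics(design, cov, {"intercept": 3.0}, 0.0, 1.0, seed=1)
        assert truth.z[:, 1].sum() == 0

    def test_intercept_only_occupancy_fraction(self):
        # beta0 = 0 -> psi = 0.5; binomial check at n = 10,000, 3 SE
        design = _intercept_design(10_000)
        cov = generate_cell_covariates(design, seed=0)
        truth = simulate_dynamics(design, cov, {"intercept": 0.0}, 0.0, 0.0, seed=2)
        se = np.sqrt(0.25 / 10_000)
        assert abs(truth.z[:, 0].mean() - 0.5) < 3 * se

    def test_year_two_matches_markov_chain(self):
        # empirical psi2 vs psi1(1-eps) + (1-psi1)gamma at Monte-Carlo error
        design = _intercept_design(10_000, n_years=2)
        cov = generate_cell_covariates(design, seed=0)
        gamma, eps = 0.3, 0.2
        truth = simulate_dynamics(design, cov, {"intercept": 0.0}, gamma, eps, seed=3)
        psi1 = truth.z[:, 0].mean()
        expected = psi1 * (1 - eps) + (1 - psi1) * gamma
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(truth.z[:, 1].mean() - expected) < 4 * se

    def test_unmatched_beta_name_errors(self):
        design = _intercept_design(10)
        cov = generate_cell_covariates(design, seed=0)
        with pytest.raises(KeyError, match="NotACovariate"):
            simulate_dynamics(design, cov, {"intercept": 0, "NotACovariate": 1}, 0, 0)

    def test_region_offsets_shift_occupancy(self):
        design = build_survey_design(n_cells=4000, n_years=1, seed=5)
        cov = generate_cell_covariates(design, seed=5)
        beta = {"intercept": -1.0, "region:Piedmont": 2.0}
        truth = simulate_dynamics(design, cov, beta, 0, 0, seed=6)
        pied = cov["region"].to_numpy() == "Piedmont"
        assert truth.z[pied, 0].mean() > truth.z[~pied, 0].mean() + 0.2


class TestDetections:
    def test_no_false_positives(self, small_study):
        det, truth, design = (small_study["detections"], small_study["truth"],
                              small_study["design"])
        cell_idx = {c: i for i, c in enumerate(design.cells)}
        year_idx = {y: t for t, y in enumerate(design.years)}
        z = truth.z[det["cell_id"].map(cell_idx), det["year"].map(year_idx)]
        assert (det.loc[z == 0, "y"] == 0).all()

    def test_perfect_detection_when_occupied(self):
        design = _intercept_design(50)
        cov = generate_cell_covariates(design, seed=0)
        truth = simulate_dynamics(design, cov, {"intercept": 20.0}, 0, 0, seed=1)
        assert truth.z.all()
        det = simulate_detections(truth, design, {"intercept": 30.0}, seed=2)
        assert (det["y"] == 1).all()

    def test_cumulative_detection_probability(self):
        # p = 0.5, z = 1, J = 4: P(>=1 detection) = 1 - 0.5^4 = 0.9375
        design = _intercept_design(10_000, n_stationary=4, n_mobile=0)
        cov = generate_cell_covariates(design, seed=0)
        truth = simulate_dynamics(design, cov, {"intercept": 25.0}, 0, 0, seed=1)
        det = simulate_detections(truth, design, {"intercept": 0.0}, seed=3)
        frac = det.groupby("cell_id")["y"].max().mean()
        se = np.sqrt(0.9375 * (1 - 0.9375) / 10_000)
        assert abs(frac - 0.9375) < 3 * se

    def test_unmatched_alpha_name_errors(self, small_study):
        with pytest.raises(KeyError, match="bogus"):
            simulate_detections(small_study["truth"], small_study["design"],
                                {"intercept": 0, "bogus": 1.0}, seed=0)

    def test_survey_covariates_recorded_per_record(self, small_study):
        det = small_study["detections"]
        for col in ("duration", "clutter", "temperature", "rain", "issue", "type"):
            assert col in det.columns
        assert set(det["clutter"]).issubset({0, 1, 2})
        assert set(det["type"]) == {0, 1}

    def test_missingness_drops_occasions(self):
        design = _intercept_design(100)
        cov = generate_cell_covariates(design, seed=0)
        truth = simulate_dynamics(design, cov, {"intercept": 0.0}, 0, 0, seed=1)
        model = SurveyCovariateModel(missing_rate=0.3)
        det = simulate_detections(truth, design, {"intercept": 0.0},
                                  survey_covariate_model=model, seed=2)
        assert len(det) < 600

    def test_deterministic_and_seed_sensitive(self, small_study):
        s = small_study
        a = simulate_detections(s["truth"], s["design"], s["config"].alpha, seed=11)
        b = simulate_detections(s["truth"], s["design"], s["config"].alpha, seed=11)
        c = simulate_detections(s["truth"], s["design"], s["config"].alpha, seed=12)
        assert a.equals(b)
        assert not a["y"].equals(c["y"])


class TestCovariateTable:
    def test_columns_and_bounds(self, small_study):
        cov = small_study["covariates"]
        for col in ("Ag", "Dev", "Forest", "F.Wet"):
            assert cov[col].between(0, 100).all()
        assert (cov[["Stream", "Pri", "Sec", "Ter", "Qua", "F.ED", "F.Wet.ED"]] >= 0).all().all()
        assert cov[["Ag", "Dev", "Forest", "F.Wet"]].sum(axis=1).max() <= 100 + 1e-9

    def test_default_correlations_realized(self):
        design = build_survey_design(n_cells=400, seed=3)
        cov = generate_cell_covariates(design, seed=3)
        r = np.corrcoef(cov["Dev"], cov["Pri"])[0, 1]
        assert r > 0.6
        r2 = np.corrcoef(cov["F.Wet"], cov["F.Wet.ED"])[0, 1]
        assert r2 > 0.7
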