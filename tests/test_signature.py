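"""Supervised-PC signature: Cox screen, selection, SVD projection, risk groups."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from phosphosig import DegenerateDataError, SimConfig, ValidationError, simulate_cohort
from phosphosig.io import zscore_by_probe
from phosphosig.signature import (
    SignatureModel,
    apply_signature,
    assign_risk_groups,
    fit_signature,
    select_features,
    select_threshold_cv,
    univariate_cox_screen,
)


@pytest.fixture(scope="module")
def trained():
    cfg = SimConfig(
        n_probes=200, n_samples_per_group=100, n_de_probes=0, n_prognostic=8,
        beta_range=(0.7, 1.0), probe_sd=0.8, censor_rate=0.3, seed=21,
    )
    cohort = simulate_cohort(cfg)
    z = zscore_by_probe(cohort.expression)
    t = cohort.clinical["time"].values
    e = cohort.clinical["event"].values
    screen = univariate_cox_screen(z, t, e)
    probes = select_features(screen, 0.25)
    model = fit_signature(z.loc[probes], t, e)
    return cohort, z, t, e, screen, probes, model


class TestCoxScreen:
    def test_matches_lifelines_per_probe(self, trained):
        cohort, z, t, e, screen, probes, model = trained
        for probe in list(z.index[:3]) + probes[:2]:
            df = pd.DataFrame({"x": z.loc[probe].values, "time": t, "event": e})
            cph = CoxPHFitter().fit(df, "time", "event")
            assert screen.loc[probe, "coef"] == pytest.approx(float(cph.params_["x"]), abs=1e-5)
            assert screen.loc[probe, "se"] == pytest.approx(
                float(cph.standard_errors_["x"]), abs=1e-5
            )

    def test_handles_tied_event_times_like_lifelines(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(size=n)
        t = np.round(rng.exponential(20, n))  # heavy ties
        t[t == 0] = 1
        e = rng.integers(0, 2, n)
        e[:10] = 1
        z = pd.DataFrame([x], index=["p"], columns=[f"s{i}" for i in range(n)])
        screen = univariate_cox_screen(z, t, e)
        cph = CoxPHFitter().fit(pd.DataFrame({"x": x, "time": t, "event": e}), "time", "event")
        assert screen.loc["p", "coef"] == pytest.approx(float(cph.params_["x"]), abs=1e-5)

    def test_null_probe_coef_small(self):
        rng = np.random.default_rng(1)
        n = 400
        x = rng.standard_normal((1, n))
        t = rng.exponential(50, n)
        z = pd.DataFrame(x, index=["p"], columns=[f"s{i}" for i in range(n)])
        z = zscore_by_probe(z)
        screen = univariate_cox_screen(z, t, np.ones(n, dtype=int))
        assert abs(screen.loc["p", "coef"]) < 0.2

    def test_negating_probe_negates_coef(self, trained):
        cohort, z, t, e, screen, probes, model = trained
        flipped = univariate_cox_screen(-z.iloc[:5], t, e)
        np.testing.assert_allclose(
            flipped["coef"].values, -screen["coef"].values[:5], atol=1e-7
        )
        np.testing.assert_allclose(
            flipped["score"].abs().values, screen["score"].abs().values[:5], atol=1e-7
        )

    def test_zero_events_rejected(self):
        z = pd.DataFrame(np.random.default_rng(2).normal(size=(3, 10)))
        with pytest.raises(ValidationError):
            univariate_cox_screen(z, np.arange(1, 11, dtype=float), np.zeros(10, dtype=int))

    def test_standardized_score_is_coef_over_se(self, trained):
        cohort, z, t, e, *_ = trained
        std = univariate_cox_screen(z.iloc[:10], t, e, score_type="standardized")
        np.testing.assert_allclose(
            std["score"].values, (std["coef"] / std["se"]).values, atol=1e-12
        )


class TestSelectFeatures:
    def _screen(self, scores):
        return pd.DataFrame(
            {"coef": scores, "se": 0.1, "score": scores, "converged": True},
            index=[f"p{i}" for i in range(len(scores))],
        )

    def test_inclusive_threshold_keeps_exact_hits(self):
        # a score of exactly 1 stays in at threshold 1 (boundary is inclusive)
        out = select_features(self._screen([-2.24, 1.0, 0.5]), 1.0)
        assert out == ["p0", "p1"]

    def test_threshold_above_max_errors(self):
        with pytest.raises(ValidationError, match="lower the threshold"):
            select_features(self._screen([0.2, -0.3]), 5.0)

    def test_tiny_threshold_selects_all_converged(self):
        screen = self._screen([0.5, -0.4, 0.3])
        screen.loc["p2", "converged"] = False
        assert set(select_features(screen, 1e-9)) == {"p0", "p1"}


class TestFitApply:
    def test_projection_identity_on_training_data(self, trained):
        cohort, z, t, e, screen, probes, model = trained
        reproduced = apply_signature(model, z.loc[probes])
        np.testing.assert_allclose(
            reproduced.values, model.training_index.values, atol=1e-10
        )

    def test_svd_structure(self, trained):
        *_, model = trained
        U, D = model.U, model.D
        np.testing.assert_allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-8)
        assert (np.diff(D) <= 1e-12).all() and (D > 0).all()

    def test_sign_gauge_invariance(self, trained):
        """Flipping a singular-vector pair and refitting leaves all indices equal."""
        cohort, z, t, e, screen, probes, model = trained
        from phosphosig.signature import _cox_on_scores

        X = z.loc[probes].values
        V = X.T @ model.U @ np.diag(1.0 / model.D)
        for flip in range(3):
            U2 = model.U.copy()
            U2[:, flip] *= -1
            V2 = X.T @ U2 @ np.diag(1.0 / model.D)
            beta2, _ = _cox_on_scores(V2, t, e, 3)
            idx2 = V2[:, :3] @ beta2
            np.testing.assert_allclose(idx2, model.training_index.values, atol=1e-6)

    def test_zero_test_matrix_gives_zero_indices(self, trained):
        *_, probes, model = trained
        zeros = pd.DataFrame(
            np.zeros((len(probes), 4)), index=probes, columns=list("abcd")
        )
        assert (apply_signature(model, zeros) == 0).all()

    def test_linearity_in_patient_vector(self, trained):
        cohort, z, t, e, screen, probes, model = trained
        X = z.loc[probes].iloc[:, :5].copy()
        doubled = X.copy()
        doubled.iloc[:, 2] *= 2.0
        base = apply_signature(model, X)
        scaled = apply_signature(model, doubled)
        assert scaled.iloc[2] == pytest.approx(2 * base.iloc[2], abs=1e-10)

    def test_missing_probe_rejected(self, trained):
        *_, probes, model = trained
        with pytest.raises(ValidationError, match="lacks"):
            apply_signature(model, pd.DataFrame(np.zeros((2, 3)), index=probes[:2]))

    def test_rank_deficient_matrix_rejected(self):
        X = pd.DataFrame(
            np.outer([1.0, 2.0, 3.0, 4.0], np.random.default_rng(3).normal(size=20))
        )
        X.index = [f"p{i}" for i in range(4)]
        t = np.arange(1.0, 21.0)
        with pytest.raises(DegenerateDataError):
            fit_signature(X, t, np.ones(20, dtype=int))

    def test_json_round_trip(self, trained, tmp_path):
        *_, model = trained
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SignatureModel.from_json(path)
        np.testing.assert_allclose(back.U, model.U)
        np.testing.assert_allclose(back.D, model.D)
        np.testing.assert_allclose(back.beta, model.beta)
        assert back.selected_probes == model.selected_probes


class TestRiskGroups:
    def test_quintile_rule_counts(self):
        out = assign_risk_groups(pd.Series(np.arange(1.0, 11.0)), "quintile_3v2")
        assert (out["group"].values[:6] == "lower_3_quintiles").all()
        assert (out["group"].values[6:] == "upper_2_quintiles").all()

    def test_median_rule_counts(self):
        out = assign_risk_groups(pd.Series(np.arange(1.0, 11.0)), "median")
        assert (out["group"].values[:5] == "below_median").all()
        assert (out["group"].values[5:] == "above_median").all()

    def test_ties_at_cutoff_go_low(self):
        idx = pd.Series([0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        out = assign_risk_groups(idx, "quintile_3v2")
        cutoff = np.quantile(idx.values, 0.6)
        assert (out.loc[idx == cutoff, "group"] == "lower_3_quintiles").all()

    def test_degenerate_indices_rejected(self):
        with pytest.raises(DegenerateDataError):
            assign_risk_groups(pd.Series(np.ones(10)))


class TestThresholdCV:
    def test_deterministic_per_seed(self, trained):
        cohort, z, t, e, *_ = trained
        sub = z.iloc[:60]
        grid = [0.2, 0.4, 0.8]
        thr1 = select_threshold_cv(sub, t, e, grid=grid, k_folds=3, seed=5)
        thr2 = select_threshold_cv(sub, t, e, grid=grid, k_folds=3, seed=5)
        assert thr1 == thr2 and thr1 in grid

    def test_recovers_planted_probes(self):
        cfg = SimConfig(
            n_probes=150, n_samples_per_group=250, n_de_probes=0, n_prognostic=10,
            beta_range=(1.2, 1.2), probe_sd=1.0, censor_rate=0.2, seed=31,
        )
        cohort = simulate_cohort(cfg)
        z = zscore_by_probe(cohort.expression)
        t = cohort.clinical["time"].values
        e = cohort.clinical["event"].values
        thr = select_threshold_cv(z, t, e, grid=[0.1, 0.3, 0.6], k_folds=4, seed=1)
        screen = univariate_cox_screen(z, t, e)
        selected = set(select_features(screen, thr))
        planted = set(cohort.truth_prognostic)
        assert len(planted & selected) >= 8
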