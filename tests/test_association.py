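"""Session table assembly, mixed-model estimation and diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from postictal import (
    COVARIATES,
    DomainLMM,
    SimConfig,
    build_session_table,
    fit_domain_lmm,
    midazolam_sensitivity,
    score_rot_log,
    simulate_study,
    vif_screen,
)
from postictal.simulate import CONTINUOUS_COVARIATES


@pytest.fixture(scope="module")
def study_table(small_study):
    rot = score_rot_log(small_study.rot_log)
    return build_session_table(small_study.sessions, rots=rot)


def _zero_noise_table(n_subj=12, n_sess=5, seed=0):
    """Deterministic outcome = exact linear predictor (no noise anywhere)."""
    cfg = SimConfig(n_subjects=n_subj, sessions_per_subject=float(n_sess),
                    seed=seed, random_effect_sds=(0.0, 0.0), resid_sd=0.0,
                    question_sd=0.0, baseline_disoriented_prob=0.0,
                    question_interval=1e-6)
    study = simulate_study(cfg)
    rot = score_rot_log(study.rot_log)
    return build_session_table(study.sessions, rots=rot), cfg


class TestBuildSessionTable:
    def test_join_and_standardization(self, small_study):
        rot = score_rot_log(small_study.rot_log)
        table = build_session_table(small_study.sessions, rots=rot)
        assert len(table) == len(small_study.sessions)
        for c in CONTINUOUS_COVARIATES:
            assert table[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert table[c].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert set(table["midazolam"]) <= {0, 1}

    def test_duplicate_session_id(self, small_study):
        dup = pd.concat([small_study.sessions, small_study.sessions.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            build_session_table(dup)

    def test_missing_domain_dropped_per_model(self, study_table):
        table = study_table.copy()
        sid = table["session_id"].iloc[0]
        table.loc[table["session_id"] == sid, "rot_place"] = np.nan
        m_place = DomainLMM("place").fit(table)
        m_person = DomainLMM("person").fit(table)
        assert m_place.n_obs_ == table["rot_place"].notna().sum()
        assert m_person.n_obs_ == table["rot_person"].notna().sum()


class TestDegenerateAndOLS:
    def test_zero_noise_recovers_generating_betas_exactly(self):
        table, cfg = _zero_noise_table()
        m = DomainLMM("person").fit(table)
        assert m.method_ == "OLS-degenerate"
        beta = cfg.beta_truth["person"]
        for cov in COVARIATES:
            assert m.coef_.loc[cov, "beta"] == pytest.approx(
                beta.get(cov, 0.0), abs=1e-6)
        assert m.coef_.loc["Intercept", "beta"] == pytest.approx(24.0, abs=1e-6)

    def test_forced_zero_random_effects_equal_lstsq(self, study_table):
        """Equivalence oracle: random effects forced to zero == plain least
        squares, checked against numpy's lstsq independently."""
        m = DomainLMM("person", random_effects=False).fit(study_table)
        data = study_table[["subject_id", "rot_person"] + COVARIATES].dropna()
        X = np.column_stack([np.ones(len(data)),
                             data[COVARIATES].to_numpy(float)])
        beta_ref, *_ = np.linalg.lstsq(X, data["rot_person"].to_numpy(), rcond=None)
        np.testing.assert_allclose(m.coef_["beta"].to_numpy(), beta_ref,
                                   atol=1e-6)


class TestMixedModel:
    def test_reml_fit_reports(self, study_table):
        res = fit_domain_lmm(study_table, "person")
        assert res.method == "REML"
        assert res.n_subjects == 16
        assert set(res.coef.index) == set(COVARIATES) | {"Intercept"}
        # CI contains the point estimate; p-values are probabilities
        assert ((res.coef["ci_low"] <= res.coef["beta"])
                & (res.coef["beta"] <= res.coef["ci_high"])).all()
        assert res.coef["p"].between(0, 1).all()
        assert (res.vif >= 1).all()
        assert "resid_shapiro_p" in res.diagnostics

    def test_singularity_fallback_with_zero_slope_variance(self):
        """True random-slope variance 0: the full specification is singular on
        most replicates and the intercept-only downgrade keeps estimates
        unbiased."""
        fallbacks, est = [], []
        for seed in range(6):
            cfg = SimConfig(n_subjects=16, sessions_per_subject=6.0,
                            seed=400 + seed, random_effect_sds=(5.0, 0.0))
            study = simulate_study(cfg)
            table = build_session_table(
                study.sessions, rots=score_rot_log(study.rot_log))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = DomainLMM("person").fit(table)
            fallbacks.append(m.fallback_ == "intercept-only" or m.singular_)
            est.append(m.coef_.loc["seizure_duration", "beta"])
        assert sum(fallbacks) >= 3
        assert np.mean(est) == pytest.approx(2.5, abs=0.8)

    def test_estimator_consistency_with_more_sessions(self):
        """RMSE of the T_max fixed effect shrinks as sessions/subject grow."""
        rmse = []
        for n_sess in (2, 5, 12):
            errs = []
            for seed in range(8):
                cfg = SimConfig(n_subjects=16,
                                sessions_per_subject=float(n_sess),
                                seed=700 + seed)
                study = simulate_study(cfg)
                table = build_session_table(
                    study.sessions, rots=score_rot_log(study.rot_log))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = DomainLMM("person").fit(table)
                errs.append(m.coef_.loc["t_max", "beta"] - 1.5)
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmse[2] < rmse[0]
        assert abs(np.mean(rmse[2])) < 1.5


class TestVIF:
    def test_independent_predictors(self, rng):
        df = pd.DataFrame(rng.standard_normal((500, 3)),
                          columns=["a", "b", "c"])
        v = vif_screen(df, ["a", "b", "c"])
        assert ((v > 0.9) & (v < 1.2)).all()

    def test_duplicated_column_infinite(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(100)})
        df["b"] = df["a"]
        df["c"] = rng.standard_normal(100)
        v = vif_screen(df, ["a", "b", "c"])
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_closed_form_at_correlation_0p6(self, rng):
        # two predictors with correlation rho: VIF = 1/(1-rho^2) ~ 1.5625
        n = 200_000
        x = rng.standard_normal(n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        v = vif_screen(pd.DataFrame({"t_max": x, "seizure_duration": y}),
                       ["t_max", "seizure_duration"])
        assert v["t_max"] == pytest.approx(1 / (1 - 0.36), rel=0.02)
        assert (v < 5).all()


class TestMidazolamSensitivity:
    def test_subset_size_and_agreement(self, study_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sens = midazolam_sensitivity(study_table)
        assert set(sens) == {"person", "place", "time"}
        n_free = int((study_table["midazolam"] == 0).sum())
        assert sens["person"].n_obs <= n_free
        assert "midazolam" not in sens["person"].coef.index
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = fit_domain_lmm(study_table, "person")
        diff = abs(sens["person"].coef.loc["t_max", "beta"]
                   - full.coef.loc["t_max", "beta"])
        pooled_se = (sens["person"].coef.loc["t_max", "se"]
                     + full.coef.loc["t_max", "se"])
        assert diff < 3 * pooled_se

    def test_all_midazolam_skipped(self, study_table):
        t = study_table.copy()
        t["midazolam"] = 1
        with pytest.warns(UserWarning, match="skipped"):
            assert midazolam_sensitivity(t) == {}
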