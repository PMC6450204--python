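"""REML engine: oracles, constraints, tests and BLUPs."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space

from meles.simgen import LmmTruth, simulate_lmm_records
from meles.varpart import (
    LmmError,
    LmmSpec,
    fit_lmm,
    group_effects,
    icc,
    lrt,
    preprocess_response,
    standard_tests,
    wald_fixed,
)
from meles.varpart import _Parameterization, _Problem


@pytest.fixture(scope="module")
def rec300():
    truth = LmmTruth(
        v_year=0.1, v_m=0.3, v_p=0.2, v_msg=0.4, v_psg=0.3, cov_msg_psg=-0.15, v_r=0.5
    )
    return simulate_lmm_records(truth, 300, seed=42, p_within_group=0.4)


class TestPreprocess:
    def test_zero_distance_maps_to_zero_before_scaling(self):
        df = pd.DataFrame({"pd_i": [0.0, 100.0, 400.0], "egp_i": [0, 1, 1]})
        out = preprocess_response(df, "pd", delta=1.0, sdu=False)
        assert out["response"].iloc[0] == 0.0

    def test_sdu_scaling_gives_unit_sd(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"pd_i": rng.exponential(300, 200), "egp_i": rng.integers(0, 2, 200)})
        for resp in ("pd", "egp"):
            out = preprocess_response(df, resp)
            assert np.std(out["response"], ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_log_transform_reduces_skew(self):
        rng = np.random.default_rng(1)
        pd_i = np.where(rng.random(500) < 0.6, 0.0, rng.lognormal(6, 0.7, 500))
        df = pd.DataFrame({"pd_i": pd_i, "egp_i": (pd_i > 0).astype(int)})
        from scipy.stats import skew

        out = preprocess_response(df, "pd", sdu=False)
        assert abs(skew(out["response"])) < abs(skew(pd_i))

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"pd_i": [100.0] * 5, "egp_i": [1] * 5})
        with pytest.raises(LmmError, match="zero variance"):
            preprocess_response(df, "pd")

    def test_nonbinary_egp_rejected(self):
        df = pd.DataFrame({"pd_i": [1.0, 2.0], "egp_i": [0, 2]})
        with pytest.raises(LmmError, match="binary"):
            preprocess_response(df, "egp")


class TestRemlCore:
    def test_all_variances_zero_reduces_to_ols(self, rec300):
        spec = LmmSpec(fixed=("dam_age", "sire_age"))
        prob = _Problem(rec300, spec)
        theta = np.zeros(7)
        theta[6] = 0.77
        beta, _, _, _ = prob.gls(theta)
        ols, *_ = np.linalg.lstsq(prob.X, prob.y, rcond=None)
        assert np.allclose(beta, ols, atol=1e-10)

    def test_restricted_loglik_matches_contrast_oracle(self):
        # independent oracle: error-contrast MVN likelihood K'y ~ N(0, K'VK);
        # the profile form differs from it by the constant 0.5*log|X'X|
        truth = LmmTruth()
        rec = simulate_lmm_records(truth, 30, seed=9, n_groups=5, n_years=4)
        rng = np.random.default_rng(0)
        rec["x1"] = rng.standard_normal(30)
        spec = LmmSpec(fixed=("x1",))
        prob = _Problem(rec, spec)
        par = _Parameterization(spec)
        for shift in (-0.3, 0.0, 0.4):
            theta = par.theta(par.x0(1.0) + shift)
            ll = prob.reml(theta)
            K = null_space(prob.X.T)
            KVK = K.T @ prob.V(theta) @ K
            Ky = K.T @ prob.y
            sign, ld = np.linalg.slogdet(KVK)
            ll_contrast = -0.5 * (
                ld + Ky @ np.linalg.solve(KVK, Ky) + (prob.n - prob.p) * np.log(2 * np.pi)
            )
            offset = 0.5 * np.linalg.slogdet(prob.X.T @ prob.X)[1]
            assert ll == pytest.approx(ll_contrast - offset, abs=1e-6)

    def test_analytic_gradient_matches_finite_differences(self, rec300):
        spec = LmmSpec(fixed=())
        prob = _Problem(rec300, spec)
        par = _Parameterization(spec)
        x = par.x0(float(np.var(prob.y))) + 0.1
        theta = par.theta(x)
        _, g = prob.reml(theta, grad=True)
        h = 1e-6
        for k in range(7):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (prob.reml(tp) - prob.reml(tm)) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_matches_lme4_on_independent_crossed_model(self, rec300, tmp_path):
        # independent implementation check for the covariance-free submodel
        fit = fit_lmm(rec300, LmmSpec(fixed=("dam_age",), cov=False))
        csv = tmp_path / "d.csv"
        rec300.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        m <- lmer(response ~ dam_age + (1|cohort_year) + (1|dam_id) + (1|sire_id)
                  + (1|msg) + (1|psg), data=d, REML=TRUE)
        vc <- as.data.frame(VarCorr(m))
        write.csv(vc[, c('grp','vcov')], '{tmp_path / "vc.csv"}', row.names=FALSE)
        cat(logLik(m))
        """
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        vc = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
        assert fit.components["v_m"] == pytest.approx(vc["dam_id"], abs=1e-3)
        assert fit.components["v_p"] == pytest.approx(vc["sire_id"], abs=1e-3)
        assert fit.components["v_msg"] == pytest.approx(vc["msg"], abs=1e-3)
        assert fit.components["v_psg"] == pytest.approx(vc["psg"], abs=1e-3)
        assert fit.components["v_r"] == pytest.approx(vc["Residual"], abs=1e-3)
        assert fit.loglik == pytest.approx(float(res.stdout.strip()), abs=1e-3)

    def test_label_invariance(self, rec300):
        relabeled = rec300.copy()
        mapping = {g: f"zz_{g}" for g in rec300["msg"].unique()}
        relabeled["msg"] = relabeled["msg"].map(mapping)
        relabeled["psg"] = relabeled["psg"].map(mapping)
        relabeled["dam_id"] = "D_" + relabeled["dam_id"]
        a = fit_lmm(rec300, LmmSpec(fixed=()))
        b = fit_lmm(relabeled, LmmSpec(fixed=()))
        assert a.loglik == pytest.approx(b.loglik, abs=1e-5)
        for k in a.components:
            assert a.components[k] == pytest.approx(b.components[k], abs=1e-5)

    def test_group_covariance_matrix_is_psd(self, rec300):
        fit = fit_lmm(rec300, LmmSpec(fixed=()))
        c = fit.components
        assert c["cov_msg_psg"] ** 2 <= c["v_msg"] * c["v_psg"] + 1e-12

    def test_rank_deficient_fixed_design_rejected(self, rec300):
        data = rec300.copy()
        data["dup"] = data["dam_age"]
        with pytest.raises(LmmError, match="rank-deficient"):
            fit_lmm(data, LmmSpec(fixed=("dam_age", "dup")))


class TestDerived:
    def test_icc_simple_arithmetic(self):
        class Dummy:
            components = {
                "v_year": 0.0, "v_m": 1.0, "v_p": 1.0,
                "v_msg": 0.0, "v_psg": 0.0, "cov_msg_psg": -0.3, "v_r": 2.0,
            }

        ic = icc(Dummy())
        assert ic["icc_m"] == pytest.approx(0.25)
        assert ic["icc_p"] == pytest.approx(0.25)
        assert ic["icc_r"] == pytest.approx(0.5)
        assert sum(ic.values()) == pytest.approx(1.0)

    def test_icc_sums_to_one_on_fit(self, rec300):
        fit = fit_lmm(rec300, LmmSpec(fixed=()))
        assert sum(icc(fit).values()) == pytest.approx(1.0)

    def test_lrt_identical_fits_give_zero_and_p_one(self, rec300):
        fit = fit_lmm(rec300, LmmSpec(fixed=()))
        out = lrt(fit, fit, df=1)
        assert out["statistic"] == 0.0
        assert out["p_value"] == 1.0

    def test_lrt_df_conventions(self, rec300):
        spec = LmmSpec(fixed=())
        full = fit_lmm(rec300, spec)
        tests = standard_tests(rec300, spec, full=full)
        by_term = tests.set_index("term")
        assert by_term.loc["cov_msg_psg", "df"] == 1
        assert by_term.loc["v_msg", "df"] == 2
        assert by_term.loc["v_psg", "df"] == 2
        assert by_term.loc["v_m_eq_v_p", "df"] == 1
        assert (tests["statistic"] >= 0).all()

    def test_lrt_mismatched_fixed_effects_rejected(self, rec300):
        full = fit_lmm(rec300, LmmSpec(fixed=("dam_age",)))
        red = fit_lmm(rec300, LmmSpec(fixed=(), cov=False))
        with pytest.raises(LmmError, match="fixed effects"):
            lrt(full, red)

    def test_group_effect_algebra(self):
        class Dummy:
            components = {"v_msg": 0.4, "v_psg": 0.4, "cov_msg_psg": -0.4}

            @property
            def r_msg_psg(self):
                from meles.varpart import LmmFit

                return LmmFit.r_msg_psg.fget(self)

            @property
            def source_sink_slope(self):
                from meles.varpart import LmmFit

                return LmmFit.source_sink_slope.fget(self)

        d = Dummy()
        assert d.r_msg_psg == pytest.approx(-1.0)
        assert d.source_sink_slope == pytest.approx(-1.0)

    def test_zero_cov_constraint_gives_zero_r_and_slope(self, rec300):
        fit = fit_lmm(rec300, LmmSpec(fixed=(), cov=False))
        assert fit.r_msg_psg == 0.0
        assert fit.source_sink_slope == 0.0
        ge = group_effects(fit)
        assert ge["r_msg_psg"] == 0.0
        assert len(ge["blups"]) == rec300["msg"].nunique()

    def test_blups_track_generating_group_effects(self):
        truth = LmmTruth(
            v_year=0.0, v_m=0.05, v_p=0.05, v_msg=0.5, v_psg=0.5,
            cov_msg_psg=-0.45, v_r=0.2,
        )
        rec = simulate_lmm_records(truth, 800, seed=11)
        fit = fit_lmm(rec, LmmSpec(fixed=()))
        ge = group_effects(fit)
        assert ge["r_msg_psg"] < -0.5
        b = ge["blups"]
        # maternal and paternal BLUPs anti-correlated, echoing the covariance
        r = np.corrcoef(b["maternal_blup"], b["paternal_blup"])[0, 1]
        assert r < -0.3

    def test_wald_detects_large_effect_and_rank_error(self, rec300):
        data = rec300.copy()
        data["response"] = data["response"] + 1.5 * data["msg_group_size"]
        fit = fit_lmm(
            data, LmmSpec(fixed=("msg_group_size", "dam_age")), compute_se=True
        )
        w = wald_fixed(fit).set_index("term")
        assert w.loc["msg_group_size", "p_value"] < 1e-6
        assert w.loc["msg_group_size", "df2"] > 1
        assert w.loc["dam_age", "p_value"] > 0.001


class TestCalibrationLight:
    def test_wald_type_i_error_reasonable(self):
        # null covariate: rejection rate near alpha over modest replicates
        truth = LmmTruth(
            v_year=0.05, v_m=0.2, v_p=0.2, v_msg=0.2, v_psg=0.2,
            cov_msg_psg=-0.1, v_r=0.5,
        )
        rej = 0
        n_rep = 40
        for rep in range(n_rep):
            rec = simulate_lmm_records(truth, 150, seed=500 + rep, n_groups=10)
            fit = fit_lmm(rec, LmmSpec(fixed=("dam_age",)), compute_se=True)
            w = wald_fixed(fit).set_index("term")
            rej += w.loc["dam_age", "p_value"] < 0.05
        assert rej / n_rep < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
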