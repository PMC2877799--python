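"""First-level design construction, AR(1)-whitened fitting, and
second-level t / permutation / FDR inference."""

import numpy as np
import pandas as pd
import pytest

from actionrace import (BoldGroundTruth, FirstLevelGLM, RaceSimConfig,
                        Trial, build_design, eaa_table, fdr_bh, fit_glm,
                        generate_bold, generate_subject, hrf,
                        permutation_correlation, second_level_t,
                        two_sample_t)


@pytest.fixture
def subject_and_design(default_cfg):
    rng = np.random.default_rng(10)
    subj = generate_subject(default_cfg, rng)
    eaa = eaa_table(subj.trials, {"chosen": subj.params_chosen,
                                  "specified": subj.params_specified})
    dm = build_design(subj, 1, eaa=eaa, tr=default_cfg.tr,
                      n_volumes=default_cfg.n_volumes)
    return subj, eaa, dm


class TestHRF:
    def test_peak_near_five_seconds(self):
        dt = 0.01
        h = hrf(32.0, dt)
        assert np.argmax(h) * dt == pytest.approx(5.0, abs=0.1)
        assert h.max() == pytest.approx(1.0)

    def test_zero_at_onset(self):
        assert hrf(32.0, 0.125)[0] == 0.0

    def test_integral_sanity(self):
        dt = 0.125
        h = hrf(32.0, dt)
        area = h.sum() * dt
        assert 0 < area < 32.0

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            hrf(32.0, 0.0)


class TestBuildDesign:
    def test_model1_structure(self, subject_and_design):
        _, _, dm = subject_and_design
        assert dm.columns[:3] == ["TASK", "EAA", "CvS"]
        assert "constant" in dm.columns
        assert any(c.startswith("drift_") for c in dm.columns)
        assert "ERR" not in dm.columns  # no errors simulated
        # no column survives as all-zero
        assert not np.any(np.all(dm.frame.to_numpy() == 0, axis=0))

    def test_eaa_correlates_imperfectly_with_rt(self, default_cfg):
        """EAA shares a linear part with RT but adds a distinct
        non-linear part: 0 < r < 1 between the convolved columns."""
        rng = np.random.default_rng(12)
        subj = generate_subject(default_cfg, rng)
        eaa = eaa_table(subj.trials, {"chosen": subj.params_chosen,
                                      "specified": subj.params_specified})
        dm = build_design(subj, 2, eaa=eaa, tr=default_cfg.tr,
                          n_volumes=default_cfg.n_volumes)
        r = np.corrcoef(dm.frame["EAA"], dm.frame["RT"])[0, 1]
        assert 0.0 < abs(r) < 1.0

    def test_all_specified_drops_cvs(self, default_cfg):
        cfg = RaceSimConfig(proportions=(0.0, 2 / 3, 1 / 3))
        subj = generate_subject(cfg, rng=1)
        eaa = eaa_table(subj.trials, {"specified": subj.params_specified})
        with pytest.warns(UserWarning, match="CvS"):
            dm = build_design(subj, 1, eaa=eaa, tr=cfg.tr,
                              n_volumes=cfg.n_volumes)
        assert "CvS" not in dm.columns
        assert "CvS" in dm.metadata["dropped"]

    def test_error_trials_modelled_separately(self, default_cfg):
        cfg = RaceSimConfig(error_rate=0.3, seed=3)
        subj = generate_subject(cfg)
        params = {"chosen": subj.params_chosen,
                  "specified": subj.params_specified}
        eaa = eaa_table(subj.trials, params)
        dm = build_design(subj, 1, eaa=eaa, tr=cfg.tr,
                          n_volumes=cfg.n_volumes)
        assert "ERR" in dm.columns

    def test_modulator_centering_is_shift_invariant(self, subject_and_design,
                                                    default_cfg):
        """Adding a constant to every trial's EAA must not change the
        EAA column: the modulator is mean-centered before convolution,
        so only trial-to-trial variation survives."""
        from dataclasses import replace
        subj, eaa, dm = subject_and_design
        shifted = [(t, replace(e, eaa_total=e.eaa_total + 5.0))
                   for t, e in eaa]
        dm2 = build_design(subj, 1, eaa=shifted, tr=default_cfg.tr,
                           n_volumes=default_cfg.n_volumes)
        assert np.allclose(dm.frame["EAA"], dm2.frame["EAA"])
        assert not np.allclose(dm.frame["TASK"], dm.frame["TASK"] * 0)

    def test_volume_mismatch_rejected(self, subject_and_design, default_cfg):
        subj, eaa, _ = subject_and_design
        with pytest.raises(ValueError):
            build_design(subj, 1, eaa=eaa, tr=default_cfg.tr, n_volumes=20)

    def test_orthogonalize_flag(self, default_cfg):
        rng = np.random.default_rng(14)
        subj = generate_subject(default_cfg, rng)
        eaa = eaa_table(subj.trials, {"chosen": subj.params_chosen,
                                      "specified": subj.params_specified})
        dm = build_design(subj, 1, eaa=eaa, tr=default_cfg.tr,
                          n_volumes=default_cfg.n_volumes, orthogonalize=True)
        # each modulator is orthogonal to the regressors before it
        X = dm.frame
        assert abs(X["TASK"] @ X["EAA"]) < 1e-8
        assert abs(X["TASK"] @ X["CvS"]) < 1e-8
        assert abs(X["EAA"] @ X["CvS"]) < 1e-8


class TestFitGLM:
    def test_noiseless_exact_recovery(self, subject_and_design):
        _, _, dm = subject_and_design
        true = np.zeros(len(dm.columns))
        true[dm.columns.index("TASK")] = 2.0
        true[dm.columns.index("EAA")] = -1.0
        y = dm.frame.to_numpy() @ true
        res = fit_glm(y, dm)
        assert np.allclose(res.betas.to_numpy(), true, atol=1e-8)
        assert res.ar1_rho == 0.0

    def test_white_noise_rho_near_zero(self):
        n = 10_000
        X = pd.DataFrame({"constant": np.ones(n)})
        y = np.random.default_rng(6).standard_normal(n)
        res = fit_glm(y, X)
        assert abs(res.ar1_rho) < 0.05

    def test_whitened_residuals_uncorrelated(self, subject_and_design):
        """AR(1) noise with known rho: the whitened residual series
        passes a lag-1 autocorrelation check, |r1| < 2/sqrt(n)."""
        _, _, dm = subject_and_design
        truth = BoldGroundTruth(betas={"TASK": 1.0}, ar1_rho=0.4,
                                noise_sd=1.0)
        y = generate_bold(dm, truth, np.random.default_rng(15))
        m = FirstLevelGLM().fit(dm, y)
        e = m.resid_
        r1 = e[1:] @ e[:-1] / (e @ e)
        assert abs(r1) < 2 / np.sqrt(e.size)

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8],
                          "c": [0.0, 1, 0, 1]})
        with pytest.raises(ValueError, match="b"):
            FirstLevelGLM().fit(X, np.zeros(4))

    def test_dof_and_contrast_shape(self, subject_and_design):
        _, _, dm = subject_and_design
        y = np.random.default_rng(16).standard_normal(dm.frame.shape[0])
        m = FirstLevelGLM().fit(dm, y)
        assert m.dof_ == dm.frame.shape[0] - dm.frame.shape[1]
        est, t, p = m.contrast({"EAA": 1.0})
        assert np.isfinite([est, t, p]).all()

    def test_eaa_power_at_default_snr(self, default_cfg):
        """beta_EAA = 1 at default noise: the EAA contrast is positive
        in virtually every replicate (t ~ 8 at this SNR)."""
        rng = np.random.default_rng(17)
        truth = BoldGroundTruth(betas={"TASK": 1.0, "EAA": 1.0})
        pos = 0
        n_rep = 40
        for _ in range(n_rep):
            subj = generate_subject(default_cfg, rng)
            eaa = eaa_table(subj.trials, {"chosen": subj.params_chosen,
                                          "specified": subj.params_specified})
            dm = build_design(subj, 1, eaa=eaa, tr=default_cfg.tr,
                              n_volumes=default_cfg.n_volumes)
            y = generate_bold(dm, truth, rng)
            _, t, _ = FirstLevelGLM().fit(dm, y).contrast({"EAA": 1.0})
            pos += t > 0
        assert pos >= 0.95 * n_rep

    def test_model2_keeps_eaa_effect_specific(self, default_cfg):
        """BOLD generated with a pure EAA effect and no RT effect:
        in the joint EAA+RT model the EAA beta stays significantly
        positive and the RT beta does not, in >= 80% of replicates."""
        rng = np.random.default_rng(18)
        truth = BoldGroundTruth(betas={"TASK": 1.0, "EAA": 1.0})
        ok = 0
        n_rep = 30
        for _ in range(n_rep):
            subj = generate_subject(default_cfg, rng)
            eaa = eaa_table(subj.trials, {"chosen": subj.params_chosen,
                                          "specified": subj.params_specified})
            dm = build_design(subj, 2, eaa=eaa, tr=default_cfg.tr,
                              n_volumes=default_cfg.n_volumes)
            y = generate_bold(dm, truth, rng)
            m = FirstLevelGLM().fit(dm, y)
            _, te, pe = m.contrast({"EAA": 1.0})
            _, _, prt = m.contrast({"RT": 1.0})
            ok += (pe < 0.05 and te > 0 and prt >= 0.05)
        assert ok >= 0.8 * n_rep


class TestSecondLevel:
    def test_all_zero_values(self):
        res = second_level_t([0.0, 0.0, 0.0])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_hand_example(self):
        res = second_level_t([1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-9)
        assert res["dof"] == 2

    def test_degenerate_nonzero_constant(self):
        res = second_level_t([1.0, 1.0, 1.0])
        assert res["degenerate"]

    def test_type_one_error_calibrated(self):
        """Null simulation: rejection rate at alpha = 0.05 is 0.05
        within Monte-Carlo error."""
        rng = np.random.default_rng(19)
        n_sims = 10_000
        rej = 0
        for _ in range(n_sims):
            rej += second_level_t(rng.standard_normal(20))["p"] < 0.05
        assert rej / n_sims == pytest.approx(0.05, abs=0.01)

    def test_two_sample(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            second_level_t([1.0, 2.0])


class TestPermutationCorrelation:
    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(20)
        C = rng.standard_normal((15, 3))
        cov = rng.standard_normal(15)
        a = permutation_correlation(C, cov, n_perm=500, rng=1)
        b = permutation_correlation(C, -cov, n_perm=500, rng=1)
        assert np.allclose(a.p_corrected, b.p_corrected)
        assert np.allclose(a.statistic, -b.statistic)

    def test_p_floor(self):
        rng = np.random.default_rng(21)
        cov = rng.standard_normal(20)
        res = permutation_correlation(cov[:, None], cov, n_perm=500, rng=2)
        assert res.p_corrected[0] == pytest.approx(1 / 501)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            permutation_correlation(np.random.default_rng(0)
                                    .standard_normal((10, 2)),
                                    np.ones(10), n_perm=200, rng=0)

    def test_input_validation(self):
        rng = np.random.default_rng(22)
        with pytest.raises(ValueError):
            permutation_correlation(rng.standard_normal((5, 2)),
                                    rng.standard_normal(5), n_perm=200)
        with pytest.raises(ValueError):
            permutation_correlation(rng.standard_normal((10, 2)),
                                    rng.standard_normal(10), n_perm=10)


class TestFDR:
    def test_step_up_example(self):
        """0.04 <= 3*0.05/4 fails, so exactly the first two reject."""
        reject, thresh = fdr_bh([0.001, 0.02, 0.04, 0.2], q=0.05)
        assert list(reject) == [True, True, False, False]
        assert thresh == pytest.approx(0.02)

    def test_all_ones(self):
        reject, _ = fdr_bh([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_single_p(self):
        reject, _ = fdr_bh([0.04], q=0.05)
        assert reject.all()

    def test_empty(self):
        reject, thresh = fdr_bh([], q=0.05)
        assert reject.size == 0 and thresh == 0.0
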