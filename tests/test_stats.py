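"""Exclusions, evidence predictors, and mixed-effects analyses."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from comddm import TaskConfig, make_fixture
from comddm.glmm import LogisticGLMM, lr_test
from comddm.stats import (
    apply_exclusions,
    attach_evidence_predictors,
    fit_com_probability_model,
    fit_com_speed_model,
)


class TestExclusions:
    def test_fixture_counts_by_enumeration(self):
        fx = make_fixture("exclusions")
        kept, rep = apply_exclusions(fx["trials"])
        e = fx["expected"]
        assert rep.n_no_response == e["n_no_response"]
        assert rep.n_multi_change == e["n_multi_change"]
        assert rep.n_fast_com == e["n_fast_com"]
        assert rep.n_fast_initial == e["n_fast_initial"]
        assert rep.n_retained == e["n_retained_default"] == len(kept)
        kept2, rep2 = apply_exclusions(fx["trials"], exclude_fast_initial=True)
        assert rep2.n_retained == e["n_retained_strict"] == len(kept2)

    def test_clean_table_passes_through(self):
        fx = make_fixture("exclusions")
        clean = fx["trials"].iloc[:2]
        kept, rep = apply_exclusions(clean)
        assert rep.n_retained == 2
        assert (rep.n_no_response, rep.n_multi_change, rep.n_fast_com,
                rep.n_fast_initial) == (0, 0, 0, 0)
        pd.testing.assert_frame_equal(kept, clean)

    def test_first_rule_attribution(self):
        # a no-response trial with n_changes=2 counts once, as no-response
        fx = make_fixture("exclusions")
        row = fx["trials"].iloc[[2]]
        assert row["n_changes"].iloc[0] == 2
        _, rep = apply_exclusions(row)
        assert rep.n_no_response == 1 and rep.n_multi_change == 0

    def test_row_order_invariance(self):
        fx = make_fixture("exclusions")
        perm = fx["trials"].sample(frac=1.0, random_state=1)
        _, a = apply_exclusions(fx["trials"])
        _, b = apply_exclusions(perm)
        assert a.as_dict() == b.as_dict()

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="missing required"):
            apply_exclusions(pd.DataFrame({"participant": []}))


class TestPredictors:
    def _trials(self, rt):
        return pd.DataFrame(
            [{"participant": "P01", "session": 1, "correct_side": "left",
              "initial_choice": "left", "initial_rt": rt, "n_changes": 0,
              "final_choice": "left", "com_latency": np.nan}]
        )

    def test_constant_residuals(self):
        cfg = TaskConfig()
        res = np.full((1, 173), 0.3)
        out = attach_evidence_predictors(self._trials(0.5), res, cfg)
        assert out["first_frame"].iloc[0] == pytest.approx(0.3)
        assert out["pre_response_mean"].iloc[0] == pytest.approx(0.3)
        assert out["win_0_200"].iloc[0] == pytest.approx(0.3)
        assert out["win_200_400"].iloc[0] == pytest.approx(0.3)

    def test_zero_to_200ms_window_has_15_frames(self):
        # frames 0..14 start before 200 ms; frame 15 starts exactly at 200 ms
        cfg = TaskConfig()
        res = np.zeros((1, 173))
        res[0, :15] = 1.0
        res[0, 15] = -5.0  # must not leak into the window
        out = attach_evidence_predictors(self._trials(0.79), res, cfg)
        assert out["win_0_200"].iloc[0] == pytest.approx(1.0)

    def test_pre_response_mean_excludes_first_frame(self):
        cfg = TaskConfig()
        res = np.zeros((1, 173))
        res[0, 0] = 1.0
        rt = 3 * cfg.frame_duration + 1e-4  # response lands in frame 3
        out = attach_evidence_predictors(self._trials(rt), res, cfg)
        assert out["pre_response_mean"].iloc[0] == pytest.approx(0.0)

    def test_window_truncated_by_early_response_is_flagged(self):
        cfg = TaskConfig()
        res = np.zeros((1, 173))
        res[0, :30] = 0.5
        out = attach_evidence_predictors(self._trials(0.25), res, cfg)
        assert bool(out["win_200_400_truncated"].iloc[0])
        assert out["win_200_400"].iloc[0] == pytest.approx(0.5)


def _simulate_glmm_data(seed, n_per=120, n_groups=4, beta=(0.2, -1.0, 0.4, -0.8),
                        sigma=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, sigma)
        acc = rng.integers(0, 2, n_per)
        ev = rng.uniform(-1, 1, n_per)
        eta = beta[0] + beta[1] * acc + beta[2] * ev + beta[3] * acc * ev + b
        y = rng.random(n_per) < expit(eta)
        rows.append(pd.DataFrame({"participant": f"G{g}", "com": y.astype(int),
                                  "accuracy": acc, "evidence": ev}))
    return pd.concat(rows, ignore_index=True)


class TestLogisticGLMM:
    def test_matches_lme4_on_fixture(self, tmp_path):
        """Independent oracle: lme4::glmer at the same nAGQ on the same data."""
        d = _simulate_glmm_data(42)
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        rcode = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            'm <- glmer(com ~ accuracy*evidence + (1|participant),'
            '           data=d, family=binomial, nAGQ=10);'
            'cat(logLik(m), fixef(m), sqrt(unlist(VarCorr(m))), sep=",")'
        )
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        vals = np.array([float(x) for x in out.stdout.strip().split(",")])
        g = LogisticGLMM(d, "com", ["accuracy", "evidence",
                                    "accuracy:evidence"], "participant",
                         nagq=10)
        res = g.fit()
        assert res.loglike == pytest.approx(vals[0], abs=1e-3)
        np.testing.assert_allclose(res.params, vals[1:5], atol=2e-3)
        assert res.sigma == pytest.approx(vals[5], abs=5e-3)

    def test_constant_evidence_reduces_to_accuracy_model(self):
        d = _simulate_glmm_data(7)
        d["evidence"] = 0.0
        full = LogisticGLMM(d, "com", ["accuracy", "evidence",
                                       "accuracy:evidence"],
                            "participant").fit()
        red = LogisticGLMM(d, "com", ["accuracy"], "participant").fit()
        lr = lr_test(full.loglike, red.loglike, df=2)
        assert lr["chi2"] < 1e-3

    def test_needs_binary_response(self):
        d = _simulate_glmm_data(1)
        d.loc[0, "com"] = 2
        with pytest.raises(ValueError, match="binary"):
            LogisticGLMM(d, "com", ["accuracy"], "participant")


class TestBehaviouralModels:
    def test_probability_model_direction_on_study_data(self, study_retained):
        retained, _, _ = study_retained
        res = fit_com_probability_model(retained, nagq=5)
        assert res["lr"]["p"] < 0.05
        assert res["interaction"] < 0  # fewer changes when frame 0 backs the choice

    def test_speed_model_scale_invariance(self, study_retained):
        retained, _, _ = study_retained
        a = fit_com_speed_model(retained)
        scaled = retained.copy()
        scaled["first_frame"] = scaled["first_frame"] * 3.0
        b = fit_com_speed_model(scaled)
        assert a["lr"]["chi2"] == pytest.approx(b["lr"]["chi2"], abs=1e-4)

    def test_speed_model_null_under_shuffled_latencies(self, study_retained):
        retained, _, _ = study_retained
        rng = np.random.default_rng(12)
        shuffled = retained.copy()
        com_idx = shuffled.index[shuffled["n_changes"].eq(1)]
        lat = shuffled.loc[com_idx, "com_latency"].to_numpy()
        shuffled.loc[com_idx, "com_latency"] = rng.permutation(lat)
        res = fit_com_speed_model(shuffled)
        assert res["lr"]["p"] > 0.01

    def test_single_participant_rejected(self, study_retained):
        retained, _, _ = study_retained
        one = retained[retained["participant"] == retained["participant"].iloc[0]]
        with pytest.raises(ValueError, match="participants"):
            fit_com_probability_model(one)
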