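"""Reverse correlation: classification, kernels, splits, smoothing, tests."""

import numpy as np
import pandas as pd
import pytest

from comddm import TaskConfig, make_fixture
from comddm.kernels import (
    classify_responses,
    compute_kernels,
    first_frame_contrast,
    framewise_tests,
    median_split_com_rt,
    response_type_groups,
    smooth_kernel,
)


@pytest.fixture()
def config():
    return TaskConfig()


def _trial(**kw):
    row = {
        "participant": "P01", "session": 1, "correct_side": "left",
        "initial_choice": "left", "initial_rt": 0.4, "n_changes": 0,
        "final_choice": "left", "com_latency": np.nan,
    }
    row.update(kw)
    return row


class TestClassification:
    @pytest.mark.parametrize(
        "kw,expected",
        [
            (dict(), "correct"),
            (dict(initial_choice="right", final_choice="right"), "error"),
            (dict(initial_choice="right", final_choice="left", n_changes=1,
                  com_latency=0.3), "corrected_error"),
            (dict(final_choice="right", n_changes=1, com_latency=0.3),
             "spoilt_correct"),
            (dict(n_changes=2), "excluded"),
            (dict(initial_choice="none", initial_rt=np.nan,
                  final_choice="none"), "excluded"),
        ],
    )
    def test_mapping(self, kw, expected):
        out = classify_responses(pd.DataFrame([_trial(**kw)]))
        assert out.iloc[0] == expected

    def test_inconsistent_latency_raises(self):
        bad = pd.DataFrame([_trial(com_latency=0.3)])
        with pytest.raises(ValueError, match="n_changes"):
            classify_responses(bad)

    def test_single_change_must_flip(self):
        bad = pd.DataFrame([_trial(n_changes=1, com_latency=0.3)])
        with pytest.raises(ValueError, match="flip"):
            classify_responses(bad)

    def test_group_sizes_conserved(self, study_dataset):
        rt = classify_responses(study_dataset.trials)
        counts = rt.value_counts()
        assert counts.sum() == len(study_dataset.trials)


class TestKernels:
    def test_three_trial_fixture_exact(self, config):
        fx = make_fixture("kernels")
        k = compute_kernels(fx["trials"], fx["residuals"], config,
                            lock="stimulus_onset")
        np.testing.assert_allclose(
            k.condition("correct")["mean"], fx["expected"]["correct_mean"]
        )
        np.testing.assert_allclose(
            k.condition("error")["mean"], fx["expected"]["error_mean"]
        )
        all_mask = {"all": np.ones(3, bool)}
        k_all = compute_kernels(fx["trials"], fx["residuals"], config,
                                groups=all_mask)
        np.testing.assert_allclose(
            k_all.condition("all")["mean"], fx["expected"]["all_mean"]
        )

    def test_null_fixture_kernel_is_flat(self, config):
        fx = make_fixture("null")
        k = compute_kernels(
            fx["trials"], fx["residuals"], config,
            groups={"all": np.ones(len(fx["trials"]), bool)},
        )
        sub = k.condition("all")
        assert np.all(np.abs(sub["mean"]) < 4 * sub["se"])

    def test_min_trials_drops_sparse_bins(self, config):
        # 99 change-of-mind trials: every com-locked bin sits under the
        # 100-trial floor and must be absent
        rng = np.random.default_rng(0)
        rows = [
            _trial(n_changes=1, final_choice="right",
                   com_latency=float(rng.uniform(0.2, 0.5)))
            for _ in range(99)
        ]
        trials = pd.DataFrame(rows)
        res = rng.normal(size=(99, 173)) * 0.1
        k = compute_kernels(trials, res, config, lock="com_response",
                            groups={"com": np.ones(99, bool)},
                            min_trials=100)
        assert len(k.table) == 0
        k2 = compute_kernels(trials, res, config, lock="com_response",
                             groups={"com": np.ones(99, bool)}, min_trials=50)
        assert len(k2.table) > 0

    def test_empty_condition_warns_not_fatal(self, config):
        fx = make_fixture("kernels")
        with pytest.warns(UserWarning, match="no trials"):
            k = compute_kernels(
                fx["trials"], fx["residuals"], config,
                groups={"none": np.zeros(3, bool),
                        "all": np.ones(3, bool)},
            )
        assert k.conditions == ["all"]

    def test_unknown_lock_raises(self, config):
        fx = make_fixture("kernels")
        with pytest.raises(ValueError, match="lock"):
            compute_kernels(fx["trials"], fx["residuals"], config,
                            lock="feedback")

    def test_response_lock_alignment_floor_snapping(self, config):
        # one trial, response at 0.4 s -> frame 30; the bin at time 0 must
        # hold frame 30's residual
        res = np.arange(173, dtype=float)[None, :] / 200.0
        trials = pd.DataFrame([_trial(initial_rt=0.4)])
        k = compute_kernels(trials, res, config, lock="initial_response",
                            groups={"one": np.ones(1, bool)}, min_trials=1)
        sub = k.condition("one")
        at_zero = sub.loc[np.isclose(sub["time"], 0.0), "mean"].iloc[0]
        frame = int(np.floor(0.4 / config.frame_duration + 1e-9))
        assert at_zero == pytest.approx(res[0, frame])


class TestMedianSplit:
    def test_even_cell_split(self):
        rows = [
            _trial(n_changes=1, final_choice="right", com_latency=v)
            for v in (0.2, 0.4, 0.6, 0.8)
        ]
        labels = median_split_com_rt(pd.DataFrame(rows))
        assert list(labels) == ["fast", "fast", "slow", "slow"]

    def test_per_cell_vs_pooled_disagree(self):
        fx = make_fixture("median_split")
        labels = median_split_com_rt(fx["trials"])
        assert list(labels) == fx["expected"]["per_cell"]
        pooled = fx["trials"]["com_latency"] < fx["expected"]["pooled_median"]
        pooled_labels = np.where(pooled, "fast", "slow")
        assert list(labels) != list(pooled_labels)

    def test_all_ties_go_slow_with_warning(self):
        rows = [
            _trial(n_changes=1, final_choice="right", com_latency=0.5)
            for _ in range(4)
        ]
        with pytest.warns(UserWarning, match="equal"):
            labels = median_split_com_rt(pd.DataFrame(rows))
        assert (labels == "slow").all()

    def test_sparse_cell_skipped(self):
        rows = [_trial(n_changes=1, final_choice="right", com_latency=0.5)]
        with pytest.warns(UserWarning, match="skipped"):
            labels = median_split_com_rt(pd.DataFrame(rows))
        assert labels.isna().all()


class TestSmoothing:
    def _kernel(self, values, config):
        trials = pd.DataFrame([_trial(initial_rt=10.0)])
        res = np.array([values], dtype=float)
        return compute_kernels(trials, res, config,
                               groups={"c": np.ones(1, bool)})

    def test_span_one_is_identity(self, config):
        k = self._kernel([0.0, 3.0, 0.0, 1.0], config)
        sm = smooth_kernel(k, span=1)
        np.testing.assert_allclose(sm.condition("c")["mean"],
                                   k.condition("c")["mean"])

    def test_edge_shrinkage_arithmetic(self, config):
        k = self._kernel([0.0, 3.0, 0.0], config)
        sm = smooth_kernel(k, span=3)
        np.testing.assert_allclose(sm.condition("c")["mean"], [1.5, 1.0, 1.5])

    def test_constant_series_unchanged(self, config):
        k = self._kernel([0.7] * 6, config)
        sm = smooth_kernel(k, span=3)
        np.testing.assert_allclose(sm.condition("c")["mean"], 0.7)

    def test_even_span_rejected(self, config):
        k = self._kernel([0.0, 1.0], config)
        with pytest.raises(ValueError, match="odd"):
            smooth_kernel(k, span=2)


class TestFramewise:
    def test_alpha_nesting_and_null_rate(self, config):
        fx = make_fixture("null")
        n = len(fx["trials"])
        rng = np.random.default_rng(3)
        a = rng.random(n) < 0.5
        out = framewise_tests(fx["trials"], fx["residuals"], config,
                              a, ~a)
        assert (out["sig_0.01"] <= out["sig_0.05"]).all()
        # independent random split: false-positive count stays near nominal
        assert out["sig_0.01"].sum() <= max(4, 0.06 * len(out))

    def test_power_at_shifted_bin(self, config):
        rng = np.random.default_rng(4)
        n = 400
        res = rng.normal(0, 0.2, size=(n, 10))
        res[: n // 2, 4] += 0.2  # 1 SD shift at frame 4 for group A
        trials = pd.DataFrame([_trial(initial_rt=10.0) for _ in range(n)])
        mask = np.zeros(n, bool)
        mask[: n // 2] = True
        out = framewise_tests(trials, res, config, mask, ~mask)
        flagged = out.loc[out["sig_0.01"], "time"].to_numpy()
        assert np.isclose(flagged, 4 * config.frame_duration).any()


def test_first_frame_contrast_null_on_independent_responses(config):
    fx = make_fixture("null")
    out = first_frame_contrast(fx["trials"], fx["residuals"], n_boot=200,
                               rng=np.random.default_rng(9))
    assert abs(out["contrast"]) < 4 * out["se"]
    lo, hi = out["ci95"]
    assert lo < 0 < hi
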