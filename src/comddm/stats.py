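"""Trial exclusions, evidence predictors, and mixed-effects analyses.

The two focal analyses ask whether the very first frame of stimulus evidence
predicts (a) whether an initial decision is later reversed and (b) how
quickly the reversal happens.  Both are interaction tests: evidence is coded
toward the *correct* side, so "support for the initial decision" is carried
by the initial-accuracy x evidence interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .glmm import LogisticGLMM, lr_test
from .stimuli import TaskConfig

__all__ = [
    "ExclusionReport",
    "apply_exclusions",
    "attach_evidence_predictors",
    "fit_com_probability_model",
    "fit_com_speed_model",
    "compare_window_models",
]

_REQUIRED = (
    "participant", "session", "correct_side", "initial_choice", "initial_rt",
    "n_changes", "final_choice", "com_latency",
)


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts; a trial hitting several rules is counted
    once, under the first rule in the order listed."""

    n_input: int
    n_no_response: int
    n_multi_change: int
    n_fast_com: int
    n_fast_initial: int
    fast_initial_excluded: bool
    n_retained: int

    def as_dict(self) -> dict:
        return asdict(self)


def apply_exclusions(
    trials: pd.DataFrame,
    fast_com_cutoff: float = 0.05,
    fast_initial_cutoff: float = 0.15,
    exclude_fast_initial: bool = False,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the standard trial exclusions, in order:

    1. no initial response; 2. more than one change of mind; 3. change-of-mind
    latency below 50 ms; 4. initial RT below 150 ms -- screened and reported
    but, by default, *not* excluded (set ``exclude_fast_initial=True`` to
    drop them too).
    """
    missing = [c for c in _REQUIRED if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    no_resp = trials["initial_choice"].eq("none") | trials["initial_rt"].isna()
    multi = ~no_resp & trials["n_changes"].gt(1)
    fast_com = (
        ~no_resp & ~multi
        & trials["com_latency"].notna()
        & trials["com_latency"].lt(fast_com_cutoff)
    )
    fast_init = (
        ~no_resp & ~multi & ~fast_com & trials["initial_rt"].lt(fast_initial_cutoff)
    )
    drop = no_resp | multi | fast_com
    if exclude_fast_initial:
        drop = drop | fast_init
    report = ExclusionReport(
        n_input=len(trials),
        n_no_response=int(no_resp.sum()),
        n_multi_change=int(multi.sum()),
        n_fast_com=int(fast_com.sum()),
        n_fast_initial=int(fast_init.sum()),
        fast_initial_excluded=exclude_fast_initial,
        n_retained=int((~drop).sum()),
    )
    return trials[~drop].copy(), report


def attach_evidence_predictors(
    trials: pd.DataFrame,
    residuals: np.ndarray,
    config: TaskConfig,
    windows: tuple[tuple[float, float], ...] = ((0.0, 0.2), (0.2, 0.4)),
) -> pd.DataFrame:
    """Attach per-trial evidence predictors (all in [-1, 1], toward correct).

    first_frame: the frame-0 residual.  pre_response_mean: mean over frames 1
    .. (response frame - 1), i.e. the fully pre-response frames with the
    initial frame excluded.  win_{a}_{b}: mean over frames whose onsets fall
    in [a, b) seconds; if the response lands before a window's end the mean
    uses only that trial's pre-response frames (flagged in
    ``win_{a}_{b}_truncated``).
    """
    residuals = np.asarray(residuals, dtype=float)
    fd = config.frame_duration
    out = trials.copy()
    out["first_frame"] = residuals[:, 0]
    rt = trials["initial_rt"].to_numpy(float)
    resp_frame = np.where(
        np.isfinite(rt), np.floor(rt / fd + 1e-9), residuals.shape[1]
    ).astype(int)

    pre = np.full(len(trials), np.nan)
    for i in range(len(trials)):
        m = resp_frame[i]
        if m >= 2:
            pre[i] = residuals[i, 1:m].mean()
    out["pre_response_mean"] = pre

    onsets = config.frame_onsets(residuals.shape[1])
    for a, b in windows:
        in_win = (onsets >= a - 1e-9) & (onsets < b - 1e-9)
        col = _window_name(a, b)
        vals = np.full(len(trials), np.nan)
        trunc = np.zeros(len(trials), dtype=bool)
        idx_all = np.flatnonzero(in_win)
        for i in range(len(trials)):
            idx = idx_all[idx_all < resp_frame[i]]
            if len(idx) < len(idx_all):
                trunc[i] = True
            if len(idx):
                vals[i] = residuals[i, idx].mean()
        out[col] = vals
        out[col + "_truncated"] = trunc
    return out


def _window_name(a: float, b: float) -> str:
    return f"win_{int(round(a * 1000))}_{int(round(b * 1000))}"


def _model_frame(trials: pd.DataFrame, predictor: str) -> pd.DataFrame:
    d = pd.DataFrame(
        {
            "participant": trials["participant"].astype(str),
            "com": trials["n_changes"].ge(1).astype(int),
            "accuracy": trials["initial_choice"]
            .eq(trials["correct_side"])
            .astype(int),
            "evidence": trials[predictor].astype(float),
        }
    )
    return d.dropna(subset=["evidence"])


def fit_com_probability_model(
    trials: pd.DataFrame,
    predictor: str = "first_frame",
    nagq: int = 10,
    sign_toward: str = "correct",
) -> dict:
    """Logistic GLMM of change-of-mind occurrence.

    com ~ accuracy + evidence + accuracy:evidence + (1 | participant),
    fit by adaptive-quadrature ML; the likelihood-ratio test drops the
    interaction.  ``sign_toward="initial"`` re-signs evidence toward each
    trial's initial choice (alternative coding; the interaction then moves
    into the main evidence effect).
    """
    d = _model_frame(trials, predictor)
    if d["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants for a mixed model")
    if sign_toward == "initial":
        d["evidence"] *= np.where(d["accuracy"] == 1, 1.0, -1.0)
    elif sign_toward != "correct":
        raise ValueError("sign_toward must be 'correct' or 'initial'")
    full = LogisticGLMM(
        d, "com", ["accuracy", "evidence", "accuracy:evidence"],
        "participant", nagq=nagq,
    )
    res_full = full.fit()
    reduced = LogisticGLMM(d, "com", ["accuracy", "evidence"], "participant",
                           nagq=nagq)
    res_red = reduced.fit()
    lr = lr_test(res_full.loglike, res_red.loglike)
    if not (res_full.converged and res_red.converged):
        lr["flag"] = "non-convergence"
    return {
        "full": res_full,
        "reduced": res_red,
        "lr": lr,
        "interaction": float(res_full.coef()["accuracy:evidence"]),
        "aic": res_full.aic,
        "r2": res_full.pseudo_r2(full.X),
        "coding": {"accuracy": "treatment(0=error,1=correct)",
                   "evidence": sign_toward},
    }


def fit_com_speed_model(trials: pd.DataFrame, predictor: str = "first_frame") -> dict:
    """Linear mixed model of change-of-mind latency on change trials.

    com_latency ~ accuracy * evidence + (1 | participant), ML fit
    (REML off: LR tests on fixed effects need ML).  Latency is modelled
    untransformed; its distribution is close to normal, unlike initial RTs.
    """
    com = trials[trials["n_changes"].eq(1) & trials["com_latency"].notna()]
    d = _model_frame(com, predictor)
    d["latency"] = com["com_latency"].loc[d.index].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m_full = smf.mixedlm(
            "latency ~ accuracy * evidence", d, groups=d["participant"]
        ).fit(reml=False)
        m_red = smf.mixedlm(
            "latency ~ accuracy + evidence", d, groups=d["participant"]
        ).fit(reml=False)
    lr = lr_test(m_full.llf, m_red.llf)
    if not (m_full.converged and m_red.converged):
        lr["flag"] = "non-convergence"
    return {
        "full": m_full,
        "reduced": m_red,
        "lr": lr,
        "interaction": float(m_full.params["accuracy:evidence"]),
    }


def compare_window_models(
    trials: pd.DataFrame,
    window_a: str,
    window_b: str,
    nagq: int = 10,
) -> dict:
    """Non-nested comparison of two change-probability GLMMs that differ in
    their evidence window.  Reports AIC and marginal/conditional pseudo-R^2
    per model; no p-value is attached."""
    out = {}
    for key, win in (("a", window_a), ("b", window_b)):
        res = fit_com_probability_model(trials, predictor=win, nagq=nagq)
        out[key] = {"window": win, "aic": res["aic"], "r2": res["r2"]}
    out["preferred"] = (
        out["a"]["window"] if out["a"]["aic"] < out["b"]["aic"]
        else out["b"]["window"]
    )
    return out
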