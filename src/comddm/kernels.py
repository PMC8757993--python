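"""Psychophysical reverse correlation: kernels, splits, smoothing, tests.

A psychophysical kernel is the frame-wise average of residual stimulus
evidence over trials sharing a decision outcome, time-locked to stimulus
onset, the initial response, or the change-of-mind response.  Because the
residuals are zero-mean by construction, any structure in a kernel reflects
the influence of the stimulus fluctuations on behaviour.

Sign convention: residuals are stored signed toward the *correct* side;
``sign_toward="initial"`` re-signs them toward each trial's initial choice
as a presentation/contrast transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stimuli import TaskConfig

__all__ = [
    "classify_responses",
    "response_type_groups",
    "compute_kernels",
    "median_split_com_rt",
    "smooth_kernel",
    "framewise_tests",
    "first_frame_contrast",
    "KernelEstimate",
]

LOCKS = ("stimulus_onset", "initial_response", "com_response")

RESPONSE_TYPES = ("correct", "error", "corrected_error", "spoilt_correct")


def classify_responses(trials: pd.DataFrame) -> pd.Series:
    """Derive the response type of every trial.

    correct / error: no change of mind, initial choice right / wrong;
    corrected_error: one change, wrong -> right; spoilt_correct: one change,
    right -> wrong; excluded: no initial response or more than one change.
    Inconsistent records (a change latency without a change, or a single
    change that does not flip the choice) raise.
    """
    t = trials
    no_resp = t["initial_choice"].eq("none") | t["initial_rt"].isna()
    has_lat = t["com_latency"].notna()
    if bool((has_lat & t["n_changes"].eq(0)).any()):
        raise ValueError("com_latency present on a trial with n_changes == 0")
    one = t["n_changes"].eq(1) & ~no_resp
    if bool((one & t["final_choice"].eq(t["initial_choice"])).any()):
        raise ValueError("single change of mind must flip the choice")
    init_correct = t["initial_choice"].eq(t["correct_side"])
    out = pd.Series("excluded", index=t.index, dtype=object)
    keep = ~no_resp & t["n_changes"].le(1)
    out[keep & t["n_changes"].eq(0) & init_correct] = "correct"
    out[keep & t["n_changes"].eq(0) & ~init_correct] = "error"
    out[keep & one & ~init_correct] = "corrected_error"
    out[keep & one & init_correct] = "spoilt_correct"
    return out


def response_type_groups(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """Boolean masks for the four response types (excluded trials in none)."""
    rt = classify_responses(trials)
    return {name: (rt == name).to_numpy() for name in RESPONSE_TYPES}


@dataclass
class KernelEstimate:
    """Time-locked mean residual evidence per condition.

    ``table`` is tidy: one row per (condition, time) with columns mean, se, n.
    """

    lock: str
    table: pd.DataFrame
    sign_toward: str = "correct"

    def condition(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["condition"] == name]
        return sub.sort_values("time").reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))


def _lock_frames(trials: pd.DataFrame, lock: str, config: TaskConfig) -> np.ndarray:
    """Frame index of the lock event per trial (floor snapping); NaN -> -1."""
    fd = config.frame_duration
    if lock == "stimulus_onset":
        return np.zeros(len(trials), dtype=np.int64)
    if lock == "initial_response":
        t = trials["initial_rt"].to_numpy(float)
    elif lock == "com_response":
        t = (
            trials["initial_rt"].to_numpy(float)
            + trials["com_latency"].to_numpy(float)
        )
    else:
        raise ValueError(f"unknown lock {lock!r}; expected one of {LOCKS}")
    frames = np.full(len(trials), -1, dtype=np.int64)
    ok = np.isfinite(t)
    frames[ok] = np.floor(t[ok] / fd + 1e-9).astype(np.int64)
    return frames


def _displayed_frames(trials: pd.DataFrame, config: TaskConfig, n_frames: int) -> np.ndarray:
    """Number of frames actually on screen per trial."""
    fd = config.frame_duration
    rt = trials["initial_rt"].to_numpy(float)
    shown = np.where(
        np.isfinite(rt),
        np.floor((rt + config.post_decision_window) / fd + 1e-9),
        np.floor(config.deadline / fd + 1e-9),
    ).astype(np.int64)
    return np.minimum(shown, n_frames)


def _signed_residuals(
    trials: pd.DataFrame, residuals: np.ndarray, sign_toward: str
) -> np.ndarray:
    if sign_toward == "correct":
        return residuals
    if sign_toward != "initial":
        raise ValueError("sign_toward must be 'correct' or 'initial'")
    sgn = np.where(
        trials["initial_choice"].to_numpy() == trials["correct_side"].to_numpy(),
        1.0,
        -1.0,
    )
    return residuals * sgn[:, None]


def _accumulate(
    residuals: np.ndarray,
    mask: np.ndarray,
    lock_frames: np.ndarray,
    shown: np.ndarray,
    offset: int,
    n_bins: int,
):
    """Per-bin n, sum, sum of squares for one condition."""
    n = np.zeros(n_bins)
    s = np.zeros(n_bins)
    s2 = np.zeros(n_bins)
    idx = np.flatnonzero(mask & (lock_frames >= 0))
    for i in idx:
        r = residuals[i, : shown[i]]
        b0 = offset - lock_frames[i]
        sl = slice(b0, b0 + shown[i])
        n[sl] += 1
        s[sl] += r
        s2[sl] += r * r
    return n, s, s2


def compute_kernels(
    trials: pd.DataFrame,
    residuals: np.ndarray,
    config: TaskConfig,
    lock: str = "stimulus_onset",
    groups: dict[str, np.ndarray] | None = None,
    min_trials: int = 100,
    sign_toward: str = "correct",
) -> KernelEstimate:
    """Average residual evidence per condition and signed time bin.

    Trials are pooled across participants before averaging.  For the
    response-locked and change-of-mind-locked kernels, bins backed by fewer
    than ``min_trials`` trials are dropped (noisy-estimate guard); the
    stimulus-onset lock keeps all bins.  Empty conditions are flagged with a
    warning, not fatal.
    """
    residuals = np.asarray(residuals, dtype=float)
    if len(trials) != residuals.shape[0]:
        raise ValueError("trials and residual matrix row counts differ")
    if lock not in LOCKS:
        raise ValueError(f"unknown lock {lock!r}; expected one of {LOCKS}")
    if groups is None:
        groups = response_type_groups(trials)
    n_frames = residuals.shape[1]
    lock_frames = _lock_frames(trials, lock, config)
    shown = _displayed_frames(trials, config, n_frames)
    signed = _signed_residuals(trials, residuals, sign_toward)
    offset = 0 if lock == "stimulus_onset" else n_frames
    n_bins = offset + n_frames
    times = (np.arange(n_bins) - offset) * config.frame_duration

    rows = []
    for name, mask in groups.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != len(trials):
            raise ValueError(f"group {name!r} mask length mismatch")
        if not mask.any():
            warnings.warn(f"condition {name!r} has no trials", stacklevel=2)
            continue
        n, s, s2 = _accumulate(signed, mask, lock_frames, shown, offset, n_bins)
        keep = n >= (min_trials if lock != "stimulus_onset" else 1)
        keep &= n >= 1
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s / n
            var = np.maximum(s2 / n - mean**2, 0.0) * n / np.maximum(n - 1, 1)
            se = np.sqrt(var / n)
        rows.append(
            pd.DataFrame(
                {
                    "condition": name,
                    "time": times[keep],
                    "mean": mean[keep],
                    "se": se[keep],
                    "n": n[keep].astype(int),
                }
            )
        )
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["condition", "time", "mean", "se", "n"])
    )
    return KernelEstimate(lock=lock, table=table, sign_toward=sign_toward)


def median_split_com_rt(trials: pd.DataFrame) -> pd.Series:
    """Label change-of-mind trials fast/slow by a per-participant,
    per-session median split of the change-of-mind latency.

    Latencies strictly below the cell median are "fast"; at or above it,
    "slow" (midpoint median for even counts; exact-median ties go to slow so
    splits are reproducible).  Cells with fewer than 2 change trials are
    skipped with a warning.
    """
    labels = pd.Series(pd.NA, index=trials.index, dtype=object)
    is_com = trials["com_latency"].notna() & trials["n_changes"].eq(1)
    for (p, s), cell in trials[is_com].groupby(["participant", "session"]):
        if len(cell) < 2:
            warnings.warn(
                f"participant {p} session {s}: <2 change-of-mind trials, skipped",
                stacklevel=2,
            )
            continue
        med = cell["com_latency"].median()
        labels.loc[cell.index] = np.where(
            cell["com_latency"] < med, "fast", "slow"
        )
        if (cell["com_latency"] == med).all():
            warnings.warn(
                f"participant {p} session {s}: all change latencies equal, "
                "all labelled slow",
                stacklevel=2,
            )
    return labels


def smooth_kernel(kernel: KernelEstimate, span: int = 3) -> KernelEstimate:
    """Centered moving average of the kernel means (display only).

    The window shrinks symmetrically at the edges.  Statistics are always run
    on the unsmoothed series; this transform exists for plotting parity.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be an odd integer >= 1")
    half = span // 2
    parts = []
    for cond in kernel.conditions:
        sub = kernel.condition(cond).copy()
        x = sub["mean"].to_numpy()
        sm = np.empty_like(x)
        for i in range(len(x)):
            sm[i] = x[max(0, i - half) : min(len(x), i + half + 1)].mean()
        sub["mean"] = sm
        parts.append(sub)
    table = pd.concat(parts, ignore_index=True) if parts else kernel.table.copy()
    return KernelEstimate(lock=kernel.lock, table=table, sign_toward=kernel.sign_toward)


def framewise_tests(
    trials: pd.DataFrame,
    residuals: np.ndarray,
    config: TaskConfig,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    lock: str = "stimulus_onset",
    alphas: tuple[float, ...] = (0.01, 0.05),
    sign_toward: str = "correct",
) -> pd.DataFrame:
    """Per-frame two-sample t-tests between two trial groups.

    Residual values are pooled across participants within each group; the
    tests are illustrative and deliberately uncorrected for multiple
    comparisons.  Bins with fewer than 2 trials on either side get no flag.
    Student's pooled-variance t is used.
    """
    residuals = np.asarray(residuals, dtype=float)
    lock_frames = _lock_frames(trials, lock, config)
    shown = _displayed_frames(trials, config, residuals.shape[1])
    signed = _signed_residuals(trials, residuals, sign_toward)
    offset = 0 if lock == "stimulus_onset" else residuals.shape[1]
    n_bins = offset + residuals.shape[1]
    times = (np.arange(n_bins) - offset) * config.frame_duration

    stats = {}
    for key, mask in (("a", np.asarray(mask_a, bool)), ("b", np.asarray(mask_b, bool))):
        stats[key] = _accumulate(signed, mask, lock_frames, shown, offset, n_bins)

    na, sa, sa2 = stats["a"]
    nb, sb, sb2 = stats["b"]
    ok = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma, mb = sa / na, sb / nb
        va = (sa2 - na * ma**2) / np.maximum(na - 1, 1)
        vb = (sb2 - nb * mb**2) / np.maximum(nb - 1, 1)
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / np.maximum(df, 1)
        tstat = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
    pval = np.full(n_bins, np.nan)
    pval[ok] = 2 * sps.t.sf(np.abs(tstat[ok]), df[ok])
    out = pd.DataFrame(
        {"time": times, "n_a": na.astype(int), "n_b": nb.astype(int),
         "t": np.where(ok, tstat, np.nan), "p": pval}
    )
    for a in alphas:
        out[f"sig_{a}"] = ok & (pval < a)
    return out[ok | (na + nb > 0)].reset_index(drop=True)


def first_frame_contrast(
    trials: pd.DataFrame,
    residuals: np.ndarray,
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Change-vs-no-change contrast of first-frame support for the initial
    response, within initial-accuracy class.

    Support is the frame-0 residual signed toward the trial's initial choice.
    The contrast is computed separately for initially-wrong trials
    (corrected_error minus error) and initially-correct trials
    (spoilt_correct minus correct), then combined by change-trial-count
    weighting.  The within-class definition matters: change trials are
    heavily enriched in errors, and errors carry systematically stronger
    noise selection, so a pooled change-vs-no-change difference would pick up
    that composition shift even when the first frame plays no causal role.
    Negative values mean changes of mind followed *weaker* initial-choice
    evidence.  Optional nonparametric bootstrap (resampling trials within
    each class) gives a 95% CI on the combined contrast.
    """
    rt = classify_responses(trials)
    sgn = np.where(
        trials["initial_choice"].to_numpy() == trials["correct_side"].to_numpy(),
        1.0,
        -1.0,
    )
    support = np.asarray(residuals, float)[:, 0] * sgn
    pairs = {
        "error": ("corrected_error", "error"),
        "correct": ("spoilt_correct", "correct"),
    }
    cells = {}
    out = {"by_class": {}}
    for cls, (com_t, nocom_t) in pairs.items():
        a = support[(rt == com_t).to_numpy()]
        b = support[(rt == nocom_t).to_numpy()]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"class {cls!r} too sparse for a contrast", stacklevel=2)
            continue
        d = float(a.mean() - b.mean())
        se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
        cells[cls] = (a, b)
        out["by_class"][cls] = {
            "contrast": d, "se": se, "n_change": len(a), "n_nochange": len(b)
        }
    if not cells:
        raise ValueError("no accuracy class has enough trials")
    w = np.array([out["by_class"][c]["n_change"] for c in cells], float)
    w /= w.sum()
    ds = np.array([out["by_class"][c]["contrast"] for c in cells])
    ses = np.array([out["by_class"][c]["se"] for c in cells])
    out["contrast"] = float(w @ ds)
    out["se"] = float(np.sqrt(np.sum((w * ses) ** 2)))
    if n_boot > 0:
        rng = np.random.default_rng() if rng is None else rng
        boots = np.empty(n_boot)
        for k in range(n_boot):
            acc = 0.0
            for wi, (a, b) in zip(w, cells.values()):
                ia = rng.integers(0, len(a), len(a))
                ib = rng.integers(0, len(b), len(b))
                acc += wi * (a[ia].mean() - b[ib].mean())
            boots[k] = acc
        out["ci95"] = (float(np.quantile(boots, 0.025)),
                       float(np.quantile(boots, 0.975)))
    return out
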