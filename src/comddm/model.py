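"""Extended drift-diffusion model with post-decisional accumulation and a
decaying first-frame evidence bias.

Evidence for the correct option is accumulated between absorbing bounds 0 and
B (start ~ Uniform around B/2 with range Sz).  After the first crossing,
accumulation continues for a ``timeOut`` fraction of the 1.5 s post-decision
window; re-crossing a change-of-mind threshold at distance B_CoM back from
the initial bound reverses the response.

The drift on a trial is  mu + externalVar(t) + internalVar, where
internalVar ~ N(0, eta) is fixed within a trial and externalVar is a decaying
"snapshot" of the first stimulus frame: it starts at s * firstFrame and
shrinks linearly toward zero at rate ``slope`` (the literal signed form
s*firstFrame - slope*t is available as ``ext_mode="literal"``).

Within-trial noise is the sum of a stimulus-driven component (one
N(0, theta) draw per 13.33 ms frame, truncated at 1 SD, held across that
frame's 1 ms steps) and endogenous N(0, 0.1) noise drawn fresh every step.
By default both enter through the standard Euler-Maruyama sqrt(dt) scaling;
the frame-held stimulus draw carries a per-step weight 1/sqrt(steps-in-frame)
so a frame contributes exactly the increment variance an iid per-step draw
with the same marginal would, giving a stepsize- and framerate-independent
diffusion limit (see :func:`effective_diffusion_sd`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sps

from .stimuli import TaskConfig

__all__ = [
    "ModelParams",
    "VARIANTS",
    "drift_at",
    "effective_diffusion_sd",
    "stimulus_gain",
    "simulate_experiment",
    "params_to_json",
    "params_from_json",
]

VARIANTS = ("coupled", "decoupled", "novar")


@dataclass(frozen=True)
class ModelParams:
    """Extended-DDM parameter vector.

    Field names follow the model's conventional symbols: ``B`` bound
    separation (lower bound at 0), ``Sz`` uniform starting-point range around
    B/2, ``B_CoM`` change-of-mind threshold distance back from the initial
    bound, ``timeOut`` fraction of the post-decision window with active
    accumulation, ``mu`` mean drift (evidence/s, signed toward correct),
    ``eta`` SD of internal across-trial drift variability, ``slope`` decay
    rate of the external drift component (evidence/s^2), ``s`` weight of the
    first-frame snapshot, ``theta`` SD of stimulus-driven within-trial noise,
    ``tnd``/``tndVar`` mean/SD of the non-decision time (s).
    """

    B: float
    mu: float
    Sz: float = 0.0
    B_CoM: float = 0.0
    timeOut: float = 1.0
    eta: float = 0.0
    slope: float = 0.0
    s: float = 0.0
    theta: float = 0.0
    tnd: float = 0.25
    tndVar: float = 0.0
    stepsize: float = 0.001
    endo_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("B must be positive")
        if not (0 <= self.Sz < self.B):
            raise ValueError("Sz must lie in [0, B)")
        if not (0 <= self.B_CoM <= self.B):
            raise ValueError("B_CoM must lie in [0, B]")
        if not (0 <= self.timeOut <= 1):
            raise ValueError("timeOut must lie in [0, 1]")
        if min(self.eta, self.slope, self.theta, self.tndVar) < 0:
            raise ValueError("eta, slope, theta, tndVar must be >= 0")
        if self.tnd <= 0:
            raise ValueError("tnd must be positive")
        if self.stepsize <= 0:
            raise ValueError("stepsize must be positive")

    def for_variant(self, variant: str) -> "ModelParams":
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if variant == "novar":
            return replace(self, eta=0.0, s=0.0)
        return self


_SYMBOL_KEYS = (
    "B", "Sz", "B_CoM", "timeOut", "mu", "eta", "slope", "s", "theta",
    "tnd", "tndVar",
)


def params_to_json(params: ModelParams, path=None) -> str:
    """Serialise parameters as JSON keyed by the conventional symbols."""
    d = asdict(params)
    payload = {k: d[k] for k in _SYMBOL_KEYS}
    payload["stepsize"] = params.stepsize
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def params_from_json(src) -> ModelParams:
    if isinstance(src, (str, bytes)) and str(src).lstrip().startswith("{"):
        payload = json.loads(src)
    else:
        with open(src) as fh:
            payload = json.load(fh)
    return ModelParams(**payload)


def drift_at(
    params: ModelParams,
    t: float,
    first_frame: float,
    internal_var_draw: float,
    variant: str = "coupled",
    ext_mode: str = "decay",
) -> float:
    """Instantaneous drift rate mu + externalVar(t) + internalVar.

    ``ext_mode="decay"`` (default): the snapshot decays toward zero and stops
    there, sign(ff) * max(0, s|ff| - slope*t).  ``ext_mode="literal"``
    computes s*ff - slope*t with no floor.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    p = params.for_variant(variant)
    if variant == "novar":
        ext = 0.0
    elif ext_mode == "decay":
        ext = np.sign(first_frame) * max(0.0, p.s * abs(first_frame) - p.slope * t)
    elif ext_mode == "literal":
        ext = p.s * first_frame - p.slope * t
    else:
        raise ValueError(f"unknown ext_mode {ext_mode!r}")
    return p.mu + ext + internal_var_draw


def effective_diffusion_sd(params: ModelParams) -> float:
    """Continuum diffusion SD of the within-trial noise under the default
    Euler-Maruyama scheme: sqrt(Var[truncN(0, theta, +/- theta)] + endo_sd^2).

    The truncated-normal variance comes from scipy (independent of the
    simulator); theta = 0 degenerates to the endogenous SD alone.
    """
    if params.theta == 0:
        v_stim = 0.0
    else:
        v_stim = sps.truncnorm.var(-1.0, 1.0) * params.theta**2
    return float(np.sqrt(v_stim + params.endo_noise_sd**2))


def stimulus_gain(params: ModelParams, config: TaskConfig) -> float:
    """Gain mapping a normalized stimulus residual into model noise units.

    Internally generated stimulus noise is truncN(0, theta, +/- theta) with
    SD std_tr(1) * theta.  A rendered residual (difference of two truncated
    luminance draws, normalized by the truncation box) has SD
    sqrt(2) * std_tr(k) / (2k) with k the truncation width in SDs.  The gain
    equates the two SDs, so stimulus-driven and self-generated simulations
    share the same effective diffusion (at the defaults the gain is
    sqrt(2) * theta).
    """
    std_unit = sps.truncnorm.std(-1.0, 1.0)
    k = config.truncation_sds
    sd_residual = np.sqrt(2.0) * sps.truncnorm.std(-k, k) / (2.0 * k)
    return float(params.theta * std_unit / sd_residual)


# --------------------------------------------------------------------------
# simulation core
# --------------------------------------------------------------------------


@njit(cache=True)
def _sim_core(
    z0,            # (n,) starting DV
    base_drift,    # (n,) mu + internalVar per trial
    ext_ff,        # (n,) first-frame driver (already the value entering externalVar)
    s, slope,
    ext_decay,     # bool: decaying snapshot vs literal signed form
    X,             # (n, F) per-frame stimulus noise, model units, toward correct
    frame_of_step, # (T,) frame index of each step
    w_step,        # (T,) per-step stimulus weight (1/sqrt(steps in frame); 1 in literal scheme)
    tnd,           # (n,) non-decision times
    B, Bcom, dt, endo_sd,
    n_dec_steps, n_post_steps,
    em_scheme,     # bool: sqrt(dt) noise scaling vs literal *dt
    deadline,
    seed,
):
    n = z0.shape[0]
    choice = np.zeros(n, dtype=np.int8)
    t_dec = np.full(n, np.nan)
    com = np.zeros(n, dtype=np.bool_)
    t_com = np.full(n, np.nan)
    sdt = np.sqrt(dt)
    np.random.seed(seed)
    for i in range(n):
        dv = z0[i]
        ff = ext_ff[i]
        crossed = 0
        t_cross = -1
        for t in range(n_dec_steps):
            tt = t * dt
            if ext_decay:
                e = s * abs(ff) - slope * tt
                if e < 0.0:
                    e = 0.0
                if ff < 0.0:
                    e = -e
            else:
                e = s * ff - slope * tt
            drift = base_drift[i] + e
            noise = X[i, frame_of_step[t]] * w_step[t] + endo_sd * np.random.standard_normal()
            if em_scheme:
                dv += drift * dt + noise * sdt
            else:
                dv += drift * dt + noise * dt
            if dv >= B:
                crossed = 1
                t_cross = t
                break
            if dv <= 0.0:
                crossed = -1
                t_cross = t
                break
        if crossed == 0:
            continue
        dec_time = (t_cross + 1) * dt
        if dec_time + tnd[i] > deadline + 1e-12:
            # crossing too late to register before the response deadline
            continue
        choice[i] = crossed
        t_dec[i] = dec_time
        # post-decision accumulation for timeOut * window seconds
        com_bound = B - Bcom if crossed == 1 else Bcom
        for k in range(n_post_steps):
            u = t_cross + 1 + k
            tt = u * dt
            if ext_decay:
                e = s * abs(ff) - slope * tt
                if e < 0.0:
                    e = 0.0
                if ff < 0.0:
                    e = -e
            else:
                e = s * ff - slope * tt
            drift = base_drift[i] + e
            noise = X[i, frame_of_step[u]] * w_step[u] + endo_sd * np.random.standard_normal()
            if em_scheme:
                dv += drift * dt + noise * sdt
            else:
                dv += drift * dt + noise * dt
            if (crossed == 1 and dv <= com_bound) or (crossed == -1 and dv >= com_bound):
                com[i] = True
                t_com[i] = (u + 1) * dt
                break
    return choice, t_dec, com, t_com


def _step_geometry(config: TaskConfig, dt: float):
    """Frame index and stimulus weight for every simulation step."""
    n_dec = int(round(config.deadline / dt))
    n_post_full = int(round(config.post_decision_window / dt))
    n_total = n_dec + n_post_full
    t_mid = (np.arange(n_total) + 0.5) * dt  # step midpoints avoid edge ties
    frame_of_step = np.floor(t_mid / config.frame_duration).astype(np.int64)
    counts = np.bincount(frame_of_step)
    w_step = 1.0 / np.sqrt(counts[frame_of_step])
    return n_dec, frame_of_step, w_step


def _truncated_theta_draws(rng, theta, size):
    if theta == 0:
        return np.zeros(size)
    out = rng.normal(0.0, theta, size=size)
    bad = np.abs(out) > theta
    while bad.any():
        out[bad] = rng.normal(0.0, theta, size=int(bad.sum()))
        bad = np.abs(out) > theta
    return out


def simulate_experiment(
    params: ModelParams,
    variant: str,
    config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    stimulus_residuals: np.ndarray | None = None,
    scheme: str = "em",
    ext_mode: str = "decay",
    participant: str = "sim",
    session: int = 1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a batch of trials; returns (trial table, residual matrix).

    The trial table uses the behavioural schema (participant, session,
    correct_side, initial_choice, initial_rt, n_changes, final_choice,
    com_latency, plus model-side diagnostics first_frame / dv_start).
    The residual matrix is the per-trial per-frame stimulus noise rescaled by
    theta into [-1, 1] and signed toward the correct side, i.e. exactly what
    reverse correlation consumes.

    ``stimulus_residuals`` optionally drives the model with externally
    rendered stimuli (values in [-1, 1]); the model-space noise is then
    theta * residual.  ``variant``: "coupled" uses the trial's own frame-0
    noise as the snapshot driver; "decoupled" uses a random permutation of
    those values across trials (identical marginal, independent of the
    trial's stimulus); "novar" switches all across-trial drift variability
    off (eta = s = 0).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if scheme not in ("em", "literal"):
        raise ValueError(f"unknown scheme {scheme!r}")
    p = params.for_variant(variant)
    dt = p.stepsize
    n_dec_steps, frame_of_step, w_step = _step_geometry(config, dt)
    if scheme == "literal":
        w_step = np.ones_like(w_step)
    n_frames = int(frame_of_step.max()) + 1
    n_post_steps = int(round(p.timeOut * config.post_decision_window / dt))

    if stimulus_residuals is not None:
        stimulus_residuals = np.asarray(stimulus_residuals, dtype=float)
        if stimulus_residuals.shape[0] != n_trials:
            raise ValueError("stimulus_residuals row count != n_trials")
        if stimulus_residuals.shape[1] < n_frames:
            raise ValueError(
                f"stimulus_residuals must cover {n_frames} frames"
            )
        scale = stimulus_gain(p, config)
        res_obs = stimulus_residuals[:, :n_frames]
        X = scale * res_obs
    else:
        X = _truncated_theta_draws(rng, p.theta, (n_trials, n_frames))
        res_obs = X / p.theta if p.theta > 0 else X

    z0 = p.B / 2.0 + (rng.uniform(-0.5, 0.5, n_trials) * p.Sz if p.Sz > 0
                      else np.zeros(n_trials))
    internal = rng.normal(0.0, p.eta, n_trials) if p.eta > 0 else np.zeros(n_trials)
    base_drift = p.mu + internal

    ff = X[:, 0].copy()
    if variant == "decoupled":
        ext_ff = ff[rng.permutation(n_trials)]
    else:
        ext_ff = ff

    tnd = rng.normal(p.tnd, p.tndVar, n_trials) if p.tndVar > 0 else np.full(
        n_trials, p.tnd
    )
    bad = tnd < 0
    while bad.any():
        tnd[bad] = rng.normal(p.tnd, p.tndVar, int(bad.sum()))
        bad = tnd < 0

    seed = int(rng.integers(0, 2**31 - 1))
    choice, t_dec, com, t_com = _sim_core(
        z0, base_drift, ext_ff, p.s, p.slope, ext_mode == "decay",
        X, frame_of_step, w_step, tnd,
        p.B, p.B_CoM, dt, p.endo_noise_sd,
        n_dec_steps, n_post_steps, scheme == "em", config.deadline, seed,
    )

    correct_right = rng.random(n_trials) < 0.5
    correct_side = np.where(correct_right, "right", "left")
    other_side = np.where(correct_right, "left", "right")
    responded = choice != 0
    initial_correct = choice == 1
    initial_choice = np.where(
        responded, np.where(initial_correct, correct_side, other_side), "none"
    )
    final_choice = initial_choice.copy()
    flip = responded & com
    final_choice[flip & initial_correct] = other_side[flip & initial_correct]
    final_choice[flip & ~initial_correct] = correct_side[flip & ~initial_correct]

    initial_rt = np.where(responded, t_dec + tnd, np.nan)
    com_latency = np.where(com, t_com - t_dec, np.nan)

    trials = pd.DataFrame(
        {
            "participant": participant,
            "session": session,
            "trial": np.arange(n_trials),
            "correct_side": correct_side,
            "initial_choice": initial_choice,
            "initial_rt": initial_rt,
            "n_changes": com.astype(int),
            "final_choice": final_choice,
            "com_latency": com_latency,
            "first_frame": res_obs[:, 0],
            "dv_start": z0,
        }
    )
    return trials, res_obs
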