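"""Synthetic statokinesigram cohorts with planted quiet/unquiet structure.

The generator produces cohorts whose only class difference is the stationary
occupancy of a latent "unquiet" regime, so every downstream claim (mixture
separation, occupancy recovery, block-vs-global discrimination) can be tested
against known ground truth.

Generative model, per trajectory:

* a two-state Markov chain over consecutive ``block_grain_s`` windows selects
  the quiet (QB) / unquiet (UB) regime; the transition matrix is
  ``T = persistence * I + (1 - persistence) * 1 pi^T`` so the stationary UB
  probability equals the configured occupancy exactly;
* within a regime, each sway axis follows an exact-discretized
  Ornstein-Uhlenbeck (mean-reverting AR(1)) process around a slowly moving
  centre (itself a slow OU process modelling postural drift), evaluated
  directly at the irregular native timestamps; the UB regime scales the sway
  innovations by an amplitude factor (and optionally adds an absolute-scale
  episode component and extra centre drift);
* each subject carries a class-independent log-normal baseline amplitude
  multiplier, emulating the large between-individual variability of sway
  magnitude in elderly cohorts;
* timestamps sit on a jittered native grid (uniform jitter up to
  ``jitter_frac`` of the native period), emulating the variable acquisition
  rate of consumer force platforms;
* the eyes-closed condition inflates both regimes' amplitudes by a fixed
  factor, reflecting the larger sway without visual stabilisation.

The emitted ground-truth regime tracks are for validation only; they never
feed the analysis pipeline.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .cop_data import Cohort, Condition, Label, RawTrajectory, SubjectRecord
from .exceptions import ValidationError


@dataclasses.dataclass
class SimConfig:
    """Cohort and sway-dynamics parameters.

    Defaults emulate the study conditions: 126 community-dwelling elderly
    subjects (18 fallers), 25-s recordings per condition at an irregular
    native rate, and unquiet-regime occupancies of 0.37 (fallers) versus
    0.10 (non-fallers).
    """

    n_fallers: int = 18
    n_nonfallers: int = 108
    duration_s: float = 25.0
    #: native acquisition rate (Hz); consumer boards report 30-40 Hz unevenly
    native_rate_hz: float = 34.0
    #: timestamp jitter as a fraction of the native period (< 0.5 keeps order)
    jitter_frac: float = 0.4
    #: regime dwell granularity (s)
    block_grain_s: float = 2.0
    p_ub_faller: float = 0.37
    p_ub_nonfaller: float = 0.10
    #: self-transition tendency of the regime chain
    persistence: float = 0.7
    #: OU mean-reversion rate (1/s)
    mean_reversion_rate: float = 1.5
    #: quiet-regime innovation scale per axis (cm / sqrt(s))
    quiet_sd_x: float = 0.25
    quiet_sd_y: float = 0.40
    #: diffusion scale of the slowly moving sway centre (cm / sqrt(s))
    drift_sd: float = 0.06
    #: relaxation timescale of the sway centre (s); keeps paths bounded and
    #: centre velocity low, so drift shows in position spread, not speed
    centre_timescale_s: float = 50.0
    #: multiplier (>= 1) on the baseline innovation scale in the UB regime
    ub_amplitude: float = 4.0
    #: additive innovation of UB episodes on the ML axis (cm / sqrt(s));
    #: an absolute scale — a weight shift or balance correction displaces the
    #: CoP by a magnitude unrelated to the subject's baseline tremor.  The AP
    #: axis gets this scaled by quiet_sd_y / quiet_sd_x
    ub_sd: float = 0.0
    #: multiplier (>= 1) on the centre diffusion in the UB regime
    ub_drift_mult: float = 1.0
    #: sd (log scale) of the per-window intensity jitter of UB episodes
    ub_amp_jitter_sd: float = 0.0
    #: amplitude inflation for the eyes-closed condition (both regimes)
    ec_inflation: float = 1.3
    #: sd (log scale) of the per-subject baseline amplitude multiplier;
    #: class-independent, so classes still differ only in UB occupancy
    subject_amp_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fallers < 1 or self.n_nonfallers < 1:
            raise ValidationError("need at least one subject per class")
        for name in ("p_ub_faller", "p_ub_nonfaller"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.ub_amplitude < 1.0:
            raise ValidationError("ub_amplitude must be >= 1")
        if self.ub_drift_mult < 1.0:
            raise ValidationError("ub_drift_mult must be >= 1")
        if self.ub_sd < 0.0:
            raise ValidationError("ub_sd must be non-negative")
        if not 0.0 <= self.persistence < 1.0:
            raise ValidationError("persistence must be in [0, 1)")
        if not 0.0 <= self.jitter_frac < 0.5:
            raise ValidationError("jitter_frac must be in [0, 0.5)")
        if self.duration_s <= 0 or self.native_rate_hz <= 0:
            raise ValidationError("duration and native rate must be positive")

    def p_ub(self, label: Label) -> float:
        return self.p_ub_faller if Label(label) is Label.FALLER else self.p_ub_nonfaller


def _simulate_regime_chain(
    n_windows: int, p_ub: float, persistence: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean UB indicator per window; stationary P(UB) = p_ub exactly."""
    states = np.empty(n_windows, dtype=bool)
    states[0] = rng.random() < p_ub
    for k in range(1, n_windows):
        if rng.random() < persistence:
            states[k] = states[k - 1]
        else:
            states[k] = rng.random() < p_ub
    return states


def _jittered_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    period = 1.0 / config.native_rate_hz
    n = int(math.floor(config.duration_s * config.native_rate_hz)) + 1
    base = np.arange(n) * period
    jitter = rng.uniform(-config.jitter_frac, config.jitter_frac, size=n) * period
    jitter[0] = abs(jitter[0])  # keep t_0 >= 0
    return base + jitter


def _ou_path(
    times: np.ndarray,
    sd_step: np.ndarray,
    drift_mult: np.ndarray,
    drift_sd: float,
    theta: float,
    theta_c: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact OU discretization around a slowly moving OU centre.

    The fast process (rate ``theta``) models sway proper; the centre is a
    second, slow OU process (rate ``theta_c``) modelling postural drift.
    ``sd_step[k]`` is the innovation scale (cm/sqrt(s)) of the interval
    ending at sample k; ``drift_mult[k]`` scales the centre diffusion there.
    """
    n = len(times)
    dt = np.diff(times)
    a = np.exp(-theta * dt)
    ac = np.exp(-theta_c * dt)
    innov_scale = np.sqrt((1.0 - a * a) / (2.0 * theta))
    drift_scale = drift_sd * np.sqrt((1.0 - ac * ac) / (2.0 * theta_c))
    eps = rng.standard_normal(n - 1)
    eta = rng.standard_normal(n - 1)
    x = np.empty(n)
    x[0] = 0.0
    c = 0.0
    for k in range(1, n):
        x[k] = (
            c
            + (x[k - 1] - c) * a[k - 1]
            + sd_step[k] * innov_scale[k - 1] * eps[k - 1]
        )
        c = c * ac[k - 1] + drift_mult[k] * drift_scale[k - 1] * eta[k - 1]
    return x


def simulate_trajectory(
    label: Label,
    condition: Condition,
    config: SimConfig,
    seed_or_rng,
    subject_amp: Optional[float] = None,
) -> Tuple[RawTrajectory, np.ndarray]:
    """One irregularly sampled trajectory plus its ground-truth regime track.

    ``subject_amp`` is the subject's baseline amplitude multiplier; when None
    a fresh log-normal multiplier is drawn (``sd = config.subject_amp_sd`` on
    the log scale).  Returns ``(trajectory, ub_windows)`` where ``ub_windows``
    is the boolean UB indicator of each consecutive ``block_grain_s`` window.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    label = Label(label)
    condition = Condition(condition)
    if subject_amp is None:
        subject_amp = float(np.exp(config.subject_amp_sd * rng.standard_normal()))
    times = _jittered_times(config, rng)
    n_windows = int(math.ceil(config.duration_s / config.block_grain_s))
    states = _simulate_regime_chain(
        n_windows, config.p_ub(label), config.persistence, rng
    )
    window_idx = np.clip(
        (np.maximum(times, 0.0) / config.block_grain_s).astype(int), 0, n_windows - 1
    )
    jitter = np.exp(config.ub_amp_jitter_sd * rng.standard_normal(n_windows))
    # additive UB innovation: baseline sway (subject-scaled) plus an
    # absolute-scale episode component, combined in quadrature
    ub_add = np.where(states, config.ub_sd * jitter, 0.0)[window_idx]
    mult = np.where(states, config.ub_amplitude, 1.0)[window_idx]
    drift_mult = np.where(states, config.ub_drift_mult, 1.0)[window_idx]
    axis_ratio = config.quiet_sd_y / config.quiet_sd_x
    base_x = subject_amp * config.quiet_sd_x * mult
    base_y = subject_amp * config.quiet_sd_y * mult
    sd_step_x = np.sqrt(base_x**2 + ub_add**2)
    sd_step_y = np.sqrt(base_y**2 + (axis_ratio * ub_add) ** 2)
    cond_scale = config.ec_inflation if condition is Condition.EC else 1.0
    sd_step_x = cond_scale * sd_step_x
    sd_step_y = cond_scale * sd_step_y
    drift_mult = cond_scale * drift_mult
    theta = config.mean_reversion_rate
    theta_c = 1.0 / config.centre_timescale_s
    drift_sd = subject_amp * config.drift_sd
    x = _ou_path(times, sd_step_x, drift_mult, drift_sd, theta, theta_c, rng)
    y = _ou_path(times, sd_step_y, drift_mult, drift_sd, theta, theta_c, rng)
    return RawTrajectory(times=times, x=x, y=y, condition=condition), states


def simulate_cohort(config: SimConfig) -> Tuple[Cohort, pd.DataFrame]:
    """Full cohort (both conditions per subject) plus ground-truth tracks.

    Per-subject random streams are spawned from ``config.seed`` so the cohort
    is bit-reproducible.  The ground-truth frame has columns
    ``subject_id, condition, window_start_s, state`` with state in
    {"QB", "UB"}.
    """
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_fallers + config.n_nonfallers
    children = ss.spawn(n_total)
    subjects: List[SubjectRecord] = []
    truth_rows = []
    specs = [(Label.FALLER, i, f"F{i + 1:03d}") for i in range(config.n_fallers)] + [
        (Label.NON_FALLER, i, f"N{i + 1:03d}") for i in range(config.n_nonfallers)
    ]
    for (label, _, sid), child in zip(specs, children):
        rng = np.random.default_rng(child)
        amp = float(np.exp(config.subject_amp_sd * rng.standard_normal()))
        trajs = {}
        for cond in (Condition.EO, Condition.EC):
            traj, states = simulate_trajectory(
                label, cond, config, rng, subject_amp=amp
            )
            trajs[cond] = traj
            for w, ub in enumerate(states):
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "condition": cond.value,
                        "window_start_s": w * config.block_grain_s,
                        "state": "UB" if ub else "QB",
                    }
                )
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                label=label,
                eo=trajs[Condition.EO],
                ec=trajs[Condition.EC],
            )
        )
    truth = pd.DataFrame(
        truth_rows, columns=["subject_id", "condition", "window_start_s", "state"]
    )
    return Cohort(subjects), truth


def null_config(base: Optional[SimConfig] = None, **overrides) -> SimConfig:
    """Config with no class difference: equal occupancies, unit amplitude."""
    base = base if base is not None else SimConfig()
    fields = dataclasses.asdict(base)
    fields.update(
        p_ub_faller=base.p_ub_nonfaller,
        ub_amplitude=1.0,
        ub_sd=0.0,
        ub_drift_mult=1.0,
        ub_amp_jitter_sd=0.0,
    )
    fields.update(overrides)
    return SimConfig(**fields)
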