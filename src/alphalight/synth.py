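"""Seeded synthetic sessions for the blue-enriched-light attention study.

The generator emulates the study design that the inference stages assume:
24 participants each tested under low / medium / high blue-enriched light
(counterbalanced order, 72 sessions), performing a four-patch random-dot
motion detection task of 336 trials per session. Each session yields

* a trial schedule balanced within 48-trial blocks over 24 trial types
  (3 incoherent-motion delays x 4 quadrants x 2 coherent directions),
* per-trial behaviour (response times coupled to the realised pre-target
  alpha envelope, with a light-dependent coupling slope and a
  left-hemifield-specific benefit of brighter light), and
* raw-like epoched EEG: 1/f background noise on a 64-channel 10-10 cap
  plus an 8-13 Hz oscillation over parieto-occipital channels whose
  amplitude scales with light (more steeply over the right hemisphere),
  drifts with time-on-task, and desynchronises contralaterally to the
  target from 50 ms after target onset.

The realised per-trial envelope values that drive behaviour are recorded
in the trial table (``log_alpha_true_*`` columns) so that recovery tests
have ground truth without touching the EEG path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .containers import EpochSet, LIGHT_LEVELS, QUADRANTS
from .montage import CANDIDATES, CHANNELS_64, contralateral

TWO_OVER_PI = 2.0 / math.pi


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleConfig:
    """Trial-schedule parameters of the random-dot motion task.

    Defaults give the study design: 3 delays x 4 quadrants x 2 directions
    x 2 repetitions = 48 trials per block, 7 blocks = 336 trials.
    """

    delays_s: tuple[float, ...] = (1.8, 2.8, 3.8)
    quadrants: tuple[str, ...] = QUADRANTS
    directions: tuple[str, ...] = ("up", "down")
    reps_per_block: int = 2
    n_blocks: int = 7

    def __post_init__(self) -> None:
        if len(self.delays_s) != 3:
            raise ValueError("exactly 3 incoherent-motion delays required")
        if len(self.quadrants) != 4:
            raise ValueError("exactly 4 target quadrants required")
        if len(self.directions) != 2:
            raise ValueError("exactly 2 coherent directions required")
        if int(self.reps_per_block) != self.reps_per_block or self.reps_per_block < 1:
            raise ValueError("reps_per_block must be a positive integer")
        if int(self.n_blocks) != self.n_blocks or self.n_blocks < 1:
            raise ValueError("n_blocks must be a positive integer")

    @property
    def n_trial_types(self) -> int:
        return len(self.delays_s) * len(self.quadrants) * len(self.directions)

    @property
    def block_length(self) -> int:
        return self.n_trial_types * self.reps_per_block

    @property
    def n_trials(self) -> int:
        return self.block_length * self.n_blocks


@dataclass(frozen=True)
class GeneratorParams:
    """Generative parameters; defaults are calibrated to the study's
    reported condition structure.

    Alpha side: the parieto-occipital envelope has baseline oscillation
    amplitude ``alpha_base`` (uV); light multiplies it by hemisphere- and
    dose-specific gains whose logs mirror the reported high/medium vs low
    contrasts on log alpha (right: 0, .04, .07; left: 0, .01, .03). Trial
    amplitudes carry lognormal noise (a bilaterally shared component plus
    a hemisphere-specific one, so left and right alpha co-fluctuate), a
    time-on-task drift, and stable per-participant (and per-hemisphere)
    offsets.

    Behaviour side: left-hemifield response times average 499 / 497 / 490 ms
    under low / medium / high light while right-hemifield times stay flat;
    RT is coupled to the session-demeaned realised log envelope with a
    slope (ms per log unit) that weakens as light gets brighter; a
    hemifield-specific time-on-task drift makes right-hemifield responses
    slower early in the session, an advantage that wanes.
    """

    # alpha envelope
    alpha_base: float = 10.0
    light_gain_right: tuple[float, float, float] = (
        1.0, math.exp(0.04), math.exp(0.07))
    light_gain_left: tuple[float, float, float] = (
        1.0, math.exp(0.01), math.exp(0.03))
    desync_depth: float = 0.3
    tot_alpha_slope: float = 0.2
    alpha_trial_sigma: float = 0.25
    alpha_shared_sigma: float = 0.3
    alpha_subject_sd: float = 0.15
    alpha_hemisphere_sd: float = 0.05
    # behaviour
    rt_intercept_ms: float = 499.0
    hemifield_offset_ms: float = 0.0
    light_left_rt_effect_ms: tuple[float, float, float] = (0.0, -2.0, -9.0)
    alpha_rt_slope_ms: tuple[float, float, float] = (8.0, 5.2, 3.0)
    tot_rt_interaction_ms: float = 12.0
    subject_intercept_sd_ms: float = 5.0
    subject_hemifield_sd_ms: float = 3.0
    subject_alpha_slope_sd_ms: float = 1.5
    resid_sd_ms: float = 50.0
    miss_rate: float = 0.026
    # EEG plumbing
    artifact_rate: float = 0.03
    artifact_amplitude_uv: float = 150.0
    noise_sd_uv: float = 5.0
    noise_exponent: float = 1.0
    true_electrodes_left: tuple[str, ...] = ("P5", "P7", "PO7", "O1")
    true_electrodes_right: tuple[str, ...] = ("P6", "P8", "PO8", "O2")
    candidate_weight: float = 0.5
    fs_hz: float = 500.0
    t_start_ms: float = -700.0
    t_stop_ms: float = 1200.0

    def __post_init__(self) -> None:
        for name in ("alpha_trial_sigma", "alpha_shared_sigma",
                     "alpha_subject_sd",
                     "alpha_hemisphere_sd", "subject_intercept_sd_ms",
                     "subject_hemifield_sd_ms", "subject_alpha_slope_sd_ms",
                     "resid_sd_ms", "noise_sd_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(g <= 0 for g in self.light_gain_right + self.light_gain_left):
            raise ValueError("light gains must be positive")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must lie in [0, 1]")
        if not 0.0 <= self.desync_depth <= 1.0:
            raise ValueError("desync_depth must lie in [0, 1]")

    def light_index(self, light: str) -> int:
        return LIGHT_LEVELS.index(light)


@dataclass(frozen=True)
class SessionSpec:
    """One participant x light-condition testing session."""

    participant_id: str
    light_condition: str
    condition_order: int
    seed: int
    subject_seed: int

    def __post_init__(self) -> None:
        if self.light_condition not in LIGHT_LEVELS:
            raise ValueError(f"unknown light level {self.light_condition!r}")

    @property
    def session_id(self) -> str:
        return f"{self.participant_id}-{self.light_condition}"


#: The 6 counterbalanced orders of (low, medium, high).
CONDITION_ORDERS = tuple(permutations(LIGHT_LEVELS))


def build_study(n_participants: int = 24, seed: int = 0) -> list[SessionSpec]:
    """Session specs for a counterbalanced within-subject study.

    Each participant completes one session per light level; participants
    are assigned to the 6 condition orders as evenly as divisibility
    allows (4 per order at the default n=24).
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants * len(LIGHT_LEVELS) + n_participants)
    specs = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        order_idx = p % len(CONDITION_ORDERS)
        subject_seed = int(children[n_participants * len(LIGHT_LEVELS) + p]
                           .generate_state(1)[0] % (2 ** 31))
        for c, light in enumerate(LIGHT_LEVELS):
            sess_seed = int(children[p * len(LIGHT_LEVELS) + c]
                            .generate_state(1)[0] % (2 ** 31))
            specs.append(SessionSpec(
                participant_id=pid,
                light_condition=light,
                condition_order=order_idx + 1,
                seed=sess_seed,
                subject_seed=subject_seed,
            ))
    return specs


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

_QUADRANT_HEMI = {"UL": "left", "LL": "left", "UR": "right", "LR": "right"}
_QUADRANT_VERT = {"UL": "upper", "UR": "upper", "LL": "lower", "LR": "lower"}


def make_schedule(config: ScheduleConfig, seed: int) -> pd.DataFrame:
    """Pseudorandom trial order with exact balance inside every block.

    Every consecutive block of ``block_length`` trials contains each of
    the ``n_trial_types`` delay x quadrant x direction combinations
    exactly ``reps_per_block`` times; order within a block is a seeded
    permutation.
    """
    rng = np.random.default_rng(seed)
    types = list(product(config.delays_s, config.quadrants,
                         config.directions))
    block = types * config.reps_per_block
    rows = []
    for _ in range(config.n_blocks):
        idx = rng.permutation(len(block))
        rows.extend(block[i] for i in idx)
    df = pd.DataFrame(rows, columns=["delay_s", "quadrant", "direction"])
    df.insert(0, "trial_number", np.arange(1, len(df) + 1))
    df["hemifield"] = df["quadrant"].map(_QUADRANT_HEMI)
    df["vertical_field"] = df["quadrant"].map(_QUADRANT_VERT)
    return df


def dot_motion_speed(displacement_deg: float, frame_rate: float) -> float:
    """Coherent-dot speed (deg/s) from per-frame displacement and frame rate."""
    if displacement_deg < 0 or frame_rate < 0:
        raise ValueError("displacement and frame rate must be non-negative")
    return displacement_deg * frame_rate


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def _desync_profile(times_s: np.ndarray, depth: float,
                    onset_s: float = 0.05, offset_s: float = 0.6,
                    ramp_s: float = 0.1) -> np.ndarray:
    """Raised-cosine amplitude drop from ``onset`` to ``offset`` seconds."""
    prof = np.ones_like(times_s)
    t = times_s
    down = (t >= onset_s) & (t < onset_s + ramp_s)
    prof[down] = 1.0 - depth * 0.5 * (
        1 - np.cos(np.pi * (t[down] - onset_s) / ramp_s))
    flat = (t >= onset_s + ramp_s) & (t < offset_s - ramp_s)
    prof[flat] = 1.0 - depth
    up = (t >= offset_s - ramp_s) & (t < offset_s)
    prof[up] = 1.0 - depth * 0.5 * (
        1 + np.cos(np.pi * (t[up] - (offset_s - ramp_s)) / ramp_s))
    return prof


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, fs: float, exponent: float,
                sd: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, scaled to the requested RMS."""
    if sd == 0:
        return np.zeros(shape + (n_samples,), dtype=np.float32)
    # draw the spectrum directly: circular stationary Gaussian noise
    n_freq = n_samples // 2 + 1
    draws = rng.standard_normal(shape + (n_freq, 2))
    spec = draws.view(np.complex128)[..., 0]
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= gain
    noise = sp_fft.irfft(spec.astype(np.complex64), n=n_samples, axis=-1)
    rms = noise.std()
    if rms > 0:
        noise *= np.float32(sd / rms)
    return noise


def _subject_effects(params: GeneratorParams, subject_seed: int) -> dict:
    """Participant-level random effects, identical across the participant's
    sessions (same subject seed -> same draws)."""
    rng = np.random.default_rng(subject_seed)
    return {
        "rt_intercept": rng.normal(0.0, params.subject_intercept_sd_ms),
        "rt_hemifield": rng.normal(0.0, params.subject_hemifield_sd_ms),
        "rt_alpha_slope": rng.normal(0.0, params.subject_alpha_slope_sd_ms),
        "alpha_intercept": rng.normal(0.0, params.alpha_subject_sd),
        "alpha_hemi_left": rng.normal(0.0, params.alpha_hemisphere_sd),
        "alpha_hemi_right": rng.normal(0.0, params.alpha_hemisphere_sd),
    }


def simulate_session(spec: SessionSpec, params: GeneratorParams,
                     schedule: pd.DataFrame, *, eeg: bool = True,
                     channels: list[str] | None = None,
                     ) -> tuple[EpochSet | None, pd.DataFrame]:
    """Simulate one session: behaviour always, epoched EEG optionally.

    With ``eeg=False`` only the trial table is produced; all behavioural
    draws come from a random stream separate from the EEG noise stream,
    so the table is identical between the two modes.

    The trial table carries ground truth for recovery tests:
    ``log_alpha_true_left/right/pooled`` (log of the expected rectified
    envelope in uV at a weight-1.0 electrode) and ``alpha_dev`` (the
    session-demeaned pooled log envelope that response times were
    coupled to), plus the ``artifact_injected`` flag.
    """
    required = {"trial_number", "delay_s", "quadrant", "hemifield",
                "vertical_field", "direction"}
    if not required.issubset(schedule.columns):
        raise ValueError("schedule is missing required columns")
    n = len(schedule)
    li = params.light_index(spec.light_condition)
    ss = np.random.SeedSequence(spec.seed)
    rng_beh, rng_eeg = (np.random.default_rng(c) for c in ss.spawn(2))
    subj = _subject_effects(params, spec.subject_seed)

    u = (schedule["trial_number"].to_numpy(float) - 1.0) / max(n - 1, 1)
    drift = params.tot_alpha_slope * (u - 0.5)
    # a shared trial-level fluctuation couples the two hemispheres
    # (posterior alpha co-varies bilaterally trial to trial)
    eps_shared = rng_beh.normal(0.0, params.alpha_shared_sigma, n)
    eps_left = eps_shared + rng_beh.normal(0.0, params.alpha_trial_sigma, n)
    eps_right = eps_shared + rng_beh.normal(0.0, params.alpha_trial_sigma,
                                            n)

    # realised oscillation amplitude per trial and hemisphere (uV)
    amp = {}
    gains = {"left": params.light_gain_left, "right": params.light_gain_right}
    hemi_off = {"left": subj["alpha_hemi_left"],
                "right": subj["alpha_hemi_right"]}
    eps = {"left": eps_left, "right": eps_right}
    for hemi in ("left", "right"):
        amp[hemi] = (params.alpha_base * gains[hemi][li]
                     * np.exp(subj["alpha_intercept"] + hemi_off[hemi]
                              + drift + eps[hemi]))

    env = {h: TWO_OVER_PI * amp[h] for h in ("left", "right")}
    log_pooled = np.log(0.5 * (env["left"] + env["right"]))
    alpha_dev = log_pooled - log_pooled.mean()

    is_right = (schedule["hemifield"] == "right").to_numpy()
    is_left = ~is_right
    rt = (params.rt_intercept_ms + subj["rt_intercept"]
          + is_right * (params.hemifield_offset_ms + subj["rt_hemifield"]
                        + params.tot_rt_interaction_ms * (0.5 - u))
          + is_left * params.light_left_rt_effect_ms[li]
          + (params.alpha_rt_slope_ms[li] + subj["rt_alpha_slope"]) * alpha_dev
          + rng_beh.normal(0.0, params.resid_sd_ms, n))

    responded = rng_beh.random(n) >= params.miss_rate
    artifact = rng_beh.random(n) < params.artifact_rate

    trials = schedule.copy()
    trials.insert(0, "session_id", spec.session_id)
    trials.insert(1, "participant_id", spec.participant_id)
    trials.insert(2, "condition_order", spec.condition_order)
    trials.insert(3, "light_condition", spec.light_condition)
    trials["responded"] = responded
    trials["rt_ms"] = np.where(responded, rt, np.nan)
    trials["log_alpha_true_left"] = np.log(env["left"])
    trials["log_alpha_true_right"] = np.log(env["right"])
    trials["log_alpha_true_pooled"] = log_pooled
    trials["alpha_dev"] = alpha_dev
    trials["artifact_injected"] = artifact

    if not eeg:
        return None, trials

    labels = list(channels) if channels is not None else list(CHANNELS_64)
    for hemi in ("left", "right"):
        pool = (params.true_electrodes_left if hemi == "left"
                else params.true_electrodes_right)
        for lab in pool:
            if lab not in labels:
                raise ValueError(f"true electrode {lab} not in channel set")
    n_samples = int(round((params.t_stop_ms - params.t_start_ms)
                          / 1000.0 * params.fs_hz))
    times_s = (params.t_start_ms / 1000.0
               + np.arange(n_samples) / params.fs_hz)

    volts = _pink_noise(rng_eeg, (n, len(labels)), n_samples,
                        params.fs_hz, params.noise_exponent,
                        params.noise_sd_uv)

    freq = rng_eeg.uniform(9.0, 11.0, n)
    phase = rng_eeg.uniform(0.0, 2.0 * np.pi, n)
    carrier = np.sin(2.0 * np.pi * freq[:, None] * times_s[None, :]
                     + phase[:, None]).astype(np.float32)
    desync = _desync_profile(times_s, params.desync_depth).astype(np.float32)

    osc = {}
    for hemi in ("left", "right"):
        wave = amp[hemi].astype(np.float32)[:, None] * carrier
        # suppress the hemisphere contralateral to the target
        contra_rows = (schedule["hemifield"].map(contralateral) == hemi
                       ).to_numpy()
        wave[contra_rows] *= desync[None, :]
        osc[hemi] = wave

    weights = _topography_weights(labels, params)
    for ci, lab in enumerate(labels):
        w, hemi = weights[ci]
        if w > 0:
            volts[:, ci, :] += w * osc[hemi]

    epochs = EpochSet(voltages=volts, fs=params.fs_hz,
                      t_start_ms=params.t_start_ms, channel_labels=labels)
    if artifact.any():
        epochs, _ = _inject_at(epochs, np.flatnonzero(artifact),
                               params.artifact_amplitude_uv, rng_eeg)
    return epochs, trials


def _topography_weights(labels: list[str], params: GeneratorParams
                        ) -> list[tuple[float, str]]:
    """Projection weight and source hemisphere per channel: 1.0 on the
    'true' electrodes, ``candidate_weight`` on remaining candidates,
    0 elsewhere."""
    out = []
    true_set = {"left": set(params.true_electrodes_left),
                "right": set(params.true_electrodes_right)}
    for lab in labels:
        w, hemi = 0.0, "left"
        for h in ("left", "right"):
            if lab in true_set[h]:
                w, hemi = 1.0, h
            elif lab in CANDIDATES[h]:
                w, hemi = params.candidate_weight, h
        out.append((w, hemi))
    return out


def _inject_at(epochs: EpochSet, idx: np.ndarray, amplitude_uv: float,
               rng: np.random.Generator) -> tuple[EpochSet, np.ndarray]:
    """Add a >amplitude transient on one channel of each listed trial,
    inside -480..-120 ms (clear of both target onset and the -100..0 ms
    baseline window)."""
    out = epochs.copy()
    times = out.times_ms
    width_ms = 20.0
    for i in idx:
        ch = rng.integers(0, len(out.channel_labels))
        t0 = rng.uniform(-480.0, -120.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        bump = (1.05 * amplitude_uv * sign
                * np.exp(-0.5 * ((times - t0) / width_ms) ** 2))
        out.voltages[i, ch, :] += bump.astype(out.voltages.dtype)
    return out, np.asarray(idx, dtype=int)


def inject_artifacts(epochs: EpochSet, rate: float, amplitude_uv: float,
                     seed: int) -> tuple[EpochSet, np.ndarray]:
    """Contaminate a seeded ~``rate`` fraction of trials with a voltage
    transient exceeding ``amplitude_uv`` in the pre-target interval.

    Returns the contaminated EpochSet and the affected trial indices.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if amplitude_uv <= 100.0:
        raise ValueError("amplitude must exceed the 100 uV screen, "
                         "otherwise the contamination is undetectable")
    rng = np.random.default_rng(seed)
    mask = rng.random(epochs.n_trials) < rate
    if not mask.any():
        return epochs.copy(), np.array([], dtype=int)
    return _inject_at(epochs, np.flatnonzero(mask), amplitude_uv, rng)
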