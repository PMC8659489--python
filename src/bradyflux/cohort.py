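"""Synthetic paired pre-/post-medication wrist-accelerometer cohorts.

Emulates the recording design of a naturalistic levodopa wearing-off
study: each subject wears a single wrist tri-axial accelerometer for one
pre-medication (OFF) and one post-medication (ON) session of unconstrained
home activity.  The generated signal is

    gravity (slowly rotating 9.81 m/s^2 vector)
    + movement bouts (semi-Markov rest/active alternation; active bouts
      are 0.5-3 Hz band-limited oscillations under a blockwise amplitude
      envelope)
    + optional 4-6 Hz rest tremor, optional ON-state dyskinetic component
    + white sensor noise.

The discriminative medication effect is placed on the *within-window
variability* of the movement amplitude, not on its energy: the ON-state
envelope spends part of its time in deeper amplitude dips, with the
high-level dwell fraction adjusted so that the envelope's mean square
(hence RMS and band power) and its ceiling (hence the maximum) are
preserved, while the coefficient of variation rises.  A separate
``bradykinesia_gain`` damps the overall OFF-state amplitude.

All state asymmetries scale continuously with ``medication_effect``; at
``medication_effect = 0`` the OFF and ON sessions are draws from exactly
the same distribution (and are bit-identical when generated from the same
session seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy.optimize import brentq

GRAVITY = 9.81  # m/s^2
ENVELOPE_BLOCK_S = 8.0  # envelope piecewise-constant block length
ENVELOPE_RAMP_S = 3.0  # smoothing of envelope transitions (keeps the
                       # amplitude-modulation spectrum below the 0.3 Hz
                       # band edge of the spectral features)
BASE_DIP_DEPTH = 0.5  # OFF-state envelope dip depth (fraction of ceiling)
BASE_DIP_FRACTION = 0.5  # OFF-state probability of a dipped block
SESSION_AMP_SD = 0.0  # log-sd of per-session global amplitude factor
                      # (same-day sessions, same device and placement)
BOUT_AMP_SD = 0.35  # log-sd of per-bout intensity (activity heterogeneity)
REST_AMP_FRACTION = 0.06  # micro-movement amplitude during rest bouts
SPIKE_RATE_HZ = 25.0  # contact transients per second during activity
SPIKE_AMP_FACTOR = 8.0  # spike peak relative to the bout amplitude
SPIKE_HALF_WIDTH_S = 0.0075  # half-width of a contact transient

State = Literal["pre", "post"]


class InvalidConfigError(ValueError):
    """Raised for non-physical simulation settings."""


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level settings; defaults mirror the study design
    (20 subjects, paired ~60 min sessions at 200 Hz)."""

    n_subjects: int = 20
    session_minutes: float = 60.0
    fs: float = 200.0
    bout_mean_active_s: float = 30.0
    bout_mean_rest_s: float = 20.0
    medication_effect: float = 1.0
    bradykinesia_gain: float = 0.6
    tremor_fraction: float = 0.3
    tremor_on_reduction: float = 0.5
    dyskinesia_fraction: float = 0.2
    noise_sd: float = 0.05
    gravity_drift_rate: float = 0.001  # rad/s
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be >= 1")
        if self.session_minutes <= 0 or self.fs <= 0:
            raise InvalidConfigError("session duration and fs must be positive")
        if self.bout_mean_active_s <= 0 or self.bout_mean_rest_s <= 0:
            raise InvalidConfigError("bout dwell means must be positive")
        if self.medication_effect < 0:
            raise InvalidConfigError("medication_effect must be >= 0")
        if not (0 < self.bradykinesia_gain <= 1):
            raise InvalidConfigError("bradykinesia_gain must be in (0, 1]")
        for name in ("tremor_fraction", "tremor_on_reduction", "dyskinesia_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise InvalidConfigError(f"{name} must be a proportion")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject latent draws shared by both sessions."""

    subject_id: str
    effect: float  # realised medication effect (scales all asymmetries)
    base_amp: float  # m/s^2 movement amplitude ceiling
    has_tremor: bool
    tremor_freq: float  # Hz
    tremor_amp: float  # m/s^2
    tremor_axis: tuple[float, float, float]
    has_dyskinesia: bool
    dysk_freq: float  # Hz
    dysk_axis: tuple[float, float, float]
    session_seed_pre: int
    session_seed_post: int


@dataclass
class RawRecording:
    """One session of raw tri-axial samples."""

    subject_id: str
    state: State
    fs: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    @property
    def duration_s(self) -> float:
        return self.t[-1] - self.t[0] + 1.0 / self.fs


@dataclass
class ClinicalScores:
    subject_id: str
    bradykinesia_pre: int
    bradykinesia_post: int
    tremor_pre: int
    tremor_post: int
    aims_pre: int
    aims_post: int


@dataclass
class Cohort:
    config: SimulationConfig
    subjects: list[SubjectParams]
    recordings: list[tuple[RawRecording, RawRecording]]  # (pre, post) pairs
    scores: list[ClinicalScores] = field(default_factory=list)


def _gravity_series(rng: np.random.Generator, n: int, fs: float, drift_rate: float) -> np.ndarray:
    """Slowly rotating gravity vector, (n, 3) in m/s^2."""
    u0 = rng.normal(size=3)
    u0 /= np.linalg.norm(u0)
    w = rng.normal(size=3)
    w -= (w @ u0) * u0  # rotation axis orthogonal to u0
    norm = np.linalg.norm(w)
    if norm < 1e-12 or drift_rate == 0.0:
        return np.tile(GRAVITY * u0, (n, 1))
    w /= norm
    theta = drift_rate * (np.arange(n) / fs)
    # Rodrigues formula for u0 with w ⟂ u0: u(t) = u0 cosθ + (w × u0) sinθ
    cross = np.cross(w, u0)
    u = np.outer(np.cos(theta), u0) + np.outer(np.sin(theta), cross)
    return GRAVITY * u


def _bout_spans(
    rng: np.random.Generator, n: int, fs: float, mean_active_s: float, mean_rest_s: float
) -> list[tuple[int, int, bool]]:
    """(start, stop, active) spans from an alternating exponential dwell
    process covering the whole session."""
    spans = []
    pos = 0
    active = rng.random() < mean_active_s / (mean_active_s + mean_rest_s)
    while pos < n:
        mean = mean_active_s if active else mean_rest_s
        length = max(1, int(round(rng.exponential(mean) * fs)))
        spans.append((pos, min(pos + length, n), active))
        pos += length
        active = not active
    return spans


DIP_JITTER_SD = 0.12  # bout-to-bout spread of the dip depth


@lru_cache(maxsize=8)
def _smoothing_geometry(fs: float) -> tuple[float, float]:
    """Constants (c1, c2) of the smoothed blockwise envelope.

    With iid two-level blocks L and a smoothing kernel spanning at most
    two blocks, the smoothed envelope at any phase is a convex mixture
    a*L_j + (1-a)*L_{j+1}, so its mean square averaged over phases is
    c1*E[L^2] + c2*E[L]^2 with c1 = <a^2 + (1-a)^2>, c2 = 1 - c1.
    """
    block = max(1, int(round(ENVELOPE_BLOCK_S * fs)))
    width = int(round(ENVELOPE_RAMP_S * fs))
    kernel = np.hanning(max(width, 2))
    kernel /= kernel.sum()
    half = kernel.size // 2
    # weight of the current block for each in-block phase position
    alphas = np.empty(block)
    offsets = np.arange(kernel.size) - half
    for t in range(block):
        alphas[t] = kernel[(t + offsets) // block == 0].sum()
    c1 = float(np.mean(alphas**2 + (1.0 - alphas) ** 2))
    return c1, 1.0 - c1


def _dip_parameters(
    effect: float, state: State, jitter: float, fs: float
) -> tuple[float, float]:
    """Envelope dip depth and high-level dwell probability for one bout.

    The ON state dips deeper; the high-level dwell probability is solved
    so that the *smoothed* envelope's mean square matches the OFF-state
    reference, which keeps RMS/band power comparable across states while
    the within-window coefficient of variation increases with ``effect``.
    The envelope ceiling is 1 in both states, so window maxima match
    too.  ``jitter`` perturbs the depth bout-to-bout.
    """
    c1, c2 = _smoothing_geometry(fs)

    def smoothed_ms(beta: float, p: float) -> float:
        m1 = p + (1.0 - p) * (1.0 - beta)
        m2 = p + (1.0 - p) * (1.0 - beta) ** 2
        return c1 * m2 + c2 * m1**2

    target = smoothed_ms(BASE_DIP_DEPTH, BASE_DIP_FRACTION)
    beta_state = BASE_DIP_DEPTH if state == "pre" else BASE_DIP_DEPTH * (1.0 + effect)
    beta = float(np.clip(beta_state + DIP_JITTER_SD * jitter, 0.05, 0.95))
    lo, hi = smoothed_ms(beta, 0.0), smoothed_ms(beta, 1.0)
    if target <= lo:
        return beta, 0.0
    if target >= hi:
        return beta, 1.0
    p = float(brentq(lambda q: smoothed_ms(beta, q) - target, 0.0, 1.0, xtol=1e-10))
    return beta, p


def _smooth_envelope(env: np.ndarray, fs: float) -> np.ndarray:
    """Replace hard envelope steps by ~3 s cosine ramps so the amplitude
    modulation stays below the analysed 0.3-4 Hz band."""
    width = int(round(ENVELOPE_RAMP_S * fs))
    if env.size <= 2 or width < 2:
        return env
    kernel = np.hanning(min(width, env.size))
    kernel /= kernel.sum()
    padded = np.pad(env, (kernel.size // 2, kernel.size - 1 - kernel.size // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def simulate_session(
    config: SimulationConfig,
    params: SubjectParams,
    state: State,
    session_seed: int | None = None,
) -> RawRecording:
    """Generate one raw session for a subject in a given medication state.

    All randomness derives from ``session_seed`` (defaulting to the
    subject's per-state seed); the state enters only through deterministic
    parameters, so two states simulated from the same seed are
    bit-identical whenever their parameterisations coincide
    (``medication_effect = 0``).
    """
    config.validate()
    if state not in ("pre", "post"):
        raise ValueError(f"unknown state {state!r}")
    if session_seed is None:
        session_seed = (
            params.session_seed_pre if state == "pre" else params.session_seed_post
        )
    rng = np.random.default_rng(session_seed)

    n = int(round(config.session_minutes * 60.0 * config.fs))
    t = np.arange(n) / config.fs
    r = min(params.effect, 1.0)  # saturating asymmetry scale

    gravity = _gravity_series(rng, n, config.fs, config.gravity_drift_rate)
    spans = _bout_spans(
        rng, n, config.fs, config.bout_mean_active_s, config.bout_mean_rest_s
    )

    session_factor = float(np.exp(rng.normal(0.0, SESSION_AMP_SD)))
    state_gain = config.bradykinesia_gain**r if state == "pre" else 1.0
    block = max(1, int(round(ENVELOPE_BLOCK_S * config.fs)))

    # movement bouts: every bout is its own "activity" with its own
    # intensity, axis loading and 0.5-3 Hz tone mixture; within a bout a
    # blockwise two-level envelope carries the medication effect.  All
    # random draws are state-independent (the state enters only through
    # deterministic parameters), so an effect-free ON session generated
    # from the same seed is bit-identical to its OFF counterpart.
    movement = np.zeros((n, 3))
    n_tones = 3
    spike_half = max(1, int(round(SPIKE_HALF_WIDTH_S * config.fs)))
    spike_shape = 0.5 * (1 + np.cos(np.linspace(-np.pi, np.pi, 2 * spike_half + 1)))
    for start, stop, active in spans:
        bout_amp_factor = float(np.exp(rng.normal(0.0, BOUT_AMP_SD)))
        dip_jitter = float(rng.normal())
        freqs = rng.uniform(0.5, 3.0, size=n_tones)
        phases = rng.uniform(0, 2 * np.pi, size=(3, n_tones))
        weights = rng.dirichlet(np.ones(n_tones), size=3)
        axis_weights = rng.dirichlet(np.ones(3) * 8.0)
        n_blocks = -(-(stop - start) // block)
        u_blocks = rng.random(n_blocks)
        # rest bouts carry small state-independent micro-movements; the
        # medication effect acts only on true activity
        effect = params.effect if active else 0.0
        beta, p_high = _dip_parameters(effect, state, dip_jitter, config.fs)
        levels = np.where(u_blocks < p_high, 1.0, 1.0 - beta)
        envelope = _smooth_envelope(
            np.repeat(levels, block)[: stop - start], config.fs
        )
        amp = params.base_amp * session_factor * bout_amp_factor
        amp *= state_gain if active else REST_AMP_FRACTION
        tb = t[start:stop]
        for axis in range(3):
            osc = np.zeros(stop - start)
            for k in range(n_tones):
                osc += np.sqrt(2.0 * weights[axis, k]) * np.sin(
                    2 * np.pi * freqs[k] * tb + phases[axis, k]
                )
            movement[start:stop, axis] = np.sqrt(3.0 * axis_weights[axis]) * osc
        movement[start:stop] *= (amp * envelope)[:, None]

        # contact/impact transients: brief broad-band spikes that dominate
        # the raw-magnitude variability of active windows (they are mostly
        # attenuated by the 3.5 Hz low-pass before feature extraction)
        # spike amplitude tracks the activity's intensity but not the
        # medication state: contact transients come from the interaction
        # with objects, not from the damped voluntary oscillation
        duration_s = (stop - start) / config.fs
        n_spikes = rng.poisson(SPIKE_RATE_HZ * duration_s)
        positions = rng.integers(0, max(stop - start, 1), size=n_spikes)
        spike_base = params.base_amp * session_factor * bout_amp_factor
        spike_amps = SPIKE_AMP_FACTOR * spike_base * np.exp(rng.normal(0.0, 0.5, size=n_spikes))
        spike_axes = rng.normal(size=(n_spikes, 3))
        if active and n_spikes:
            spike_axes /= np.linalg.norm(spike_axes, axis=1, keepdims=True)
            for pos, s_amp, axis_vec in zip(positions, spike_amps, spike_axes):
                centre = start + int(pos)
                lo = max(centre - spike_half, start)
                hi = min(centre + spike_half + 1, stop)
                seg = spike_shape[(lo - centre + spike_half) : (hi - centre + spike_half)]
                env_here = envelope[min(int(pos), stop - start - 1)]
                movement[lo:hi] += (s_amp * env_here * seg)[:, None] * axis_vec

    signal = gravity + movement

    if params.has_tremor:
        tremor_gain = 1.0 - config.tremor_on_reduction * r if state == "post" else 1.0
        phase = rng.uniform(0, 2 * np.pi)
        direction = np.asarray(params.tremor_axis)
        tremor = params.tremor_amp * tremor_gain * np.sin(
            2 * np.pi * params.tremor_freq * t + phase
        )
        signal += tremor[:, None] * direction

    # dyskinetic slow large-amplitude component, present only with
    # medication on board (amplitude ∝ realised effect); intermittent,
    # with its own on/off bout process
    dysk_gain = r if (params.has_dyskinesia and state == "post") else 0.0
    dysk_phase = rng.uniform(0, 2 * np.pi)
    dysk_spans = _bout_spans(rng, n, config.fs, 20.0, 30.0)
    if dysk_gain > 0:
        dysk_mask = np.zeros(n)
        for start, stop, active in dysk_spans:
            if active:
                dysk_mask[start:stop] = 1.0
        dysk = 1.0 * dysk_gain * np.sin(2 * np.pi * params.dysk_freq * t + dysk_phase)
        signal += (dysk * dysk_mask)[:, None] * np.asarray(params.dysk_axis)

    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=(n, 3))

    return RawRecording(
        subject_id=params.subject_id,
        state=state,
        fs=config.fs,
        t=t,
        ax=signal[:, 0],
        ay=signal[:, 1],
        az=signal[:, 2],
    )


def draw_subject_params(config: SimulationConfig) -> list[SubjectParams]:
    """Deterministic per-subject latent draws from the cohort seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:03d}"
        effect = config.medication_effect * rng.uniform(0.7, 1.3)
        base_amp = float(np.exp(rng.normal(np.log(3.0), 0.25)))
        has_tremor = rng.random() < config.tremor_fraction
        tremor_freq = rng.uniform(4.0, 6.0)
        tremor_amp = float(np.exp(rng.normal(np.log(0.6), 0.3)))
        tremor_axis = rng.normal(size=3)
        tremor_axis /= np.linalg.norm(tremor_axis)
        has_dysk = rng.random() < config.dyskinesia_fraction
        dysk_freq = rng.uniform(0.5, 1.5)
        dysk_axis = rng.normal(size=3)
        dysk_axis /= np.linalg.norm(dysk_axis)
        seed_pre, seed_post = rng.integers(0, 2**31 - 1, size=2)
        subjects.append(
            SubjectParams(
                subject_id=subject_id,
                effect=effect,
                base_amp=base_amp,
                has_tremor=has_tremor,
                tremor_freq=tremor_freq,
                tremor_amp=tremor_amp,
                tremor_axis=tuple(tremor_axis),
                has_dyskinesia=has_dysk,
                dysk_freq=dysk_freq,
                dysk_axis=tuple(dysk_axis),
                session_seed_pre=int(seed_pre),
                session_seed_post=int(seed_post),
            )
        )
    return subjects


def _clinical_scores(
    rng: np.random.Generator, params: SubjectParams, config: SimulationConfig
) -> ClinicalScores:
    r = min(params.effect, 1.5)
    brady_pre = int(np.clip(round(rng.uniform(6, 14)), 0, 16))
    improvement = int(np.clip(round(3.0 * r + rng.normal(0, 0.8)), 0, brady_pre))
    tremor_pre = int(np.clip(round(rng.uniform(2, 8)), 0, 12)) if params.has_tremor else 0
    tremor_post = (
        int(np.clip(round(tremor_pre * (1 - config.tremor_on_reduction * min(r, 1.0))), 0, 12))
        if params.has_tremor
        else 0
    )
    aims_post = int(np.clip(round(rng.uniform(2, 8) * min(r, 1.0)), 0, 28)) if params.has_dyskinesia else 0
    return ClinicalScores(
        subject_id=params.subject_id,
        bradykinesia_pre=brady_pre,
        bradykinesia_post=brady_pre - improvement,
        tremor_pre=tremor_pre,
        tremor_post=tremor_post,
        aims_pre=0,
        aims_post=aims_post,
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one pre and one post recording plus clinical scores per
    subject.  Bradykinesia improvement magnitude tracks each subject's
    realised medication effect, so rank correlations against downstream
    model performance are meaningful."""
    config.validate()
    subjects = draw_subject_params(config)
    score_rng = np.random.default_rng(np.random.default_rng(config.seed ^ 0x5EED).integers(2**31))
    recordings = []
    scores = []
    for params in subjects:
        pre = simulate_session(config, params, "pre")
        post = simulate_session(config, params, "post")
        recordings.append((pre, post))
        scores.append(_clinical_scores(score_rng, params, config))
    return Cohort(config=config, subjects=subjects, recordings=recordings, scores=scores)
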