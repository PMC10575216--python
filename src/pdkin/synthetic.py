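"""Synthetic cohort of parkinsonian walkers with phenotype-consistent kinematics.

No public motion-capture dataset exists for this analysis, so every
downstream stage is exercised against virtual participants whose marker
kinematics carry the phenotype signatures the features are designed to
measure:

* **TD** (tremor-dominant): a 4-6 Hz resting-tremor oscillation rides on
  the wrist markers (full amplitude, mediolateral + vertical) and on the
  thigh/shank markers at half amplitude — resting tremor in PD involves
  the legs as well as the arms.
* **PIGD** (postural instability / gait difficulty): shorter strides,
  larger stride-to-stride variability, and — for participants with
  freezing of gait — episodes during which forward progression collapses
  while a 3-8 Hz trembling appears on the shank and heel markers.

The kinematic model is deliberately simple: each marker is the sum of a
sacral path (forward progression x heading), a fixed anthropometric offset
(scaled by height), sinusoidal gait oscillations driven by a common stride
phase with multiplicative stride-time and stride-length variability,
phenotype tremor/freeze oscillations, and white Gaussian sensor noise.
This is the simplest construction that produces the spectral band
structure and spatiotemporal parameters the features measure; it makes no
claim to biomechanical joint validity (see docs/methods.md).

Conventions: 120 frames/s, cm units, X mediolateral / Y vertical /
Z anterior.  Left heel strike is defined at integer stride phase (the
anterior extremum of the left heel relative to the sacrum); the stance
fraction (duty factor) is 0.60, so the left toe-off falls at phase 0.6,
the right heel strike at 0.5 and the right toe-off at 0.1.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidArgumentError
from .mocap import CANONICAL_MARKERS, Recording
from .subtyping import GAIT_ITEMS, TREMOR_ITEMS, UpdrsScores, classify_subtype

RATE = 120.0  # frames/s of the emulated optical capture system

#: Mean session durations (s) of the three clinical scripts.
SESSION_DURATIONS: dict[str, float] = {
    "walk_thru": 4.75,
    "turn_360": 63.9,
    "tug": 86.0,
}

DUTY_FACTOR = 0.60  # stance fraction of the gait cycle

_SESSION_CODE = {"walk_thru": 1, "turn_360": 2, "tug": 3}


@dataclass
class PhenotypeParams:
    """Generative gait/tremor parameters for one virtual participant."""

    subtype_label: str  # "TD" or "PIGD"
    stride_frequency: float  # Hz (strides/s; cadence = 120*this in steps/min)
    stride_length: float  # cm
    step_width: float  # cm
    arm_swing_amplitude: float  # cm
    tremor_amplitude: float  # cm, 0 for non-tremulous phenotypes
    tremor_frequency: float  # Hz, drawn in [4, 6]
    freeze_rate: float  # episodes per minute of walking, >= 0
    freeze_duration: float  # s, mean episode length
    freeze_band_frequency: float  # Hz, drawn in [3, 8]
    gait_variability_cv: float  # stride-to-stride coefficient of variation
    sensor_noise_sd: float  # cm
    height: float  # cm

    def __post_init__(self) -> None:
        if self.subtype_label not in ("TD", "PIGD"):
            raise InvalidArgumentError(f"unknown subtype {self.subtype_label!r}")
        if self.stride_frequency <= 0:
            raise InvalidArgumentError("stride_frequency must be > 0")
        for name in ("stride_length", "step_width", "arm_swing_amplitude",
                     "tremor_amplitude", "freeze_rate", "freeze_duration",
                     "gait_variability_cv", "sensor_noise_sd", "height"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.subtype_label == "TD" and self.tremor_amplitude <= 0:
            raise InvalidArgumentError("TD phenotypes must have tremor_amplitude > 0")
        if self.freeze_rate > 0 and self.freeze_duration <= 0:
            raise InvalidArgumentError(
                "freeze_rate > 0 requires freeze_duration > 0")


@dataclass
class VirtualParticipant:
    participant_id: str
    phenotype: PhenotypeParams
    fog_score: int  # MDS-UPDRS item 3.11, 0-4

    def __post_init__(self) -> None:
        if not 0 <= self.fog_score <= 4:
            raise InvalidArgumentError("fog_score must be in 0..4")
        if (self.fog_score > 0) != (self.phenotype.freeze_rate > 0):
            raise InvalidArgumentError(
                "fog_score > 0 must coincide with freeze_rate > 0")


@dataclass
class GroundTruth:
    """Generator-side truth used as the oracle for gait-feature tests."""

    heel_strike_times_left: np.ndarray
    heel_strike_times_right: np.ndarray
    toe_off_times_left: np.ndarray
    toe_off_times_right: np.ndarray
    true_knee_angle: np.ndarray  # degrees, left side, per frame
    true_ankle_angle: np.ndarray  # degrees, left side, per frame
    freeze_intervals: list[tuple[float, float]]
    true_label: str
    # convenience truths (generative parameters, not derived from events)
    true_stride_length: float = 0.0
    true_cadence: float = 0.0
    true_support_pct: float = 100 * DUTY_FACTOR
    true_initial_double_support_pct: float = 100 * (DUTY_FACTOR - 0.5)
    true_single_support_pct: float = 100 * (1 - DUTY_FACTOR)


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode()) % (2**31)


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(keys)))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def sample_phenotype(subtype: str, with_fog: bool,
                     rng: np.random.Generator) -> PhenotypeParams:
    """Draw one phenotype from the cohort's generative distributions.

    TD and PIGD stride parameters deliberately overlap (the clinical
    literature disagrees on whether spatiotemporal gait separates the
    subtypes); the reliable discriminators are spectral — tremor for TD,
    freeze-band trembling for PIGD with FOG.
    """
    height = float(np.clip(rng.normal(172.0, 9.0), 150.0, 200.0))
    if subtype == "TD":
        return PhenotypeParams(
            subtype_label="TD",
            stride_frequency=float(np.clip(rng.normal(0.95, 0.08), 0.6, 1.3)),
            stride_length=float(np.clip(rng.normal(118.0, 14.0), 70.0, 160.0)),
            step_width=float(np.clip(rng.normal(10.0, 2.0), 5.0, 20.0)),
            arm_swing_amplitude=float(np.clip(rng.normal(11.0, 3.0), 3.0, 20.0)),
            tremor_amplitude=float(rng.uniform(1.5, 3.0)),
            tremor_frequency=float(rng.uniform(4.0, 6.0)),
            freeze_rate=0.0,
            freeze_duration=0.0,
            freeze_band_frequency=float(rng.uniform(3.0, 8.0)),
            gait_variability_cv=float(np.clip(rng.normal(0.03, 0.01), 0.01, 0.08)),
            sensor_noise_sd=0.15,
            height=height,
        )
    if subtype == "PIGD":
        freeze_rate = float(rng.uniform(2.0, 5.0)) if with_fog else 0.0
        return PhenotypeParams(
            subtype_label="PIGD",
            stride_frequency=float(np.clip(rng.normal(0.90, 0.08), 0.6, 1.3)),
            stride_length=float(np.clip(rng.normal(104.0, 14.0), 60.0, 150.0)),
            step_width=float(np.clip(rng.normal(12.0, 2.5), 5.0, 22.0)),
            arm_swing_amplitude=float(np.clip(rng.normal(8.0, 2.5), 2.0, 16.0)),
            tremor_amplitude=0.0,
            tremor_frequency=float(rng.uniform(4.0, 6.0)),
            freeze_rate=freeze_rate,
            freeze_duration=float(rng.uniform(1.5, 4.0)) if with_fog else 0.0,
            freeze_band_frequency=float(rng.uniform(3.0, 8.0)),
            gait_variability_cv=float(np.clip(rng.normal(0.06, 0.015), 0.02, 0.12)),
            sensor_noise_sd=0.15,
            height=height,
        )
    raise InvalidArgumentError(f"unknown subtype {subtype!r}")


def _fog_score_from_rate(freeze_rate: float) -> int:
    if freeze_rate <= 0:
        return 0
    return int(np.clip(round(freeze_rate) - 1, 1, 4))


def generate_cohort(n_participants: int, td_fraction: float,
                    fog_fraction_within_pigd: float,
                    seed: int) -> list[VirtualParticipant]:
    """Generate a deterministic cohort of virtual participants.

    ``round(n * td_fraction)`` participants are TD, the rest PIGD;
    ``round(fog_fraction_within_pigd * n_pigd)`` of the PIGD participants
    freeze (FOG score > 0).  Identifiers P001.. are unique and stable.
    """
    if n_participants < 2:
        raise InvalidArgumentError("need at least 2 participants")
    for name, frac in (("td_fraction", td_fraction),
                       ("fog_fraction_within_pigd", fog_fraction_within_pigd)):
        if not 0 <= frac <= 1:
            raise InvalidArgumentError(f"{name} must be in [0, 1], got {frac}")
    n_td = int(round(n_participants * td_fraction))
    n_pigd = n_participants - n_td
    n_fog = int(round(fog_fraction_within_pigd * n_pigd))

    rng = _rng(seed)
    subtypes = np.array(["TD"] * n_td + ["PIGD"] * n_pigd)
    rng.shuffle(subtypes)
    pigd_positions = np.flatnonzero(subtypes == "PIGD")
    fog_positions = set(rng.permutation(pigd_positions)[:n_fog].tolist())

    cohort = []
    for i, subtype in enumerate(subtypes):
        pid = f"P{i + 1:03d}"
        with_fog = i in fog_positions
        pheno = sample_phenotype(str(subtype), with_fog, _rng(seed, 1, i))
        cohort.append(VirtualParticipant(
            participant_id=pid, phenotype=pheno,
            fog_score=_fog_score_from_rate(pheno.freeze_rate)))
    return cohort


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------

def _warp_phase(phi: np.ndarray, duty: float = DUTY_FACTOR) -> np.ndarray:
    """Warp stride phase so the anterior trough falls at ``phi = duty``.

    Piecewise-linear map of the fractional phase: [0, duty] -> [0, 0.5],
    [duty, 1] -> [0.5, 1].  Heel strike (anterior maximum of cos(2*pi*g))
    stays at integer phase; toe-off (minimum) moves to ``duty``.
    """
    frac = np.mod(phi, 1.0)
    g = np.where(frac < duty, frac * (0.5 / duty),
                 0.5 + (frac - duty) * (0.5 / (1 - duty)))
    return np.floor(phi) + g


def _smooth_noise(n: int, knot_spacing: int, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Piecewise-linear low-frequency noise with the given pointwise SD."""
    if sd <= 0:
        return np.zeros(n)
    k = max(2, n // max(knot_spacing, 1) + 2)
    knots = rng.normal(0.0, sd, k)
    return np.interp(np.arange(n), np.linspace(0, n - 1, k), knots)


def _smooth_gate(mask: np.ndarray, ramp_frames: int) -> np.ndarray:
    """Turn a boolean mask into a 0..1 envelope with linear ramps.

    Edges are padded with their boundary value so a session that starts
    or ends mid-activity is not artificially ramped down.
    """
    env = mask.astype(float)
    if ramp_frames > 1:
        pad = ramp_frames
        padded = np.concatenate([np.full(pad, env[0]), env,
                                 np.full(pad, env[-1])])
        kernel = np.ones(ramp_frames) / ramp_frames
        env = np.convolve(padded, kernel, mode="same")[pad:-pad]
    return env


def _swing_bump(frac: np.ndarray, duty: float = DUTY_FACTOR) -> np.ndarray:
    """Smooth 0..1 bump over the swing portion [duty, 1] of the cycle."""
    x = (frac - duty) / (1 - duty)
    return np.where((x > 0) & (x < 1), np.sin(np.pi * np.clip(x, 0, 1))**2, 0.0)


def _planar_angle_deg(u_y, u_z, v_y, v_z):
    """Angle (deg) between two sagittal-plane vectors; 0 when collinear."""
    dot = u_y * v_y + u_z * v_z
    nu = np.hypot(u_y, u_z)
    nv = np.hypot(v_y, v_z)
    cosang = np.clip(dot / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def _session_profile(session_type: str, n: int, rate: float,
                     rng: np.random.Generator):
    """Activity (0..1 stepping), heading angle (rad) and progression gate."""
    t = np.arange(n) / rate
    duration = n / rate
    active = np.ones(n, bool)
    theta = np.zeros(n)
    prog = np.ones(n)
    if session_type == "walk_thru":
        pass
    elif session_type == "turn_360":
        # stepping in place while rotating; ~21 s per revolution
        n_turns = max(1, round(duration / 21.0))
        theta = 2 * np.pi * n_turns * t / duration
        prog[:] = 0.0
    elif session_type == "tug":
        # stand 2 s, walk out, 180-degree turn 2 s, walk back, turn 2 s
        plan = [("stand", 2.0), ("walk", None), ("turn", 2.0),
                ("walk", None), ("turn", 2.0)]
        fixed = sum(d for _, d in plan if d is not None)
        walk_len = max(duration - fixed, 0.2 * duration) / 2
        if duration <= fixed + 1.0:  # very short request: scale the script
            scale = duration / (fixed + 4.0)
            plan = [(k, (d if d is not None else 2.0) * scale) for k, d in plan]
            walk_len = 2.0 * scale
        t0 = 0.0
        heading = 0.0
        for kind, d in plan:
            d = walk_len if d is None else d
            i0, i1 = int(t0 * rate), min(int((t0 + d) * rate), n)
            if kind == "stand":
                active[i0:i1] = False
                prog[i0:i1] = 0.0
                theta[i0:i1] = heading
            elif kind == "walk":
                theta[i0:i1] = heading
            elif kind == "turn":
                prog[i0:i1] = 0.0
                span = max(i1 - i0, 1)
                theta[i0:i1] = heading + np.pi * np.arange(span) / span
                heading += np.pi
            t0 += d
        theta[int(t0 * rate):] = heading
    else:
        raise InvalidArgumentError(
            f"unknown session_type {session_type!r}; "
            f"expected one of {sorted(SESSION_DURATIONS)}")
    return t, active, theta, prog


def _freeze_intervals(active: np.ndarray, rate: float, freeze_rate: float,
                      freeze_duration: float,
                      rng: np.random.Generator) -> list[tuple[float, float]]:
    """Place non-overlapping freeze episodes inside the walking portions."""
    walk_seconds = float(active.sum()) / rate
    if freeze_rate <= 0 or walk_seconds < 6.0:
        return []
    expected = freeze_rate * walk_seconds / 60.0
    k = int(rng.poisson(expected))
    if walk_seconds > 15.0:
        k = max(k, 1)  # long walking scripts in freezers show >= 1 episode
    if k == 0:
        return []
    active_times = np.flatnonzero(active) / rate
    intervals: list[tuple[float, float]] = []
    for _ in range(200):
        if len(intervals) >= k:
            break
        d = float(np.clip(rng.normal(freeze_duration, 0.3 * freeze_duration),
                          0.8, 3 * freeze_duration))
        start = float(rng.choice(active_times))
        end = start + d
        if end > active_times[-1] - 0.5:
            continue
        if any(start < e + 1.0 and end > s - 1.0 for s, e in intervals):
            continue
        intervals.append((start, end))
    return sorted(intervals)


def synthesize_session(participant: VirtualParticipant, session_type: str,
                       duration: float | None = None,
                       seed: int = 0) -> tuple[Recording, GroundTruth]:
    """Synthesize one recording and its generator-side ground truth.

    ``duration`` defaults to the mean clinical duration of the session
    script.  Identical ``(participant, session_type, duration, seed)``
    give byte-identical outputs.
    """
    pp = participant.phenotype
    if session_type not in SESSION_DURATIONS:
        raise InvalidArgumentError(
            f"unknown session_type {session_type!r}; "
            f"expected one of {sorted(SESSION_DURATIONS)}")
    if duration is None:
        duration = SESSION_DURATIONS[session_type]
    if duration <= 2.0 / pp.stride_frequency:
        raise InvalidArgumentError(
            f"duration {duration} s too short: need more than one full "
            f"stride ({2.0 / pp.stride_frequency:.2f} s)")

    rng = _rng(seed, _stable_hash(participant.participant_id),
               _SESSION_CODE[session_type], int(round(duration * 1000)))
    n = int(round(duration * RATE))
    t, active_mask, theta, prog = _session_profile(session_type, n, RATE, rng)

    freezes = _freeze_intervals(active_mask, RATE, pp.freeze_rate,
                                pp.freeze_duration, rng)
    freeze_mask = np.zeros(n, bool)
    for s, e in freezes:
        freeze_mask[int(s * RATE):int(e * RATE)] = True
    freeze_env = _smooth_gate(freeze_mask, int(0.25 * RATE))

    # Stepping activity: 1 while walking, ~0.03 during freezes, 0 standing.
    act = _smooth_gate(active_mask, int(0.25 * RATE))
    act = act * (1.0 - 0.97 * freeze_env)

    # Stride phase with multiplicative rate variability (stride-time CV).
    knot = max(int(RATE / pp.stride_frequency), 2)
    eta_t = _smooth_noise(n, knot, pp.gait_variability_cv, rng)
    phi_rate = pp.stride_frequency * (1.0 + eta_t) * act
    phi0 = rng.uniform(0.0, 1.0)
    phi = phi0 + np.cumsum(phi_rate) / RATE
    phi += 1e-9 * np.arange(n)  # keep strictly increasing through plateaus

    # Sacral path: forward speed = stride_length * phase rate (displacement
    # per stride = stride_length exactly), modulated per-stride in length.
    eta_l = _smooth_noise(n, knot, pp.gait_variability_cv, rng)
    speed = pp.stride_length * (1.0 + eta_l) * phi_rate * prog
    path_x = np.cumsum(speed * np.sin(theta)) / RATE
    path_z = np.cumsum(speed * np.cos(theta)) / RATE

    s = pp.height / 172.0  # anthropometric scale
    phi_l = _warp_phase(phi)
    phi_r = _warp_phase(phi + 0.5)
    frac_l = np.mod(phi + 0.0, 1.0)
    frac_r = np.mod(phi + 0.5, 1.0)
    two_pi = 2 * np.pi

    # Oscillation amplitudes (cm); fractions of stride length for the leg
    # markers so longer strides move the markers further.
    a_heel = 0.30 * pp.stride_length
    a_shank = 0.22 * pp.stride_length
    a_thigh = 0.12 * pp.stride_length
    lift = 8.0 * s

    def osc(amp, phase, lag=0.0):
        return amp * np.cos(two_pi * (phase + lag)) * act

    # Local (body-frame) offsets relative to the sacrum: (X, Y, Z) in cm.
    local = {}
    sway = 1.2 * np.sin(two_pi * phi) * act
    bob = 1.2 * np.cos(2 * two_pi * phi_l) * act
    local["Head"] = (0.8 * np.sin(two_pi * phi) * act,
                     0.40 * pp.height + np.zeros(n), np.zeros(n))
    local["Chest"] = (0.5 * np.sin(two_pi * phi) * act,
                      0.25 * pp.height + np.zeros(n), np.zeros(n))
    # Arms swing in anti-phase with the ipsilateral leg.
    wrist_y = -12.0 * s
    local["L.Wrist"] = (-22.0 * s + 1.0 * np.sin(two_pi * phi) * act,
                        wrist_y + np.zeros(n),
                        osc(pp.arm_swing_amplitude, phi + 0.5))
    local["R.Wrist"] = (22.0 * s + 1.0 * np.sin(two_pi * phi + np.pi) * act,
                        wrist_y + np.zeros(n),
                        osc(pp.arm_swing_amplitude, phi))
    local["L.Thigh"] = (-11.0 * s + np.zeros(n), -0.14 * pp.height + np.zeros(n),
                        a_thigh * np.cos(two_pi * phi_l + 0.6) * act)
    local["R.Thigh"] = (11.0 * s + np.zeros(n), -0.14 * pp.height + np.zeros(n),
                        a_thigh * np.cos(two_pi * phi_r + 0.6) * act)
    local["L.Shank"] = (-11.0 * s + np.zeros(n), -0.32 * pp.height + np.zeros(n),
                        a_shank * np.cos(two_pi * phi_l + 1.2) * act)
    local["R.Shank"] = (11.0 * s + np.zeros(n), -0.32 * pp.height + np.zeros(n),
                        a_shank * np.cos(two_pi * phi_r + 1.2) * act)
    local["L.Heel"] = (-pp.step_width / 2 + np.zeros(n),
                       -0.46 * pp.height + lift * _swing_bump(frac_l) * act,
                       a_heel * np.cos(two_pi * phi_l) * act)
    local["R.Heel"] = (pp.step_width / 2 + np.zeros(n),
                       -0.46 * pp.height + lift * _swing_bump(frac_r) * act,
                       a_heel * np.cos(two_pi * phi_r) * act)

    # Phenotype oscillations. Tremor is a resting tremor: not gated by
    # stepping activity; it rides on wrists (full) and thigh/shank (half).
    if pp.tremor_amplitude > 0:
        for marker, gain, axes in (("L.Wrist", 1.0, (0, 1)),
                                   ("R.Wrist", 0.8, (0, 1)),
                                   ("L.Thigh", 0.5, (0,)),
                                   ("R.Thigh", 0.4, (0,)),
                                   ("L.Shank", 0.5, (0,)),
                                   ("R.Shank", 0.4, (0,))):
            ph = rng.uniform(0, two_pi)
            wave = pp.tremor_amplitude * gain * np.sin(
                two_pi * pp.tremor_frequency * t + ph)
            x, y, z = local[marker]
            if 0 in axes:
                x = x + wave
            if 1 in axes:
                y = y + 0.7 * wave
            local[marker] = (x, y, z)

    # Freeze-band trembling on shanks/heels (and faintly thighs) during
    # episodes; forward progression is already collapsed by `act`.
    if freezes:
        for marker, gain in (("L.Shank", 1.0), ("R.Shank", 0.9),
                             ("L.Heel", 1.0), ("R.Heel", 0.9),
                             ("L.Thigh", 0.4), ("R.Thigh", 0.4)):
            ph = rng.uniform(0, two_pi)
            wave = 1.4 * gain * freeze_env * np.sin(
                two_pi * pp.freeze_band_frequency * t + ph)
            x, y, z = local[marker]
            local[marker] = (x + wave, y, z + 0.8 * wave)

    # Assemble world coordinates: rotate the local frame by the heading and
    # translate by the sacral path. Vertical is unaffected by the heading.
    sac_y = 0.53 * pp.height + bob
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    local["Sacral"] = (sway, np.zeros(n), np.zeros(n))
    clean = np.empty((n, len(CANONICAL_MARKERS), 3))
    for mi, name in enumerate(CANONICAL_MARKERS):
        lx, ly, lz = local[name]
        clean[:, mi, 0] = path_x + lx * cos_t + lz * sin_t
        clean[:, mi, 1] = sac_y + ly
        clean[:, mi, 2] = path_z - lx * sin_t + lz * cos_t

    noisy = clean + rng.normal(0.0, pp.sensor_noise_sd, clean.shape)
    recording = Recording(
        data=noisy, sampling_rate=RATE,
        marker_names=list(CANONICAL_MARKERS),
        session_type=session_type,
        participant_id=participant.participant_id,
        session_id=f"{participant.participant_id}-{session_type}-{seed}")

    gt = _ground_truth(participant, clean, phi, act, t, freezes)
    return recording, gt


def _crossing_times(phi: np.ndarray, t: np.ndarray, offset: float,
                    act: np.ndarray) -> np.ndarray:
    """Times where ``phi`` crosses ``k + offset`` during active stepping."""
    lo = math.ceil(phi[0] - offset)
    hi = math.floor(phi[-1] - offset)
    if hi < lo:
        return np.asarray([])
    targets = np.arange(lo, hi + 1) + offset
    times = np.interp(targets, phi, t)
    act_at = np.interp(times, t, act)
    keep = (act_at > 0.9) & (times > t[0] + 0.05) & (times < t[-1] - 0.05)
    return times[keep]


def _ground_truth(participant: VirtualParticipant, clean: np.ndarray,
                  phi: np.ndarray, act: np.ndarray, t: np.ndarray,
                  freezes: list[tuple[float, float]]) -> GroundTruth:
    pp = participant.phenotype
    idx = {m: i for i, m in enumerate(CANONICAL_MARKERS)}

    def seg_angle(a, b, c):
        # planar (sagittal Y-Z) angle at b between segments a->b and b->c
        u_y = clean[:, idx[b], 1] - clean[:, idx[a], 1]
        u_z = clean[:, idx[b], 2] - clean[:, idx[a], 2]
        v_y = clean[:, idx[c], 1] - clean[:, idx[b], 1]
        v_z = clean[:, idx[c], 2] - clean[:, idx[b], 2]
        return _planar_angle_deg(u_y, u_z, v_y, v_z)

    knee = seg_angle("Sacral", "L.Thigh", "L.Shank")
    ankle = seg_angle("L.Thigh", "L.Shank", "L.Heel")

    return GroundTruth(
        heel_strike_times_left=_crossing_times(phi, t, 0.0, act),
        heel_strike_times_right=_crossing_times(phi, t, 0.5, act),
        toe_off_times_left=_crossing_times(phi, t, DUTY_FACTOR, act),
        toe_off_times_right=_crossing_times(phi, t, DUTY_FACTOR - 0.5, act),
        true_knee_angle=knee,
        true_ankle_angle=ankle,
        freeze_intervals=freezes,
        true_label=pp.subtype_label,
        true_stride_length=pp.stride_length,
        true_cadence=120.0 * pp.stride_frequency,
    )


# ---------------------------------------------------------------------------
# UPDRS synthesis
# ---------------------------------------------------------------------------

def synthesize_updrs(participant: VirtualParticipant,
                     noise_level: float = 0.0, seed: int = 0) -> UpdrsScores:
    """Item scores whose tremor/gait ratio reproduces the intended label.

    At ``noise_level = 0`` the construction guarantees
    ``classify_subtype(result).label == phenotype.subtype_label``.  With
    noise, each item is independently jittered by +/-1 (probability
    ``noise_level``), emulating rater variability.
    """
    if not 0 <= noise_level <= 1:
        raise InvalidArgumentError("noise_level must be in [0, 1]")
    pp = participant.phenotype
    rng = _rng(seed, _stable_hash(participant.participant_id), 99)

    if pp.subtype_label == "TD":
        # tremor burden maps amplitude [1.5, 3] cm -> items around 2-3
        base_t = int(np.clip(round(1.0 + pp.tremor_amplitude), 2, 4))
        tremor = {i: base_t for i in TREMOR_ITEMS}
        tremor["3.18"] = max(base_t - 1, 1)  # constancy a notch lower
        gait_burden = int(np.clip(round((125.0 - pp.stride_length) / 30.0), 0, 1))
        gait = {i: gait_burden for i in GAIT_ITEMS}
        gait["3.11"] = participant.fog_score
    else:
        gait_burden = int(np.clip(
            round(1.5 + (120.0 - pp.stride_length) / 25.0 + 0.3 * pp.freeze_rate),
            2, 4))
        gait = {i: gait_burden for i in GAIT_ITEMS}
        gait["2.13"] = int(np.clip(round(0.8 * pp.freeze_rate), 0, 4))
        gait["3.11"] = participant.fog_score
        base_t = int(np.clip(round(pp.tremor_amplitude), 0, 1))
        tremor = {i: base_t for i in TREMOR_ITEMS}
        tremor["3.16"] = 0

    # Guarantee the ratio rule lands on the intended side at zero noise.
    def means(tr, ga):
        return (sum(tr.values()) / 5.0, sum(ga.values()) / 5.0)

    tm, gm = means(tremor, gait)
    if pp.subtype_label == "TD":
        while gm > 0 and tm / gm < 1.15:
            item = max(GAIT_ITEMS, key=lambda i: gait[i])
            if gait[item] == 0:
                break
            gait[item] -= 1
            tm, gm = means(tremor, gait)
    else:
        while gm == 0 or (tm / gm) > 0.90:
            item = min(GAIT_ITEMS, key=lambda i: gait[i])
            if gait[item] == 4:
                tremor = {i: max(v - 1, 0) for i, v in tremor.items()}
            else:
                gait[item] += 1
            tm, gm = means(tremor, gait)

    if noise_level > 0:
        for items in (tremor, gait):
            for key in items:
                if rng.uniform() < noise_level:
                    items[key] = int(np.clip(
                        items[key] + rng.choice([-1, 1]), 0, 4))

    scores = UpdrsScores(participant_id=participant.participant_id,
                         tremor_items=tremor, gait_items=gait)
    if noise_level == 0:
        assert classify_subtype(scores).label == pp.subtype_label
    return scores


# ---------------------------------------------------------------------------
# Cohort export
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    """Write events and freeze intervals to a tidy CSV sidecar."""
    import pandas as pd

    rows = []
    for side, arr in (("left", gt.heel_strike_times_left),
                      ("right", gt.heel_strike_times_right)):
        rows += [{"side": side, "event": "heel_strike", "time_s": float(v)}
                 for v in arr]
    for side, arr in (("left", gt.toe_off_times_left),
                      ("right", gt.toe_off_times_right)):
        rows += [{"side": side, "event": "toe_off", "time_s": float(v)}
                 for v in arr]
    for s, e in gt.freeze_intervals:
        rows.append({"side": "both", "event": "freeze_start", "time_s": s})
        rows.append({"side": "both", "event": "freeze_end", "time_s": e})
    path = Path(path)
    pd.DataFrame(rows, columns=["side", "event", "time_s"]).to_csv(
        path, index=False)
    return path


def write_updrs_csv(scores: list[UpdrsScores], path: str | Path) -> Path:
    """Long-format UPDRS CSV: participant_id, item, score."""
    import pandas as pd

    rows = []
    for s in scores:
        for item, v in {**s.tremor_items, **s.gait_items}.items():
            rows.append({"participant_id": s.participant_id,
                         "item": item, "score": v})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_cohort_manifest(cohort: list[VirtualParticipant],
                          path: str | Path, seed: int | None = None) -> Path:
    """YAML manifest of the cohort's generative parameters."""
    entries = []
    for p in cohort:
        d = {"participant_id": p.participant_id, "fog_score": p.fog_score,
             **{k: (round(v, 6) if isinstance(v, float) else v)
                for k, v in vars(p.phenotype).items()}}
        entries.append(d)
    path = Path(path)
    path.write_text(yaml.safe_dump(
        {"seed": seed, "n_participants": len(cohort), "participants": entries},
        sort_keys=False))
    return path
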