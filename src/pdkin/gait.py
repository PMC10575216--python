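"""Marker-based gait event detection and spatiotemporal parameters.

Event detection is coordinate-based (no force plates): a heel strike is a
local maximum of the heel's anterior (Z) position *relative to the sacrum*,
a toe-off a local minimum of the same signal, with extrema below a
prominence threshold rejected.  Events are only accepted where the smoothed
sacral horizontal speed exceeds a threshold, which excludes standing,
freezing episodes and turning-in-place strides; gait parameters are
therefore meaningful for straight-walking segments.

These operations expect the *gap-filled, raw-amplitude* recording: the
relative heel signal used for detection is hip-centered internally, while
stride/step lengths and forward velocity need the world-frame sacral and
heel paths (hip-centering would zero them out, and Z-scored trajectories
destroy lengths altogether).

With only mid-segment markers available (no knee/ankle markers in the
11-marker set), sagittal "knee" and "ankle" angles are segment-vector
approximations: the knee angle is the planar angle between the
Sacral->Thigh and Thigh->Shank vectors, the ankle angle between
Thigh->Shank and Shank->Heel, both projected on the sagittal (Y-Z) plane.
They are proxies for the anatomical angles, not inverse kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    DegenerateGeometryError,
    InsufficientGaitError,
    ValidationError,
)
from .mocap import Recording

#: Default mean height (cm) imputed when a participant's height is unknown.
DEFAULT_HEIGHT_CM = 180.0

SPEED_THRESHOLD_CM_S = 25.0  # sacral horizontal speed gate for valid strides
MIN_EXCURSION_CM = 5.0  # minimum heel anterior excursion to attempt detection


@dataclass
class GaitEvents:
    """Per-side heel-strike and toe-off times (s), each sorted ascending."""

    heel_strikes_left: np.ndarray
    heel_strikes_right: np.ndarray
    toe_offs_left: np.ndarray
    toe_offs_right: np.ndarray

    def strikes(self, side: str) -> np.ndarray:
        return self.heel_strikes_left if side == "left" else self.heel_strikes_right

    def toe_offs(self, side: str) -> np.ndarray:
        return self.toe_offs_left if side == "left" else self.toe_offs_right


@dataclass
class GaitParameters:
    """Session-level summarized spatiotemporal and sagittal-angle parameters."""

    step_length_avg_left: float
    step_length_avg_right: float
    stride_length_avg_left: float
    stride_length_avg_right: float
    forward_velocity_avg: float
    cadence_avg: float
    total_support_pct_left: float
    total_support_pct_right: float
    swing_pct_left: float
    swing_pct_right: float
    initial_double_support_pct_left: float
    initial_double_support_pct_right: float
    single_support_pct_left: float
    single_support_pct_right: float
    step_width: float
    knee_angle_range_left: float = np.nan
    knee_angle_range_right: float = np.nan
    knee_angle_avg_left: float = np.nan
    knee_angle_avg_right: float = np.nan
    ankle_angle_range_left: float = np.nan
    ankle_angle_range_right: float = np.nan
    ankle_angle_avg_left: float = np.nan
    ankle_angle_avg_right: float = np.nan

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(int(width), 1)
    return np.convolve(x, np.ones(width) / width, mode="same")


def _dominant_stride_frequency(sig: np.ndarray, rate: float) -> float:
    f, p = sps.periodogram(sig, fs=rate, window="hann", detrend="constant")
    sel = (f >= 0.3) & (f <= 3.0)
    if not sel.any() or p[sel].max() <= 0:
        return 1.0
    return float(f[sel][np.argmax(p[sel])])


def _enforce_alternation(strikes: np.ndarray, toe_offs: np.ndarray,
                         sig: np.ndarray, rate: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Keep a strictly alternating strike/toe-off sequence.

    When two events of the same kind are consecutive, the more extreme one
    (higher peak for strikes, lower trough for toe-offs) is kept.
    """
    events = [(i, "S") for i in strikes] + [(i, "T") for i in toe_offs]
    events.sort()
    kept: list[tuple[int, str]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = (sig[idx] > sig[prev]) if kind == "S" else (sig[idx] < sig[prev])
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    s = np.array([i for i, k in kept if k == "S"], dtype=float) / rate
    t = np.array([i for i, k in kept if k == "T"], dtype=float) / rate
    return s, t


def detect_gait_events(recording: Recording,
                       prominence_frac: float = 0.1,
                       min_excursion: float = MIN_EXCURSION_CM,
                       speed_threshold: float = SPEED_THRESHOLD_CM_S,
                       exclude_slow: bool = True) -> GaitEvents:
    """Detect heel strikes and toe-offs from heel anterior excursions.

    Raises ``InsufficientGaitError`` when fewer than two heel strikes are
    found on either side (standing still, turning in place, or a recording
    too short to contain two strides).
    """
    rate = recording.sampling_rate
    sac_z = recording.channel("Sacral", "Z")
    sac_x = recording.channel("Sacral", "X")

    # Hip-centered input (sacral ~constant) carries no path information;
    # the speed gate is then unavailable and is skipped.
    ambulatory = max(np.ptp(sac_z), np.ptp(sac_x)) > 1.0
    if exclude_slow and ambulatory:
        vx = np.gradient(sac_x) * rate
        vz = np.gradient(sac_z) * rate
        speed = _moving_average(np.hypot(vx, vz), int(0.5 * rate))
        valid = speed > speed_threshold
    else:
        valid = np.ones(recording.n_frames, bool)

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for side, marker in (("left", "L.Heel"), ("right", "R.Heel")):
        sig = recording.channel(marker, "Z") - sac_z
        excursion = float(np.ptp(sig))
        if excursion < min_excursion:
            out[side] = (np.asarray([]), np.asarray([]))
            continue
        f0 = _dominant_stride_frequency(sig, rate)
        distance = max(int(0.4 * rate / f0), 2)
        prom = prominence_frac * excursion
        peaks, _ = sps.find_peaks(sig, prominence=prom, distance=distance)
        troughs, _ = sps.find_peaks(-sig, prominence=prom, distance=distance)
        peaks = peaks[valid[peaks]]
        troughs = troughs[valid[troughs]]
        out[side] = _enforce_alternation(peaks, troughs, sig, rate)

    for side in ("left", "right"):
        if len(out[side][0]) < 2:
            raise InsufficientGaitError(
                f"fewer than 2 heel strikes detected on the {side} side")

    return GaitEvents(heel_strikes_left=out["left"][0],
                      heel_strikes_right=out["right"][0],
                      toe_offs_left=out["left"][1],
                      toe_offs_right=out["right"][1])


def _interp_channel(recording: Recording, marker: str, axis: str,
                    times: np.ndarray) -> np.ndarray:
    return np.interp(times, recording.times,
                     recording.channel(marker, axis))


def _valid_cycles(strikes: np.ndarray) -> np.ndarray:
    """Boolean per cycle; rejects cycles spanning gated-out gaps."""
    d = np.diff(strikes)
    if d.size == 0:
        return np.asarray([], bool)
    return d < 1.8 * np.median(d)


def spatiotemporal_params(recording: Recording, events: GaitEvents,
                          include_angles: bool = True) -> GaitParameters:
    """Summarize spatiotemporal gait parameters over a session.

    Step length is the anterior distance between contralateral heel
    positions at successive strikes; stride length between successive
    ipsilateral strikes; cadence 60 x steps / time between first and last
    strike; support and swing percentages come from strike/toe-off phase
    fractions of each gait cycle. Cycles whose duration exceeds 1.8x the
    median (i.e. spanning excluded turning or freezing segments) are
    dropped from the per-cycle averages.
    """
    duration = recording.duration
    all_events = np.concatenate([events.heel_strikes_left,
                                 events.heel_strikes_right,
                                 events.toe_offs_left, events.toe_offs_right])
    if all_events.size and (all_events.min() < -1e-9
                            or all_events.max() > duration + 1e-9):
        raise ValidationError("event times fall outside the recording")
    for side in ("left", "right"):
        if len(events.strikes(side)) < 2:
            raise InsufficientGaitError(f"fewer than 2 strikes on {side} side")

    heel_z = {s: _interp_channel(recording, m, "Z", events.strikes(s))
              for s, m in (("left", "L.Heel"), ("right", "R.Heel"))}
    heel_x = {s: _interp_channel(recording, m, "X", events.strikes(s))
              for s, m in (("left", "L.Heel"), ("right", "R.Heel"))}

    stride = {}
    for side in ("left", "right"):
        ok = _valid_cycles(events.strikes(side))
        d = np.abs(np.diff(heel_z[side]))
        stride[side] = float(d[ok].mean()) if ok.any() else float("nan")

    # merge strikes to get steps (successive contralateral strikes)
    merged = sorted([(t, "left") for t in events.heel_strikes_left]
                    + [(t, "right") for t in events.heel_strikes_right])
    times = np.array([t for t, _ in merged])
    sides = [s for _, s in merged]
    step_gaps = np.diff(times)
    med_gap = np.median(step_gaps) if step_gaps.size else 0.0
    step_lengths: dict[str, list[float]] = {"left": [], "right": []}
    pos = {"left": dict(zip(events.heel_strikes_left, heel_z["left"])),
           "right": dict(zip(events.heel_strikes_right, heel_z["right"]))}
    for i in range(1, len(merged)):
        t0, s0 = merged[i - 1]
        t1, s1 = merged[i]
        if s0 == s1 or (med_gap and (t1 - t0) > 1.8 * med_gap):
            continue
        step_lengths[s1].append(abs(pos[s1][t1] - pos[s0][t0]))

    # cadence: steps per minute over the strike-bounded interval; step
    # intervals spanning gated-out segments (freezes, turns) are dropped so
    # the rate reflects actual walking
    span = times[-1] - times[0]
    if step_gaps.size and med_gap > 0:
        ok_gaps = step_gaps < 1.8 * med_gap
        walk_time = float(step_gaps[ok_gaps].sum())
        cadence = (60.0 * int(ok_gaps.sum()) / walk_time
                   if walk_time > 0 else float("nan"))
    else:
        cadence = float("nan")

    sac_z = recording.channel("Sacral", "Z")
    z0 = float(np.interp(times[0], recording.times, sac_z))
    z1 = float(np.interp(times[-1], recording.times, sac_z))
    velocity = abs(z1 - z0) / span if span > 0 else float("nan")

    support, ids, single = {}, {}, {}
    for side, other in (("left", "right"), ("right", "left")):
        st = events.strikes(side)
        to = events.toe_offs(side)
        to_o = events.toe_offs(other)
        st_o = events.strikes(other)
        ok = _valid_cycles(st)
        sup_v, ids_v, ss_v = [], [], []
        for k in range(len(st) - 1):
            if not ok[k]:
                continue
            t0, t1 = st[k], st[k + 1]
            cyc = t1 - t0
            to_i = to[(to > t0) & (to < t1)]
            if to_i.size:
                sup_v.append(100.0 * (to_i[0] - t0) / cyc)
            to_c = to_o[(to_o > t0) & (to_o < t1)]
            if to_c.size:
                ids_v.append(100.0 * (to_c[0] - t0) / cyc)
                st_c = st_o[(st_o > to_c[0]) & (st_o <= t1)]
                if st_c.size:
                    ss_v.append(100.0 * (st_c[0] - to_c[0]) / cyc)
        support[side] = float(np.mean(sup_v)) if sup_v else float("nan")
        ids[side] = float(np.mean(ids_v)) if ids_v else float("nan")
        single[side] = float(np.mean(ss_v)) if ss_v else float("nan")

    # step width: mediolateral distance between heels at paired strikes
    widths = []
    xs = {"left": dict(zip(events.heel_strikes_left, heel_x["left"])),
          "right": dict(zip(events.heel_strikes_right, heel_x["right"]))}
    for i in range(1, len(merged)):
        t0, s0 = merged[i - 1]
        t1, s1 = merged[i]
        if s0 == s1 or (med_gap and (t1 - t0) > 1.8 * med_gap):
            continue
        widths.append(abs(xs[s1][t1] - xs[s0][t0]))
    step_width = float(np.mean(widths)) if widths else float("nan")

    angles = {}
    if include_angles:
        ja = joint_angles(recording)
        for joint in ("knee", "ankle"):
            for side in ("left", "right"):
                arr = getattr(ja, f"{joint}_{side}")
                angles[f"{joint}_angle_range_{side}"] = float(np.ptp(arr))
                angles[f"{joint}_angle_avg_{side}"] = float(np.mean(arr))

    def _mean(v):
        return float(np.mean(v)) if len(v) else float("nan")

    return GaitParameters(
        step_length_avg_left=_mean(step_lengths["left"]),
        step_length_avg_right=_mean(step_lengths["right"]),
        stride_length_avg_left=stride["left"],
        stride_length_avg_right=stride["right"],
        forward_velocity_avg=velocity,
        cadence_avg=cadence,
        total_support_pct_left=support["left"],
        total_support_pct_right=support["right"],
        swing_pct_left=100.0 - support["left"],
        swing_pct_right=100.0 - support["right"],
        initial_double_support_pct_left=ids["left"],
        initial_double_support_pct_right=ids["right"],
        single_support_pct_left=single["left"],
        single_support_pct_right=single["right"],
        step_width=step_width,
        **angles,
    )


@dataclass
class JointAngles:
    """Sagittal-plane segment-vector angles (degrees), per frame and side."""

    knee_left: np.ndarray
    knee_right: np.ndarray
    ankle_left: np.ndarray
    ankle_right: np.ndarray


def _planar_angle(recording: Recording, a: str, b: str, c: str) -> np.ndarray:
    """Sagittal (Y-Z) angle at b between segments a->b and b->c; 0 = collinear."""
    ay, az = recording.channel(a, "Y"), recording.channel(a, "Z")
    by, bz = recording.channel(b, "Y"), recording.channel(b, "Z")
    cy, cz = recording.channel(c, "Y"), recording.channel(c, "Z")
    uy, uz = by - ay, bz - az
    vy, vz = cy - by, cz - bz
    nu = np.hypot(uy, uz)
    nv = np.hypot(vy, vz)
    bad = (nu < 1e-9) | (nv < 1e-9)
    if bad.any():
        frame = int(np.flatnonzero(bad)[0])
        raise DegenerateGeometryError(
            f"coincident {a}/{b}/{c} sagittal positions at frame {frame}")
    cosang = np.clip((uy * vy + uz * vz) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def joint_angles(recording: Recording) -> JointAngles:
    """Segment-vector knee and ankle angles for both sides."""
    return JointAngles(
        knee_left=_planar_angle(recording, "Sacral", "L.Thigh", "L.Shank"),
        knee_right=_planar_angle(recording, "Sacral", "R.Thigh", "R.Shank"),
        ankle_left=_planar_angle(recording, "L.Thigh", "L.Shank", "L.Heel"),
        ankle_right=_planar_angle(recording, "R.Thigh", "R.Shank", "R.Heel"),
    )


LENGTH_PARAMS = ("step_length_avg_left", "step_length_avg_right",
                 "stride_length_avg_left", "stride_length_avg_right",
                 "step_width")


def gait_feature_vector(recording: Recording,
                        height: float | None = None,
                        normalize_by_height: bool = False,
                        events: GaitEvents | None = None,
                        include_angles: bool = True) -> pd.Series:
    """One summarized gait-parameter vector for a session.

    With ``normalize_by_height``, length parameters are divided by the
    participant's height; when the height is unknown the population mean
    of 180 cm is imputed, so a 90 cm step at the default height maps to
    0.5. Dataset-level Z-standardization of the resulting table is a
    training step and is not applied here.
    """
    if events is None:
        events = detect_gait_events(recording)
    params = spatiotemporal_params(recording, events,
                                   include_angles=include_angles)
    vec = params.to_series()
    if not include_angles:
        vec = vec.drop([k for k in vec.index if "angle" in k])
    if normalize_by_height:
        h = DEFAULT_HEIGHT_CM if height is None else float(height)
        vec[list(LENGTH_PARAMS)] = vec[list(LENGTH_PARAMS)] / h
    return vec
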