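"""Marker-trajectory containers, TRC/CSV I/O, preprocessing and windowing.

A :class:`Recording` holds a ``frames x markers x 3`` block of 3D marker
positions (cm) sampled at a fixed rate (120 frames/s for the optical system
this package models).  Axis convention throughout: X = mediolateral,
Y = vertical, Z = anterior-posterior (walking direction); the convention is
a package decision and is carried in the docs rather than the data.

Preprocessing mirrors clinical mocap practice for this analysis:

1. :func:`fill_gaps` — linear interpolation of interior gaps, linear
   extrapolation of leading/trailing gaps (marker dropout is 2-5% typical);
2. :func:`hip_center` — subtract the sacral marker per frame so trajectories
   are body-relative;
3. :func:`zscore` — per-channel standardization over the session;
4. :func:`segment` — 4-s sliding windows with 1 s of shared signal between
   consecutive windows (step 3 s); shorter recordings yield one fallback
   window covering the whole recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InvalidArgumentError,
    UnrecoverableGapError,
    ValidationError,
)

#: Canonical marker order used by the full-body analysis set.
CANONICAL_MARKERS: tuple[str, ...] = (
    "Head",
    "Chest",
    "Sacral",
    "L.Wrist",
    "R.Wrist",
    "L.Thigh",
    "R.Thigh",
    "L.Shank",
    "R.Shank",
    "L.Heel",
    "R.Heel",
)

AXES: tuple[str, ...] = ("X", "Y", "Z")

#: Default alias table mapping common vendor spellings to canonical names.
DEFAULT_ALIASES: dict[str, str] = {
    "head": "Head",
    "chest": "Chest",
    "sternum": "Chest",
    "sacral": "Sacral",
    "sacrum": "Sacral",
    "lwrist": "L.Wrist",
    "l.wrist": "L.Wrist",
    "left_wrist": "L.Wrist",
    "rwrist": "R.Wrist",
    "r.wrist": "R.Wrist",
    "right_wrist": "R.Wrist",
    "lthigh": "L.Thigh",
    "l.thigh": "L.Thigh",
    "rthigh": "R.Thigh",
    "r.thigh": "R.Thigh",
    "lshank": "L.Shank",
    "l.shank": "L.Shank",
    "rshank": "R.Shank",
    "r.shank": "R.Shank",
    "lheel": "L.Heel",
    "l.heel": "L.Heel",
    "rheel": "R.Heel",
    "r.heel": "R.Heel",
}

SESSION_TYPES: tuple[str, ...] = ("walk_thru", "turn_360", "tug")


def canonical_marker_name(name: str, aliases: dict[str, str] | None = None,
                          strict: bool = False) -> str:
    """Map a marker name to its canonical spelling via the alias table."""
    if name in CANONICAL_MARKERS:
        return name
    table = DEFAULT_ALIASES if aliases is None else {**DEFAULT_ALIASES, **aliases}
    key = name.strip().lower().replace(" ", "_")
    if key in table:
        return table[key]
    if strict:
        raise ValidationError(f"unknown marker name {name!r}")
    return name


@dataclass
class Recording:
    """A multi-marker 3D trajectory block.

    ``data`` has shape ``(n_frames, n_markers, 3)`` in cm; missing samples
    are NaN and are also exposed through :attr:`missing_mask`.
    """

    data: np.ndarray
    sampling_rate: float
    marker_names: list[str] = field(default_factory=lambda: list(CANONICAL_MARKERS))
    session_type: str | None = None
    participant_id: str | None = None
    session_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValidationError(
                f"data must be (frames, markers, 3), got {self.data.shape}")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if len(self.marker_names) != self.data.shape[1]:
            raise ValidationError("marker_names length does not match data")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValidationError("marker names must be unique")

    # -- basic accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (frames, markers, 3); True where a sample is missing."""
        return ~np.isfinite(self.data)

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise ValidationError(f"marker {name!r} not present in recording") from None

    def channel(self, marker: str, axis: str) -> np.ndarray:
        """One (frames,) channel, e.g. ``channel("L.Heel", "Z")``."""
        return self.data[:, self.marker_index(marker), AXES.index(axis)]

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(),
                       marker_names=list(self.marker_names))


@dataclass
class Window:
    """One analysis window cut from a recording."""

    data: np.ndarray  # (window_frames, markers, 3)
    start_time: float
    window_index: int
    sampling_rate: float
    marker_names: list[str]
    participant_id: str | None = None
    session_id: str | None = None
    session_type: str | None = None
    label: str | None = None
    is_fallback: bool = False

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise ValidationError(f"marker {name!r} not present in window") from None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path,
                    fmt: str | None = None) -> Path:
    """Write a recording to TRC or wide CSV (format inferred from suffix)."""
    path = Path(path)
    fmt = fmt or ("trc" if path.suffix.lower() == ".trc" else "csv")
    if fmt == "trc":
        _write_trc(recording, path)
    elif fmt == "csv":
        _write_csv(recording, path)
    else:
        raise InvalidArgumentError(f"unknown format {fmt!r}")
    return path


def read_recording(path: str | Path, fmt: str | None = None,
                   aliases: dict[str, str] | None = None,
                   strict: bool = False) -> Recording:
    """Read a TRC or wide-CSV recording.

    Marker names are mapped to canonical spellings through the alias table;
    under ``strict=True`` an unmapped name raises ``ValidationError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("trc" if path.suffix.lower() == ".trc" else "csv")
    if fmt == "trc":
        rec = _read_trc(path)
    elif fmt == "csv":
        rec = _read_csv(path)
    else:
        raise InvalidArgumentError(f"unknown format {fmt!r}")
    rec.marker_names = [canonical_marker_name(m, aliases, strict)
                        for m in rec.marker_names]
    if len(set(rec.marker_names)) != len(rec.marker_names):
        raise ValidationError("duplicate marker names after canonicalization")
    return rec


def _fmt_cell(v: float) -> str:
    return "" if not math.isfinite(v) else f"{v:.6f}"


def _write_trc(rec: Recording, path: Path) -> None:
    n, m = rec.n_frames, len(rec.marker_names)
    rate = rec.sampling_rate
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{n}\t{m}\tcm\t{rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(rec.marker_names) + "\t\t",
        "\t\t" + "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(m)),
        "",
    ]
    flat = rec.data.reshape(n, m * 3)
    for i in range(n):
        row = [str(i + 1), f"{i / rate:.6f}"] + [_fmt_cell(v) for v in flat[i]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def _read_trc(path: Path) -> Recording:
    raw = path.read_text().replace("\r\n", "\n").replace("\r", "\n").split("\n")
    if len(raw) < 6:
        raise FormatError(f"{path}: truncated TRC header (line {len(raw)})")
    try:
        hdr_vals = raw[2].split("\t")
        rate = float(hdr_vals[0])
        n_markers = int(hdr_vals[3])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: bad TRC header values (line 3): {exc}") from None
    name_cells = raw[3].split("\t")[2:]
    names = [c for c in name_cells if c.strip()]
    if len(names) != n_markers:
        raise FormatError(
            f"{path}: header declares {n_markers} markers but names row "
            f"(line 4) lists {len(names)}")
    rows = []
    for lineno, line in enumerate(raw[5:], start=6):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < 2 + 3 * n_markers:
            cells = cells + [""] * (2 + 3 * n_markers - len(cells))
        try:
            vals = [float(c) if c.strip() else math.nan
                    for c in cells[2:2 + 3 * n_markers]]
        except ValueError as exc:
            raise FormatError(f"{path}: bad value on line {lineno}: {exc}") from None
        rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float).reshape(len(rows), n_markers, 3)
    return Recording(data=data, sampling_rate=rate, marker_names=list(names))


def _write_csv(rec: Recording, path: Path) -> None:
    cols = {"Time": np.round(rec.times, 9)}
    for mi, name in enumerate(rec.marker_names):
        for ai, ax in enumerate(AXES):
            cols[f"{name}_{ax}"] = rec.data[:, mi, ai]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def _read_csv(path: Path) -> Recording:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: {exc}") from None
    markers: list[str] = []
    for col in df.columns:
        if col.endswith("_X"):
            markers.append(col[:-2])
    if not markers:
        raise FormatError(f"{path}: no '<Marker>_X' columns found")
    for m in markers:
        for ax in AXES:
            if f"{m}_{ax}" not in df.columns:
                raise FormatError(f"{path}: missing column '{m}_{ax}'")
    if "Time" in df.columns and len(df) > 1:
        dt = np.diff(df["Time"].to_numpy())
        rate = 1.0 / float(np.median(dt))
        if abs(rate - round(rate)) < 0.01:  # absorb written-time rounding
            rate = float(round(rate))
    else:
        rate = 120.0
    data = np.stack(
        [np.stack([df[f"{m}_{ax}"].to_numpy(float) for ax in AXES], axis=1)
         for m in markers], axis=1)
    return Recording(data=data, sampling_rate=round(rate, 6),
                     marker_names=markers)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def fill_gaps(recording: Recording) -> Recording:
    """Fill missing samples channel-wise.

    Interior gaps are linearly interpolated between the flanking observed
    samples; leading/trailing gaps are linearly extrapolated from the two
    nearest observed samples.  A channel with fewer than two observed
    samples cannot be reconstructed and raises ``UnrecoverableGapError``.
    Observed samples are never modified.
    """
    out = recording.copy()
    n = out.n_frames
    idx = np.arange(n, dtype=float)
    for mi, name in enumerate(out.marker_names):
        for ai, ax in enumerate(AXES):
            ch = out.data[:, mi, ai]
            obs = np.isfinite(ch)
            if obs.all():
                continue
            n_obs = int(obs.sum())
            if n_obs < 2:
                raise UnrecoverableGapError(
                    f"channel {name}_{ax} has {n_obs} observed sample(s); "
                    "need at least 2")
            xo, yo = idx[obs], ch[obs]
            filled = np.interp(idx, xo, yo)
            # np.interp clamps at the edges; extrapolate from the two
            # nearest observed samples instead.
            if not obs[0]:
                slope = (yo[1] - yo[0]) / (xo[1] - xo[0])
                lead = idx < xo[0]
                filled[lead] = yo[0] + slope * (idx[lead] - xo[0])
            if not obs[-1]:
                slope = (yo[-1] - yo[-2]) / (xo[-1] - xo[-2])
                trail = idx > xo[-1]
                filled[trail] = yo[-1] + slope * (idx[trail] - xo[-1])
            filled[obs] = yo
            out.data[:, mi, ai] = filled
    return out


def hip_center(recording: Recording) -> Recording:
    """Express every marker relative to the same frame's sacral position."""
    out = recording.copy()
    si = out.marker_index("Sacral")
    out.data = out.data - out.data[:, si:si + 1, :]
    return out


def zscore(recording: Recording) -> Recording:
    """Standardize each channel to mean 0, population SD 1 over the session.

    Zero-variance channels (e.g. the sacral channels after hip-centering)
    map to all zeros so downstream features stay finite.
    """
    out = recording.copy()
    flat = out.data.reshape(out.n_frames, -1)
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    z = (flat - mu) / safe
    z[:, sd == 0] = 0.0
    out.data = z.reshape(out.data.shape)
    return out


def segment(recording: Recording, window_s: float = 4.0,
            overlap_s: float = 1.0) -> list[Window]:
    """Cut a recording into sliding windows.

    Consecutive windows share ``overlap_s`` seconds of signal, i.e. the
    hop is ``window_s - overlap_s``.  A recording shorter than one window
    yields a single whole-recording window flagged ``is_fallback`` rather
    than being dropped (straight-walk trials are often under 4 s).
    """
    if overlap_s < 0 or overlap_s >= window_s:
        raise InvalidArgumentError(
            f"need window_s > overlap_s >= 0, got {window_s=}, {overlap_s=}")
    rate = recording.sampling_rate
    wlen = int(round(window_s * rate))
    step = int(round((window_s - overlap_s) * rate))
    meta = dict(sampling_rate=rate, marker_names=list(recording.marker_names),
                participant_id=recording.participant_id,
                session_id=recording.session_id,
                session_type=recording.session_type)
    if recording.n_frames < wlen:
        return [Window(data=recording.data.copy(), start_time=0.0,
                       window_index=0, is_fallback=True, **meta)]
    windows = []
    k = 0
    while k * step + wlen <= recording.n_frames:
        s = k * step
        windows.append(Window(data=recording.data[s:s + wlen].copy(),
                              start_time=s / rate, window_index=k, **meta))
        k += 1
    return windows


def preprocess(recording: Recording, window_s: float = 4.0,
               overlap_s: float = 1.0) -> list[Window]:
    """Full preprocessing chain: fill_gaps -> hip_center -> zscore -> segment."""
    return segment(zscore(hip_center(fill_gaps(recording))),
                   window_s=window_s, overlap_s=overlap_s)
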