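"""Per-window statistical and temporal-frequency features.

Each of the 33 channels (11 markers x X/Y/Z) of an analysis window yields
eight features:

====================  =====================================================
``mean``/``minimum``/ plain sample statistics (population variance)
``maximum``/``variance``
``fi``                freezing index: spectral power in the freeze band
                      (3-8 Hz) over power in the locomotor band (0.5-3 Hz);
                      high when trembling episodes dominate locomotion
``cenfreq``           spectral centroid (power-weighted mean frequency)
                      within the search band
``domfreq``           frequency of the largest periodogram bin within the
                      search band (ties break toward the lower frequency)
``wav``               mean absolute detail coefficient of a 4-level db4
                      discrete wavelet transform, pooled across levels
====================  =====================================================

Spectra are single-taper Hann periodograms of the mean-removed signal: at
a 4-s window this gives 0.25 Hz bins, the best frequency resolution the
window admits.  Feature names follow the ``<feature>-<Marker>_<axis>``
convention, e.g. ``fi-L.Thigh_Z``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .errors import InvalidArgumentError, ValidationError
from .mocap import AXES, CANONICAL_MARKERS, Window

FEATURE_NAMES: tuple[str, ...] = (
    "mean", "minimum", "maximum", "variance", "fi", "cenfreq", "domfreq", "wav")

#: Default spectral bands (Hz). The freeze/locomotor split follows the
#: freezing-index literature; the centroid/dominant search band excludes DC
#: drift below 0.5 Hz and sensor noise above 12 Hz.
FREEZE_BAND: tuple[float, float] = (3.0, 8.0)
LOCOMOTOR_BAND: tuple[float, float] = (0.5, 3.0)
SPECTRAL_BAND: tuple[float, float] = (0.5, 12.0)

WAVELET = "db4"
WAVELET_LEVEL = 4


def statistical_features(x: np.ndarray) -> tuple[float, float, float, float]:
    """Return (mean, minimum, maximum, population variance) of a signal."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidArgumentError("empty signal")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("signal contains non-finite values")
    return float(x.mean()), float(x.min()), float(x.max()), float(x.var())


def power_spectrum(x: np.ndarray, rate: float,
                   axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann periodogram of the mean-removed signal.

    Returns ``(frequencies, power)`` with the DC bin dropped, so
    frequencies span ``(0, rate/2]``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 8:
        raise InvalidArgumentError(
            f"signal too short for a spectrum ({x.shape[axis]} < 8 samples)")
    if rate <= 0:
        raise InvalidArgumentError("rate must be positive")
    # symmetric taper so the estimate is exactly invariant to time reversal
    taper = sps.windows.hann(x.shape[axis], sym=True)
    f, p = sps.periodogram(x, fs=rate, window=taper, detrend="constant",
                           axis=axis)
    return f[1:], np.take(p, np.arange(1, len(f)), axis=axis)


def _band_power(f: np.ndarray, p: np.ndarray, band: tuple[float, float],
                axis: int = -1) -> np.ndarray:
    lo, hi = band
    sel = (f >= lo) & (f < hi)
    if hi >= f[-1]:
        sel |= f == f[-1]
    return np.compress(sel, p, axis=axis).sum(axis=axis)


def _check_band(band: tuple[float, float], rate: float, name: str) -> None:
    lo, hi = band
    if not (0 < lo < hi <= rate / 2):
        raise InvalidArgumentError(
            f"{name} band {band} must satisfy 0 < lo < hi <= rate/2")


def freezing_index(x: np.ndarray, rate: float,
                   freeze_band: tuple[float, float] = FREEZE_BAND,
                   locomotor_band: tuple[float, float] = LOCOMOTOR_BAND) -> float:
    """Ratio of freeze-band to locomotor-band spectral power.

    The locomotor power is floored at a tiny epsilon so the ratio stays
    finite; an all-zero signal returns 0.
    """
    _check_band(freeze_band, rate, "freeze")
    _check_band(locomotor_band, rate, "locomotor")
    if not (locomotor_band[1] <= freeze_band[0]
            or freeze_band[1] <= locomotor_band[0]):
        raise InvalidArgumentError("freeze and locomotor bands must be disjoint")
    f, p = power_spectrum(x, rate)
    num = _band_power(f, p, freeze_band)
    den = _band_power(f, p, locomotor_band)
    eps = 1e-12 * max(float(p.sum()), 1.0)
    return float(num / max(den, eps))


def central_frequency(x: np.ndarray, rate: float,
                      band: tuple[float, float] = SPECTRAL_BAND) -> float:
    """Power-weighted mean frequency (spectral centroid) within ``band``.

    Returns 0 when the band carries no power (e.g. a constant signal).
    """
    _check_band(band, rate, "search")
    f, p = power_spectrum(x, rate)
    sel = (f >= band[0]) & (f <= band[1])
    tot = p[sel].sum()
    if tot <= 0:
        return 0.0
    return float((f[sel] * p[sel]).sum() / tot)


def dominant_frequency(x: np.ndarray, rate: float,
                       band: tuple[float, float] = SPECTRAL_BAND) -> float:
    """Frequency of the largest periodogram bin within ``band``.

    Ties break toward the lower frequency; a zero-power band returns 0.
    """
    _check_band(band, rate, "search")
    f, p = power_spectrum(x, rate)
    sel = (f >= band[0]) & (f <= band[1])
    fb, pb = f[sel], p[sel]
    if fb.size == 0 or pb.max() <= 0:
        return 0.0
    return float(fb[int(np.argmax(pb))])


def wavelet_mean(x: np.ndarray, wavelet: str = WAVELET,
                 level: int = WAVELET_LEVEL) -> float:
    """Mean absolute detail coefficient of a multilevel DWT.

    Detail coefficients from all ``level`` levels of a symmetric-padded
    Daubechies-4 decomposition are pooled; the approximation band is
    excluded.  Scale-equivariant: ``wavelet_mean(a*x) == |a|*wavelet_mean(x)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise InvalidArgumentError(
            f"signal too short for the wavelet transform ({x.size} < 16)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pywt warns when level > dwt_max_level
        coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=level)
    details = np.concatenate([np.abs(c) for c in coeffs[1:]])
    return float(details.mean())


@dataclass
class FeatureVector:
    """Named per-window feature values (length 11 x 3 x 8 = 264)."""

    names: list[str]
    values: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def feature_names(markers: tuple[str, ...] = CANONICAL_MARKERS) -> list[str]:
    """Deterministic name order: marker-major, then axis, then feature."""
    return [f"{feat}-{m}_{ax}" for m in markers for ax in AXES
            for feat in FEATURE_NAMES]


def extract_window_features(
    window: Window,
    freeze_band: tuple[float, float] = FREEZE_BAND,
    locomotor_band: tuple[float, float] = LOCOMOTOR_BAND,
    spectral_band: tuple[float, float] = SPECTRAL_BAND,
    wavelet: str = WAVELET,
    level: int = WAVELET_LEVEL,
) -> FeatureVector:
    """Assemble the full-body 264-feature vector for one window.

    Per-feature Z-standardization across the dataset is deliberately *not*
    applied here: it is a training-fold-level step (see
    :mod:`pdkin.classify`) so that validation/test windows never leak into
    the statistics.
    """
    missing = [m for m in CANONICAL_MARKERS if m not in window.marker_names]
    if missing:
        raise ValidationError(f"window is missing marker(s): {', '.join(missing)}")
    order = [window.marker_index(m) for m in CANONICAL_MARKERS]
    arr = window.data[:, order, :].reshape(window.n_frames, -1)  # (n, 33)
    rate = window.sampling_rate

    mean = arr.mean(axis=0)
    mn = arr.min(axis=0)
    mx = arr.max(axis=0)
    var = arr.var(axis=0)

    f, p = power_spectrum(arr, rate, axis=0)  # p: (bins, 33)
    eps = 1e-12 * np.maximum(p.sum(axis=0), 1.0)
    fi = _band_power(f, p, freeze_band, axis=0) / np.maximum(
        _band_power(f, p, locomotor_band, axis=0), eps)

    sel = (f >= spectral_band[0]) & (f <= spectral_band[1])
    pb = p[sel]
    tot = pb.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cen = np.where(tot > 0, (f[sel, None] * pb).sum(axis=0) / np.where(
            tot > 0, tot, 1.0), 0.0)
    peak = pb.max(axis=0)
    dom = np.where(peak > 0, f[sel][np.argmax(pb, axis=0)], 0.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coeffs = pywt.wavedec(arr, wavelet, mode="symmetric", level=level, axis=0)
    details = np.concatenate([np.abs(c) for c in coeffs[1:]], axis=0)
    wav = details.mean(axis=0)

    block = np.stack([mean, mn, mx, var, fi, cen, dom, wav], axis=1)  # (33, 8)
    values = block.reshape(-1)
    names = feature_names()
    if not np.all(np.isfinite(values)):
        bad = [names[i] for i in np.flatnonzero(~np.isfinite(values))][:5]
        raise ValidationError(f"non-finite feature values: {bad}")
    return FeatureVector(names=names, values=values)


def windows_to_feature_table(
    windows: list[Window],
    labels: dict[str, str] | None = None,
    fog_scores: dict[str, int] | None = None,
    **feature_kwargs,
) -> pd.DataFrame:
    """Tidy feature table: one row per window, metadata then 264 features.

    ``labels`` and ``fog_scores`` map participant_id to subtype label and
    FOG score (MDS-UPDRS item 3.11) respectively.
    """
    rows = []
    for w in windows:
        fv = extract_window_features(w, **feature_kwargs)
        meta = {
            "participant_id": w.participant_id,
            "session_id": w.session_id,
            "session_type": w.session_type,
            "window_index": w.window_index,
            "start_time": w.start_time,
            "label": (labels or {}).get(w.participant_id, w.label),
            "fog_score": (fog_scores or {}).get(w.participant_id, np.nan),
        }
        rows.append({**meta, **dict(zip(fv.names, fv.values))})
    return pd.DataFrame(rows)
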