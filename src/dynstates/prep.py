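"""Post-processing of network component time courses.

The chain mirrors standard group-ICA time-course cleanup for resting-state
fMRI: discard equilibration volumes, remove polynomial trends (orders 1-3
plus the mean), regress the six realignment parameters and their temporal
derivatives, repair outliers detected by a median-absolute-deviation rule
with a cubic-spline fit through the clean samples, and low-pass filter with
a 0.15 Hz cutoff using a zero-phase Butterworth filter.

Spectral quality-control metrics used for component selection (low-frequency
power ratio and spectral dynamic range) are provided alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline


@dataclass
class PrepConfig:
    """Settings for the time-course post-processing chain."""

    detrend_orders: tuple[int, ...] = (1, 2, 3)
    regress_motion: bool = True
    mad_threshold: float = 3.5
    lowpass_cutoff_hz: float = 0.15
    filter_order: int = 5
    n_discard: int = 10

    def validate(self, tr_seconds: float) -> None:
        nyquist = 0.5 / tr_seconds
        if not 0 < self.lowpass_cutoff_hz < nyquist:
            raise ValueError(
                f"low-pass cutoff {self.lowpass_cutoff_hz} Hz must lie below "
                f"Nyquist {nyquist} Hz"
            )
        if self.mad_threshold <= 0:
            raise ValueError("mad_threshold must be positive")


@dataclass
class SpectralQCMetrics:
    """Spectral component-selection metrics for one time course."""

    component: str
    low_freq_ratio: float  # power below 0.1 Hz over power in 0.15-0.25 Hz
    dynamic_range: float  # max spectral power minus min spectral power
    passes_low_freq: bool = field(default=False)
    passes_dynamic_range: bool = field(default=False)


def _poly_design(T: int, orders) -> np.ndarray:
    # time scaled to [-1, 1] for conditioning; intercept always included
    t = np.linspace(-1.0, 1.0, T)
    cols = [np.ones(T)] + [t**o for o in sorted(set(orders))]
    return np.column_stack(cols)


def detrend_polynomial(series, orders=(1, 2, 3)) -> np.ndarray:
    """Remove the least-squares polynomial trend (mean plus given orders)."""
    x = np.asarray(series, dtype=float)
    if x.size <= max(orders, default=0) + 1:
        raise ValueError("series too short for requested polynomial orders")
    X = _poly_design(x.size, orders)
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    return x - X @ beta


def motion_design(motion: np.ndarray) -> np.ndarray:
    """Stack motion parameters with their backward-difference derivatives.

    The first row of each derivative column is zero.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion must be a T x 6 matrix")
    dm = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
    return np.hstack([m, dm])


def regress_nuisance(series, motion) -> np.ndarray:
    """Regress out motion parameters and their temporal derivatives.

    Returns the residual of the series after projecting onto the 12-column
    motion design plus an intercept. Rank-deficient designs are handled by
    the pseudo-inverse with a warning.
    """
    x = np.asarray(series, dtype=float)
    X = np.hstack([np.ones((x.size, 1)), motion_design(motion)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudo-inverse")
    beta = np.linalg.pinv(X) @ x
    return x - X @ beta


def despike_mad_spline(series, threshold: float = 3.5):
    """Flag outliers by the MAD rule and repair them with a cubic spline.

    A sample is flagged when ``|x - median| > threshold * 1.4826 * MAD``.
    Flagged samples are replaced by a cubic spline fit through the
    unflagged samples only; unflagged samples are returned unchanged.

    Returns ``(repaired, mask)`` where ``mask`` marks flagged samples.
    A zero MAD (degenerate scale) flags nothing. More than half the
    series flagged raises an error.
    """
    x = np.asarray(series, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    mask = np.zeros(x.size, dtype=bool)
    if mad == 0:
        return x.copy(), mask
    mask = np.abs(x - med) > threshold * 1.4826 * mad
    if not mask.any():
        return x.copy(), mask
    if mask.sum() > 0.5 * x.size:
        raise ValueError("more than half of the samples flagged as outliers")
    clean_idx = np.flatnonzero(~mask)
    if clean_idx.size < 8:
        raise ValueError("fewer than 8 clean samples; cannot fit spline")
    spline = CubicSpline(clean_idx, x[clean_idx])
    repaired = x.copy()
    repaired[mask] = spline(np.flatnonzero(mask))
    return repaired, mask


def lowpass_filter(series, cutoff_hz: float, tr_seconds: float, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (forward-backward)."""
    x = np.asarray(series, dtype=float)
    nyquist = 0.5 / tr_seconds
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz")
    sos = signal.butter(order, cutoff_hz / nyquist, btype="low", output="sos")
    return signal.sosfiltfilt(sos, x)


def spectral_qc(series, tr_seconds: float, component: str = "") -> SpectralQCMetrics:
    """Periodogram-based component-selection metrics.

    ``low_freq_ratio`` integrates power over [0, 0.1) Hz and divides by the
    power in [0.15, 0.25] Hz (truncated to Nyquist with a warning if the
    sampling rate does not reach 0.25 Hz). ``dynamic_range`` is the
    difference between the maximum and minimum spectral power.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for a stable spectrum")
    fs = 1.0 / tr_seconds
    freqs, power = signal.periodogram(x, fs=fs)
    hi_upper = 0.25
    if freqs[-1] < 0.25:
        warnings.warn("Nyquist below 0.25 Hz; truncating the high band")
        hi_upper = freqs[-1]
    low = power[freqs < 0.1].sum()
    hi_band = (freqs >= 0.15) & (freqs <= hi_upper)
    high = power[hi_band].sum()
    ratio = float(low / high) if high > 0 else np.inf
    dyn = float(power.max() - power.min())
    return SpectralQCMetrics(
        component=component,
        low_freq_ratio=ratio,
        dynamic_range=dyn,
        passes_low_freq=ratio > 1.0,
        passes_dynamic_range=dyn > 0.0,
    )


def preprocess_subject(
    data: np.ndarray,
    tr_seconds: float,
    motion: np.ndarray | None = None,
    config: PrepConfig | None = None,
) -> np.ndarray:
    """Run the full post-processing chain on a T x C component matrix.

    Order: discard first ``n_discard`` volumes, detrend, motion regression
    (when motion parameters are available), despike, low-pass filter.
    """
    cfg = config or PrepConfig()
    cfg.validate(tr_seconds)
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a T x C matrix")
    if cfg.n_discard >= X.shape[0]:
        raise ValueError("n_discard leaves no volumes to analyse")
    X = X[cfg.n_discard :]
    mot = None if motion is None else np.asarray(motion, dtype=float)[cfg.n_discard :]
    out = np.empty_like(X)
    for c in range(X.shape[1]):
        x = detrend_polynomial(X[:, c], cfg.detrend_orders)
        if cfg.regress_motion and mot is not None:
            x = regress_nuisance(x, mot)
        x, _ = despike_mad_spline(x, cfg.mad_threshold)
        x = lowpass_filter(x, cfg.lowpass_cutoff_hz, tr_seconds, cfg.filter_order)
        out[:, c] = x
    return out
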