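"""Seed-to-seed resting-state functional connectivity with motion cleaning.

The cleaning chain applied to a (volumes x ROIs) matrix sampled at TR 2 s:

1. linear + quadratic detrending,
2. regression of the six rigid-body motion parameters,
3. framewise-displacement (FD) scrubbing mask, FD > 0.5 mm,
4. linear interpolation across masked volumes (so the filter never sees
   spike transients),
5. zero-phase FIR band-pass, 0.01-0.08 Hz,
6. optional nuisance regression (e.g. white-matter / CSF reference signals),
7. masked volumes dropped, Pearson correlation per ROI pair, Fisher z.

FD follows the backward-difference convention: the sum of absolute
translation increments (mm) plus absolute rotation increments converted to
arc length on a 50 mm sphere.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import signal

DEFAULT_BAND = (0.01, 0.08)
FD_THRESHOLD = 0.5
HEAD_RADIUS_MM = 50.0


@dataclasses.dataclass(frozen=True)
class ConnectivityResult:
    roi_a: str
    roi_b: str
    r: float
    z: float  # Fisher z = atanh(r)
    n_volumes: int
    n_scrubbed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def framewise_displacement(
    motion: np.ndarray, head_radius: float = HEAD_RADIUS_MM
) -> np.ndarray:
    """Per-volume FD from a (volumes x 6) motion table.

    Columns 0-2 are translations in mm, columns 3-5 rotations in degrees;
    rotations contribute arc length radius * angle(rad).  FD of the first
    volume is defined as 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have six columns (3 trans mm, 3 rot deg)")
    d = np.abs(np.diff(motion, axis=0))
    trans = d[:, :3].sum(axis=1)
    rot = np.deg2rad(d[:, 3:]).sum(axis=1) * head_radius
    fd = np.concatenate([[0.0], trans + rot])
    return fd


def scrub_mask(fd: np.ndarray, threshold: float = FD_THRESHOLD) -> np.ndarray:
    """Boolean keep-mask: True where FD <= threshold."""
    fd = np.asarray(fd, dtype=float)
    keep = fd <= threshold
    if keep.sum() < 0.5 * len(fd):
        raise ValueError(
            f"scrubbing removed {len(fd) - keep.sum()} of {len(fd)} volumes; "
            "series unusable (>50% above threshold)"
        )
    return keep


def detrend_linquad(series: np.ndarray) -> np.ndarray:
    """Remove per-column linear and quadratic trends (with intercept)."""
    y = np.atleast_2d(np.asarray(series, dtype=float).T).T
    n = y.shape[0]
    t = np.linspace(-1.0, 1.0, n)
    X = np.column_stack([np.ones(n), t, t**2])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def nuisance_regress(series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residualise each column of ``series`` against ``regressors`` (+intercept).

    Residuals are orthogonal to every regressor column.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float).T).T
    R = np.atleast_2d(np.asarray(regressors, dtype=float).T).T
    if R.shape[0] != y.shape[0]:
        raise ValueError("regressors and series must have equal length")
    X = np.column_stack([np.ones(y.shape[0]), R])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("nuisance regressor set is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def bandpass(
    series: np.ndarray,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    tr: float = 2.0,
    numtaps: int = 79,
) -> np.ndarray:
    """Zero-phase FIR band-pass (Hamming window, applied forward-backward).

    ``numtaps`` must satisfy the filtfilt padding requirement
    3*(numtaps-1) < n_volumes; the default 79 suits 240-volume series.
    """
    fs = 1.0 / tr
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz)")
    y = np.atleast_2d(np.asarray(series, dtype=float).T).T
    if y.shape[0] <= 3 * (numtaps - 1):
        raise ValueError("series too short for the filter order")
    taps = signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs)
    taps -= taps.mean()  # force exactly zero DC gain
    return signal.filtfilt(taps, [1.0], y, axis=0)


def _interpolate_masked(series: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Linearly interpolate masked volumes per column (edges held constant)."""
    y = series.copy()
    if keep.all():
        return y
    idx = np.arange(len(keep))
    for j in range(y.shape[1]):
        y[~keep, j] = np.interp(idx[~keep], idx[keep], y[keep, j])
    return y


def clean_series(
    series: np.ndarray,
    motion: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
    tr: float = 2.0,
    fd_threshold: float = FD_THRESHOLD,
    head_radius: float = HEAD_RADIUS_MM,
    band: tuple[float, float] = DEFAULT_BAND,
    interpolate_scrubbed: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full cleaning chain; returns (cleaned series, keep mask).

    The returned series still contains the masked volumes (interpolated or
    raw); correlation steps must apply the mask.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float).T).T
    y = detrend_linquad(y)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        y = nuisance_regress(y, detrend_linquad(motion))
        fd = framewise_displacement(motion, head_radius)
        keep = scrub_mask(fd, fd_threshold)
    else:
        keep = np.ones(y.shape[0], dtype=bool)
    if interpolate_scrubbed:
        y = _interpolate_masked(y, keep)
    y = bandpass(y, band[0], band[1], tr)
    if nuisance is not None:
        y = nuisance_regress(y, nuisance)
    return y, keep


def seed_connectivity(
    series: np.ndarray,
    roi_a: int | str,
    roi_b: int | str,
    mask: np.ndarray | None = None,
    roi_names: list[str] | None = None,
    min_volumes: int = 30,
) -> ConnectivityResult:
    """Pearson r between two cleaned ROI series over unmasked volumes, plus Fisher z."""
    y = np.asarray(series, dtype=float)
    names = roi_names or [f"roi{i}" for i in range(y.shape[1])]
    ia = names.index(roi_a) if isinstance(roi_a, str) else int(roi_a)
    ib = names.index(roi_b) if isinstance(roi_b, str) else int(roi_b)
    if ia == ib:
        raise ValueError("self-connectivity is not meaningful (roi_a == roi_b)")
    keep = np.ones(y.shape[0], dtype=bool) if mask is None else np.asarray(mask, bool)
    n = int(keep.sum())
    if n < min_volumes:
        raise ValueError(f"only {n} usable volumes; need at least {min_volumes}")
    a, b = y[keep, ia], y[keep, ib]
    r = float(np.corrcoef(a, b)[0, 1])
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    return ConnectivityResult(
        roi_a=names[ia],
        roi_b=names[ib],
        r=r,
        z=float(np.arctanh(r)),
        n_volumes=n,
        n_scrubbed=int((~keep).sum()),
    )


def connectivity_matrix(
    series: np.ndarray,
    motion: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
    roi_names: list[str] | None = None,
    tr: float = 2.0,
    **clean_kwargs,
) -> list[ConnectivityResult]:
    """Clean a resting series and return connectivity for every ROI pair."""
    y = np.atleast_2d(np.asarray(series, dtype=float).T).T
    names = roi_names or [f"roi{i}" for i in range(y.shape[1])]
    cleaned, keep = clean_series(y, motion=motion, nuisance=nuisance, tr=tr, **clean_kwargs)
    return [
        seed_connectivity(cleaned, a, b, mask=keep, roi_names=names)
        for a, b in itertools.combinations(range(len(names)), 2)
    ]
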