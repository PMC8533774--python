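"""Variable-flip-angle T1 mapping and relative-enhancement computation.

The signal model is the spoiled gradient-echo (SPGR) equation

    S(a) = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),   E1 = exp(-TR / T1).

Pixel-wise fitting initializes T1 and M0 from the linearized form
(S/sin a against S/tan a; the slope is E1) and refines both parameters by
bounded nonlinear least squares on the SPGR model.  The default
acquisition uses flip angles 2/5/15/20/25 degrees at TR 7.92 ms.  After a
hepatobiliary contrast agent, uptake is summarized as the relative
enhancement RE = (T1pre - T1post) / T1pre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FLIP_ANGLES_DEG = (2.0, 5.0, 15.0, 20.0, 25.0)
DEFAULT_TR_MS = 7.92
T1_BOUNDS_MS = (1.0, 10000.0)


@dataclass
class VfaStack:
    signals: np.ndarray              # (angles, rows, cols)
    flip_angles_deg: tuple
    tr_ms: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        angles = np.asarray(self.flip_angles_deg, dtype=float)
        if self.signals.ndim != 3 or self.signals.shape[0] != len(angles):
            raise ValueError("signals must be (n_angles, rows, cols)")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("flip angles must be strictly increasing")
        if np.any(angles <= 0) or np.any(angles > 90):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")
        if self.mask is None:
            self.mask = np.ones(self.signals.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class T1Map:
    t1_ms: np.ndarray
    m0: np.ndarray
    fit_error: np.ndarray
    valid: np.ndarray


@dataclass
class REMap:
    re: np.ndarray
    dt1_ms: np.ndarray
    valid: np.ndarray


def spgr_signal(t1_ms, m0, alpha_deg, tr_ms):
    """Closed-form SPGR signal; inputs may be scalars or arrays."""
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    if tr_ms <= 0:
        raise ValueError("TR must be positive")
    if not (0 < alpha_deg <= 90):
        raise ValueError("flip angle must lie in (0, 90] degrees")
    a = np.deg2rad(alpha_deg)
    e1 = np.exp(-tr_ms / t1)
    return np.asarray(m0, dtype=float) * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))


def _linear_init(S, sin_a, tan_a):
    """DESPOT1-style linearization: slope of S/sin a on S/tan a equals E1."""
    y = S / sin_a[None, :]
    x = S / tan_a[None, :]
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=1)
    sxy = ((x - xm) * (y - ym)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, np.nan)
    intercept = ym[:, 0] - slope * xm[:, 0]
    return slope, intercept


def fit_t1_vfa(
    stack: VfaStack,
    signal_floor_frac: float = 0.01,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> T1Map:
    """Pixel-wise T1/M0 fit of an SPGR stack.

    Pixels whose maximum signal is below ``signal_floor_frac`` of the stack
    maximum, or whose linearized slope falls outside (0, 1), are marked
    invalid.  Refinement is a bounds-clipped Gauss-Newton iteration on
    (T1, M0) with T1 confined to [1, 10000] ms.
    """
    angles = np.asarray(stack.flip_angles_deg, dtype=float)
    if len(angles) < 3:
        raise ValueError("T1 fitting requires at least 3 flip angles")
    tr = stack.tr_ms
    a_rad = np.deg2rad(angles)
    sin_a, cos_a, tan_a = np.sin(a_rad), np.cos(a_rad), np.tan(a_rad)

    shape = stack.signals.shape[1:]
    S_all = stack.signals.reshape(len(angles), -1).T  # (P, A)
    peak = S_all.max()
    floor = signal_floor_frac * peak if peak > 0 else 0.0
    candidate = stack.mask.ravel() & (S_all.max(axis=1) >= floor) & (floor > 0)

    t1 = np.full(S_all.shape[0], np.nan)
    m0 = np.full(S_all.shape[0], np.nan)
    err = np.full(S_all.shape[0], np.nan)
    valid = np.zeros(S_all.shape[0], dtype=bool)

    if candidate.any():
        S = S_all[candidate]
        slope, intercept = _linear_init(S, sin_a, tan_a)
        ok = np.isfinite(slope) & (slope > 0) & (slope < 1)
        t1_c = np.full(S.shape[0], np.nan)
        m0_c = np.full(S.shape[0], np.nan)
        if ok.any():
            t1_0 = np.clip(-tr / np.log(slope[ok]), *T1_BOUNDS_MS)
            m0_0 = np.maximum(intercept[ok] / (1 - slope[ok]), 1e-12)
            t1_k, m0_k = t1_0.copy(), m0_0.copy()
            Sk = S[ok]
            for _ in range(max_iter):
                e1 = np.exp(-tr / t1_k)[:, None]
                denom = 1 - e1 * cos_a[None, :]
                model = m0_k[:, None] * sin_a[None, :] * (1 - e1) / denom
                resid = model - Sk
                dS_dE1 = m0_k[:, None] * sin_a[None, :] * (cos_a[None, :] - 1) / denom**2
                dE1_dT1 = (e1[:, 0] * tr / t1_k**2)[:, None]
                J1 = dS_dE1 * dE1_dT1
                J2 = model / m0_k[:, None]
                a11 = (J1 * J1).sum(axis=1) + 1e-12
                a12 = (J1 * J2).sum(axis=1)
                a22 = (J2 * J2).sum(axis=1) + 1e-12
                g1 = (J1 * resid).sum(axis=1)
                g2 = (J2 * resid).sum(axis=1)
                det = a11 * a22 - a12**2
                det = np.where(np.abs(det) > 1e-300, det, 1e-300)
                d_t1 = (a22 * g1 - a12 * g2) / det
                d_m0 = (a11 * g2 - a12 * g1) / det
                d_t1 = np.clip(d_t1, -0.5 * t1_k, 0.5 * t1_k)  # trust region
                t1_new = np.clip(t1_k - d_t1, *T1_BOUNDS_MS)
                m0_new = np.maximum(m0_k - d_m0, 1e-12)
                step = np.abs(t1_new - t1_k) / t1_k
                t1_k, m0_k = t1_new, m0_new
                if step.max() < tol:
                    break
            e1 = np.exp(-tr / t1_k)[:, None]
            model = m0_k[:, None] * sin_a[None, :] * (1 - e1) / (1 - e1 * cos_a[None, :])
            rms = np.sqrt(((model - Sk) ** 2).mean(axis=1))
            t1_c[ok], m0_c[ok] = t1_k, m0_k
            idx = np.flatnonzero(candidate)
            err[idx[ok]] = rms
        t1[candidate] = t1_c
        m0[candidate] = m0_c
        v = candidate.copy()
        v[candidate] = ok & np.isfinite(t1_c) & np.isfinite(m0_c)
        valid = v

    return T1Map(
        t1_ms=t1.reshape(shape),
        m0=m0.reshape(shape),
        fit_error=err.reshape(shape),
        valid=valid.reshape(shape),
    )


def relative_enhancement(t1_pre: T1Map, t1_post: T1Map) -> REMap:
    """RE = (T1pre - T1post) / T1pre, defined where both maps are valid."""
    if t1_pre.t1_ms.shape != t1_post.t1_ms.shape:
        raise ValueError("pre and post maps must share a shape")
    valid = t1_pre.valid & t1_post.valid & (t1_pre.t1_ms > 0)
    dt1 = np.where(valid, t1_pre.t1_ms - t1_post.t1_ms, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        re = np.where(valid, dt1 / t1_pre.t1_ms, np.nan)
    return REMap(re=re, dt1_ms=dt1, valid=valid)


def _map_values(map_or_array):
    if isinstance(map_or_array, T1Map):
        return map_or_array.t1_ms, map_or_array.valid
    if isinstance(map_or_array, REMap):
        return map_or_array.re, map_or_array.valid
    arr = np.asarray(map_or_array, dtype=float)
    return arr, np.isfinite(arr)


def roi_stats(map_or_array, rois: dict) -> pd.DataFrame:
    """Mean, SD and pixel count per ROI over valid pixels only.

    ``rois`` maps ROI name to a boolean mask of the map's shape.
    """
    values, valid = _map_values(map_or_array)
    rows = []
    for name, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError(f"ROI {name!r} shape does not match the map")
        sel = values[mask & valid]
        if sel.size == 0:
            raise ValueError(f"ROI {name!r} contains no valid pixels")
        rows.append((name, sel.mean(), sel.std(ddof=0), sel.size))
    return pd.DataFrame(rows, columns=["roi", "mean", "sd", "n"]).set_index("roi")


def roi_timecourse(dynamic_series, rois: dict, timestamps=None) -> pd.DataFrame:
    """Mean signal per ROI per frame, ordered by time.

    ``dynamic_series`` is (frames, rows, cols).  Without timestamps the
    frame index is used (with a warning).
    """
    series = np.asarray(dynamic_series, dtype=float)
    if series.ndim != 3:
        raise ValueError("dynamic series must be (frames, rows, cols)")
    if timestamps is None:
        warnings.warn("no timestamps provided; using frame indices", stacklevel=2)
        timestamps = np.arange(series.shape[0], dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) != series.shape[0]:
        raise ValueError("one timestamp per frame required")
    order = np.argsort(timestamps, kind="stable")
    data = {}
    for name, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != series.shape[1:]:
            raise ValueError(f"ROI {name!r} shape does not match the frames")
        if not mask.any():
            raise ValueError(f"ROI {name!r} is empty")
        data[name] = series[order][:, mask].mean(axis=1)
    return pd.DataFrame(data, index=pd.Index(timestamps[order], name="time_s"))
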