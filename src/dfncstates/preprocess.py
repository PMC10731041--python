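"""Quality control and postprocessing of component time courses.

Inputs are per-subject matrices of independent-component (IC) signals —
one column per component, one row per repetition time (TR).  The stages
here mirror the standard resting-state dFNC preparation: discard of
initial equilibration frames, head-motion screening on rigid-body
realignment parameters, despiking, detrending, low-pass filtering, and
the static (whole-scan) functional network connectivity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ComponentTimeSeries",
    "TimecoursePreprocessor",
    "discard_initial_frames",
    "frame_displacement",
    "motion_exclude",
    "despike",
    "lowpass_filter",
    "static_fnc",
    "load_timecourse_tsv",
]

#: Fisher transform clamp: |r| is pulled away from 1 by this margin so z stays finite.
R_CLAMP = 1.0 - 1e-12


@dataclass
class ComponentTimeSeries:
    """One subject's T×C matrix of component signals sampled every ``tr_seconds``."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    component_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (T x C) array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in time courses of {self.subject_id!r}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.component_ids:
            self.component_ids = [f"IC{j + 1}" for j in range(self.data.shape[1])]
        if len(self.component_ids) != self.data.shape[1]:
            raise ValueError("component_ids length must match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


def load_timecourse_tsv(path, subject_id: str, tr_seconds: float, header: bool = True) -> ComponentTimeSeries:
    """Read a TSV time-course matrix (rows = TRs, columns = components)."""
    df = pd.read_csv(path, sep="\t", header=0 if header else None)
    ids = [str(c) for c in df.columns] if header else []
    return ComponentTimeSeries(subject_id, df.to_numpy(dtype=float), tr_seconds, ids)


def load_motion_tsv(path, rotation_unit: str = "rad") -> np.ndarray:
    """Read a 6-column rigid-body motion file (x, y, z mm; pitch, roll, yaw).

    ``rotation_unit`` must be given explicitly ('rad' or 'deg'); degree
    rotations are converted so downstream code always sees radians.
    """
    if rotation_unit not in ("rad", "deg"):
        raise ValueError("rotation_unit must be 'rad' or 'deg'")
    m = pd.read_csv(path, sep=r"\s+", header=None).to_numpy(dtype=float)
    if m.shape[1] != 6:
        raise ValueError(f"motion file must have 6 columns, got {m.shape[1]}")
    if rotation_unit == "deg":
        m = m.copy()
        m[:, 3:] = np.radians(m[:, 3:])
    return m


def motion_qc_report(
    motion: np.ndarray,
    mean_fd_limit: float = 0.5,
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 3.0,
) -> dict:
    """Per-subject QC summary: mean FD, motion extremes and keep decision."""
    fd = frame_displacement(motion)
    keep, reasons = motion_exclude(
        fd, motion, mean_fd_limit, max_translation_mm, max_rotation_deg
    )
    return {
        "mean_fd": float(np.mean(fd)),
        "max_translation": float(np.max(np.abs(motion[:, :3]))),
        "max_rotation_deg": float(np.degrees(np.max(np.abs(motion[:, 3:])))),
        "kept": keep,
        "reasons": reasons,
    }


def discard_initial_frames(series: ComponentTimeSeries, n_discard: int) -> ComponentTimeSeries:
    """Drop the first ``n_discard`` rows (scanner equilibration frames)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= series.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_timepoints} frames"
        )
    return replace(series, data=series.data[n_discard:].copy())


def frame_displacement(motion: np.ndarray, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Power's frame displacement from 6 rigid-body parameters.

    ``motion`` is F×6: three translations (mm) then three rotations
    (radians).  Rotations are converted to arc length on a sphere of
    ``rotation_radius_mm``.  The first frame has FD 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be an F x 6 array (3 translations, 3 rotations)")
    if motion.shape[0] < 2:
        raise ValueError("frame displacement needs at least 2 frames")
    if not np.all(np.isfinite(motion)):
        raise ValueError("non-finite motion parameters")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def motion_exclude(
    fd: np.ndarray,
    raw_motion: np.ndarray,
    mean_fd_limit: float = 0.5,
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 3.0,
) -> tuple[bool, list[str]]:
    """Keep/drop decision from motion QC; thresholds are strict (``>``).

    Returns ``(keep, reasons)`` where ``reasons`` lists every violated rule.
    A subject sitting exactly at a limit is kept.
    """
    raw_motion = np.asarray(raw_motion, dtype=float)
    reasons = []
    mean_fd = float(np.mean(fd))
    max_trans = float(np.max(np.abs(raw_motion[:, :3])))
    max_rot_deg = float(np.degrees(np.max(np.abs(raw_motion[:, 3:]))))
    if mean_fd > mean_fd_limit:
        reasons.append(f"mean FD {mean_fd:.3f} mm > {mean_fd_limit} mm")
    if max_trans > max_translation_mm:
        reasons.append(f"max translation {max_trans:.2f} mm > {max_translation_mm} mm")
    if max_rot_deg > max_rotation_deg:
        reasons.append(f"max rotation {max_rot_deg:.2f} deg > {max_rotation_deg} deg")
    return (len(reasons) == 0, reasons)


def _robust_linear_trend(x: np.ndarray, n_iter: int = 25, eps: float = 1e-8) -> np.ndarray:
    """Least-absolute-deviations straight line via iteratively reweighted LS."""
    t = np.arange(x.size, dtype=float)
    A = np.column_stack([np.ones_like(t), t])
    w = np.ones_like(x)
    beta = np.zeros(2)
    for _ in range(n_iter):
        Aw = A * w[:, None]
        beta_new, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ x, rcond=None)
        if np.allclose(beta_new, beta, atol=1e-12, rtol=0.0):
            beta = beta_new
            break
        beta = beta_new
        w = 1.0 / np.maximum(np.abs(x - A @ beta), eps)
    return A @ beta


def despike(series: ComponentTimeSeries, c1: float = 2.5, c2: float = 4.0) -> ComponentTimeSeries:
    """Compress outlying samples toward a robust linear trend.

    Per component: fit an L1 straight-line trend, estimate the residual
    scale as 1.4826·MAD, and map residuals with |r|/σ̂ > ``c1`` to
    sign(r)·σ̂·(c1 + (c2−c1)·tanh((|r|/σ̂ − c1)/(c2 − c1))), a smooth
    compression bounded by ``c2``·σ̂.  Samples inside the band, and
    components with zero residual scale, pass through unchanged.
    """
    if series.n_timepoints < 5:
        raise ValueError("despike needs at least 5 timepoints")
    if not (0 < c1 < c2):
        raise ValueError("need 0 < c1 < c2")
    out = series.data.copy()
    for j in range(series.n_components):
        x = series.data[:, j]
        trend = _robust_linear_trend(x)
        resid = x - trend
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if sigma == 0.0:
            continue
        s = resid / sigma
        spikes = np.abs(s) > c1
        if not spikes.any():
            continue
        a = np.abs(s[spikes])
        compressed = c1 + (c2 - c1) * np.tanh((a - c1) / (c2 - c1))
        out[spikes, j] = trend[spikes] + np.sign(s[spikes]) * compressed * sigma
    return replace(series, data=out)


def lowpass_filter(series: ComponentTimeSeries, cutoff_hz: float = 0.15, order: int = 5) -> ComponentTimeSeries:
    """Zero-phase Butterworth low-pass after linear detrending.

    The detrend supplies the low-frequency (drift) end of the band-pass;
    the filter is applied forward-backward so no phase is introduced.
    """
    fs = 1.0 / series.tr_seconds
    nyquist = fs / 2.0
    if not (0 < cutoff_hz < nyquist):
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie below Nyquist {nyquist} Hz")
    x = signal.detrend(series.data, axis=0, type="linear")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=fs)
    y = signal.filtfilt(b, a, x, axis=0)
    return replace(series, data=y)


def static_fnc(series: ComponentTimeSeries) -> np.ndarray:
    """Whole-scan Fisher-z connectivity matrix (C×C, zero diagonal).

    Pairs involving a constant component are set to 0 with a warning;
    |r| is clamped to ``R_CLAMP`` so z stays finite for collinear pairs.
    """
    if series.n_timepoints < 3:
        raise ValueError("static FNC needs at least 3 timepoints")
    x = series.data
    sd = x.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    if constant.any():
        warnings.warn(
            f"constant components {np.flatnonzero(constant).tolist()} in "
            f"{series.subject_id!r}: their correlations set to 0",
            stacklevel=2,
        )
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    near_one = np.abs(r) >= R_CLAMP
    np.fill_diagonal(near_one, False)
    if near_one.any():
        warnings.warn("correlations at ±1 clamped before Fisher transform", stacklevel=2)
    z = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0


class TimecoursePreprocessor(BaseEstimator, TransformerMixin):
    """Fixed-order postprocessing: discard → despike → detrend + low-pass.

    A stateless transformer over T×C arrays (or :class:`ComponentTimeSeries`);
    ``fit`` only validates parameters so the class composes with sklearn
    pipelines.

    Parameters
    ----------
    tr_seconds : sampling interval, used only when transforming bare arrays.
    n_discard : initial frames to drop (0 for series already trimmed).
    despike_c1, despike_c2 : spike flag / ceiling thresholds in robust-σ units.
    lowpass_hz : low-pass cutoff; linear detrend is always applied first.
    """

    def __init__(
        self,
        tr_seconds: float = 2.5,
        n_discard: int = 0,
        despike_c1: float = 2.5,
        despike_c2: float = 4.0,
        lowpass_hz: float = 0.15,
    ):
        self.tr_seconds = tr_seconds
        self.n_discard = n_discard
        self.despike_c1 = despike_c1
        self.despike_c2 = despike_c2
        self.lowpass_hz = lowpass_hz

    def fit(self, X=None, y=None):
        if self.lowpass_hz >= 0.5 / self.tr_seconds:
            raise ValueError("lowpass_hz must be below Nyquist")
        self.stages_ = ["discard", "despike", "detrend+lowpass"]
        return self

    def transform_series(self, series: ComponentTimeSeries) -> ComponentTimeSeries:
        out = discard_initial_frames(series, self.n_discard) if self.n_discard else series
        out = despike(out, self.despike_c1, self.despike_c2)
        return lowpass_filter(out, self.lowpass_hz)

    def transform(self, X):
        if isinstance(X, ComponentTimeSeries):
            return self.transform_series(X)
        series = ComponentTimeSeries("array", np.asarray(X, dtype=float), self.tr_seconds)
        return self.transform_series(series).data
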