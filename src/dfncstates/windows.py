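"""Tapered sliding-window functional network connectivity.

The window is a rectangle convolved with a Gaussian kernel (giving a
smooth taper), slid along the time axis in fixed TR steps.  Within every
window a *weighted* Pearson correlation matrix is computed — the taper
weights act as observation weights, so the estimate is invariant to
affine rescaling of the signals — and Fisher z-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import R_CLAMP, ComponentTimeSeries

__all__ = [
    "WindowSpec",
    "WindowedFNCSeries",
    "SlidingWindowFNC",
    "window_count",
    "width_from_seconds",
    "make_taper",
    "windowed_fnc",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: width and Gaussian taper σ in TRs."""

    width_tr: int = 18
    gaussian_sigma_tr: float = 3.0
    step_tr: int = 1
    tr_seconds: float = 2.5

    def __post_init__(self) -> None:
        if self.width_tr < 2:
            raise ValueError("window width must be at least 2 TRs")
        if self.step_tr < 1:
            raise ValueError("step must be at least 1 TR")
        if self.gaussian_sigma_tr <= 0:
            raise ValueError("gaussian sigma must be positive")

    @property
    def width_seconds(self) -> float:
        return self.width_tr * self.tr_seconds


def width_from_seconds(seconds: float, tr_seconds: float) -> int:
    """Window width in TRs for a target duration (45 s at TR 2.5 s → 18)."""
    w = int(round(seconds / tr_seconds))
    if w < 2:
        raise ValueError("window shorter than 2 TRs")
    return w


def window_count(n_timepoints: int, width_tr: int, step_tr: int = 1) -> int:
    """Number of windows: floor((T − W) / step).

    Start indices run over 0 .. T−W−1 (the last full-length start, T−W,
    is not used); this convention yields 212 windows for T=230, W=18,
    step=1 and matches the count produced by the standard dFNC toolbox.
    """
    if n_timepoints <= width_tr:
        raise ValueError(
            f"need more timepoints ({n_timepoints}) than window width ({width_tr})"
        )
    return (n_timepoints - width_tr) // step_tr


@dataclass(frozen=True)
class TaperedWindow:
    weights: np.ndarray


def make_taper(spec: WindowSpec) -> TaperedWindow:
    """Rectangle ⊛ Gaussian taper, truncated at ±4σ, normalized to sum 1."""
    w = spec.width_tr
    radius = max(1, int(np.ceil(4 * spec.gaussian_sigma_tr)))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / spec.gaussian_sigma_tr) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(w), kernel, mode="full")  # length w + 2*radius
    weights = full[radius : radius + w]
    weights = weights / weights.sum()
    return TaperedWindow(weights)


@dataclass
class WindowedFNCSeries:
    """Per-subject sequence of windowed Fisher-z connectivity matrices."""

    subject_id: str
    matrices: np.ndarray  # N_w x C x C
    window_starts: np.ndarray  # 0-based inclusive start rows
    spec: WindowSpec

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_components(self) -> int:
        return self.matrices.shape[1]

    def save(self, path) -> None:
        """Compressed array store plus a JSON sidecar with the geometry."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), matrices=self.matrices,
                            window_starts=self.window_starts)
        sidecar = {"subject_id": self.subject_id, "spec": asdict(self.spec)}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "WindowedFNCSeries":
        import json
        from pathlib import Path

        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            sidecar["subject_id"], arrays["matrices"], arrays["window_starts"],
            WindowSpec(**sidecar["spec"]),
        )


def _weighted_windowed_corr(data: np.ndarray, starts: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized weighted Pearson correlation for every window."""
    w = weights / weights.sum()
    segs = sliding_window_view(data, len(w), axis=0)[starts]  # N x C x W
    mu = segs @ w
    dev = segs - mu[..., None]
    cov = np.einsum("ncw,w,ndw->ncd", dev, w, dev, optimize=True)
    var = np.einsum("ncc->nc", cov)
    bad = var <= 1e-14
    denom = np.sqrt(np.einsum("nc,nd->ncd", var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / denom
    if bad.any():
        warnings.warn(
            "window with zero weighted variance: affected correlations set to 0",
            stacklevel=3,
        )
        mask = bad[:, :, None] | bad[:, None, :]
        corr[mask] = 0.0
    return corr


def windowed_fnc(
    series: ComponentTimeSeries,
    spec: WindowSpec | None = None,
    fisher_z: bool = True,
) -> WindowedFNCSeries:
    """Tapered sliding-window connectivity series for one subject.

    Window t covers rows [t·step, t·step + W); correlations are weighted
    by the taper and, by default, clamped away from ±1 and Fisher
    z-transformed (``fisher_z=False`` keeps raw r for clustering on the
    correlation scale instead), with a zero diagonal.
    """
    spec = spec or WindowSpec(tr_seconds=series.tr_seconds)
    n = window_count(series.n_timepoints, spec.width_tr, spec.step_tr)
    starts = np.arange(n) * spec.step_tr
    taper = make_taper(spec)
    corr = _weighted_windowed_corr(series.data, starts, taper.weights)
    if fisher_z:
        corr = np.arctanh(np.clip(corr, -R_CLAMP, R_CLAMP))
    idx = np.arange(corr.shape[1])
    corr[:, idx, idx] = 0.0
    corr = (corr + corr.transpose(0, 2, 1)) / 2.0
    return WindowedFNCSeries(series.subject_id, corr, starts, spec)


class SlidingWindowFNC(BaseEstimator, TransformerMixin):
    """Transformer: T×C time-course array → N_w×C×C windowed z-matrices.

    Parameters mirror :class:`WindowSpec`.  ``fit`` computes the taper;
    ``transform`` accepts a 2-D array or a :class:`ComponentTimeSeries`.
    """

    def __init__(
        self,
        width_tr: int = 18,
        gaussian_sigma_tr: float = 3.0,
        step_tr: int = 1,
        tr_seconds: float = 2.5,
        fisher_z: bool = True,
    ):
        self.width_tr = width_tr
        self.gaussian_sigma_tr = gaussian_sigma_tr
        self.step_tr = step_tr
        self.tr_seconds = tr_seconds
        self.fisher_z = fisher_z

    def _spec(self) -> WindowSpec:
        return WindowSpec(self.width_tr, self.gaussian_sigma_tr, self.step_tr, self.tr_seconds)

    def fit(self, X=None, y=None):
        self.taper_weights_ = make_taper(self._spec()).weights
        return self

    def transform(self, X):
        if not isinstance(X, ComponentTimeSeries):
            X = ComponentTimeSeries("array", np.asarray(X, dtype=float), self.tr_seconds)
        return windowed_fnc(X, self._spec(), fisher_z=self.fisher_z).matrices
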