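"""Spectral screening of candidate component time courses.

Meaningful resting-state components are dominated by low-frequency
power.  Each candidate is scored by (a) the ratio of integrated spectral
power below 0.10 Hz to the 0.15–0.25 Hz band and (b) the dynamic range
of its spectrum — the drop from the peak power to the minimum power at
frequencies beyond the peak.  Components are kept when both scores clear
their thresholds.  Spatial-map criteria (gray-matter peak location,
artifact overlap) require spatial maps and are outside this module's
scope; network labels are supplied externally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SpectralQuality",
    "spectral_quality",
    "classify_components",
    "SpectralComponentSelector",
]

LOW_BAND_HZ = (0.0, 0.10)
HIGH_BAND_HZ = (0.15, 0.25)


@dataclass(frozen=True)
class SpectralQuality:
    """Spectral scores for one component."""

    low_high_ratio: float
    dynamic_range: float  # power units: peak minus post-peak minimum
    dynamic_range_relative: float  # dynamic range / total integrated power
    flagged: bool = False  # constant or otherwise unscorable


def _band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float, open_hi: bool) -> float:
    mask = (freqs >= lo) & ((freqs < hi) if open_hi else (freqs <= hi))
    if mask.sum() < 2:
        return float(psd[mask].sum()) if mask.any() else 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def spectral_quality(data: np.ndarray, tr_seconds: float) -> list[SpectralQuality]:
    """Welch-spectrum quality scores per component of a T×C matrix.

    Segments of min(T, 128) samples with 50% overlap and a Hann window;
    band integrals by the trapezoid rule over [0, 0.10) Hz and
    [0.15, 0.25] Hz (the latter truncated at Nyquist when TR > 2 s).
    Constant components are flagged with zero scores.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    t = data.shape[0]
    if t < 32:
        raise ValueError("spectral scoring needs at least 32 timepoints")
    fs = 1.0 / tr_seconds
    nperseg = min(t, 128)
    out = []
    for j in range(data.shape[1]):
        x = data[:, j]
        if np.std(x) == 0:
            out.append(SpectralQuality(0.0, 0.0, 0.0, flagged=True))
            continue
        freqs, psd = signal.welch(
            x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
        )
        low = _band_integral(freqs, psd, *LOW_BAND_HZ, open_hi=True)
        high = _band_integral(freqs, psd, *HIGH_BAND_HZ, open_hi=False)
        if high <= 0:
            warnings.warn(
                f"component {j}: no spectral mass in {HIGH_BAND_HZ} Hz band", stacklevel=2
            )
            ratio = np.inf
        else:
            ratio = low / high
        imax = int(np.argmax(psd))
        dyn = float(psd[imax] - psd[imax:].min())
        total = float(np.trapezoid(psd, freqs))
        out.append(SpectralQuality(float(ratio), dyn, dyn / total if total > 0 else 0.0))
    return out


def classify_components(
    qualities: list[SpectralQuality],
    ratio_threshold: float = 4.0,
    range_threshold: float = 0.025,
) -> np.ndarray:
    """Keep mask: ratio ≥ ratio_threshold AND relative dynamic range ≥ range_threshold.

    The dynamic-range rule uses the scale-invariant relative score
    (fraction of total integrated power), so the decision does not
    depend on signal units.  Flagged (constant) components are rejected.
    """
    if ratio_threshold < 0 or range_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    keep = np.array(
        [
            (not q.flagged)
            and q.low_high_ratio >= ratio_threshold
            and q.dynamic_range_relative >= range_threshold
            for q in qualities
        ]
    )
    return keep


class SpectralComponentSelector(BaseEstimator, TransformerMixin):
    """Transformer dropping components that fail the spectral criteria.

    ``fit`` scores every column of a T×C matrix; ``transform`` keeps the
    passing columns.  ``get_support()`` exposes the boolean keep mask.
    """

    def __init__(
        self,
        tr_seconds: float = 2.5,
        ratio_threshold: float = 4.0,
        range_threshold: float = 0.025,
    ):
        self.tr_seconds = tr_seconds
        self.ratio_threshold = ratio_threshold
        self.range_threshold = range_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.qualities_ = spectral_quality(X, self.tr_seconds)
        self.support_ = classify_components(
            self.qualities_, self.ratio_threshold, self.range_threshold
        )
        self.n_kept_ = int(self.support_.sum())
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "low_high_ratio": [q.low_high_ratio for q in self.qualities_],
                "dynamic_range": [q.dynamic_range for q in self.qualities_],
                "dynamic_range_relative": [q.dynamic_range_relative for q in self.qualities_],
                "flagged": [q.flagged for q in self.qualities_],
                "kept": self.support_,
            }
        )
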