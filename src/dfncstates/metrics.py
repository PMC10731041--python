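"""Temporal properties of per-subject state label sequences.

Fractional time (percent of windows in each state), mean dwell time
(average consecutive-window run length per state) and the number of
transitions between different states, plus per-state mean connectivity
strength used by the edgewise group contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import StateModel
from .windows import WindowedFNCSeries

__all__ = [
    "fractional_time",
    "mean_dwell_time",
    "n_transitions",
    "run_lengths",
    "temporal_metrics_table",
    "state_strength",
    "state_strength_tables",
]


def _check_labels(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("label sequence is empty")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    return labels


def fractional_time(labels: np.ndarray, k: int) -> np.ndarray:
    """Percent of windows spent in each state (length-k vector, sums to 100)."""
    labels = _check_labels(labels, k)
    counts = np.bincount(labels, minlength=k + 1)[1:]
    return 100.0 * counts / labels.size


def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encoding: (state of each run, length of each run)."""
    labels = np.asarray(labels, dtype=int)
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return labels[starts], ends - starts


def mean_dwell_time(labels: np.ndarray, k: int, unvisited: str = "zero") -> np.ndarray:
    """Mean consecutive-window run length per state.

    ``unvisited`` selects the convention for states the subject never
    enters: ``"zero"`` (default, keeps group tests balanced) or
    ``"missing"`` (NaN, excluded from comparisons downstream).
    """
    if unvisited not in ("zero", "missing"):
        raise ValueError("unvisited must be 'zero' or 'missing'")
    labels = _check_labels(labels, k)
    states, lengths = run_lengths(labels)
    out = np.zeros(k) if unvisited == "zero" else np.full(k, np.nan)
    for s in range(1, k + 1):
        mask = states == s
        if mask.any():
            out[s - 1] = lengths[mask].mean()
    return out


def n_transitions(labels: np.ndarray) -> int:
    """Number of consecutive-window state changes."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("label sequence is empty")
    return int(np.sum(np.diff(labels) != 0))


def temporal_metrics_table(
    model: StateModel,
    tr_seconds: float = 2.5,
    step_tr: int = 1,
    unvisited: str = "zero",
) -> pd.DataFrame:
    """Per-subject metrics: fractional time %, dwell (windows and seconds), transitions."""
    rows = []
    for subject, labels in model.labels_by_subject.items():
        ft = fractional_time(labels, model.k)
        dw = mean_dwell_time(labels, model.k, unvisited=unvisited)
        row: dict = {"subject_id": subject}
        for s in range(model.k):
            row[f"frac_time_s{s + 1}"] = ft[s]
        for s in range(model.k):
            row[f"dwell_s{s + 1}"] = dw[s]
            row[f"dwell_sec_s{s + 1}"] = dw[s] * tr_seconds * step_tr
        row["n_transitions"] = n_transitions(labels)
        rows.append(row)
    return pd.DataFrame(rows)


def state_strength(
    windows: WindowedFNCSeries, labels: np.ndarray, state: int
) -> np.ndarray | None:
    """Mean z matrix over one subject's windows assigned to ``state``.

    Returns ``None`` when the subject never visits the state (the
    subject is then excluded from that state's group tests).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != windows.n_windows:
        raise ValueError("labels length must equal number of windows")
    mask = labels == state
    if not mask.any():
        return None
    return windows.matrices[mask].mean(axis=0)


def state_strength_tables(
    windows_by_subject: dict[str, WindowedFNCSeries],
    model: StateModel,
) -> dict[int, pd.DataFrame]:
    """Per state: subjects × edges table of mean z (upper triangle).

    Subjects that never visit a state are absent from that state's table.
    Edge columns are named ``e{i}_{j}`` with 0-based component indices.
    """
    from .clustering import matrices_to_features

    c = model.n_components
    iu = np.triu_indices(c, k=1)
    cols = [f"e{i}_{j}" for i, j in zip(*iu)]
    out: dict[int, pd.DataFrame] = {}
    for state in range(1, model.k + 1):
        rows, idx = [], []
        for subject, labels in model.labels_by_subject.items():
            m = state_strength(windows_by_subject[subject], labels, state)
            if m is not None:
                rows.append(matrices_to_features(m)[0])
                idx.append(subject)
        out[state] = pd.DataFrame(rows, index=idx, columns=cols)
    return out
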