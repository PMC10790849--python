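"""Event-locked functional connectivity: pre-beep windows, Pearson FC,
Fisher Z, and edge vectorization.

A 44-channel montage yields a 44 x 44 correlation matrix per beep whose
strict lower triangle, taken in row-major order ((1,0), (2,0), (2,1), ...),
is the C(44,2) = 946-dimensional edge vector used as the regression design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Pre-stimulus window lengths (seconds) evaluated in the hyperparameter grid.
DEFAULT_WINDOWS: tuple[float, ...] = (10.0, 15.0, 20.0)


class WindowError(ValueError):
    """Raised when a pre-beep window would precede the recording start."""


def n_window_samples(window_s: float, fs: float) -> int:
    """Number of samples in a pre-beep window: floor(window_s * fs)."""
    return int(np.floor(window_s * fs))


def extract_window(
    values: np.ndarray,
    time: np.ndarray,
    beep_time: float,
    window_s: float,
) -> np.ndarray:
    """Extract the pre-stimulus window ending at (and excluding) the beep.

    The window is half-open: it contains exactly ``floor(window_s * fs)``
    samples strictly before ``beep_time``, so prediction uses only
    pre-event data.

    Parameters
    ----------
    values : (n_samples, n_channels) array
    time : (n_samples,) array of sample times in seconds
    beep_time : beep onset in seconds
    window_s : window length in seconds

    Raises
    ------
    WindowError
        If the window would extend before the first sample; callers drop
        the trial (with a logged reason) in that case.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    if values.shape[0] != time.shape[0]:
        raise ValueError("values and time have mismatched lengths")
    fs = 1.0 / float(np.median(np.diff(time)))
    m = n_window_samples(window_s, fs)
    end = int(np.searchsorted(time, beep_time))
    start = end - m
    if start < 0:
        raise WindowError(
            f"window of {window_s} s before beep at {beep_time:.2f} s "
            "precedes recording start"
        )
    return values[start:end]


def fc_matrix(window: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a windowed multichannel segment.

    Channels with zero variance get all their edges set to 0 (diagonal kept
    at 1) with a warning, so trial counts stay aligned with behavior.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 3:
        raise ValueError("need a 2-D window with at least 3 samples")
    sd = window.std(axis=0)
    dead = sd == 0
    n_ch = window.shape[1]
    r = np.zeros((n_ch, n_ch))
    live = ~dead
    if live.sum() >= 2:
        r_live = np.corrcoef(window[:, live], rowvar=False)
        r[np.ix_(live, live)] = r_live
    elif live.sum() == 1:
        r[np.ix_(live, live)] = 1.0
    if dead.any():
        warnings.warn(
            f"zero-variance channel(s) {np.flatnonzero(dead).tolist()}; "
            "their edges set to 0",
            stacklevel=2,
        )
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Fisher Z-transform of a correlation matrix, off-diagonal entries only.

    |r| is clipped to 1 - eps so perfectly (anti)correlated channels stay
    finite.  The diagonal is set to 0 and excluded from downstream use.
    """
    r = np.asarray(r, dtype=float)
    z = np.arctanh(np.clip(r, -1.0 + eps, 1.0 - eps))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    return z


def n_edges(n_channels: int) -> int:
    return n_channels * (n_channels - 1) // 2


def edge_pairs(n_channels: int) -> np.ndarray:
    """(n_edges, 2) channel pairs (i, j), i > j, in vectorization order."""
    ii, jj = np.tril_indices(n_channels, k=-1)
    return np.column_stack([ii, jj])


def pair_to_edge(i: int, j: int) -> int:
    """Edge-vector index of the unordered channel pair {i, j}."""
    if i == j:
        raise ValueError("no self-edge in the vectorization")
    i, j = (i, j) if i > j else (j, i)
    return i * (i - 1) // 2 + j


def edge_to_pair(idx: int, n_channels: int) -> tuple[int, int]:
    """Inverse of :func:`pair_to_edge` for a given montage size."""
    pairs = edge_pairs(n_channels)
    if not 0 <= idx < len(pairs):
        raise IndexError(f"edge index {idx} out of range")
    i, j = pairs[idx]
    return int(i), int(j)


def vectorize(matrix: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Strict lower triangle of a symmetric matrix in row-major order."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if np.abs(m - m.T).max() > atol:
        raise ValueError("matrix is not symmetric")
    ii, jj = np.tril_indices(m.shape[0], k=-1)
    return m[ii, jj]


def devectorize(vec: np.ndarray, n_channels: int, diag: float = 0.0) -> np.ndarray:
    """Rebuild a symmetric matrix from its strict-lower-triangle vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape[0] != n_edges(n_channels):
        raise ValueError(
            f"expected {n_edges(n_channels)} edges for {n_channels} channels"
        )
    m = np.full((n_channels, n_channels), diag, dtype=float)
    ii, jj = np.tril_indices(n_channels, k=-1)
    m[ii, jj] = vec
    m[jj, ii] = vec
    return m


@dataclass
class TrialSet:
    """Per-beep Fisher-z edge vectors for one window size.

    Attributes
    ----------
    window_s : window length in seconds
    X : (n_trials, n_edges) Fisher-z design matrix
    trial_index : indices into the session's beep list (dropped beeps absent)
    dropped : beep indices without sufficient pre-stimulus history
    n_channels : montage size (44 by default)
    """

    window_s: float
    X: np.ndarray
    trial_index: np.ndarray
    dropped: list[int] = field(default_factory=list)
    n_channels: int = 44

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def edge_columns(self) -> list[str]:
        return [f"e{i}_{j}" for i, j in edge_pairs(self.n_channels)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.edge_columns())
        df.insert(0, "trial", self.trial_index)
        return df

    def index_map(self) -> dict[str, list[int]]:
        return {
            f"{k}": [int(i), int(j)]
            for k, (i, j) in enumerate(edge_pairs(self.n_channels))
        }

    def write(self, csv_path, index_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if index_path is not None:
            with open(index_path, "w") as fh:
                json.dump(self.index_map(), fh)


def build_trialset(
    oxy: np.ndarray,
    time: np.ndarray,
    beep_times: np.ndarray,
    window_s: float,
) -> TrialSet:
    """Compute one Fisher-z edge vector per beep with sufficient history.

    Trial order matches the beep order; beeps whose window precedes the
    recording start are dropped and recorded in ``dropped``.
    """
    rows, kept, dropped = [], [], []
    for t_idx, beep in enumerate(np.asarray(beep_times, dtype=float)):
        try:
            win = extract_window(oxy, time, beep, window_s)
        except WindowError:
            dropped.append(t_idx)
            continue
        rows.append(vectorize(fisher_z(fc_matrix(win))))
        kept.append(t_idx)
    n_ch = oxy.shape[1]
    X = np.array(rows) if rows else np.empty((0, n_edges(n_ch)))
    return TrialSet(
        window_s=float(window_s),
        X=X,
        trial_index=np.asarray(kept, dtype=int),
        dropped=dropped,
        n_channels=n_ch,
    )


def build_trialsets(
    oxy: np.ndarray,
    time: np.ndarray,
    beep_times: np.ndarray,
    windows=DEFAULT_WINDOWS,
) -> dict[float, TrialSet]:
    return {
        float(w): build_trialset(oxy, time, beep_times, w) for w in windows
    }
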