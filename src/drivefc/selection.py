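"""Stability-based edge selection: repeated subsampling without
replacement plus Spearman screening.

For each of NB subsets (a fraction BP of the trials, drawn without
replacement), every edge is screened by the two-sided Spearman correlation
of its Fisher-z values against BRT; edges with p < 0.05 are hits.  Edges
whose hit frequency across the NB subsets reaches the stability threshold
FP are selected.  No multiple-testing correction is applied across the
946 edges — stability thresholding is the only control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._stats import spearman_vector

#: Tolerance when comparing hit frequencies to FP, so that e.g. 7/10 >= 0.7.
_FP_TOL = 1e-9


def round_half_away(x: float) -> int:
    """Round half away from zero (symmetric rounding), e.g. 23.2 -> 23, 23.5 -> 24."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class SelectionParams:
    """Hyperparameters of the stability selection step.

    nb : number of subsets drawn (grid: 10, 20, 50, 100, 300)
    bp : subsample proportion (grid: 0.6, 0.8)
    fp : stability threshold on the hit frequency (grid: 0.5 ... 1.0)
    alpha : per-subset screening level (0.05, strict inequality)
    """

    nb: int = 100
    bp: float = 0.8
    fp: float = 0.5
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.nb < 1:
            raise ValueError("nb must be >= 1")
        if not 0 < self.bp <= 1:
            raise ValueError("bp must be in (0, 1]")
        if not 0 < self.fp <= 1:
            raise ValueError("fp must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SelectionResult:
    """Outcome of one stability-selection run."""

    selected_edges: np.ndarray  # sorted edge indices
    frequency: np.ndarray  # per-edge hit fraction in [0, 1]
    params: SelectionParams
    per_subset_hits: np.ndarray | None = field(default=None, repr=False)

    def report(self) -> dict:
        return {
            "params": {
                "nb": self.params.nb,
                "bp": self.params.bp,
                "fp": self.params.fp,
                "alpha": self.params.alpha,
                "seed": self.params.seed,
            },
            "selected_edges": self.selected_edges.tolist(),
            "frequency": self.frequency.tolist(),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh)


def subset_size(n: int, bp: float) -> int:
    return round_half_away(bp * n)


def draw_subsets(
    n: int,
    params: SelectionParams,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Draw NB index sets of size round(bp*n), without replacement.

    Raises
    ------
    ValueError
        If the subset size is below 3 (correlation undefined).
    """
    size = subset_size(n, params.bp)
    if size < 3:
        raise ValueError(
            f"subset size {size} < 3; correlation undefined (n={n}, bp={params.bp})"
        )
    rng = np.random.default_rng(params.seed) if rng is None else rng
    return [np.sort(rng.choice(n, size=size, replace=False)) for _ in range(params.nb)]


def screen_subset(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """Edges significantly rank-correlated with BRT within one subset.

    Returns a boolean mask over edges, True where the two-sided Spearman
    p-value is strictly below ``alpha``.  A constant ``y`` within the
    subset yields an empty mask with a warning.
    """
    idx = np.asarray(idx, dtype=int)
    ysub = np.asarray(y, dtype=float)[idx]
    if np.all(ysub == ysub[0]):
        warnings.warn("constant BRT within subset; no edges screened")
        return np.zeros(np.asarray(X).shape[1], dtype=bool)
    _, p = spearman_vector(np.asarray(X, dtype=float)[idx], ysub)
    return p < alpha


def edge_frequencies(
    X: np.ndarray,
    y: np.ndarray,
    nb: int,
    bp: float,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hit frequency of each edge over NB subsampled screenings."""
    n = len(y)
    params = SelectionParams(nb=nb, bp=bp, fp=1.0, alpha=alpha)
    subsets = draw_subsets(n, params, rng)
    counts = np.zeros(np.asarray(X).shape[1])
    for idx in subsets:
        counts += screen_subset(X, y, idx, alpha)
    return counts / nb


def aggregate(hits: np.ndarray, params: SelectionParams) -> SelectionResult:
    """Threshold per-subset hit masks at the stability frequency FP.

    ``hits`` is an (NB, n_edges) boolean array.  An edge is selected when
    its hit fraction is >= FP (so FP = 1.0 selects the intersection of all
    per-subset significant sets).
    """
    hits = np.asarray(hits, dtype=bool)
    if hits.ndim != 2 or hits.shape[0] < 1:
        raise ValueError("hits must be (NB, n_edges) with NB >= 1")
    freq = hits.mean(axis=0)
    selected = np.flatnonzero(freq + _FP_TOL >= params.fp)
    return SelectionResult(
        selected_edges=selected,
        frequency=freq,
        params=params,
        per_subset_hits=hits,
    )


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    params: SelectionParams,
    rng: np.random.Generator | None = None,
    keep_hits: bool = False,
) -> SelectionResult:
    """Full stability selection: draw subsets, screen, aggregate."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    subsets = draw_subsets(len(y), params, rng)
    hits = np.stack(
        [screen_subset(X, y, idx, params.alpha) for idx in subsets]
    )
    res = aggregate(hits, params)
    if not keep_hits:
        res.per_subset_hits = None
    return res


def select_by_frequency(freq: np.ndarray, fp: float) -> np.ndarray:
    """Selected edge indices given precomputed frequencies (>= FP rule)."""
    return np.flatnonzero(np.asarray(freq) + _FP_TOL >= fp)
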