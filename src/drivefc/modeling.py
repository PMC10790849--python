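"""Per-participant regression of brake reaction time on selected
functional-connectivity edges.

:class:`BrtRegression` is the model object: it is built from per-window
trial design matrices (N x 946 Fisher-z edge values) and the N observed
BRTs.  ``fit`` performs one stability selection plus ordinary least
squares on the full data; ``loocv`` runs leave-one-out cross-validation
with feature selection nested inside every fold; ``grid_search`` evaluates
the full hyperparameter grid (window x NB x BP x FP, 180 combinations at
the defaults) and records the best combination under two criteria: the
average training-fold rank correlation, and the pooled held-out rank
correlation.  Hyperparameter tuning deliberately sits outside the CV loop,
so the held-out criterion is optimistically biased; both are reported.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import spearman_pvalue, spearman_scalar
from .selection import (
    SelectionParams,
    edge_frequencies,
    select_by_frequency,
    select_features,
)

__all__ = [
    "GridSpec",
    "DEFAULT_GRID",
    "REDUCED_GRID",
    "FittedModel",
    "CVResult",
    "GridResult",
    "BrtRegression",
    "fit_ols",
    "loocv",
    "evaluate_significance",
]


@dataclass(frozen=True)
class GridSpec:
    """Cartesian hyperparameter grid, enumerated in fixed ascending order."""

    windows: tuple[float, ...] = (10.0, 15.0, 20.0)
    nb: tuple[int, ...] = (10, 20, 50, 100, 300)
    bp: tuple[float, ...] = (0.6, 0.8)
    fp: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

    def combinations(self) -> list[tuple[float, int, float, float]]:
        """(window, nb, bp, fp) tuples; ties in model selection break by
        this order (window asc, NB asc, BP asc, FP asc)."""
        return list(itertools.product(self.windows, self.nb, self.bp, self.fp))

    def __len__(self) -> int:
        return (
            len(self.windows) * len(self.nb) * len(self.bp) * len(self.fp)
        )


#: The study's full grid: 3 windows x 5 NB x 2 BP x 6 FP = 180 combinations.
DEFAULT_GRID = GridSpec()

#: Small grid for desk-scale cohort runs; includes the stability-selection
#: reference point (NB=100, BP=0.8, FP=0.5) used by the recovery analyses.
REDUCED_GRID = GridSpec(
    windows=(10.0, 20.0), nb=(20, 100), bp=(0.8,), fp=(0.5, 0.7, 0.9)
)


@dataclass
class FittedModel:
    """Selected edges and OLS coefficients of one trained model."""

    selected_edges: np.ndarray
    coefficients: np.ndarray  # ms per Fisher-z unit, one per edge
    intercept: float  # ms
    training_indices: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.selected_edges.size == 0:
            return np.full(X.shape[0], self.intercept)
        return self.intercept + X[:, self.selected_edges] @ self.coefficients


def fit_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit of y on [1, X]; minimum-norm when rank-deficient.

    Returns (coefficients, intercept).  An empty feature set degrades to
    an intercept-only model (the training mean) with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        warnings.warn("empty feature set; intercept-only model")
        return np.empty(0), float(y.mean())
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta[1:], float(beta[0])


def evaluate_significance(rho: float, n: int) -> float:
    """Two-sided p-value of the no-correlation null for Spearman rho.

    Exact permutation null for n <= 9 (tie-free assumption), t
    approximation with n - 2 df otherwise.
    """
    if n < 4:
        raise ValueError("need at least 4 pairs to test a correlation")
    return float(np.atleast_1d(spearman_pvalue(rho, n))[0])


@dataclass
class CVResult:
    """Pooled leave-one-out outcome for one hyperparameter combination."""

    predicted: np.ndarray  # ms, one per trial (each held out once)
    measured: np.ndarray  # ms
    avg_training_rho: float
    test_rho: float
    test_p: float
    mae_ms: float
    mae_sd_ms: float
    avg_n_features: float
    params: SelectionParams | None = None
    window_s: float | None = None

    @property
    def n(self) -> int:
        return len(self.measured)

    def summary(self) -> str:
        lines = [
            "Leave-one-out cross-validation",
            "------------------------------",
            f"trials (N):                 {self.n}",
            f"avg training Spearman rho:  {self.avg_training_rho:.3f}",
            f"held-out Spearman rho:      {self.test_rho:.3f}",
            f"held-out p (no corr.):      {self.test_p:.3g}",
            f"MAE of BRT:                 {self.mae_ms:.1f} ms "
            f"(SD {self.mae_sd_ms:.1f} ms)",
            f"avg selected edges / fold:  {self.avg_n_features:.1f}",
        ]
        if self.window_s is not None and self.params is not None:
            lines.insert(
                2,
                f"window {self.window_s:g} s, NB={self.params.nb}, "
                f"BP={self.params.bp:g}, FP={self.params.fp:g}",
            )
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Measured vs predicted BRT scatter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.measured, self.predicted, s=18)
        ax.set_xlabel("measured BRT (ms)")
        ax.set_ylabel("predicted BRT (ms)")
        ax.set_title(f"rho = {self.test_rho:.2f} (p = {self.test_p:.3g})")
        return ax


def _training_rho(fitted: np.ndarray, y: np.ndarray) -> float:
    rho = spearman_scalar(fitted, y)
    return rho


def _fold_fit(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    selected: np.ndarray,
) -> FittedModel:
    coef, intercept = fit_ols(X[np.ix_(train, selected)], y[train])
    return FittedModel(
        selected_edges=np.asarray(selected, dtype=int),
        coefficients=coef,
        intercept=intercept,
        training_indices=train,
    )


def fold_prediction(
    X: np.ndarray, y: np.ndarray, params: SelectionParams, fold: int
) -> float:
    """Held-out prediction of one LOOCV fold (used by leakage probes).

    Feature selection and the OLS fit see only the N-1 training trials;
    the held-out trial's BRT cannot influence its own prediction.
    """
    n = len(y)
    train = np.delete(np.arange(n), fold)
    rng = np.random.default_rng(params.seed + fold)
    freq = edge_frequencies(
        X[train], y[train], params.nb, params.bp, params.alpha, rng
    )
    selected = select_by_frequency(freq, params.fp)
    model = _fold_fit(X, y, train, selected)
    return float(model.predict(X[fold][None, :])[0])


def _pool_cv(
    preds: np.ndarray,
    y: np.ndarray,
    train_rhos: list[float],
    n_feats: list[int],
    params: SelectionParams | None,
    window_s: float | None,
) -> CVResult:
    abs_err = np.abs(preds - y)
    rho = spearman_scalar(preds, y)
    return CVResult(
        predicted=preds,
        measured=np.asarray(y, dtype=float),
        avg_training_rho=float(np.mean(train_rhos)),
        test_rho=rho,
        test_p=evaluate_significance(rho, len(y)),
        mae_ms=float(abs_err.mean()),
        mae_sd_ms=float(abs_err.std(ddof=1)),
        avg_n_features=float(np.mean(n_feats)),
        params=params,
        window_s=window_s,
    )


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    params: SelectionParams,
    window_s: float | None = None,
) -> CVResult:
    """Leave-one-out CV with feature selection nested in every fold.

    Per-fold selection is seeded with ``params.seed + fold`` so folds are
    independent but the whole run is reproducible.  Folds whose selection
    is empty fall back to an intercept-only prediction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 trials for LOOCV")
    preds = np.empty(n)
    train_rhos, n_feats = [], []
    for i in range(n):
        train = np.delete(np.arange(n), i)
        rng = np.random.default_rng(params.seed + i)
        freq = edge_frequencies(
            X[train], y[train], params.nb, params.bp, params.alpha, rng
        )
        selected = select_by_frequency(freq, params.fp)
        model = _fold_fit(X, y, train, selected)
        preds[i] = model.predict(X[i][None, :])[0]
        train_rhos.append(_training_rho(model.predict(X[train]), y[train]))
        n_feats.append(selected.size)
    return _pool_cv(preds, y, train_rhos, n_feats, params, window_s)


@dataclass
class GridResult:
    """Every grid combination's CV outcome plus the two chosen models."""

    table: pd.DataFrame
    cv: dict[tuple, CVResult] = field(repr=False, default_factory=dict)
    chosen_by_training: tuple | None = None
    chosen_by_test: tuple | None = None
    grid: GridSpec | None = None
    seed: int = 0

    def best(self, criterion: str = "test") -> CVResult:
        key = (
            self.chosen_by_training
            if criterion == "training"
            else self.chosen_by_test
        )
        return self.cv[key]

    def summary(self) -> str:
        rows = [
            "Hyperparameter grid search",
            "--------------------------",
            f"combinations evaluated: {len(self.table)}",
        ]
        for crit, key in (
            ("training", self.chosen_by_training),
            ("test", self.chosen_by_test),
        ):
            cv = self.cv[key]
            w, nb, bp, fp = key
            rows.append(
                f"chosen by {crit:8s}: window {w:g} s, NB={nb}, BP={bp:g}, "
                f"FP={fp:g} | train rho {cv.avg_training_rho:.3f}, "
                f"test rho {cv.test_rho:.3f} (p={cv.test_p:.3g}), "
                f"MAE {cv.mae_ms:.0f} ms"
            )
        return "\n".join(rows)


class BrtRegression:
    """Connectivity-to-BRT regression model for one participant.

    Parameters
    ----------
    trial_matrices : mapping window_s -> (N, n_edges) Fisher-z design, or a
        single (N, n_edges) array (then ``window_s`` labels it).
    brt_ms : (N,) observed brake reaction times, outliers already removed.
    seed : master seed for all subset drawing.
    """

    def __init__(self, trial_matrices, brt_ms, seed: int = 0, window_s: float = 20.0):
        if isinstance(trial_matrices, np.ndarray):
            trial_matrices = {float(window_s): trial_matrices}
        self.trial_matrices = {
            float(w): np.asarray(m, dtype=float)
            for w, m in trial_matrices.items()
        }
        self.y = np.asarray(brt_ms, dtype=float)
        for w, m in self.trial_matrices.items():
            if m.shape[0] != len(self.y):
                raise ValueError(
                    f"window {w}: {m.shape[0]} trials vs {len(self.y)} BRTs"
                )
        if seed < 0:
            raise ValueError("seed must be nonnegative")
        self.seed = int(seed)

    @property
    def windows(self) -> list[float]:
        return sorted(self.trial_matrices)

    @property
    def n_trials(self) -> int:
        return len(self.y)

    def _design(self, window_s: float | None) -> tuple[float, np.ndarray]:
        if window_s is None:
            if len(self.trial_matrices) != 1:
                raise ValueError("several windows available; specify one")
            window_s = self.windows[0]
        return float(window_s), self.trial_matrices[float(window_s)]

    def fit(
        self, params: SelectionParams, window_s: float | None = None
    ) -> "BrtRegressionResults":
        """One stability selection plus OLS on the full trial set."""
        w, X = self._design(window_s)
        sel = select_features(X, self.y, params)
        coef, intercept = fit_ols(X[:, sel.selected_edges], self.y)
        model = FittedModel(
            selected_edges=sel.selected_edges,
            coefficients=coef,
            intercept=intercept,
            training_indices=np.arange(self.n_trials),
        )
        fitted = model.predict(X)
        return BrtRegressionResults(
            model=model,
            selection=sel,
            fitted=fitted,
            measured=self.y,
            training_rho=_training_rho(fitted, self.y),
            window_s=w,
        )

    def loocv(
        self, params: SelectionParams, window_s: float | None = None
    ) -> CVResult:
        w, X = self._design(window_s)
        return loocv(X, self.y, params, window_s=w)

    def grid_search(self, grid: GridSpec = DEFAULT_GRID) -> GridResult:
        """Evaluate every (window, NB, BP, FP) combination by LOOCV.

        Screening frequencies are FP-independent, so each (window, NB, BP)
        triple is screened once per fold and all FP thresholds reuse the
        cached frequencies.  Per-combination fold seeds derive from the
        model's master seed via ``SeedSequence``.
        """
        n = self.n_trials
        rows = []
        cvs: dict[tuple, CVResult] = {}
        for w_idx, w in enumerate(grid.windows):
            X = self.trial_matrices[float(w)]
            for nb in grid.nb:
                for bp in grid.bp:
                    fold_freq = []
                    fold_train = []
                    for i in range(n):
                        train = np.delete(np.arange(n), i)
                        ss = np.random.SeedSequence(
                            [self.seed, w_idx, nb, int(round(bp * 100)), i]
                        )
                        rng = np.random.default_rng(ss)
                        fold_freq.append(
                            edge_frequencies(
                                X[train], self.y[train], nb, bp, 0.05, rng
                            )
                        )
                        fold_train.append(train)
                    for fp in grid.fp:
                        params = SelectionParams(
                            nb=nb, bp=bp, fp=fp, seed=self.seed
                        )
                        preds = np.empty(n)
                        train_rhos, n_feats = [], []
                        for i in range(n):
                            selected = select_by_frequency(fold_freq[i], fp)
                            model = _fold_fit(
                                X, self.y, fold_train[i], selected
                            )
                            preds[i] = model.predict(X[i][None, :])[0]
                            train_rhos.append(
                                _training_rho(
                                    model.predict(X[fold_train[i]]),
                                    self.y[fold_train[i]],
                                )
                            )
                            n_feats.append(selected.size)
                        cv = _pool_cv(
                            preds, self.y, train_rhos, n_feats, params, w
                        )
                        key = (float(w), nb, bp, fp)
                        cvs[key] = cv
                        rows.append(
                            {
                                "window_s": float(w),
                                "nb": nb,
                                "bp": bp,
                                "fp": fp,
                                "avg_training_rho": cv.avg_training_rho,
                                "test_rho": cv.test_rho,
                                "test_p": cv.test_p,
                                "mae_ms": cv.mae_ms,
                                "mae_sd_ms": cv.mae_sd_ms,
                                "avg_n_features": cv.avg_n_features,
                            }
                        )
        table = pd.DataFrame(rows)
        keys = list(cvs)
        by_train = max(
            range(len(keys)), key=lambda k: (cvs[keys[k]].avg_training_rho, -k)
        )
        by_test = max(
            range(len(keys)), key=lambda k: (cvs[keys[k]].test_rho, -k)
        )
        return GridResult(
            table=table,
            cv=cvs,
            chosen_by_training=keys[by_train],
            chosen_by_test=keys[by_test],
            grid=grid,
            seed=self.seed,
        )


@dataclass
class BrtRegressionResults:
    """Full-data fit: selected edges, coefficients, and training fit."""

    model: FittedModel
    selection: object
    fitted: np.ndarray
    measured: np.ndarray
    training_rho: float
    window_s: float

    @property
    def selected_edges(self) -> np.ndarray:
        return self.model.selected_edges

    @property
    def params(self) -> np.ndarray:
        """OLS coefficients (ms per Fisher-z unit), statsmodels naming."""
        return self.model.coefficients

    @property
    def intercept(self) -> float:
        return self.model.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def edge_pattern(self, montage, participant: str = ""):
        """Project the selected edges onto the AAL region parcellation."""
        from .interpretation import edges_to_region_matrix

        return edges_to_region_matrix(
            self.selected_edges, montage, participant=participant
        )

    def summary(self) -> str:
        p = self.selection.params
        lines = [
            "BRT ~ functional connectivity (full-data fit)",
            "---------------------------------------------",
            f"window {self.window_s:g} s, NB={p.nb}, BP={p.bp:g}, "
            f"FP={p.fp:g}, alpha={p.alpha:g}",
            f"trials:            {len(self.measured)}",
            f"selected edges:    {self.selected_edges.size}",
            f"intercept:         {self.intercept:.1f} ms",
            f"training Spearman: {self.training_rho:.3f}",
        ]
        return "\n".join(lines)
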