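"""Subplot mean-spectrum features and the SVR yield model.

The regression features are per-subplot mean reflectance vectors.  The model
is an RBF-kernel support vector regression tuned per dataset by a C x gamma
grid search scored with leave-one-out cross-validation over the training
subplots, on a fixed 80/20 train/test split that is created once and reused
for every spectral x spatial dataset.  Accuracy is reported as MAPE (%) and
RMSE (Mg/ha).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .datacube import FieldLayout, SpectralCube, YieldTable

__all__ = [
    "FeatureTable",
    "SplitSpec",
    "RegressionResult",
    "subplot_mean_spectra",
    "tiled_mean_spectrum",
    "make_split",
    "default_param_grid",
    "tune_and_fit_svr",
    "evaluate",
    "mape",
    "rmse",
]


@dataclass
class FeatureTable:
    """Per-subplot mean spectra for one (config, GSD) dataset."""

    frame: pd.DataFrame  # rows: subplot ids; columns: band centre wavelengths
    config_name: str = ""
    gsd: float = float("nan")

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate subplot ids in feature table")

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)


@dataclass(frozen=True)
class SplitSpec:
    """A fixed train/test division of subplot ids."""

    seed: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


@dataclass
class RegressionResult:
    hyperparameters: dict
    predictions: dict[str, float]  # per test subplot
    mape: float  # percent
    rmse: float  # Mg/ha
    cv_mape: float = float("nan")  # LOO score of the selected grid point
    config_name: str = ""
    gsd: float = float("nan")

    def __post_init__(self) -> None:
        if self.mape < 0 or self.rmse < 0:
            raise ValueError("error metrics cannot be negative")


def subplot_mean_spectra(cube: SpectralCube, layout: FieldLayout) -> FeatureTable:
    """Arithmetic per-band mean over each subplot's pixels (native-GSD path)."""
    layout.validate_against(cube.shape)
    rows = {}
    for s in layout:
        block = cube.values[:, s.r0 : s.r1, s.c0 : s.c1]
        if block[0].size == 0:
            raise ValueError(f"subplot {s.id} has zero interior pixels")
        rows[s.id] = block.reshape(cube.n_bands, -1).mean(axis=1)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=cube.wavelengths)
    return FeatureTable(frame, gsd=cube.gsd)


def tiled_mean_spectrum(cube: SpectralCube) -> np.ndarray:
    """Mean spectrum of a tiled/degraded subplot product, excluding any pad.

    The boundary-influenced ring recorded by the spatial pipeline (zero pad
    plus PSF reach, in output pixels) is excluded; with the default periodic
    boundary there is no pad and the mean runs over every pixel.
    """
    pad = int(cube.meta.get("interior_margin_px", cube.meta.get("pad_px", 0)))
    v = cube.values
    if pad > 0:
        v = v[:, pad : v.shape[1] - pad, pad : v.shape[2] - pad]
    if v[0].size == 0:
        raise ValueError("no interior pixels left after excluding the pad ring")
    return v.reshape(cube.n_bands, -1).mean(axis=1, dtype=np.float64)


def make_split(subplot_ids: list[str], seed: int, test_fraction: float = 0.2) -> SplitSpec:
    """Seeded shuffle; the last ``floor(n * test_fraction)`` ids (at least 1)
    form the test set.  Identical seeds give identical splits."""
    ids = list(subplot_ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 subplots to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_test = max(1, math.floor(len(ids) * test_fraction))
    shuffled = [ids[i] for i in order]
    return SplitSpec(seed, tuple(shuffled[:-n_test]), tuple(shuffled[-n_test:]))


def mape(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute percentage error, in percent."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    if np.any(y_true <= 0):
        raise ValueError("MAPE is undefined for non-positive truth values")
    return float(100.0 * np.mean(np.abs(y_true - y_pred) / y_true))


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error, in the units of the inputs (Mg/ha here)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def default_param_grid() -> list[tuple[float, float]]:
    """(C, gamma) grid: log-decade steps, C 1e1..1e5, gamma 1e-5..1e-1.

    Ordered so that ties in the CV score resolve toward smaller C, then
    larger gamma.
    """
    cs = [10.0**k for k in range(1, 6)]
    gammas = [10.0**k for k in range(-5, 0)]
    return [(c, g) for c in cs for g in sorted(gammas, reverse=True)]


@dataclass
class FittedSVR:
    """A tuned SVR plus its train-set standardization."""

    model: SVR
    mean: np.ndarray
    std: np.ndarray
    kept: np.ndarray  # boolean mask of retained (non-degenerate) bands
    C: float
    gamma: float
    epsilon: float
    cv_mape: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept]
        return self.model.predict((X - self.mean) / self.std)


def _standardize(train: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    std = train.std(axis=0, ddof=0)
    kept = std > 0
    if not kept.any():
        raise ValueError("every feature band is constant on the training set")
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} zero-variance band(s) before SVR", stacklevel=3
        )
    mean = train[:, kept].mean(axis=0)
    return mean, std[kept], kept


def tune_and_fit_svr(
    features: FeatureTable,
    yields: YieldTable,
    split: SplitSpec,
    grid: list[tuple[float, float]] | None = None,
    epsilon: float = 0.1,
) -> FittedSVR:
    """Grid-search (C, gamma) by leave-one-out CV on the training subplots.

    Features are z-scored with training-set statistics (zero-variance bands
    dropped with a warning); each grid point is scored by LOO MAPE; the best
    point is refit on all training data.  LOO has no randomness, so the whole
    procedure is deterministic.
    """
    grid = grid if grid is not None else default_param_grid()
    if not grid:
        raise ValueError("parameter grid must be nonempty")
    X_tr = features.frame.loc[list(split.train_ids)].to_numpy(dtype=float)
    y_tr = np.array([yields[i] for i in split.train_ids])
    mean, std, kept = _standardize(X_tr)
    Z = (X_tr[:, kept] - mean) / std
    n = len(Z)
    loo_idx = np.arange(n)
    best: tuple[float, float, float] | None = None  # (score, C, gamma)
    for C, gamma in grid:
        preds = np.empty(n)
        for i in loo_idx:
            m = np.ones(n, dtype=bool)
            m[i] = False
            svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
            svr.fit(Z[m], y_tr[m])
            preds[i] = svr.predict(Z[i : i + 1])[0]
        score = mape(y_tr, preds)
        if best is None or score < best[0]:
            best = (score, C, gamma)
    cv_score, C, gamma = best
    final = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
    final.fit(Z, y_tr)
    return FittedSVR(final, mean, std, kept, C, gamma, epsilon, cv_score)


def evaluate(
    model: FittedSVR,
    features: FeatureTable,
    yields: YieldTable,
    split: SplitSpec,
) -> RegressionResult:
    """Score a fitted model on the held-out test subplots."""
    X_te = features.frame.loc[list(split.test_ids)].to_numpy(dtype=float)
    y_te = np.array([yields[i] for i in split.test_ids])
    preds = model.predict(X_te)
    return RegressionResult(
        hyperparameters={"C": model.C, "gamma": model.gamma, "epsilon": model.epsilon},
        predictions=dict(zip(split.test_ids, preds.tolist())),
        mape=mape(y_te, preds),
        rmse=rmse(y_te, preds),
        cv_mape=model.cv_mape,
        config_name=features.config_name,
        gsd=features.gsd,
    )
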