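"""Fitness-landscape regression over (genome, fitness) data.

A landscape maps the 4-component formulation simplex to expected fitness.
Two estimators are provided, both RBF-kernel:

* support vector regression with the penalty C grid-searched over
  [0.01, 0.1, 1, 10, 100] (and gamma over a documented grid) by 10-fold
  cross-validated mean squared error — the headline landscape model;
* kernel ridge regression at fixed (alpha=10, gamma=100) — a deterministic
  closed-form variant used when many landscapes must share one kernel, e.g.
  for time-evolving landscape animations.

Predictions are visualised on ternary slices: three oils free, the fourth
held at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.kernel_ridge import KernelRidge
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .genome import OILS, Genome

__all__ = [
    "LandscapeDataset",
    "LandscapeModel",
    "fit_svr",
    "fit_kernel_ridge",
    "ternary_grid",
    "plot_ternary",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class LandscapeDataset:
    """Training data: genome fractions (n, 4) and non-negative fitness (n,)."""

    X: np.ndarray
    y: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 4:
            raise ValueError("X must be (n, 4) genome fractions")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must align with X")
        if np.any(self.y < 0):
            raise ValueError("fitness must be non-negative")

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fitness_col: str = "fitness", source: str = "") -> "LandscapeDataset":
        return cls(df[list(OILS)].to_numpy(), df[fitness_col].to_numpy(), source=source)


@dataclass
class LandscapeModel:
    """A fitted landscape: estimator, chosen hyperparameters, CV diagnostics."""

    method: str                       # "svr" | "kernel_ridge"
    estimator: object
    hyperparams: dict
    cv_mse_mean: float | None = None
    cv_mse_std: float | None = None
    cv_table: pd.DataFrame | None = None
    n_train: int = 0
    source: str = ""

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def summary(self) -> str:
        lines = [
            f"Fitness landscape ({self.method}, RBF kernel)",
            f"  training points: {self.n_train}" + (f"  [{self.source}]" if self.source else ""),
            f"  hyperparameters: {self.hyperparams}",
        ]
        if self.cv_mse_mean is not None:
            lines.append(
                f"  10-fold CV MSE: {self.cv_mse_mean:.4g} (std {self.cv_mse_std:.4g})"
            )
        return "\n".join(lines)


def _cv_mse(make_est, X, y, folds: int, seed: int) -> tuple[float, float]:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in kf.split(X):
        est = make_est()
        est.fit(X[tr], y[tr])
        errs.append(mean_squared_error(y[te], est.predict(X[te])))
    return float(np.mean(errs)), float(np.std(errs))


def fit_svr(
    ds: LandscapeDataset,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    folds: int = 10,
    seed: int = 0,
) -> LandscapeModel:
    """Exhaustive (C, gamma) grid search by k-fold CV MSE, then refit on all data.

    Ties in mean CV MSE are broken towards smaller C, then smaller gamma.
    Fold assignment is seeded, so the selection is invariant to row order of
    the CV table and reproducible.
    """
    if len(ds) < folds:
        raise ValueError(f"need at least {folds} points for {folds}-fold CV")
    rows = []
    for C in c_grid:
        for gamma in gamma_grid:
            mse, std = _cv_mse(lambda: SVR(kernel="rbf", C=C, gamma=gamma), ds.X, ds.y, folds, seed)
            rows.append({"C": C, "gamma": gamma, "cv_mse": mse, "cv_mse_std": std})
    table = pd.DataFrame(rows)
    best = min(rows, key=lambda r: (r["cv_mse"], r["C"], r["gamma"]))
    est = SVR(kernel="rbf", C=best["C"], gamma=best["gamma"]).fit(ds.X, ds.y)
    return LandscapeModel(
        method="svr",
        estimator=est,
        hyperparams={"C": best["C"], "gamma": best["gamma"]},
        cv_mse_mean=best["cv_mse"],
        cv_mse_std=best["cv_mse_std"],
        cv_table=table,
        n_train=len(ds),
        source=ds.source,
    )


def fit_kernel_ridge(
    ds: LandscapeDataset, alpha: float = 10.0, gamma: float = 100.0
) -> LandscapeModel:
    """Closed-form RBF kernel ridge fit at fixed hyperparameters (deterministic)."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    est = KernelRidge(kernel="rbf", alpha=alpha, gamma=gamma).fit(ds.X, ds.y)
    return LandscapeModel(
        method="kernel_ridge",
        estimator=est,
        hyperparams={"alpha": alpha, "gamma": gamma},
        n_train=len(ds),
        source=ds.source,
    )


def ternary_grid(
    model: LandscapeModel,
    free_components: tuple[str, str, str] = ("octanol", "octanoic", "pentanol"),
    resolution: int = 20,
):
    """Predict on the barycentric grid of three oils, the fourth held at zero.

    Returns ``(bary, preds)``: ``bary`` is (m, 3) barycentric coordinates
    over the free components (m = C(resolution+2, 2) grid points including
    the vertices) and ``preds`` the model predictions at the corresponding
    4-component genomes.
    """
    idx = [OILS.index(c) for c in free_components]
    if len(set(idx)) != 3:
        raise ValueError("free_components must name three distinct oils")
    pts = []
    X = []
    for i in range(resolution + 1):
        for j in range(resolution + 1 - i):
            k = resolution - i - j
            b = (i / resolution, j / resolution, k / resolution)
            pts.append(b)
            g = np.zeros(4)
            for c, v in zip(idx, b):
                g[c] = v
            X.append(g)
    bary = np.array(pts)
    preds = model.predict(np.array(X))
    return bary, preds


def plot_ternary(model: LandscapeModel, free_components=("octanol", "octanoic", "pentanol"),
                 resolution: int = 40, ax=None):
    """Ternary heat map of the landscape (matplotlib tripcolor)."""
    import matplotlib.pyplot as plt

    bary, preds = ternary_grid(model, free_components, resolution)
    # project barycentric -> 2D equilateral triangle
    x = bary[:, 1] + bary[:, 2] / 2
    y = bary[:, 2] * np.sqrt(3) / 2
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    tpc = ax.tripcolor(x, y, preds, shading="gouraud", cmap="viridis")
    ax.figure.colorbar(tpc, ax=ax, label="predicted fitness")
    for (bx, by), name in zip([(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)], free_components):
        ax.text(bx, by - 0.04 if by == 0 else by + 0.03, name, ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
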