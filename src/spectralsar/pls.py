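"""Partial least squares regression with cross-validation and screening.

Single-response PLS (NIPALS) on column-centred features, the
squared-Pearson R² and RMSE performance metrics, leave-one-out /
k-fold cross-validation with pooled held-out predictions, automatic
component selection, and per-encoding-index model screening.

With one response variable the NIPALS weight vector per component is
X'y (normalised) — no inner iteration is needed — followed by score
projection and rank-one deflation of X and y.  Features are centred but
not variance-scaled by default; an optional flag enables unit-variance
scaling.  At full components (n_samples − 1 on a rank-deficient tall
problem) the fitted values coincide with the minimum-norm least-squares
solution, which the test suite uses as an independent oracle.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .aaindex import EncodingIndex, usable_indices
from .encoding import Energy, FeatureMatrix, Mode, encode_dataset

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    """A fitted single-response PLS regression.

    ``weights`` (p, a), ``x_loadings`` (p, a) and ``y_loadings`` (a,)
    define the latent projection; ``x_mean``/``y_mean`` (and optional
    ``x_scale``) the centring applied before it.  ``fitted_values`` are
    the training predictions stored at fit time.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    n_components: int
    x_scale: np.ndarray | None = None
    index_accession: str | None = None
    mode: str | None = None
    fitted_values: np.ndarray | None = None

    @property
    def coef(self) -> np.ndarray:
        """Regression vector b with ŷ = y_mean + (x − x_mean)/scale · b."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        # b = W (P'W)^{-1} q ; P'W is upper triangular and well conditioned
        return W @ np.linalg.solve(P.T @ W, q)

    def to_dict(self) -> dict:
        d = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "n_components": int(self.n_components),
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
            "index_accession": self.index_accession,
            "mode": self.mode,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            n_components=int(d["n_components"]),
            x_scale=None if d.get("x_scale") is None else np.asarray(d["x_scale"], dtype=float),
            index_accession=d.get("index_accession"),
            mode=d.get("mode"),
        )


def _as_matrix(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def fit_pls(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float],
    n_components: int,
    scale: bool = False,
) -> PLSModel:
    """Fit single-response NIPALS PLS on column-centred data.

    ``n_components`` must lie in 1..min(n_samples − 1, n_features).
    When the response is fully deflated before the requested number of
    components (exact fit at lower rank), extraction stops early and
    the model records the number actually extracted.

    Raises
    ------
    ValueError
        For out-of-bounds ``n_components`` or a zero-variance response.
    """
    Xv = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if yv.shape != (n,):
        raise ValueError(f"y has shape {yv.shape}, expected ({n},)")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(yv)):
        raise ValueError("y must be finite")
    if np.ptp(yv) == 0:
        raise ValueError("zero-variance response: nothing to regress on")
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components={n_components} outside 1..min(n_samples-1, n_features)={max_comp}"
        )

    x_mean = Xv.mean(axis=0)
    y_mean = float(yv.mean())
    Xc = Xv - x_mean
    x_scale = None
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        Xc = Xc / x_scale
    yc = yv - y_mean

    y_norm0 = np.linalg.norm(yc)
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    a = 0
    for _ in range(n_components):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn <= 1e2 * _EPS * max(1.0, y_norm0):
            break  # response exhausted (or orthogonal): exact fit at lower rank
        w /= wn
        t = Xc @ w
        tt = float(t @ t)
        if tt <= (1e2 * _EPS) ** 2:
            break
        W[:, a] = w
        P[:, a] = Xc.T @ t / tt
        q[a] = float(yc @ t) / tt
        Xc = Xc - np.outer(t, P[:, a])
        yc = yc - q[a] * t
        a += 1
    if a == 0:
        raise ValueError("response is orthogonal to the features; no component extracted")

    model = PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W[:, :a],
        x_loadings=P[:, :a],
        y_loadings=q[:a],
        n_components=a,
        x_scale=x_scale,
        index_accession=getattr(X, "index_accession", None),
        mode=getattr(X, "mode", None),
    )
    model.fitted_values = predict(model, Xv)
    return model


def predict(model: PLSModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Predict activities: ŷ = y_mean + centred (scaled) X · coef."""
    Xv = _as_matrix(X)
    if Xv.ndim == 1:
        Xv = Xv[None, :]
    if Xv.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"feature count {Xv.shape[1]} does not match model ({model.x_mean.shape[0]})"
        )
    Xc = Xv - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    return model.y_mean + Xc @ model.coef


@dataclass(frozen=True)
class PredictionSet:
    """Paired observed/predicted activities for n sequences."""

    y: np.ndarray
    y_hat: np.ndarray
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "y_hat", np.asarray(self.y_hat, dtype=float))
        if self.y.shape != self.y_hat.shape:
            raise ValueError("y and y_hat must have equal length")
        if self.ids and len(self.ids) != len(self.y):
            raise ValueError("ids length mismatch")

    @property
    def n(self) -> int:
        return len(self.y)


def r_squared(p: PredictionSet | None = None, y=None, y_hat=None) -> float:
    """Squared Pearson correlation between observed and predicted.

    R² = (Σ(yᵢ−ȳ)(ŷᵢ−ŷ̄))² / (Σ(yᵢ−ȳ)² Σ(ŷᵢ−ŷ̄)²).

    Affine-invariant in ŷ, so a perfectly *anti*-correlated prediction
    also scores 1 — see :func:`r2_residual` for the 1 − SSE/SST
    variant that does not.  Returns NaN (with a warning) when either
    vector has zero variance.
    """
    if p is None:
        p = PredictionSet(y=y, y_hat=y_hat)
    if p.n < 2:
        raise ValueError("need at least 2 points")
    dy = p.y - p.y.mean()
    dh = p.y_hat - p.y_hat.mean()
    denom = (dy @ dy) * (dh @ dh)
    if denom == 0:
        warnings.warn("zero variance in y or y_hat: R^2 undefined", RuntimeWarning)
        return float("nan")
    return float((dy @ dh) ** 2 / denom)


def r2_residual(p: PredictionSet | None = None, y=None, y_hat=None) -> float:
    """Coefficient of determination as 1 − SSE/SST (identity-line variant)."""
    if p is None:
        p = PredictionSet(y=y, y_hat=y_hat)
    dy = p.y - p.y.mean()
    sst = float(dy @ dy)
    if sst == 0:
        warnings.warn("zero variance in y: residual R^2 undefined", RuntimeWarning)
        return float("nan")
    res = p.y - p.y_hat
    return 1.0 - float(res @ res) / sst


def rmse(p: PredictionSet | None = None, y=None, y_hat=None) -> float:
    """Root mean squared error with divisor n (no dof correction)."""
    if p is None:
        p = PredictionSet(y=y, y_hat=y_hat)
    if p.n == 0:
        raise ValueError("empty prediction set")
    res = p.y - p.y_hat
    return float(np.sqrt(res @ res / p.n))


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome: pooled held-out predictions + metrics."""

    scheme: str
    pooled: PredictionSet
    r2: float
    rmse: float
    n_components: int
    full_set_r2: float
    full_set_rmse: float
    r2_residual: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.pooled.ids) or list(range(self.pooled.n)),
                "observed": self.pooled.y,
                "predicted": self.pooled.y_hat,
            }
        )


def _folds(
    n: int, scheme: Literal["loocv", "kfold"], k: int | None, seed: int
) -> list[np.ndarray]:
    if scheme == "loocv":
        return [np.array([i]) for i in range(n)]
    if scheme != "kfold":
        raise ValueError(f"unknown scheme {scheme!r}")
    if k is None or not 2 <= k <= n:
        raise ValueError(f"kfold requires 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def cross_validate(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float],
    n_components: int,
    scheme: Literal["loocv", "kfold"] = "loocv",
    k: int | None = None,
    seed: int = 0,
    scale: bool = False,
    ids: Sequence[str] | None = None,
) -> CVReport:
    """Fit-on-remainder / predict-held-out over each fold; pool and score.

    LOOCV (k = n) is deterministic; k-fold uses a seeded shuffle.  The
    pooled prediction set keeps input order, one held-out prediction
    per sample.  Also fits on the full set and records the full-set
    metrics (the "learning-set" stage).
    """
    Xv = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n = Xv.shape[0]
    folds = _folds(n, scheme, k, seed)
    min_train = n - max(len(f) for f in folds)
    feasible = min(min_train - 1, Xv.shape[1])
    if n_components > feasible:
        raise ValueError(
            f"n_components={n_components} infeasible for smallest training fold "
            f"(max {feasible})"
        )
    y_hat = np.empty(n)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        m = fit_pls(Xv[mask], yv[mask], n_components=n_components, scale=scale)
        y_hat[fold] = predict(m, Xv[fold])
    if ids is None:
        ids = getattr(X, "row_ids", None) or tuple(str(i) for i in range(n))
    pooled = PredictionSet(y=yv, y_hat=y_hat, ids=tuple(ids))
    full = fit_pls(Xv, yv, n_components=n_components, scale=scale)
    full_set = PredictionSet(y=yv, y_hat=full.fitted_values, ids=tuple(ids))
    scheme_label = "loocv" if scheme == "loocv" else f"kfold({k})"
    return CVReport(
        scheme=scheme_label,
        pooled=pooled,
        r2=r_squared(pooled),
        rmse=rmse(pooled),
        n_components=n_components,
        full_set_r2=r_squared(full_set),
        full_set_rmse=rmse(full_set),
        r2_residual=r2_residual(pooled),
    )


def select_components(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float],
    max_components: int,
    scale: bool = False,
) -> int:
    """Component count in 1..max_components minimising LOOCV RMSE.

    Ties (within 1e−12) break toward fewer components.
    """
    Xv = _as_matrix(X)
    n = Xv.shape[0]
    cap = min(max_components, n - 2 if n > 2 else 1, Xv.shape[1])
    if cap < 1:
        raise ValueError("no feasible component count")
    best_a, best_rmse = None, np.inf
    for a in range(1, cap + 1):
        report = cross_validate(Xv, y, n_components=a, scheme="loocv", scale=scale)
        if report.rmse < best_rmse - 1e-12:
            best_a, best_rmse = a, report.rmse
    return best_a


def screen_indices(
    seqs: Sequence[str],
    ids: Sequence[str],
    y: Sequence[float],
    db: Iterable[EncodingIndex],
    mode: Mode = "fft",
    pad_to: int | None = None,
    energy: Energy = "squared",
    max_components: int = 10,
    scale: bool = False,
) -> pd.DataFrame:
    """Rank encoding indices by LOOCV performance of their models.

    For every usable index: encode the dataset, select the component
    count, and record LOOCV and full-set R²/RMSE.  Indices whose
    feature matrix is constant across variants (identical rows carry no
    signal) are skipped with a logged warning.  The table is sorted by
    LOOCV R² descending, ties broken by lower LOOCV RMSE then input
    order.
    """
    candidates = usable_indices(db)
    if not candidates:
        raise ValueError("no usable encoding indices to screen")
    rows = []
    for order, index in enumerate(candidates):
        fm = encode_dataset(seqs, ids, index, mode=mode, pad_to=pad_to, energy=energy)
        if np.allclose(fm.values, fm.values[0], rtol=0.0, atol=0.0):
            logger.warning(
                "index %s produces identical feature rows for all variants; skipped",
                index.accession,
            )
            continue
        a = select_components(fm, y, max_components=max_components, scale=scale)
        report = cross_validate(fm, y, n_components=a, scheme="loocv", scale=scale)
        rows.append(
            {
                "accession": index.accession,
                "description": index.description,
                "n_components": a,
                "loocv_r2": report.r2,
                "loocv_rmse": report.rmse,
                "full_set_r2": report.full_set_r2,
                "full_set_rmse": report.full_set_rmse,
                "_order": order,
            }
        )
    if not rows:
        raise ValueError("all candidate indices were degenerate on this dataset")
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["loocv_r2", "loocv_rmse", "_order"],
        ascending=[False, True, True],
        kind="stable",
    ).drop(columns="_order")
    return table.reset_index(drop=True)
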