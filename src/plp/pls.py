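"""NIPALS partial least squares (PLS) regression.

Implements the classic one-component-at-a-time NIPALS decomposition

    X = T Wt + E_X,   Y = U Qt + E_Y,   U = T Bt + E_U

with the loading rescaling convention that leaves every X-loading vector p
at unit length (t and w absorb ||p||).  For a univariate response the
Y-loading is exactly 1 and no inner iteration is performed.

Prediction uses Yhat = X RCt on the preprocessed scale.  The regression
matrix is assembled as RC = Q B W*t with the X-rotation weights
W* = W (Pt W)^-1, which makes the direct formula reproduce the sequential
score computation exactly (Pt W is unit upper triangular, so W* = W when a
single component is fitted).

Preprocessing policy: X columns are autoscaled (mean 0, unit variance,
ddof=1) by default, Y columns are mean-centered.  Explained variances are
reported on this preprocessed scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConvergenceError, ValidationError
from .model_io import RunConfig

__all__ = [
    "PLSComponent",
    "PLSModel",
    "autoscale",
    "nipals_component",
    "fit_pls",
    "pls_predict",
    "explained_variance_pct",
]

_TINY = 1e-300


def autoscale(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise standardization to mean 0 and unit variance (ddof=1).

    Returns ``(scaled, mean, scale)``.  Zero-variance columns are centered
    but carried with scale 1 (a warning names them) so downstream algebra
    stays finite.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValidationError("cannot autoscale an empty table")
    mean = table.mean(axis=0)
    scale = table.std(axis=0, ddof=1)
    flat = ~(scale > 0)
    if flat.any():
        warnings.warn(
            f"zero-variance column(s) carried with scale 1: {list(table.columns[flat])}",
            stacklevel=2,
        )
        scale = scale.where(~flat, 1.0)
    return (table - mean) / scale, mean, scale


def explained_variance_pct(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """``100 * (1 - sum((Y - Yhat)^2) / sum(Y^2))`` over all entries.

    Matrices are taken as already preprocessed (centered/scaled per
    policy); the value can be negative for fits worse than zero.
    """
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise ValidationError(f"shape mismatch {Y.shape} vs {Yhat.shape}")
    denom = float(np.sum(Y * Y))
    if denom <= _TINY:
        raise ValidationError("explained variance undefined for an all-zero reference")
    return 100.0 * (1.0 - float(np.sum((Y - Yhat) ** 2)) / denom)


@dataclass
class PLSComponent:
    """One latent variable: weights w, X-scores t, X-loadings p (unit
    length after rescaling), Y-loadings q, inner-regression slope b, and
    the number of NIPALS iterations spent (0 for the univariate shortcut)."""

    w: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    b: float
    n_iter: int


def nipals_component(X: np.ndarray, Y: np.ndarray, eps: float = 1e-8,
                     max_iter: int = 500, *, _force_iterative: bool = False) -> PLSComponent:
    """Extract a single NIPALS component from preprocessed X (np x nx) and
    Y (np x ny).

    For ``ny == 1`` the Y-loading is 1 by construction and the component is
    computed in a single pass without iteration.  The iterative branch
    starts from the Y column of largest variance (deterministic) and stops
    when ``||t - t_old|| < eps``; exceeding ``max_iter`` raises
    :class:`ConvergenceError` carrying the last increment.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise AlignmentError(f"X has {X.shape[0]} rows, Y has {Y.shape[0]}")
    if X.shape[0] < 2:
        raise ValidationError("at least two observations are required")
    ny = Y.shape[1]

    def _weights(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xu = X.T @ u
        norm = np.linalg.norm(xu)
        if norm <= _TINY:
            raise ValidationError("degenerate data: X'u has zero norm")
        w = xu / norm
        return w, X @ w

    if ny == 1 and not _force_iterative:
        u = Y[:, 0]
        q = np.ones(1)
        w, t = _weights(u)
        n_iter = 0
    else:
        u = Y[:, int(np.argmax(Y.var(axis=0)))]
        t_old = None
        delta = np.inf
        for n_iter in range(1, max_iter + 1):
            w, t = _weights(u)
            yt = Y.T @ t
            norm = np.linalg.norm(yt)
            if norm <= _TINY:
                raise ValidationError("degenerate data: Y't has zero norm")
            q = yt / norm
            u = Y @ q
            if t_old is not None:
                delta = float(np.linalg.norm(t - t_old))
                if delta < eps:
                    break
            t_old = t
        else:
            raise ConvergenceError(
                f"NIPALS did not converge in {max_iter} iterations "
                f"(last ||t - t_old|| = {delta:.3e})"
            )

    tt = float(t @ t)
    if tt <= _TINY:
        raise ValidationError("degenerate data: X-score vector has zero norm")
    p = X.T @ t / tt
    p_norm = float(np.linalg.norm(p))
    if p_norm <= _TINY:
        raise ValidationError("degenerate data: X-loading vector has zero norm")
    p = p / p_norm
    t = t * p_norm
    w = w * p_norm
    b = float(u @ t) / float(t @ t)
    return PLSComponent(w=w, t=t, p=p, q=q, b=b, n_iter=n_iter)


def _nipals_decompose(X: np.ndarray, Y: np.ndarray, n_components: int,
                      eps: float, max_iter: int,
                      nonconvergence: str = "raise") -> tuple[list[PLSComponent], list[float], list[float]]:
    """Run the full deflation loop on preprocessed arrays.

    Returns the components plus cumulative explained-variance trajectories
    for X and Y.  Stops early (with a warning) if deflation exhausts the
    numerical rank of X before the requested component count.  With
    ``nonconvergence="truncate"`` a component that exhausts the NIPALS
    iteration budget ends the fit with the components extracted so far
    instead of raising — appropriate for full-rank reference fits whose
    deepest components sit at the noise floor, where nearly tied
    covariance eigenvalues make the power iteration stall.
    """
    Xc = np.array(X, dtype=float)
    Yc = np.array(Y, dtype=float)
    x0 = float(np.sum(Xc * Xc))
    y0 = float(np.sum(Yc * Yc))
    components: list[PLSComponent] = []
    r2x_cum: list[float] = []
    r2y_cum: list[float] = []
    first_t_norm = None
    for _ in range(n_components):
        try:
            comp = nipals_component(Xc, Yc, eps=eps, max_iter=max_iter)
        except ConvergenceError:
            if nonconvergence == "truncate" and components:
                warnings.warn(
                    f"NIPALS stalled at component {len(components) + 1}; "
                    f"keeping {len(components)} components", stacklevel=2,
                )
                break
            raise
        t_norm = float(np.linalg.norm(comp.t))
        if first_t_norm is None:
            first_t_norm = t_norm
        elif t_norm < 1e-12 * first_t_norm:
            warnings.warn(
                f"rank exhausted after {len(components)} components; "
                f"requested {n_components}", stacklevel=2,
            )
            break
        components.append(comp)
        Xc = Xc - np.outer(comp.t, comp.p)
        Yc = Yc - comp.b * np.outer(comp.t, comp.q)
        r2x_cum.append(100.0 * (1.0 - float(np.sum(Xc * Xc)) / x0) if x0 > _TINY else 0.0)
        r2y_cum.append(100.0 * (1.0 - float(np.sum(Yc * Yc)) / y0))
    return components, r2x_cum, r2y_cum


def _rotation_weights(W: np.ndarray, P: np.ndarray) -> np.ndarray:
    """W* = W (Pt W)^-1 so that T = X W* holds on the undeflated X."""
    ptw = P.T @ W  # unit upper triangular
    return np.linalg.solve(ptw.T, W.T).T


@dataclass
class PLSModel:
    """A fitted PLS regression.

    ``RC`` (ny x nx) acts on the preprocessed X scale and yields centered
    Y; :meth:`predict` composes the unscaling so inputs and outputs are in
    original units.
    """

    x_columns: list[str]
    y_columns: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    components: list[PLSComponent]
    RC: np.ndarray
    r2x_cum: list[float] = field(default_factory=list)
    r2y_cum: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def W(self) -> np.ndarray:
        return np.column_stack([c.w for c in self.components])

    @property
    def P(self) -> np.ndarray:
        return np.column_stack([c.p for c in self.components])

    @property
    def Q(self) -> np.ndarray:
        return np.column_stack([c.q for c in self.components])

    @property
    def T(self) -> np.ndarray:
        return np.column_stack([c.t for c in self.components])

    @property
    def B(self) -> np.ndarray:
        return np.diag([c.b for c in self.components])

    def _check_columns(self, X_new: pd.DataFrame) -> None:
        if list(X_new.columns) == self.x_columns:
            return
        missing = [c for c in self.x_columns if c not in X_new.columns]
        extra = [c for c in X_new.columns if c not in self.x_columns]
        if missing or extra:
            raise AlignmentError(
                f"predictor columns do not match training columns; "
                f"missing {missing}, unexpected {extra}"
            )

    def predict(self, X_new: pd.DataFrame) -> pd.DataFrame:
        self._check_columns(X_new)
        xs = (X_new[self.x_columns].to_numpy(dtype=float) - self.x_mean) / self.x_scale
        yhat = xs @ self.RC.T + self.y_mean
        return pd.DataFrame(yhat, index=X_new.index, columns=self.y_columns)


def _as_frame(data, prefix: str) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(
        arr, columns=[f"{prefix}{j + 1}" for j in range(arr.shape[1])]
    )


def fit_pls(X, Y, n_components: int, config: RunConfig | None = None,
            nonconvergence: str = "raise") -> PLSModel:
    """Fit a NIPALS PLS regression of Y on X.

    ``X`` and ``Y`` may be data frames (rows must carry identical
    observation labels) or plain arrays.  ``n_components`` must not exceed
    the rank of the preprocessed X.  ``nonconvergence`` is ``"raise"``
    (default: a stalled component is an error) or ``"truncate"`` (keep the
    converged components; see :func:`_nipals_decompose`).
    """
    config = config or RunConfig()
    X = _as_frame(X, "x")
    Y = _as_frame(Y, "y")
    if list(X.index) != list(Y.index):
        bad = next(
            (a, b) for a, b in zip(list(X.index), list(Y.index)) if a != b
        ) if len(X) == len(Y) else ("<length>", "<mismatch>")
        raise AlignmentError(f"X/Y row labels differ, first mismatch: {bad[0]!r} vs {bad[1]!r}")
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")

    if config.scaling_policy == "autoscale_X":
        xs_frame, x_mean, x_scale = autoscale(X)
        xs = xs_frame.to_numpy(dtype=float)
        x_mean = x_mean.to_numpy(dtype=float)
        x_scale = x_scale.to_numpy(dtype=float)
    else:
        xs = X.to_numpy(dtype=float)
        x_mean = np.zeros(X.shape[1])
        x_scale = np.ones(X.shape[1])
    y_mean = Y.mean(axis=0).to_numpy(dtype=float)
    yc = Y.to_numpy(dtype=float) - y_mean

    rank = int(np.linalg.matrix_rank(xs))
    if n_components > rank:
        raise ValidationError(
            f"n_components={n_components} exceeds the rank {rank} of the scaled X"
        )
    if n_components > xs.shape[0]:
        raise ValidationError("n_components exceeds the number of observations")

    components, r2x_cum, r2y_cum = _nipals_decompose(
        xs, yc, n_components, config.eps_convergence, config.max_nipals_iter,
        nonconvergence=nonconvergence,
    )
    W = np.column_stack([c.w for c in components])
    P = np.column_stack([c.p for c in components])
    Q = np.column_stack([c.q for c in components])
    b = np.array([c.b for c in components])
    w_star = _rotation_weights(W, P)
    RC = (Q * b) @ w_star.T
    return PLSModel(
        x_columns=[str(c) for c in X.columns],
        y_columns=[str(c) for c in Y.columns],
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        components=components,
        RC=RC,
        r2x_cum=r2x_cum,
        r2y_cum=r2y_cum,
    )


def pls_predict(model: PLSModel, X_new: pd.DataFrame) -> pd.DataFrame:
    """Predict responses for new observations in original Y units."""
    return model.predict(_as_frame(X_new, "x"))
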