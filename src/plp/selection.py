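"""Projection to latent pathways: greedy, envirome-gated selection of
elementary flux modes.

The method treats elementary flux modes (EFMs) as fixed output loadings of
a PLS-like decomposition of measured exchange fluxes ``R`` (observations x
measured reactions).  For every candidate mode ``em_k`` restricted to the
measured reactions:

1.  project the current flux residual onto the mode to obtain its
    weighting-factor series, ``lambda_k = R q_k`` with ``q_k`` the
    (unit-normalized) mode;
2.  fit a univariate NIPALS PLS of ``lambda_k`` on the envirome ``X`` with
    ``Fac`` latent variables and form the prediction ``lambda_hat_k``;
3.  score the mode by the explained flux variance of the rank-one
    reconstruction ``Rhat_k = lambda_hat_k q_k'`` (always reported against
    the undeflated calibration fluxes, so the trajectory is cumulative).

The best-scoring mode is accepted only if the squared Pearson correlation
between ``lambda_k`` and ``lambda_hat_k`` exceeds ``r2_threshold`` with
p-value below ``p_threshold`` — the gate that keeps only modes whose
activity the environment can actually explain — and if the marginal
variance gain is non-negligible.  The accepted rank-one contribution is
deflated from ``R`` and the loop repeats with the remaining modes.

The final decomposition is ``R = Lambda EM_selected' + E_R``: scores are
mode weighting factors and loadings are metabolic pathways, which is what
distinguishes the method from ordinary PLS with abstract latent variables.

Notes on conventions (the source method leaves these open):

* each inner univariate PLS restarts from the full preprocessed envirome
  matrix (no X deflation between modes);
* the weighting factors are *not* constrained to be non-negative — the
  projection is a least-squares score, not a convex weight; the fraction of
  negative entries per selected mode is reported as a diagnostic;
* the p-value is the conventional two-sided correlation test
  ``t = r sqrt((n-2)/(1-r^2))`` with ``n-2`` degrees of freedom;
* ties on the variance score break toward the lower mode id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .efm import EFMSet
from .exceptions import AlignmentError, ValidationError
from .model_io import RunConfig
from .pls import _nipals_decompose, _rotation_weights, autoscale

__all__ = [
    "CandidateScore",
    "SelectedEFM",
    "PLPModel",
    "project_lambda",
    "evaluate_candidate",
    "select_efms",
    "plp_predict",
]

logger = logging.getLogger(__name__)

_TINY = 1e-300


@dataclass(frozen=True)
class CandidateScore:
    """Diagnostics of one candidate mode at one selection iteration."""

    efm_id: int
    r2: float
    p_value: float
    var_lambda_pct: float
    var_R_pct: float
    degenerate: bool = False
    neg_lambda_frac: float = 0.0


@dataclass(frozen=True)
class SelectedEFM:
    """An accepted mode: its loading over measured reactions, the inner
    univariate-PLS regression vector on the scaled envirome, and the score
    recorded at selection time."""

    efm_id: int
    n_lv: int
    loading: np.ndarray
    rc: np.ndarray
    lam_mean: float
    score: CandidateScore


def project_lambda(R, em, normalization: str = "unit_norm") -> np.ndarray:
    """Weighting-factor series of a mode: ``lambda = R q``.

    ``em`` must be aligned to the columns of ``R`` (measured reactions).
    With ``normalization="unit_norm"`` the mode is scaled to unit Euclidean
    norm first.
    """
    R = np.asarray(R, dtype=float)
    q = np.asarray(em, dtype=float)
    if R.ndim != 2 or q.shape != (R.shape[1],):
        raise AlignmentError(
            f"mode length {q.shape} does not match {R.shape[1]} measured reactions"
        )
    if normalization == "unit_norm":
        norm = np.linalg.norm(q)
        if norm <= _TINY:
            raise ValidationError("mode has no nonzero entry over measured reactions")
        q = q / norm
    elif normalization != "raw":
        raise ValidationError(f"unknown normalization {normalization!r}")
    return R @ q


def _fit_inner_univariate(xs: np.ndarray, lam_c: np.ndarray, config: RunConfig):
    """Univariate PLS of centered lambda on scaled X; returns (rc, n_lv)."""
    comps, _, _ = _nipals_decompose(
        xs, lam_c[:, None], config.n_inner_latent,
        config.eps_convergence, config.max_nipals_iter,
    )
    W = np.column_stack([c.w for c in comps])
    P = np.column_stack([c.p for c in comps])
    b = np.array([c.b for c in comps])
    w_star = _rotation_weights(W, P)
    rc = w_star @ b  # q = 1 throughout for a univariate response
    return rc, len(comps)


def evaluate_candidate(X, R_residual, em, config: RunConfig | None = None,
                       denom: float | None = None) -> CandidateScore:
    """Score one candidate mode against the current flux residual.

    ``X`` is the preprocessed (scaled) envirome matrix, ``R_residual`` the
    current centered/deflated flux matrix, ``em`` the mode restricted to
    the measured reactions.  ``denom`` is the reference sum of squares for
    the variance percentage (defaults to that of ``R_residual``, i.e. a
    first-iteration call).

    A mode whose weighting-factor series has (numerically) zero variance is
    scored ``r2=0, p=1`` and flagged degenerate rather than raising.
    """
    config = config or RunConfig()
    score, _, _, _ = _evaluate(
        np.asarray(X, dtype=float), np.asarray(R_residual, dtype=float),
        np.asarray(em, dtype=float), config,
        denom if denom is not None else float(np.sum(np.asarray(R_residual) ** 2)),
        efm_id=0,
    )
    return score


def _evaluate(xs: np.ndarray, r_cur: np.ndarray, em: np.ndarray,
              config: RunConfig, denom: float, efm_id: int):
    """Internal scorer returning (CandidateScore, lambda_hat, q_used, rc)."""
    q = em
    if config.efm_normalization == "unit_norm":
        norm = np.linalg.norm(q)
        q = q / norm if norm > _TINY else q
    lam = r_cur @ q
    lam_mean = float(lam.mean())
    lam_c = lam - lam_mean
    lam_ss = float(lam_c @ lam_c)
    neg_frac = float(np.mean(lam < 0.0))
    scale = float(np.abs(lam).max()) if lam.size else 0.0

    base_var = 100.0 * (1.0 - float(np.sum(r_cur * r_cur)) / denom)
    if lam_ss <= max(1e-24, (1e-12 * max(scale, 1.0)) ** 2) or np.linalg.norm(q) <= _TINY:
        score = CandidateScore(efm_id, 0.0, 1.0, 0.0, base_var, True, neg_frac)
        return score, np.zeros_like(lam), q, np.zeros(xs.shape[1])

    rc, n_lv = _fit_inner_univariate(xs, lam_c, config)
    lam_hat_c = xs @ rc
    lam_hat = lam_hat_c + lam_mean
    resid = r_cur - np.outer(lam_hat, q)
    var_r = 100.0 * (1.0 - float(np.sum(resid * resid)) / denom)
    var_lambda = 100.0 * (1.0 - float(np.sum((lam_c - lam_hat_c) ** 2)) / lam_ss)
    if float(np.std(lam_hat_c)) <= 1e-15 * max(scale, 1.0):
        r2, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(lam, lam_hat)
        r2, p = float(r * r), float(p)
    score = CandidateScore(efm_id, r2, p, var_lambda, var_r, False, neg_frac)
    return score, lam_hat, q, rc


@dataclass
class PLPModel:
    """A fitted projection-to-latent-pathways decomposition."""

    x_columns: list[str]
    r_columns: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    r_mean: np.ndarray
    selected: list[SelectedEFM]
    Lambda: pd.DataFrame
    residual_R: pd.DataFrame
    cum_var_R_pct: list[float]
    config: RunConfig
    history: list[pd.DataFrame] = field(default_factory=list)

    @property
    def selected_efm_ids(self) -> list[int]:
        return [s.efm_id for s in self.selected]

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def calibration_var_R_pct(self) -> float:
        return self.cum_var_R_pct[-1] if self.cum_var_R_pct else 0.0

    def loadings_matrix(self) -> np.ndarray:
        """Measured-reaction loadings of the selected modes (nr x K)."""
        if not self.selected:
            return np.zeros((len(self.r_columns), 0))
        return np.column_stack([s.loading for s in self.selected])

    def coefficients_frame(self) -> pd.DataFrame:
        """Inner-PLS regression coefficients (scaled envirome space), one
        row per (selected mode, envirome variable)."""
        rows = []
        for s in self.selected:
            for var, c in zip(self.x_columns, s.rc):
                rows.append((s.efm_id, var, float(c)))
        return pd.DataFrame(rows, columns=["efm_id", "envirome_var", "coefficient"])

    def _scale_new(self, X_new: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.x_columns if c not in X_new.columns]
        extra = [c for c in X_new.columns if c not in self.x_columns]
        if missing or extra:
            raise AlignmentError(
                f"envirome columns do not match training columns; "
                f"missing {missing}, unexpected {extra}"
            )
        return (X_new[self.x_columns].to_numpy(dtype=float) - self.x_mean) / self.x_scale

    def predict(self, X_new: pd.DataFrame) -> pd.DataFrame:
        """Reconstruct fluxes from the envirome: ``Rhat = sum_k
        lambda_hat_k(X) q_k' + column means``.

        With no selected modes this is the column-mean baseline.
        """
        xs = self._scale_new(X_new)
        rhat = np.tile(self.r_mean, (xs.shape[0], 1))
        for s in self.selected:
            lam_hat = xs @ s.rc + s.lam_mean
            rhat += np.outer(lam_hat, s.loading)
        return pd.DataFrame(rhat, index=X_new.index, columns=self.r_columns)


def select_efms(X: pd.DataFrame, R: pd.DataFrame, efms: EFMSet,
                config: RunConfig | None = None) -> PLPModel:
    """Run the greedy selection loop.

    ``X`` and ``R`` must share row labels; every measured flux column of
    ``R`` must correspond to a row of the mode matrix.  Returns a
    :class:`PLPModel` whose ``history`` holds the full per-iteration score
    table of every remaining candidate (the audit trail behind the
    selection report).
    """
    config = config or RunConfig()
    if list(X.index) != list(R.index):
        pairs = zip(list(X.index), list(R.index))
        bad = next(((a, b) for a, b in pairs if a != b), ("<length>", "<length>"))
        raise AlignmentError(
            f"X/R row labels differ, first mismatch: {bad[0]!r} vs {bad[1]!r}"
        )
    if efms.n_modes == 0:
        raise ValidationError("empty EFM set")
    row_of = {r: i for i, r in enumerate(efms.reaction_ids)}
    missing = [c for c in R.columns if c not in row_of]
    if missing:
        raise AlignmentError(
            f"flux column(s) {missing} have no row in the EFM matrix"
        )
    n_obs = X.shape[0]
    fac = config.n_inner_latent
    if n_obs < fac + 2:
        raise ValidationError(
            f"need at least Fac+2 = {fac + 2} observations, got {n_obs}"
        )

    if config.scaling_policy == "autoscale_X":
        xs_frame, x_mean, x_scale = autoscale(X)
        xs = xs_frame.to_numpy(dtype=float)
        x_mean = x_mean.to_numpy(dtype=float)
        x_scale = x_scale.to_numpy(dtype=float)
    else:
        xs = X.to_numpy(dtype=float)
        x_mean = np.zeros(X.shape[1])
        x_scale = np.ones(X.shape[1])
    if fac > int(np.linalg.matrix_rank(xs)):
        raise ValidationError(
            f"n_inner_latent={fac} exceeds the rank of the scaled envirome matrix"
        )

    em_meas = efms.EM[[row_of[c] for c in R.columns], :]
    r_mean = R.mean(axis=0).to_numpy(dtype=float)
    r_cur = R.to_numpy(dtype=float) - r_mean
    denom = float(np.sum(r_cur * r_cur))
    if denom <= _TINY:
        raise ValidationError("flux matrix has zero variance")

    remaining = list(range(efms.n_modes))
    selected: list[SelectedEFM] = []
    lambda_columns: list[np.ndarray] = []
    cum_trajectory: list[float] = []
    history: list[pd.DataFrame] = []
    cum = 0.0
    max_select = min(config.max_efms, n_obs)

    while remaining and len(selected) < max_select:
        results = []
        for k in remaining:
            score, lam_hat, q_used, rc = _evaluate(
                xs, r_cur, em_meas[:, k], config, denom, efms.efm_ids[k]
            )
            results.append((k, score, lam_hat, q_used, rc))
        history.append(pd.DataFrame(
            [(s.efm_id, s.r2, s.p_value, s.var_lambda_pct, s.var_R_pct,
              s.degenerate, s.neg_lambda_frac) for _, s, _, _, _ in results],
            columns=["efm_id", "r2", "p_value", "var_lambda_pct", "var_R_pct",
                     "degenerate", "neg_lambda_frac"],
        ))
        k_best, best_score, best_lam_hat, best_q, best_rc = min(
            results, key=lambda item: (-item[1].var_R_pct, item[1].efm_id)
        )
        gain = best_score.var_R_pct - cum
        accepted = (
            not best_score.degenerate
            and best_score.r2 > config.r2_threshold
            and best_score.p_value < config.p_threshold
            and gain >= config.min_variance_gain
        )
        if not accepted:
            logger.info(
                "stop: best candidate EFM %s (var %.2f%%, gain %.3g, r2 %.3f, p %.2e) "
                "fails the acceptance gate",
                best_score.efm_id, best_score.var_R_pct, gain,
                best_score.r2, best_score.p_value,
            )
            break
        lam = r_cur @ best_q  # weighting factors at selection time
        r_cur = r_cur - np.outer(best_lam_hat, best_q)
        cum = best_score.var_R_pct
        cum_trajectory.append(cum)
        lambda_columns.append(lam)
        selected.append(SelectedEFM(
            efm_id=best_score.efm_id,
            n_lv=config.n_inner_latent,
            loading=best_q.copy(),
            rc=best_rc,
            lam_mean=float(lam.mean()),
            score=best_score,
        ))
        logger.info(
            "iteration %d: selected EFM %s (cum var %.2f%%, gain %.2f, "
            "r2 %.3f, p %.2e, %d candidates left)",
            len(selected), best_score.efm_id, cum, gain,
            best_score.r2, best_score.p_value, len(remaining) - 1,
        )
        remaining.remove(k_best)

    # Lambda holds the weighting factors at selection time, i.e. the
    # projections of the then-current residual onto each accepted mode.
    lam_data = (np.column_stack(lambda_columns) if lambda_columns
                else np.zeros((n_obs, 0)))
    model = PLPModel(
        x_columns=[str(c) for c in X.columns],
        r_columns=[str(c) for c in R.columns],
        x_mean=x_mean,
        x_scale=x_scale,
        r_mean=r_mean,
        selected=selected,
        Lambda=pd.DataFrame(
            lam_data, index=X.index, columns=[str(s.efm_id) for s in selected]
        ),
        residual_R=pd.DataFrame(r_cur, index=R.index, columns=R.columns),
        cum_var_R_pct=cum_trajectory,
        config=config,
        history=history,
    )
    return model


def plp_predict(model: PLPModel, X_new: pd.DataFrame) -> pd.DataFrame:
    """Functional alias for :meth:`PLPModel.predict`."""
    return model.predict(X_new)
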