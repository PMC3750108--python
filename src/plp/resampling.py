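"""Bootstrap over random calibration/validation partitions.

Each run draws a 50/50 split of the observations (without replacement,
optionally stratified by experiment label), fits the mode-selection model
and a full-component PLS on the calibration half, and evaluates both on
the validation half.  Across runs this yields

* per-mode selection frequencies (selection count / number of runs),
* per-mode regression-coefficient means, standard deviations and
  t-based confidence intervals ``B_mean +/- S * t(1 - alpha/2, dof)``,
* the paired calibration/validation explained-variance comparison between
  the constrained and the unconstrained model.

The standard deviation uses the ``z - 1`` denominator over the runs in
which a mode was actually selected.  The degrees of freedom subtract the
inner latent-variable count ``Fac``; by default ``z`` is the per-mode
selection count (``dof_policy="per_efm"``), with ``"global"`` using the
total run count instead — the two coincide for modes selected in every
run.

Reproducibility: run ``i`` uses the child seed ``(master_seed, i)``, so
adding runs never changes earlier runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .efm import EFMSet
from .exceptions import ValidationError
from .model_io import RunConfig
from .pls import explained_variance_pct, fit_pls
from .selection import select_efms

__all__ = [
    "BootstrapRun",
    "BootstrapResult",
    "run_bootstrap",
    "selection_frequency",
    "coefficient_confidence",
    "validation_win_count",
]


@dataclass
class BootstrapRun:
    run_index: int
    cal_rows: np.ndarray
    val_rows: np.ndarray
    selected_efm_ids: list[int]
    plp_cal_var: float
    plp_val_var: float
    pls_cal_var: float
    pls_val_var: float
    coefficients: dict[int, np.ndarray]  # efm_id -> inner RC on scaled X


@dataclass
class BootstrapResult:
    runs: list[BootstrapRun]
    n_runs: int
    fac: int
    x_columns: list[str]
    master_seed: int

    def variance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.run_index, len(r.selected_efm_ids), r.plp_cal_var,
                 r.plp_val_var, r.pls_cal_var, r.pls_val_var)
                for r in self.runs
            ],
            columns=["run", "n_selected", "plp_cal_var_pct", "plp_val_var_pct",
                     "pls_cal_var_pct", "pls_val_var_pct"],
        )


def _split_half(rng: np.random.Generator, n_obs: int,
                groups: Sequence | None) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive 50/50 partition (sizes equal up to 1)."""
    if groups is None:
        perm = rng.permutation(n_obs)
        n_cal = (n_obs + 1) // 2
        return np.sort(perm[:n_cal]), np.sort(perm[n_cal:])
    groups = np.asarray(groups)
    if groups.shape[0] != n_obs:
        raise ValidationError("groups length does not match the observation count")
    cal: list[int] = []
    val: list[int] = []
    seen: list = []
    for g in groups:
        if g not in seen:
            seen.append(g)
    for g in seen:
        idx = np.flatnonzero(groups == g)
        perm = rng.permutation(idx)
        half = len(idx) // 2
        take_cal = half + (1 if len(idx) % 2 == 1 and len(cal) <= len(val) else 0)
        cal.extend(perm[:take_cal].tolist())
        val.extend(perm[take_cal:].tolist())
    return np.sort(np.array(cal, dtype=int)), np.sort(np.array(val, dtype=int))


def run_bootstrap(X: pd.DataFrame, R: pd.DataFrame, efms: EFMSet,
                  config: RunConfig | None = None, n_runs: int = 200,
                  seed: int = 0, groups: Sequence | None = None,
                  pls_components: int | None = None) -> BootstrapResult:
    """Repeat PLP and full PLS over random calibration/validation splits.

    ``pls_components`` defaults to the rank of the scaled calibration
    envirome matrix of each run (the "all latent variables" comparison
    model).  The result is a pure function of the inputs and ``seed``.
    """
    config = config or RunConfig()
    fac = config.n_inner_latent
    n_obs = X.shape[0]
    if n_obs < 2 * (fac + 2):
        raise ValidationError(
            f"need at least 2*(Fac+2) = {2 * (fac + 2)} observations, got {n_obs}"
        )
    runs: list[BootstrapRun] = []
    for i in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        cal, val = _split_half(rng, n_obs, groups)
        x_cal, r_cal = X.iloc[cal], R.iloc[cal]
        x_val, r_val = X.iloc[val], R.iloc[val]

        plp_model = select_efms(x_cal, r_cal, efms, config)
        plp_val = explained_variance_pct(
            r_val.to_numpy(dtype=float) - plp_model.r_mean,
            plp_model.predict(x_val).to_numpy(dtype=float) - plp_model.r_mean,
        )

        if pls_components is None:
            x_scaled = (x_cal - x_cal.mean()) / x_cal.std(ddof=1).replace(0.0, 1.0)
            k = int(np.linalg.matrix_rank(x_scaled.to_numpy(dtype=float)))
        else:
            k = pls_components
        pls_model = fit_pls(x_cal, r_cal, n_components=k, config=config,
                            nonconvergence="truncate")
        pls_val = explained_variance_pct(
            r_val.to_numpy(dtype=float) - pls_model.y_mean,
            pls_model.predict(x_val).to_numpy(dtype=float) - pls_model.y_mean,
        )

        runs.append(BootstrapRun(
            run_index=i,
            cal_rows=cal,
            val_rows=val,
            selected_efm_ids=list(plp_model.selected_efm_ids),
            plp_cal_var=plp_model.calibration_var_R_pct,
            plp_val_var=float(plp_val),
            pls_cal_var=pls_model.r2y_cum[-1] if pls_model.r2y_cum else 0.0,
            pls_val_var=float(pls_val),
            coefficients={s.efm_id: s.rc.copy() for s in plp_model.selected},
        ))
    return BootstrapResult(
        runs=runs, n_runs=n_runs, fac=fac,
        x_columns=[str(c) for c in X.columns], master_seed=seed,
    )


def selection_frequency(result: BootstrapResult,
                        include_never: Sequence[int] | None = None) -> pd.DataFrame:
    """Selection count / total runs per mode, sorted by descending frequency.

    Modes never selected are absent unless listed in ``include_never``.
    """
    if not result.runs:
        raise ValidationError("empty bootstrap result")
    counts: dict[int, int] = {}
    for run in result.runs:
        for efm_id in run.selected_efm_ids:
            counts[efm_id] = counts.get(efm_id, 0) + 1
    if include_never is not None:
        for efm_id in include_never:
            counts.setdefault(int(efm_id), 0)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [(efm_id, c, c / result.n_runs) for efm_id, c in rows],
        columns=["efm_id", "count", "frequency"],
    )


def coefficient_confidence(result: BootstrapResult, alpha: float = 0.05,
                           fac: int | None = None,
                           dof_policy: str = "per_efm") -> pd.DataFrame:
    """Bootstrap mean/SD/confidence intervals of the inner regression
    coefficients, one row per (mode, envirome variable).

    Modes selected in fewer than two runs are excluded with a warning
    (their spread is undefined).
    """
    if dof_policy not in ("per_efm", "global"):
        raise ValidationError(f"unknown dof_policy {dof_policy!r}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    fac = result.fac if fac is None else fac
    draws: dict[int, list[np.ndarray]] = {}
    for run in result.runs:
        for efm_id, rc in run.coefficients.items():
            draws.setdefault(efm_id, []).append(np.asarray(rc, dtype=float))
    rows = []
    for efm_id in sorted(draws):
        B = np.vstack(draws[efm_id])
        z = B.shape[0]
        if z < 2:
            warnings.warn(
                f"EFM {efm_id} selected in only {z} run(s); excluded from "
                "confidence intervals", stacklevel=2,
            )
            continue
        mean = B.mean(axis=0)
        sd = B.std(axis=0, ddof=1)
        dof = max((z if dof_policy == "per_efm" else result.n_runs) - fac, 1)
        t_q = float(stats.t.ppf(1.0 - alpha / 2.0, dof))
        for j, var in enumerate(result.x_columns):
            rows.append((
                efm_id, var, z, float(mean[j]), float(sd[j]),
                float(mean[j] - t_q * sd[j]), float(mean[j] + t_q * sd[j]),
            ))
    return pd.DataFrame(
        rows,
        columns=["efm_id", "envirome_var", "n_selected", "mean", "sd",
                 "ci_low", "ci_high"],
    )


def validation_win_count(result: BootstrapResult) -> int:
    """Number of runs in which the constrained model beat full PLS on
    validation explained variance (strict inequality)."""
    return int(sum(r.plp_val_var > r.pls_val_var for r in result.runs))
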