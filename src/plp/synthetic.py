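"""Synthetic networks, mode sets and envirome/flux datasets with known
ground truth.

The dataset generator emulates the structure of a multi-experiment
bioprocess campaign: a moderate number of observations drawn from several
independent experiment blocks, envirome variables following smooth
within-block trajectories, a small subset of "active" flux modes whose
weighting factors are (softplus-rectified) linear functions of the
envirome, and measured exchange fluxes formed as the weighted sum of the
active modes plus i.i.d. Gaussian measurement noise scaled relative to the
signal.  Defaults mirror a campaign of 134 observations from 7
experiments with 26 envirome variables and 24 measured exchange fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .efm import EFMSet
from .exceptions import ValidationError
from .model_io import NetworkModel

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "generate_toy_network",
    "random_network",
    "default_reaction_ids",
    "random_modes",
    "generate_dataset",
    "experiment_groups",
]


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def _chain_network(n_reactions: int) -> NetworkModel:
    if n_reactions < 2:
        raise ValidationError("a chain needs at least 2 reactions")
    internal = tuple(f"M{i}" for i in range(1, n_reactions))
    mets = ["Sext", *internal, "Pext"]
    stoich = {}
    ids = tuple(f"v{i}" for i in range(1, n_reactions + 1))
    for i, rxn in enumerate(ids):
        stoich[rxn] = {mets[i]: Fraction(-1), mets[i + 1]: Fraction(1)}
    return NetworkModel(
        reaction_ids=ids,
        stoich=stoich,
        reversible={r: False for r in ids},
        internal_metabolites=internal,
        external_metabolites=("Sext", "Pext"),
    )


def _diamond_network() -> NetworkModel:
    """Two parallel irreversible routes from A to B plus exchanges (2 modes)."""
    ids = ("up", "top", "bot1", "bot2", "out")
    stoich = {
        "up": {"Aext": Fraction(-1), "A": Fraction(1)},
        "top": {"A": Fraction(-1), "B": Fraction(1)},
        "bot1": {"A": Fraction(-1), "C": Fraction(1)},
        "bot2": {"C": Fraction(-1), "B": Fraction(1)},
        "out": {"B": Fraction(-1), "Bext": Fraction(1)},
    }
    return NetworkModel(
        reaction_ids=ids,
        stoich=stoich,
        reversible={r: False for r in ids},
        internal_metabolites=("A", "B", "C"),
        external_metabolites=("Aext", "Bext"),
    )


def random_network(seed: int = 0, n_internal: int = 4, n_reactions: int = 7,
                   p_reversible: float = 0.3, n_extra_exchange: int = 0) -> NetworkModel:
    """A random sparse network guaranteed to contain at least one mode.

    A linear "spine" (uptake -> M1 -> ... -> Mk -> secretion) is embedded
    first; remaining reactions are random conversions between internal
    metabolites (small integer stoichiometry) or extra exchange reactions.
    """
    if n_internal < 1:
        raise ValidationError("need at least one internal metabolite")
    spine_len = n_internal + 1  # conversions along the spine + secretion
    if n_reactions < spine_len + 1:
        raise ValidationError(
            f"need at least {spine_len + 1} reactions for {n_internal} internal metabolites"
        )
    rng = np.random.default_rng(seed)
    internal = [f"M{i}" for i in range(1, n_internal + 1)]
    external = ["Sext", "Pext"]
    stoich: dict[str, dict[str, Fraction]] = {}
    reversible: dict[str, bool] = {}
    ids: list[str] = []

    def _add(name: str, coeffs: dict[str, Fraction], rev: bool) -> None:
        ids.append(name)
        stoich[name] = coeffs
        reversible[name] = rev

    _add("v1", {"Sext": Fraction(-1), internal[0]: Fraction(1)}, False)
    for i in range(n_internal - 1):
        _add(f"v{i + 2}", {internal[i]: Fraction(-1), internal[i + 1]: Fraction(1)},
             bool(rng.random() < p_reversible))
    _add(f"v{n_internal + 1}", {internal[-1]: Fraction(-1), "Pext": Fraction(1)}, False)

    n_extra = n_reactions - len(ids)
    extra_exchange = min(n_extra_exchange, n_extra)
    for j in range(n_extra):
        name = f"v{len(ids) + 1}"
        if j < extra_exchange:
            met = internal[int(rng.integers(n_internal))]
            if rng.random() < 0.5:
                coeffs = {"Sext": Fraction(-1), met: Fraction(1)}
            else:
                coeffs = {met: Fraction(-1), "Pext": Fraction(1)}
            _add(name, coeffs, False)
            continue
        a, b = rng.choice(n_internal, size=2, replace=False)
        ca = int(rng.integers(1, 3))
        cb = int(rng.integers(1, 3))
        _add(name, {internal[a]: Fraction(-ca), internal[b]: Fraction(cb)},
             bool(rng.random() < p_reversible))
    return NetworkModel(
        reaction_ids=tuple(ids),
        stoich=stoich,
        reversible=reversible,
        internal_metabolites=tuple(internal),
        external_metabolites=tuple(external),
    )


def generate_toy_network(template: str, size: int = 3, seed: int = 0,
                         **params) -> NetworkModel:
    """Build a named toy network: ``chain``, ``diamond`` or
    ``bhk_like_random`` (a sparse random network in the 30-60 reaction
    range with several exchange reactions)."""
    if template == "chain":
        return _chain_network(size)
    if template == "diamond":
        return _diamond_network()
    if template == "bhk_like_random":
        defaults = dict(n_internal=10, n_reactions=34, p_reversible=0.2,
                        n_extra_exchange=6)
        defaults.update(params)
        return random_network(seed=seed, **defaults)
    raise ValidationError(f"unknown network template {template!r}")


# ---------------------------------------------------------------------------
# Candidate mode matrices
# ---------------------------------------------------------------------------

def default_reaction_ids(n: int = 24) -> tuple[str, ...]:
    """Measured-exchange-flux names used by the default generator."""
    return tuple(f"flux{i:02d}" for i in range(1, n + 1))


def random_modes(n_modes: int = 200, reaction_ids: Sequence[str] | None = None,
                 seed: int | Sequence[int] = 0,
                 support_range: tuple[int, int] = (4, 8)) -> EFMSet:
    """A synthetic candidate-mode matrix in reduced (exchange-flux) form.

    Columns are unit-norm vectors over the measured reactions with sparse
    random supports and mixed signs (every mode consumes at least one
    compound and produces at least one).  These are stand-ins for the
    reduced form of enumerated modes — they are *not* validated against any
    stoichiometry, which is irrelevant to the selection machinery that
    consumes them.
    """
    reaction_ids = tuple(reaction_ids) if reaction_ids is not None else default_reaction_ids()
    q = len(reaction_ids)
    lo, hi = support_range
    if not (1 <= lo <= hi <= q):
        raise ValidationError(f"support_range {support_range} invalid for {q} reactions")
    rng = np.random.default_rng(seed)
    em = np.zeros((q, n_modes))
    seen: set[tuple] = set()
    k = 0
    attempts = 0
    while k < n_modes:
        attempts += 1
        if attempts > 100 * n_modes:
            raise ValidationError("could not draw enough distinct supports")
        size = int(rng.integers(lo, hi + 1))
        support = np.sort(rng.choice(q, size=size, replace=False))
        vals = rng.normal(size=size)
        vals[0] = -abs(vals[0])  # at least one consumed
        vals[-1] = abs(vals[-1])  # at least one produced
        key = (tuple(support.tolist()), tuple(np.sign(vals).astype(int).tolist()))
        if key in seen:
            continue
        seen.add(key)
        col = np.zeros(q)
        col[support] = vals / np.linalg.norm(vals)
        em[:, k] = col
        k += 1
    return EFMSet(
        efm_ids=tuple(range(1, n_modes + 1)),
        EM=em,
        reaction_ids=reaction_ids,
        reversibility_tags=(False,) * n_modes,
    )


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the dataset generator.

    Defaults reproduce the campaign shape the package targets: 134
    observations from 7 experiments, 26 envirome variables, 3 active modes,
    measurement noise at 5% of the centered flux signal RMS and 2% noise on
    the envirome trajectories.  ``lambda_offset`` shifts the softplus
    argument; the default of 5 keeps the rectification essentially inactive
    (the best linear approximation of softplus(z+5) over z ~ N(0,1) leaves
    under 1% residual), so weighting factors are positive yet linear in the
    envirome up to a distortion well below the measurement noise.
    """

    n_obs: int = 134
    n_envirome_vars: int = 26
    n_experiments: int = 7
    n_active: int = 3
    active_efm_ids: tuple[int, ...] | None = None
    coefficients: np.ndarray | None = None
    noise_sd_R: float = 0.05
    noise_sd_X: float = 0.02
    lambda_offset: float = 5.0
    n_latent_trajectories: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_obs < 2 or self.n_envirome_vars < 1:
            raise ValidationError("need at least 2 observations and 1 envirome variable")
        if not (1 <= self.n_experiments <= self.n_obs):
            raise ValidationError("n_experiments must lie in [1, n_obs]")
        if self.noise_sd_R < 0 or self.noise_sd_X < 0:
            raise ValidationError("noise standard deviations must be non-negative")
        if self.active_efm_ids is not None and len(self.active_efm_ids) == 0:
            raise ValidationError("active mode set must be non-empty")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used: the active mode ids, their
    weighting-factor series and the envirome-to-weight coefficients."""

    Lambda_true: pd.DataFrame
    active_efm_ids: tuple[int, ...]
    C: np.ndarray
    seed: int


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _draw_disjoint_active(efms: EFMSet, n_active: int,
                          rng: np.random.Generator, tol: float = 1e-12) -> tuple[int, ...]:
    """Draw an active mode set with pairwise disjoint reaction supports.

    Disjoint supports make the active modes mutually orthogonal, so each
    carries an identifiable flux signature — the textbook identifiable
    regime for a selection benchmark.  Falls back to the lowest-overlap
    draw seen if no fully disjoint set exists in the candidate dictionary.
    """
    supports = [frozenset(np.flatnonzero(np.abs(efms.EM[:, k]) > tol).tolist())
                for k in range(efms.n_modes)]
    pool = np.arange(efms.n_modes)
    best: tuple[int, list[int]] | None = None
    for _ in range(200):
        order = rng.permutation(pool)
        chosen: list[int] = []
        overlaps = 0
        for k in order:
            o = sum(len(supports[k] & supports[c]) for c in chosen)
            if o == 0:
                chosen.append(int(k))
            if len(chosen) == n_active:
                break
        if len(chosen) == n_active:
            return tuple(sorted(efms.efm_ids[k] for k in chosen))
        if best is None or len(chosen) > best[0]:
            best = (len(chosen), chosen)
    # no fully disjoint set available: top up greedily by minimal overlap
    chosen = best[1] if best else []
    while len(chosen) < n_active:
        rest = [k for k in pool if k not in chosen]
        k = min(rest, key=lambda k: sum(len(supports[k] & supports[c]) for c in chosen))
        chosen.append(int(k))
    return tuple(sorted(efms.efm_ids[k] for k in chosen))


def _block_sizes(n_obs: int, n_blocks: int) -> list[int]:
    base = n_obs // n_blocks
    sizes = [base] * n_blocks
    for i in range(n_obs - base * n_blocks):
        sizes[i] += 1
    return sizes


def generate_dataset(efms: EFMSet, spec: GeneratorSpec | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw an envirome matrix X, a flux matrix R and the ground truth.

    ``R = Lambda_true @ EM_active' + noise`` with
    ``Lambda_true = softplus(offset + X_std @ C')`` restricted to the active
    modes — weighting factors are non-negative by construction and
    near-linear in the envirome, so the selection machinery has a
    recoverable target.  Same spec, same seed: bit-identical tables.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    n_obs, nx = spec.n_obs, spec.n_envirome_vars

    if spec.active_efm_ids is None:
        active = _draw_disjoint_active(efms, spec.n_active, rng)
    else:
        active = tuple(int(i) for i in spec.active_efm_ids)
        unknown = [i for i in active if i not in efms.efm_ids]
        if unknown:
            raise ValidationError(f"active mode id(s) {unknown} not in the candidate set")

    # Smooth per-experiment trajectories of a few shared latent process
    # states, mapped through one loading matrix: envirome variables co-vary
    # strongly (the collinearity typical of bioprocess campaigns), so the
    # envirome signal is low-rank while each experiment follows its own
    # time course.
    sizes = _block_sizes(n_obs, spec.n_experiments)
    n_lat = spec.n_latent_trajectories
    loadings = rng.normal(size=(n_lat, nx))
    blocks = []
    row_ids = []
    for e, size in enumerate(sizes, start=1):
        t = np.linspace(0.0, 1.0, size)[:, None]
        coef = rng.normal(size=(4, n_lat))
        freq = rng.integers(1, 3, size=n_lat)
        phase = rng.uniform(0, 2 * np.pi, size=n_lat)
        latents = (
            coef[0] + coef[1] * t + coef[2] * t ** 2
            + coef[3] * np.sin(2 * np.pi * freq * t + phase)
        )  # size x n_lat
        blocks.append(latents @ loadings)
        row_ids.extend(f"E{e}:t{i:03d}" for i in range(size))
    x = np.vstack(blocks)
    if spec.noise_sd_X > 0:
        col_sd = x.std(axis=0, ddof=0)
        col_sd[col_sd == 0] = 1.0
        x = x + spec.noise_sd_X * col_sd * rng.standard_normal(x.shape)

    x_sd = x.std(axis=0, ddof=0)
    x_sd[x_sd == 0] = 1.0
    x_std = (x - x.mean(axis=0)) / x_sd

    if spec.coefficients is None:
        C = np.zeros((len(active), nx))
        for k in range(len(active)):
            support = rng.choice(nx, size=min(5, nx), replace=False)
            vals = rng.normal(size=support.size)
            C[k, support] = vals / np.linalg.norm(vals)
    else:
        C = np.asarray(spec.coefficients, dtype=float)
        if C.shape != (len(active), nx):
            raise ValidationError(
                f"coefficient matrix shape {C.shape} does not match "
                f"({len(active)}, {nx})"
            )

    lam_true = _softplus(spec.lambda_offset + x_std @ C.T)
    em_active = np.column_stack([efms.column(i) for i in active])
    signal = lam_true @ em_active.T
    r = signal.copy()
    if spec.noise_sd_R > 0:
        centered = signal - signal.mean(axis=0)
        rms = float(np.sqrt(np.mean(centered ** 2)))
        r = signal + spec.noise_sd_R * rms * rng.standard_normal(signal.shape)

    x_cols = [f"env{j:02d}" for j in range(1, nx + 1)]
    X = pd.DataFrame(x, index=row_ids, columns=x_cols)
    R = pd.DataFrame(r, index=row_ids, columns=list(efms.reaction_ids))
    truth = GroundTruth(
        Lambda_true=pd.DataFrame(lam_true, index=row_ids,
                                 columns=[str(i) for i in active]),
        active_efm_ids=active,
        C=C,
        seed=spec.seed,
    )
    return X, R, truth


def experiment_groups(index: Sequence[str]) -> list[str] | None:
    """Experiment labels parsed from ``"E3:t007"``-style row ids, or None
    when the ids do not carry a block prefix."""
    labels = [str(i) for i in index]
    if all(":" in lab for lab in labels):
        return [lab.split(":", 1)[0] for lab in labels]
    return None
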