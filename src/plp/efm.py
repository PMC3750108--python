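"""Elementary flux mode enumeration for small metabolic networks.

An elementary flux mode (EFM) is a support-minimal flux vector ``v`` with
``N_int v = 0`` (steady state over internal metabolites) and ``v_j >= 0``
for every irreversible reaction ``j``.  The set of EFMs generates the flux
cone: every admissible steady-state flux distribution is a non-negative
combination of EFMs.

The enumerator works in exact integer arithmetic.  Reversible reactions are
split into forward/backward halves, turning the flux cone into a pointed
cone whose extreme rays are computed by the double description method
(constraints added one hyperplane at a time with the combinatorial
adjacency test).  Rays are then mapped back to net fluxes; two-cycle
(forward+backward) rays vanish and are dropped, and fully reversible modes
— which appear once per orientation — are reoriented so their first nonzero
coefficient is positive and deduplicated.  The surviving rays are exactly
the EFMs of the original network.

Canonical output: each mode is scaled so its smallest nonzero absolute
coefficient is 1, and modes are sorted lexicographically by support and
then by coefficients, so mode identifiers are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ResourceLimitError, ValidationError
from .model_io import NetworkModel

__all__ = [
    "EFMSet",
    "build_internal_stoichiometry",
    "enumerate_efms",
    "is_elementary",
]


@dataclass(frozen=True)
class EFMSet:
    """A matrix of elementary flux modes.

    ``EM`` has one row per reaction (``reaction_ids`` order) and one column
    per mode; ``reversibility_tags[k]`` is True when every reaction carrying
    flux in mode ``k`` is reversible, i.e. the mode can run in either
    direction.
    """

    efm_ids: tuple[int, ...]
    EM: np.ndarray
    reaction_ids: tuple[str, ...]
    reversibility_tags: tuple[bool, ...]

    def __post_init__(self) -> None:
        em = np.asarray(self.EM, dtype=float)
        object.__setattr__(self, "EM", em)
        if em.ndim != 2 or em.shape != (len(self.reaction_ids), len(self.efm_ids)):
            raise ValidationError(
                f"EM shape {em.shape} does not match {len(self.reaction_ids)} reactions "
                f"x {len(self.efm_ids)} modes"
            )
        if len(set(self.efm_ids)) != len(self.efm_ids):
            raise ValidationError("duplicate EFM ids")
        if len(self.reversibility_tags) != len(self.efm_ids):
            raise ValidationError("one reversibility tag per mode required")

    @property
    def n_modes(self) -> int:
        return len(self.efm_ids)

    def column(self, efm_id: int) -> np.ndarray:
        return self.EM[:, self.efm_ids.index(efm_id)]

    def to_frame(self) -> pd.DataFrame:
        """Reactions x modes table, compatible with the data-table writer."""
        return pd.DataFrame(
            self.EM,
            index=list(self.reaction_ids),
            columns=[str(i) for i in self.efm_ids],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   reversibility_tags: Sequence[bool] | None = None) -> "EFMSet":
        try:
            ids = tuple(int(c) for c in frame.columns)
        except ValueError:
            ids = tuple(range(1, frame.shape[1] + 1))
        tags = tuple(reversibility_tags) if reversibility_tags is not None \
            else (False,) * frame.shape[1]
        return cls(
            efm_ids=ids,
            EM=frame.to_numpy(dtype=float),
            reaction_ids=tuple(str(r) for r in frame.index),
            reversibility_tags=tags,
        )

    def validate_against(self, network: NetworkModel, tol: float = 1e-9) -> None:
        """Check the steady-state, sign and support-minimality invariants."""
        if tuple(self.reaction_ids) != tuple(network.reaction_ids):
            raise ValidationError("reaction order does not match the network")
        n_int = build_internal_stoichiometry(network)
        resid = np.abs(n_int @ self.EM)
        if resid.size and resid.max() > tol * max(1.0, np.abs(self.EM).max()):
            raise ValidationError("a mode violates the steady-state constraint")
        irrev = np.array([not network.reversible[r] for r in network.reaction_ids])
        if irrev.any() and (self.EM[irrev, :] < -tol).any():
            raise ValidationError("a mode runs an irreversible reaction backwards")
        supports = [frozenset(np.flatnonzero(np.abs(self.EM[:, k]) > tol))
                    for k in range(self.n_modes)]
        for a in range(self.n_modes):
            for b in range(self.n_modes):
                if a != b and supports[a] < supports[b]:
                    raise ValidationError(
                        f"mode {self.efm_ids[b]} has a support superset of "
                        f"mode {self.efm_ids[a]}"
                    )


def build_internal_stoichiometry(network: NetworkModel) -> np.ndarray:
    """Internal-metabolite stoichiometric matrix (m_int x q, float).

    Rows follow internal-metabolite declaration order, columns reaction
    order.  Raises :class:`ValidationError` for a network without internal
    metabolites (no steady-state constraint to impose).
    """
    if not network.internal_metabolites:
        raise ValidationError("network has no internal metabolites")
    mat = np.zeros((network.n_internal, network.n_reactions))
    for j, rxn in enumerate(network.reaction_ids):
        for i, met in enumerate(network.internal_metabolites):
            mat[i, j] = float(network.coefficient(met, rxn))
    return mat


def _integer_constraint_rows(network: NetworkModel) -> list[tuple[int, ...]]:
    """Exact integer steady-state rows over the split reaction columns."""
    rev = [network.reversible[r] for r in network.reaction_ids]
    n_split = network.n_reactions + sum(rev)
    rows = []
    for met in network.internal_metabolites:
        coeffs = [network.coefficient(met, r) for r in network.reaction_ids]
        if all(c == 0 for c in coeffs):
            continue
        denom_lcm = 1
        for c in coeffs:
            if c != 0:
                denom_lcm = denom_lcm * c.denominator // gcd(denom_lcm, c.denominator)
        ints = [int(c * denom_lcm) for c in coeffs]
        row = list(ints)
        for j, is_rev in enumerate(rev):
            if is_rev:
                row.append(-ints[j])
        assert len(row) == n_split
        rows.append(tuple(row))
    return rows


def _reduce(vec: list[int]) -> tuple[int, ...]:
    g = 0
    for x in vec:
        g = gcd(g, abs(x))
    if g > 1:
        vec = [x // g for x in vec]
    return tuple(vec)


def _double_description(rows: list[tuple[int, ...]], n_cols: int,
                        max_rays: int) -> list[tuple[int, ...]]:
    """Extreme rays of {v >= 0, row . v = 0 for all rows} as integer tuples."""
    full_mask = (1 << n_cols) - 1
    rays: list[tuple[int, ...]] = []
    zmasks: list[int] = []
    for j in range(n_cols):
        unit = [0] * n_cols
        unit[j] = 1
        rays.append(tuple(unit))
        zmasks.append(full_mask & ~(1 << j))

    remaining = list(rows)
    while remaining:
        # Process next the constraint generating the fewest candidate pairs.
        best_idx, best_parts, best_cost = 0, None, None
        for idx, row in enumerate(remaining):
            nz = [(i, c) for i, c in enumerate(row) if c]
            dots = []
            for ray in rays:
                dots.append(sum(c * ray[i] for i, c in nz))
            n_pos = sum(d > 0 for d in dots)
            n_neg = sum(d < 0 for d in dots)
            cost = n_pos * n_neg
            if best_cost is None or cost < best_cost:
                best_idx, best_parts, best_cost = idx, dots, cost
                if cost == 0:
                    break
        row = remaining.pop(best_idx)
        dots = best_parts

        zeros = [(rays[i], zmasks[i]) for i, d in enumerate(dots) if d == 0]
        pos = [(rays[i], zmasks[i], dots[i]) for i, d in enumerate(dots) if d > 0]
        neg = [(rays[i], zmasks[i], dots[i]) for i, d in enumerate(dots) if d < 0]

        new_rays = list(zeros)
        for rp, zp, dp in pos:
            for rn, zn, dn in neg:
                zm = zp & zn
                adjacent = True
                for rk, zk in zip(rays, zmasks):
                    if rk is rp or rk is rn:
                        continue
                    if zm & ~zk == 0:  # some other ray vanishes wherever both do
                        adjacent = False
                        break
                if not adjacent:
                    continue
                combo = [dp * rn[i] - dn * rp[i] for i in range(n_cols)]
                vec = _reduce(combo)
                mask = 0
                for i, x in enumerate(vec):
                    if x == 0:
                        mask |= 1 << i
                new_rays.append((vec, mask))
        if len(new_rays) > max_rays:
            raise ResourceLimitError(
                f"intermediate ray count {len(new_rays)} exceeds cap {max_rays}; "
                "the network is too combinatorial for exact enumeration"
            )
        rays = [r for r, _ in new_rays]
        zmasks = [m for _, m in new_rays]
    return rays


def enumerate_efms(network: NetworkModel, max_rays: int = 200_000) -> EFMSet:
    """Enumerate all elementary flux modes of a validated network.

    Intended for networks up to roughly 60 reactions / 10^4 modes.  When the
    intermediate ray count exceeds ``max_rays`` a
    :class:`ResourceLimitError` is raised rather than silently truncating.
    """
    rows = _integer_constraint_rows(network)  # raises if no internal metabolites
    if not network.internal_metabolites:
        raise ValidationError("network has no internal metabolites")
    q = network.n_reactions
    rev = [network.reversible[r] for r in network.reaction_ids]
    back_col: dict[int, int] = {}
    col = q
    for j, is_rev in enumerate(rev):
        if is_rev:
            back_col[j] = col
            col += 1

    split_rays = _double_description(rows, col, max_rays)

    modes: dict[tuple, tuple[tuple[Fraction, ...], bool]] = {}
    for ray in split_rays:
        net = [ray[j] - (ray[back_col[j]] if j in back_col else 0) for j in range(q)]
        support = tuple(j for j, x in enumerate(net) if x != 0)
        if not support:
            continue  # futile forward/backward two-cycle
        fully_reversible = all(rev[j] for j in support)
        if fully_reversible and net[support[0]] < 0:
            net = [-x for x in net]
        # irreversible reactions must carry non-negative flux by construction
        assert all(net[j] >= 0 or rev[j] for j in support)
        smallest = min(abs(net[j]) for j in support)
        frac = tuple(Fraction(x, smallest) for x in net)
        modes[(support, frac)] = (frac, fully_reversible)

    ordered = sorted(modes.keys(), key=lambda key: (key[0], [float(x) for x in key[1]]))
    n_modes = len(ordered)
    em = np.zeros((q, n_modes))
    tags = []
    for k, key in enumerate(ordered):
        frac, fully_reversible = modes[key]
        em[:, k] = [float(x) for x in frac]
        tags.append(fully_reversible)
    return EFMSet(
        efm_ids=tuple(range(1, n_modes + 1)),
        EM=em,
        reaction_ids=tuple(network.reaction_ids),
        reversibility_tags=tuple(tags),
    )


def is_elementary(candidate: Sequence[float], network: NetworkModel,
                  tol: float = 1e-9) -> tuple[bool, np.ndarray | None]:
    """Test support-minimality of a steady-state flux vector.

    Returns ``(True, None)`` when no admissible flux vector has support
    strictly contained in the candidate's support, and ``(False, certificate)``
    with such a vector (embedded in full reaction space) otherwise.

    Raises :class:`ValidationError` when the candidate itself violates the
    steady-state or irreversibility constraints.
    """
    v = np.asarray(candidate, dtype=float)
    if v.shape != (network.n_reactions,):
        raise ValidationError(
            f"candidate length {v.shape} does not match {network.n_reactions} reactions"
        )
    scale = max(1.0, float(np.abs(v).max()))
    n_int = build_internal_stoichiometry(network)
    if np.abs(n_int @ v).max() > 1e-6 * scale:
        raise ValidationError("candidate does not satisfy the steady-state constraint")
    support_idx = np.flatnonzero(np.abs(v) > tol * scale)
    if support_idx.size == 0:
        raise ValidationError("candidate is the zero flux vector")
    for j in support_idx:
        if not network.reversible[network.reaction_ids[j]] and v[j] < 0:
            raise ValidationError(
                f"candidate runs irreversible reaction {network.reaction_ids[j]!r} backwards"
            )

    support = [network.reaction_ids[j] for j in support_idx]
    sub = network.restrict(support)
    sub_modes = enumerate_efms(sub)
    support_set = set(support_idx.tolist())
    col_of = {r: j for j, r in enumerate(network.reaction_ids)}
    for k in range(sub_modes.n_modes):
        mode_support = {
            col_of[sub.reaction_ids[i]]
            for i in np.flatnonzero(np.abs(sub_modes.EM[:, k]) > tol)
        }
        if mode_support < support_set:
            certificate = np.zeros(network.n_reactions)
            for i, r in enumerate(sub.reaction_ids):
                certificate[col_of[r]] = sub_modes.EM[i, k]
            return False, certificate
    return True, None
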