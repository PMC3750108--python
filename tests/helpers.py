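"""Shared test utilities: independent oracles and tiny input builders."""

from __future__ import annotations

import itertools

import numpy as np

from plp import NetworkModel, build_internal_stoichiometry

CHAIN_TEXT = """\
-ENZREV
-ENZIRREV
v1 v2 v3
-METINT
A B
-METEXT
Aext Bext
-CAT
v1 : Aext = A .
v2 : A = B .
v3 : B = Bext .
"""


def brute_force_efms(network: NetworkModel, tol: float = 1e-9) -> list[np.ndarray]:
    """Exhaustive elementary-mode oracle for networks with few reactions.

    For every support subset, compute the nullspace of the restricted
    internal stoichiometry; keep one-dimensional nullspaces whose generator
    has full support over the subset and admits a sign-feasible
    orientation; finally drop vectors whose support strictly contains
    another's.  Independent of the production enumerator.
    """
    N = build_internal_stoichiometry(network)
    q = network.n_reactions
    rev = [network.reversible[r] for r in network.reaction_ids]
    found: list[tuple[frozenset, np.ndarray]] = []
    for size in range(1, q + 1):
        for S in itertools.combinations(range(q), size):
            sub = N[:, S]
            _, s, vt = np.linalg.svd(sub)
            rank = int(np.sum(s > tol * max(1.0, s[0] if s.size else 1.0)))
            if len(S) - rank != 1:
                continue
            v = vt[-1, :]
            if np.min(np.abs(v)) < 1e-7:
                continue  # support smaller than S; found at a smaller subset

            def _feasible(w: np.ndarray) -> bool:
                return all(w[i] > 0 or rev[S[i]] for i in range(len(S)))

            oriented = next((w for w in (v, -v) if _feasible(w)), None)
            if oriented is None:
                continue
            full = np.zeros(q)
            full[list(S)] = oriented
            found.append((frozenset(S), full))
    return [v for S, v in found if not any(S2 < S for S2, _ in found)]


def canonical_mode(vec: np.ndarray, rev: list[bool], tol: float = 1e-9):
    """(support, scaled vector) with the enumerator's canonical convention:
    fully reversible modes oriented first-nonzero-positive, smallest
    nonzero absolute coefficient scaled to 1."""
    sup = np.flatnonzero(np.abs(vec) > tol)
    v = vec.copy()
    if all(rev[j] for j in sup) and v[sup[0]] < 0:
        v = -v
    v = v / np.abs(v[sup]).min()
    return tuple(sup.tolist()), v


def same_mode_sets(efms_a: list[np.ndarray], efms_b: list[np.ndarray],
                   rev: list[bool], atol: float = 1e-6) -> bool:
    """Equality of two mode collections up to positive scaling."""
    A = {s: v for s, v in (canonical_mode(x, rev) for x in efms_a)}
    B = {s: v for s, v in (canonical_mode(x, rev) for x in efms_b)}
    if set(A) != set(B):
        return False
    return all(np.allclose(A[s], B[s], atol=atol) for s in A)


def nnls_residual(target: np.ndarray, EM: np.ndarray, rev_tags) -> float:
    """Residual of expressing ``target`` as a non-negative combination of
    the columns of ``EM`` (reversible modes may enter with either sign)."""
    from scipy.optimize import nnls

    cols = [EM[:, k] for k in range(EM.shape[1])]
    cols += [-EM[:, k] for k in range(EM.shape[1]) if rev_tags[k]]
    A = np.column_stack(cols)
    _, resid = nnls(A, target)
    return float(resid)
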