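"""Readers and writers for metabolic networks, data tables, reports and run
configuration.

Network files use the classic sectioned Metatool dialect::

    -ENZREV
    v2
    -ENZIRREV
    v1 v3
    -METINT
    A B
    -METEXT
    Aex Bex
    -CAT
    v1 : Aex = A .
    v2 : A = B .
    v3 : B = 2 Bex .

All five section headers are required.  ``#`` starts a comment.  Reaction
equations are ``name : substrates = products`` with optional integer,
rational (``1/3``) or decimal coefficients and an optional trailing ``.``.
Reaction order is the listing order of ``-ENZREV`` followed by
``-ENZIRREV``, which fixes the column order of every downstream matrix.

Data tables (envirome ``X``, flux ``R``, EFM matrices, reports) are
delimited text with one header row of variable names and one leading column
of observation labels.  Tab or comma delimiters are sniffed from the first
line; values must be finite numbers — missing values are rejected, not
imputed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

__all__ = [
    "NetworkModel",
    "RunConfig",
    "read_metatool_network",
    "write_metatool_network",
    "read_data_table",
    "write_data_table",
    "write_selection_report",
    "read_selection_report",
    "REPORT_COLUMNS",
]

_SECTIONS = ("-ENZREV", "-ENZIRREV", "-METINT", "-METEXT", "-CAT")


# ---------------------------------------------------------------------------
# Network model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkModel:
    """A stoichiometric metabolic network.

    Parameters
    ----------
    reaction_ids
        Ordered, unique reaction names; this order defines the column order
        of every stoichiometric matrix derived from the model.
    stoich
        Mapping ``reaction -> {metabolite: coefficient}`` with products
        positive and substrates negative.  Coefficients are exact
        :class:`~fractions.Fraction` values so that elementary-mode
        enumeration can run in rational arithmetic.
    reversible
        Per-reaction reversibility flag.
    internal_metabolites, external_metabolites
        Ordered metabolite names.  Steady-state balancing applies to
        internal metabolites only; external metabolites are source/sink
        species and are never balanced.
    """

    reaction_ids: tuple[str, ...]
    stoich: Mapping[str, Mapping[str, Fraction]]
    reversible: Mapping[str, bool]
    internal_metabolites: tuple[str, ...]
    external_metabolites: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "internal_metabolites", tuple(self.internal_metabolites))
        object.__setattr__(self, "external_metabolites", tuple(self.external_metabolites))
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            dup = [r for r in self.reaction_ids if self.reaction_ids.count(r) > 1]
            raise ValidationError(f"duplicate reaction id {dup[0]!r}")
        overlap = set(self.internal_metabolites) & set(self.external_metabolites)
        if overlap:
            raise ValidationError(
                f"metabolite(s) declared both internal and external: {sorted(overlap)}"
            )
        declared = set(self.internal_metabolites) | set(self.external_metabolites)
        for rxn in self.reaction_ids:
            if rxn not in self.stoich:
                raise ValidationError(f"reaction {rxn!r} has no stoichiometry")
            for met in self.stoich[rxn]:
                if met not in declared:
                    raise ValidationError(
                        f"reaction {rxn!r} references undeclared metabolite {met!r}"
                    )
        for rxn in self.stoich:
            if rxn not in self.reaction_ids:
                raise ValidationError(f"stoichiometry given for unknown reaction {rxn!r}")

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_internal(self) -> int:
        return len(self.internal_metabolites)

    def coefficient(self, metabolite: str, reaction: str) -> Fraction:
        """Signed stoichiometric coefficient (0 if the pair is absent)."""
        return Fraction(self.stoich[reaction].get(metabolite, Fraction(0)))

    def is_reversible(self, reaction: str) -> bool:
        return bool(self.reversible[reaction])

    def restrict(self, reactions: Sequence[str]) -> "NetworkModel":
        """Sub-network over a subset of reactions (metabolite sets kept)."""
        keep = [r for r in self.reaction_ids if r in set(reactions)]
        return NetworkModel(
            reaction_ids=tuple(keep),
            stoich={r: dict(self.stoich[r]) for r in keep},
            reversible={r: self.reversible[r] for r in keep},
            internal_metabolites=self.internal_metabolites,
            external_metabolites=self.external_metabolites,
        )


def _parse_coefficient(token: str, lineno: int) -> Fraction:
    try:
        return Fraction(token)
    except (ValueError, ZeroDivisionError) as exc:
        raise FormatError(f"line {lineno}: bad stoichiometric coefficient {token!r}") from exc


def _parse_side(side: str, lineno: int) -> list[tuple[Fraction, str]]:
    terms: list[tuple[Fraction, str]] = []
    side = side.strip()
    if not side:
        return terms
    for chunk in side.split("+"):
        parts = chunk.split()
        if not parts:
            raise FormatError(f"line {lineno}: empty term in reaction equation")
        if len(parts) == 1:
            terms.append((Fraction(1), parts[0]))
        elif len(parts) == 2:
            terms.append((_parse_coefficient(parts[0], lineno), parts[1]))
        else:
            raise FormatError(f"line {lineno}: cannot parse term {' '.join(parts)!r}")
    return terms


def read_metatool_network(path: str | Path) -> NetworkModel:
    """Parse a sectioned Metatool-style network file.

    Raises
    ------
    FormatError
        If a required section is missing or a line cannot be parsed.
    ValidationError
        If a reaction references a metabolite that was never declared.
    """
    path = Path(path)
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("-"):
            name = line.split()[0].upper()
            if name not in _SECTIONS:
                raise FormatError(f"{path.name}: unknown section {name!r} at line {lineno}")
            current = name
            sections.setdefault(name, [])
            continue
        if current is None:
            raise FormatError(f"{path.name}: content before any section header at line {lineno}")
        sections[current].append((lineno, line))

    missing = [s for s in _SECTIONS if s not in sections]
    if missing:
        raise FormatError(f"{path.name}: missing section(s) {', '.join(missing)}")

    def _names(section: str) -> list[str]:
        return [tok for _, line in sections[section] for tok in line.split()]

    rev_ids = _names("-ENZREV")
    irrev_ids = _names("-ENZIRREV")
    internal = _names("-METINT")
    external = _names("-METEXT")
    reaction_ids = tuple(rev_ids + irrev_ids)
    reversible = {r: True for r in rev_ids}
    reversible.update({r: False for r in irrev_ids})

    stoich: dict[str, dict[str, Fraction]] = {}
    for lineno, line in sections["-CAT"]:
        body = line.rstrip()
        if body.endswith("."):
            body = body[:-1]
        name, sep, eq = body.partition(":")
        if not sep:
            raise FormatError(f"{path.name}: line {lineno}: expected 'name : equation'")
        name = name.strip()
        if name not in reversible:
            raise FormatError(
                f"{path.name}: line {lineno}: reaction {name!r} not listed in "
                "-ENZREV or -ENZIRREV"
            )
        lhs, sep, rhs = eq.partition("=")
        if not sep:
            raise FormatError(f"{path.name}: line {lineno}: reaction equation lacks '='")
        coeffs: dict[str, Fraction] = {}
        for c, met in _parse_side(lhs, lineno):
            coeffs[met] = coeffs.get(met, Fraction(0)) - c
        for c, met in _parse_side(rhs, lineno):
            coeffs[met] = coeffs.get(met, Fraction(0)) + c
        stoich[name] = {m: c for m, c in coeffs.items() if c != 0}

    absent = [r for r in reaction_ids if r not in stoich]
    if absent:
        raise FormatError(f"{path.name}: no -CAT equation for reaction(s) {absent}")

    return NetworkModel(
        reaction_ids=reaction_ids,
        stoich=stoich,
        reversible=reversible,
        internal_metabolites=tuple(internal),
        external_metabolites=tuple(external),
    )


def write_metatool_network(network: NetworkModel, path: str | Path) -> None:
    """Serialize a network back to the sectioned dialect (round-trip safe)."""
    lines: list[str] = []
    rev = [r for r in network.reaction_ids if network.reversible[r]]
    irr = [r for r in network.reaction_ids if not network.reversible[r]]
    lines.append("-ENZREV")
    lines.append(" ".join(rev))
    lines.append("-ENZIRREV")
    lines.append(" ".join(irr))
    lines.append("-METINT")
    lines.append(" ".join(network.internal_metabolites))
    lines.append("-METEXT")
    lines.append(" ".join(network.external_metabolites))
    lines.append("-CAT")
    for rxn in network.reaction_ids:
        subs = []
        prods = []
        for met, c in network.stoich[rxn].items():
            if c < 0:
                subs.append((met, -c))
            else:
                prods.append((met, c))

        def _side(terms: list[tuple[str, Fraction]]) -> str:
            return " + ".join(f"{m}" if c == 1 else f"{c} {m}" for m, c in terms)

        lines.append(f"{rxn} : {_side(subs)} = {_side(prods)} .")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Data tables
# ---------------------------------------------------------------------------

def _sniff_separator(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise FormatError(f"{path.name}: could not sniff delimiter (no tab or comma in header)")


def read_data_table(path: str | Path, orientation: str = "observations_rows") -> pd.DataFrame:
    """Read a delimited observations x variables table.

    The first column holds observation labels, the header row variable
    names.  Set ``orientation="variables_rows"`` for transposed files; the
    returned frame always has observations in rows.

    Raises
    ------
    FormatError
        Ragged rows (message carries the pandas line number).
    ValidationError
        Duplicate labels, missing values or non-numeric cells (message
        carries the offending coordinate).
    """
    path = Path(path)
    if orientation not in ("observations_rows", "variables_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    sep = _sniff_separator(path)
    try:
        # the python engine reports ragged lines with their line number and
        # parses floats with Python's round-trip-faithful float()
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    if df.empty and df.columns.empty:
        raise FormatError(f"{path.name}: empty table")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for axis_name, labels in (("row", df.index), ("column", df.columns)):
        if labels.has_duplicates:
            dup = labels[labels.duplicated()][0]
            raise ValidationError(f"{path.name}: duplicate {axis_name} label {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path.name}: non-numeric or missing value {df.iat[i, j]!r} at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    values = numeric.astype(float)
    if not np.isfinite(values.to_numpy()).all():
        i, j = np.argwhere(~np.isfinite(values.to_numpy()))[0]
        raise ValidationError(
            f"{path.name}: non-finite value at row {values.index[i]!r}, "
            f"column {values.columns[j]!r}"
        )
    if orientation == "variables_rows":
        values = values.T
    return values


def write_data_table(table: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    """Write a table so that :func:`read_data_table` round-trips it exactly.

    The delimiter defaults to comma for ``.csv`` paths and tab otherwise;
    floats are written with 17 significant digits (lossless for doubles).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.to_csv(path, sep=sep, float_format="%.17g")


# ---------------------------------------------------------------------------
# Selection report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ("efm_id", "n_lv", "r2", "p_value", "var_lambda_pct", "cum_var_R_pct")


def write_selection_report(model, path: str | Path) -> None:
    """Write the per-EFM selection audit table of a fitted PLP model.

    One row per selected mode in selection order with columns
    ``efm_id, n_lv, r2, p_value, var_lambda_pct, cum_var_R_pct`` (the last
    being the cumulative explained flux variance after accepting the mode).
    A model with no selected modes yields a header-only file.
    """
    rows = [
        (
            s.efm_id,
            s.n_lv,
            s.score.r2,
            s.score.p_value,
            s.score.var_lambda_pct,
            s.score.var_R_pct,
        )
        for s in model.selected
    ]
    frame = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.17g")


def read_selection_report(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    if list(frame.columns) != list(REPORT_COLUMNS):
        raise FormatError(
            f"{Path(path).name}: expected columns {list(REPORT_COLUMNS)}, "
            f"found {list(frame.columns)}"
        )
    return frame


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the selection pipeline.

    Attributes
    ----------
    n_inner_latent
        Number of latent variables (``Fac``) of each inner univariate PLS
        relating the envirome to a mode's weighting factors.  Default 4.
    r2_threshold, p_threshold
        Acceptance gate for a candidate mode: squared Pearson correlation
        between observed and predicted weighting factors must exceed
        ``r2_threshold`` (default 0.75) with two-sided p below
        ``p_threshold`` (default 0.05).
    max_efms
        Hard cap on the number of selected modes.
    eps_convergence, max_nipals_iter
        NIPALS inner-loop convergence tolerance on ``||t - t_old||``
        (default 1e-8) and iteration budget (default 5000; deep components
        on noisy data converge at a power-iteration rate and can need
        thousands of cheap iterations).
    min_variance_gain
        Minimal marginal gain (percentage points) of explained flux
        variance for a mode to be accepted; operationalizes "the explained
        variance does not increase any further".
    scaling_policy
        ``"autoscale_X"`` (column-wise mean 0 / unit variance, the default)
        or ``"raw"`` (no preprocessing of X).
    efm_normalization
        ``"unit_norm"`` scales every candidate mode to unit Euclidean norm
        over the measured reactions before projection, making variance
        comparisons invariant to the arbitrary scaling of modes; ``"raw"``
        uses modes as given.
    """

    n_inner_latent: int = 4
    r2_threshold: float = 0.75
    p_threshold: float = 0.05
    max_efms: int = 50
    eps_convergence: float = 1e-8
    max_nipals_iter: int = 5000
    min_variance_gain: float = 1e-6
    seed: int = 0
    scaling_policy: str = "autoscale_X"
    efm_normalization: str = "unit_norm"

    def __post_init__(self) -> None:
        if self.n_inner_latent < 1:
            raise ValidationError("n_inner_latent must be a positive integer")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValidationError("r2_threshold must lie in (0, 1]")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValidationError("p_threshold must lie in (0, 1)")
        if self.max_efms < 1:
            raise ValidationError("max_efms must be a positive integer")
        if self.eps_convergence <= 0:
            raise ValidationError("eps_convergence must be positive")
        if self.max_nipals_iter < 1:
            raise ValidationError("max_nipals_iter must be a positive integer")
        if self.min_variance_gain < 0:
            raise ValidationError("min_variance_gain must be non-negative")
        if self.scaling_policy not in ("autoscale_X", "raw"):
            raise ValidationError(f"unknown scaling_policy {self.scaling_policy!r}")
        if self.efm_normalization not in ("unit_norm", "raw"):
            raise ValidationError(f"unknown efm_normalization {self.efm_normalization!r}")

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, Mapping):
            raise FormatError(f"{Path(path).name}: config file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
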