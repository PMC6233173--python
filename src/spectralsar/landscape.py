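"""Mutations, combinatorial recombinants, additivity and epistasis.

Variants are sets of point substitutions relative to a wild-type
sequence, written in the standard ``A217N`` notation (wild-type
residue, 1-based position, new residue) joined by underscores.  From n
learned single mutations the 2^n possible recombinants are enumerated
exhaustively; each can be scored against the *additive* baseline

    ddG_add(g) = ddG_WT + sum over mutations m in g of (ddG_m − ddG_WT),

the activity expected if mutation effects simply summed.  Observed
departures from that baseline are epistasis: on the ΔΔG‡ scale lower
means more enantioselective, so an observed value below the additive
one is positive epistasis (better than the sum) and above it negative.

Enantioselectivity factors convert to differential activation free
energies via ΔΔG‡ = −RT ln E (kcal/mol).
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal mol^-1 K^-1

ACTIVITY_UNITS = ("ddg_kcal_per_mol", "e_value")

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class MutationError(ValueError):
    """A mutation token is malformed or inconsistent with the wild type."""


@dataclass(frozen=True, order=True)
class PointMutation:
    """A single substitution: wild-type residue, 1-based position, new residue."""

    position: int
    wt_residue: str
    mut_residue: str

    def __post_init__(self) -> None:
        if self.wt_residue == self.mut_residue:
            raise MutationError(
                f"silent substitution {self.wt_residue}{self.position}{self.mut_residue}"
            )
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"


Genotype = tuple[PointMutation, ...]


def parse_mutation(token: str, wt_sequence: str | None = None) -> PointMutation:
    """Parse a token like ``"A217N"``, optionally validating the wild type.

    Raises
    ------
    MutationError
        Malformed token; silent substitution; position beyond the
        wild-type length; or wild-type residue mismatch (the message
        names position, expected and found residues).
    """
    m = _MUTATION_RE.match(token.strip())
    if not m:
        raise MutationError(f"malformed mutation token {token!r} (expected e.g. A217N)")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    mutation = PointMutation(position=pos, wt_residue=wt, mut_residue=mut)
    if wt_sequence is not None:
        if pos > len(wt_sequence):
            raise MutationError(
                f"position {pos} beyond wild-type length {len(wt_sequence)}"
            )
        found = wt_sequence[pos - 1]
        if found != wt:
            raise MutationError(
                f"wild-type mismatch at position {pos}: token says {wt!r}, "
                f"sequence has {found!r}"
            )
    return mutation


def parse_genotype(spec: str, wt_sequence: str | None = None) -> Genotype:
    """Parse an underscore-joined mutation list; ``""`` or ``"WT"`` is wild type."""
    spec = spec.strip() if isinstance(spec, str) else ""
    if spec == "" or spec.upper() == "WT":
        return ()
    mutations = tuple(parse_mutation(tok, wt_sequence) for tok in spec.split("_"))
    positions = [m.position for m in mutations]
    if len(set(positions)) != len(positions):
        raise MutationError(f"duplicate positions in genotype {spec!r}")
    return tuple(sorted(mutations))


def format_genotype(g: Genotype) -> str:
    """Inverse of :func:`parse_genotype` (``"WT"`` for the empty genotype)."""
    return "_".join(str(m) for m in sorted(g)) if g else "WT"


def apply_genotype(wt_sequence: str, g: Genotype) -> str:
    """Apply substitutions to the wild type; the empty genotype is identity."""
    positions = [m.position for m in g]
    if len(set(positions)) != len(positions):
        raise MutationError("two mutations at one position")
    seq = list(wt_sequence)
    for m in g:
        if m.position > len(seq):
            raise MutationError(
                f"position {m.position} beyond wild-type length {len(seq)}"
            )
        if seq[m.position - 1] != m.wt_residue:
            raise MutationError(
                f"wild-type mismatch at position {m.position}: expected "
                f"{m.wt_residue!r}, found {seq[m.position - 1]!r}"
            )
        seq[m.position - 1] = m.mut_residue
    return "".join(seq)


def enumerate_genotypes(
    singles: Sequence[PointMutation], cap: int = 30
) -> list[Genotype]:
    """All 2^n combinations of n single mutations, in binary-counter order.

    Bit i of the counter selects ``singles[i]``; the wild type (empty
    genotype) comes first and the all-mutations genotype last.

    Raises
    ------
    ValueError
        Duplicate positions among the singles, or n beyond ``cap``
        (default 30 keeps the enumeration within workstation reach).
    """
    singles = list(singles)
    positions = [m.position for m in singles]
    if len(set(positions)) != len(positions):
        raise ValueError("single mutations must have pairwise distinct positions")
    n = len(singles)
    if n > cap:
        raise ValueError(f"{n} mutations exceed the enumeration cap of {cap}")
    return [
        tuple(m for i, m in enumerate(singles) if mask >> i & 1)
        for mask in range(1 << n)
    ]


def additive_prediction(
    g: Genotype,
    wt_value: float,
    single_values: Mapping[PointMutation, float],
) -> float:
    """Additive-baseline activity: WT value plus summed single-mutation effects.

    Each single mutation contributes its effect relative to the wild
    type, so a single-mutation genotype reproduces that mutant's own
    value exactly and the empty genotype returns the wild-type value.

    Raises
    ------
    KeyError
        If a mutation in ``g`` has no single-mutant value.
    """
    total = wt_value
    for m in g:
        if m not in single_values:
            raise KeyError(f"no single-mutant value for {m}")
        total += single_values[m] - wt_value
    return total


def classify_epistasis(observed: float, additive: float, tol: float = 0.0) -> str:
    """Classify a ΔΔG‡ deviation from the additive baseline.

    Lower ΔΔG‡ means higher enantioselectivity, so observed below
    additive − tol is ``"positive"`` epistasis (better than the sum),
    above additive + tol ``"negative"``, else ``"additive"``.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if observed < additive - tol:
        return "positive"
    if observed > additive + tol:
        return "negative"
    return "additive"


@dataclass
class EpistasisRecord:
    """Observed vs additive activity of one multi-point mutant."""

    genotype_id: str
    mutations: Genotype
    observed: float
    additive: float
    epistasis_class: str
    model_predictions: dict[str, float] = field(default_factory=dict)
    better_flags: dict[str, str] = field(default_factory=dict)


def build_epistasis_records(
    genotypes: Sequence[Genotype],
    observed: Sequence[float],
    wt_value: float,
    single_values: Mapping[PointMutation, float],
    model_predictions: Mapping[str, Sequence[float]] | None = None,
    tol: float = 0.0,
    ids: Sequence[str] | None = None,
) -> list[EpistasisRecord]:
    """Assemble epistasis records (with per-model better-than-additive flags)."""
    if ids is None:
        ids = [format_genotype(g) for g in genotypes]
    records = []
    for i, (g, obs) in enumerate(zip(genotypes, observed)):
        add = additive_prediction(g, wt_value, single_values)
        rec = EpistasisRecord(
            genotype_id=str(ids[i]),
            mutations=g,
            observed=float(obs),
            additive=add,
            epistasis_class=classify_epistasis(obs, add, tol=tol),
        )
        for name, preds in (model_predictions or {}).items():
            pred = float(preds[i])
            rec.model_predictions[name] = pred
            rec.better_flags[name] = (
                "I" if abs(pred - obs) < abs(add - obs) else "A"
            )
        records.append(rec)
    return records


def compare_models(
    records: Sequence[EpistasisRecord], model_name: str
) -> tuple[int, int, list[str]]:
    """Count genotypes where the model beats the additive baseline.

    A record is flagged ``I`` iff |model − observed| < |additive −
    observed| (strict; ties go to ``A``, conservatively crediting the
    simpler additive baseline).  Returns (#I, #A, per-record flags).
    """
    flags = []
    for rec in records:
        if model_name in rec.better_flags:
            flags.append(rec.better_flags[model_name])
        elif model_name in rec.model_predictions:
            pred = rec.model_predictions[model_name]
            flags.append(
                "I" if abs(pred - rec.observed) < abs(rec.additive - rec.observed) else "A"
            )
        else:
            raise KeyError(f"record {rec.genotype_id} has no prediction for {model_name!r}")
    n_i = flags.count("I")
    return n_i, len(flags) - n_i, flags


def epistasis_table(records: Sequence[EpistasisRecord]) -> pd.DataFrame:
    """Tabulate records: observed, additive, class, per-model columns."""
    model_names = sorted({name for rec in records for name in rec.model_predictions})
    rows = []
    for rec in records:
        row = {
            "id": rec.genotype_id,
            "mutations": format_genotype(rec.mutations),
            "observed": rec.observed,
            "additive": rec.additive,
            "epistasis_class": rec.epistasis_class,
        }
        for name in model_names:
            row[f"pred_{name}"] = rec.model_predictions.get(name, float("nan"))
            row[f"flag_{name}"] = rec.better_flags.get(name, "")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThermoParams:
    """Gas constant (kcal/mol/K) and absolute temperature for E ↔ ΔΔG‡."""

    R: float = GAS_CONSTANT_KCAL
    T: float = 298.15

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")


def evalue_to_ddg(E: float, params: ThermoParams = ThermoParams()) -> float:
    """ΔΔG‡ = −RT ln E (kcal/mol); requires E > 0."""
    if E <= 0:
        raise ValueError(f"E-value must be positive, got {E}")
    return -params.R * params.T * math.log(E)


def ddg_to_evalue(ddg: float, params: ThermoParams = ThermoParams()) -> float:
    """Inverse conversion E = exp(−ΔΔG‡ / RT)."""
    return math.exp(-ddg / (params.R * params.T))


def rank_variants(
    predictions: pd.DataFrame,
    unit: str = "ddg_kcal_per_mol",
    value_column: str = "predicted",
    training_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Rank variants by predicted enantioselectivity, best first.

    On the E-value scale higher is better (descending sort); on the
    ΔΔG‡ scale lower is better (ascending sort) — the two orders
    coincide through the monotone-decreasing conversion.  Ties keep
    input order (stable sort).  Adds ``rank`` (1 = best) and
    ``in_training_set`` columns.
    """
    if unit not in ACTIVITY_UNITS:
        raise ValueError(f"unknown unit {unit!r}")
    ascending = unit == "ddg_kcal_per_mol"
    ranked = predictions.sort_values(
        by=value_column, ascending=ascending, kind="stable"
    ).reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    training = set(training_ids)
    ranked["in_training_set"] = ranked["id"].isin(training)
    return ranked


# ---------------------------------------------------------------------------
# Variant-table I/O (CSV dialect: id, mutations, activity, activity_unit)
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant CSV (columns id, mutations, activity, activity_unit)."""
    # round_trip parsing keeps activities bit-exact through write/read cycles
    table = pd.read_csv(
        path, dtype={"id": str, "mutations": str}, float_precision="round_trip"
    )
    required = {"id", "mutations", "activity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    table["mutations"] = table["mutations"].fillna("")
    if "activity_unit" not in table.columns:
        table["activity_unit"] = "ddg_kcal_per_mol"
    units = set(table["activity_unit"].unique())
    if not units <= set(ACTIVITY_UNITS):
        raise ValueError(f"unknown activity units: {sorted(units - set(ACTIVITY_UNITS))}")
    if len(units) > 1:
        raise ValueError("variant table mixes activity units")
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate variant ids: {dupes}")
    return table


def write_variant_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a variant table in the CSV dialect read back by this module."""
    table.to_csv(path, index=False)


def singles_from_table(
    table: pd.DataFrame, wt_sequence: str
) -> tuple[float, dict[PointMutation, float]]:
    """Extract the wild-type activity and single-mutant activity map.

    Raises
    ------
    ValueError
        If the table lacks a wild-type row or holds no single mutants.
    """
    wt_value = None
    singles: dict[PointMutation, float] = {}
    for _, row in table.iterrows():
        g = parse_genotype(row["mutations"], wt_sequence)
        if len(g) == 0:
            wt_value = float(row["activity"])
        elif len(g) == 1:
            singles[g[0]] = float(row["activity"])
    if wt_value is None:
        raise ValueError("variant table has no wild-type row")
    if not singles:
        raise ValueError("variant table has no single-mutant rows")
    return wt_value, singles
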