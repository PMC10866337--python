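"""Reaction-solvent property tables.

One row per reaction-solvent pair: an atom-mapped reaction SMILES, a solvent
SMILES, and the two regression targets at 298 K in kcal/mol — the solvation
free energy of activation (ddG_298) and the solvation enthalpy of activation
(ddH_298).  Additional numeric columns (for example the solvation energies and
enthalpies of reactants and products, the "RP-solv" block) are carried along
as a fixed-width extras vector and injected at the regression head.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import FeatureError, ParseError, SchemaError
from .reactions import (
    MappedReaction,
    canonical_smiles,
    directed_key,
    parse_mapped_reaction,
    reaction_key,
)

__all__ = ["PairRecord", "TableSchema", "read_pair_table", "write_pair_table"]


@lru_cache(maxsize=100_000)
def _canonical_solvent(smiles: str) -> str:
    return canonical_smiles(smiles)


@dataclass
class TableSchema:
    """Column-name dialect of a pair table (defaults mirror the CSV layout
    described under External Interfaces: rxn_smiles, solvent_smiles, ddG_298,
    ddH_298)."""

    rxn_smiles: str = "rxn_smiles"
    solvent_smiles: str = "solvent_smiles"
    ddG_298: str = "ddG_298"
    ddH_298: str = "ddH_298"
    provenance: str = "provenance"
    family: str = "family"
    record_id: str = "record_id"
    extras: Optional[Tuple[str, ...]] = None  # None = autodetect leftover columns

    @property
    def required(self) -> Tuple[str, ...]:
        return (self.rxn_smiles, self.solvent_smiles, self.ddG_298, self.ddH_298)

    @property
    def optional(self) -> Tuple[str, ...]:
        return (self.provenance, self.family, self.record_id)


@dataclass
class PairRecord:
    """One reaction-solvent data point with targets and provenance."""

    reaction: MappedReaction
    solvent: str
    ddG298: float
    ddH298: float
    provenance: str = "pretrain"
    extras: Optional[np.ndarray] = None
    family: Optional[str] = None
    record_id: Optional[str] = None
    _rkey: str = field(default="", repr=False, compare=False)

    def __post_init__(self):
        if not (math.isfinite(self.ddG298) and math.isfinite(self.ddH298)):
            raise SchemaError(
                f"non-finite targets ({self.ddG298}, {self.ddH298}) "
                f"for record {self.record_id!r}"
            )

    @property
    def reaction_key(self) -> str:
        if not self._rkey:
            self._rkey = reaction_key(self.reaction)
        return self._rkey

    @property
    def directed_key(self) -> str:
        return directed_key(self.reaction)

    @property
    def solvent_key(self) -> str:
        return _canonical_solvent(self.solvent)

    @property
    def extras_width(self) -> int:
        return 0 if self.extras is None else int(self.extras.shape[0])

    @property
    def targets(self) -> np.ndarray:
        return np.array([self.ddG298, self.ddH298], dtype=np.float64)


def read_pair_table(
    path,
    schema: Optional[TableSchema] = None,
    permissive: bool = False,
    provenance: str = "pretrain",
    report: Optional[List[str]] = None,
) -> List[PairRecord]:
    """Read a UTF-8 CSV pair table into PairRecords.

    In strict mode (default) any row-level failure raises with its line
    number; in permissive mode bad rows are skipped and the messages are
    appended to ``report`` (if given).  Extras columns, when not declared in
    the schema, are every remaining column in header order; their width must
    be consistent across all rows.
    """
    schema = schema or TableSchema()
    records: List[PairRecord] = []
    problems: List[str] = report if report is not None else []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in schema.required:
            if col not in header:
                raise SchemaError(f"missing required column {col!r} in {path}")
        if schema.extras is None:
            claimed = set(schema.required) | set(schema.optional)
            extras_cols = tuple(c for c in header if c not in claimed)
        else:
            extras_cols = schema.extras
            for col in extras_cols:
                if col not in header:
                    raise SchemaError(f"missing extras column {col!r} in {path}")
        for line_no, row in enumerate(reader, start=2):
            try:
                reaction = parse_mapped_reaction(row[schema.rxn_smiles])
                extras = None
                if extras_cols:
                    try:
                        extras = np.array(
                            [float(row[c]) for c in extras_cols], dtype=np.float64
                        )
                    except (TypeError, ValueError) as exc:
                        raise FeatureError(f"bad extras value: {exc}") from exc
                rec = PairRecord(
                    reaction=reaction,
                    solvent=row[schema.solvent_smiles],
                    ddG298=float(row[schema.ddG_298]),
                    ddH298=float(row[schema.ddH_298]),
                    provenance=row.get(schema.provenance) or provenance,
                    extras=extras,
                    family=row.get(schema.family) or None,
                    record_id=row.get(schema.record_id) or f"row{line_no}",
                )
            except Exception as exc:
                message = f"line {line_no}: {exc}"
                if not permissive:
                    raise type(exc)(message) from exc
                problems.append(message)
                continue
            records.append(rec)
    widths = {r.extras_width for r in records}
    if len(widths) > 1:
        raise FeatureError(f"inconsistent extras widths across table: {sorted(widths)}")
    return records


def write_pair_table(
    records: Sequence[PairRecord],
    path,
    schema: Optional[TableSchema] = None,
    extras_names: Optional[Sequence[str]] = None,
) -> None:
    """Write records as CSV; reals use ``repr`` so a read round-trips to full
    precision."""
    schema = schema or TableSchema()
    width = records[0].extras_width if records else 0
    if extras_names is None:
        extras_names = [f"extra_{i}" for i in range(width)]
    if len(extras_names) != width:
        raise FeatureError(
            f"{len(extras_names)} extras names given for width-{width} extras"
        )
    header = list(schema.required) + list(schema.optional) + list(extras_names)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            if rec.extras_width != width:
                raise FeatureError("inconsistent extras widths across records")
            row = [
                rec.reaction.source_text or rec.reaction.smiles,
                rec.solvent,
                repr(rec.ddG298),
                repr(rec.ddH298),
                rec.provenance,
                rec.family or "",
                rec.record_id or "",
            ]
            if width:
                row.extend(repr(float(v)) for v in rec.extras)
            writer.writerow(row)


def records_from_dataframe(
    df,
    schema: Optional[TableSchema] = None,
    provenance: str = "pretrain",
) -> List[PairRecord]:
    """Build PairRecords from a pandas DataFrame with pair-table columns."""
    schema = schema or TableSchema()
    for col in schema.required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in dataframe")
    if schema.extras is None:
        claimed = set(schema.required) | set(schema.optional)
        extras_cols = tuple(c for c in df.columns if c not in claimed)
    else:
        extras_cols = schema.extras
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        extras = (
            np.array([float(row[c]) for c in extras_cols], dtype=np.float64)
            if extras_cols
            else None
        )
        records.append(
            PairRecord(
                reaction=parse_mapped_reaction(row[schema.rxn_smiles]),
                solvent=row[schema.solvent_smiles],
                ddG298=float(row[schema.ddG_298]),
                ddH298=float(row[schema.ddH_298]),
                provenance=str(row.get(schema.provenance) or provenance),
                extras=extras,
                family=row.get(schema.family) or None,
                record_id=str(row.get(schema.record_id) or f"row{i}"),
            )
        )
    return records


def records_to_dataframe(records: Sequence[PairRecord], schema: Optional[TableSchema] = None):
    """Inverse of :func:`records_from_dataframe` (extras as extra_0..k)."""
    import pandas as pd

    schema = schema or TableSchema()
    width = records[0].extras_width if records else 0
    rows = []
    for rec in records:
        row = {
            schema.rxn_smiles: rec.reaction.source_text or rec.reaction.smiles,
            schema.solvent_smiles: rec.solvent,
            schema.ddG_298: rec.ddG298,
            schema.ddH_298: rec.ddH298,
            schema.provenance: rec.provenance,
            schema.family: rec.family,
            schema.record_id: rec.record_id,
        }
        for k in range(width):
            row[f"extra_{k}"] = float(rec.extras[k])
        rows.append(row)
    return pd.DataFrame(rows)


def group_by(records: Sequence[PairRecord], key: str) -> Dict[str, List[int]]:
    """Indices of records grouped by ``reaction_key`` or ``solvent_key``."""
    if key not in ("reaction_key", "solvent_key"):
        raise ValueError(f"unknown grouping key {key!r}")
    groups: Dict[str, List[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(getattr(rec, key), []).append(i)
    return groups
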