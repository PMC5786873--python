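"""Domain types, tabular I/O and packaged reference tables.

The central container is :class:`LabeledTable`: a set of compounds, each with a
binary chemotaxis label (attractant / non-attractant), optional response
threshold ``K_D`` (M), a map of named physicochemical descriptors, and optional
structural annotations used by the aspartate-analog rules (number of carboxyl
groups, carbon-chain length between them, amino-group count, inter-carboxyl
distance R in Å).

Four small reference tables from the study this package reproduces are shipped
as CSV files and loaded via :func:`load_fixture`:

- ``table1_correlations``: 20x20 Spearman rank-correlation matrix of the
  descriptors, used by the redundancy filter.
- ``table2_summaries``: per-descriptor group means/SDs for the 7 retained
  descriptors (38 attractants vs 15 non-attractants) with printed p and
  Cohen's d.
- ``table3_misclassified``: the 11 compounds misclassified by the q- threshold.
- ``table4_aspartate``: the 17 aspartate analogs with K_D, N_Carbon, N_NH2 and
  the inter-carboxyl distance R.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "CompoundRecord",
    "DescriptorDictionary",
    "DEFAULT_DESCRIPTORS",
    "LabeledTable",
    "CorrelationMatrix",
    "FunctionalGroupAttribution",
    "GroupSummary",
    "MisclassifiedCompound",
    "read_table",
    "write_table",
    "write_report",
    "read_report",
    "load_fixture",
    "fixture_notes",
]

LABELS = ("attractant", "non_attractant", "unknown")
FUNCTIONAL_GROUPS = ("amino", "sulfonyl", "acyl", "carboxyl", "hydroxyl")

#: structural/identity columns recognised by the readers, in canonical order
STRUCTURAL_COLUMNS = ("n_carboxyl", "n_carbon", "n_nh2", "r_distance")


class ValidationError(ValueError):
    """An input violates a domain invariant (labels, ids, positivity...)."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names the row and column."""


# --------------------------------------------------------------------------
# descriptor dictionary
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorEntry:
    name: str      # canonical ASCII column name
    symbol: str    # display symbol (may contain unicode)
    unit: str


@dataclass(frozen=True)
class DescriptorDictionary:
    """Registry of descriptor names; validates tables against it."""

    entries: tuple[DescriptorEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("descriptor names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.names


_DEFAULT_ENTRIES = (
    ("E", "E", "kJ/mol"),
    ("E_aq", "E_aq", "kJ/mol"),
    ("E_sol", "E_sol", "kJ/mol"),
    ("M_W", "M_W", "Da"),
    ("E_H", "E_H", "eV"),
    ("E_L", "E_L", "eV"),
    ("E_H-E_L", "E_H−E_L", "eV"),
    ("D", "D", "debye"),
    ("A_CPK", "A_CPK", "Å^2"),
    ("PSA", "PSA", "Å^2"),
    ("V_CPK", "V_CPK", "Å^3"),
    ("O_CPK", "O_CPK", ""),
    ("AA", "AA", "Å^2"),
    ("PA", "PA", "Å^2"),
    ("q-", "q−", "kJ/mol"),
    ("APA", "APA", "Å^2"),
    ("q_ion-", "q_ion−", "kJ/mol"),
    ("q+", "q+", "kJ/mol"),
    ("LogP", "LogP", ""),
    ("P", "P", ""),
)

#: the 20 descriptors computed from compound structures in the source study:
#: 8 molecular properties (formation energies, M_W, frontier-orbital energies,
#: HOMO-LUMO gap, dipole moment) and 12 QSAR descriptors (surface areas,
#: volumes, ovality, electron/ionization potentials, LogP, polarizability)
DEFAULT_DESCRIPTORS = DescriptorDictionary(
    entries=tuple(DescriptorEntry(*e) for e in _DEFAULT_ENTRIES)
)

#: the 7 descriptors retained after rank-correlation redundancy filtering
RETAINED_DESCRIPTORS = ("E", "E_sol", "E_H-E_L", "D", "q-", "q_ion-", "q+")


def _normalize_minus(text: str) -> str:
    """Map unicode minus/dash variants to ASCII '-'."""
    return (
        text.replace("−", "-")  # minus sign
        .replace("–", "-")      # en dash
        .replace("—", "-")      # em dash
    )


def canonical_descriptor_name(name: str) -> str:
    return _normalize_minus(name.strip())


# --------------------------------------------------------------------------
# records and tables
# --------------------------------------------------------------------------

@dataclass
class CompoundRecord:
    """One compound: identity, label, potency, descriptors, structure."""

    serial_id: int
    name: str
    label: str
    k_d: float | None = None
    descriptors: dict[str, float] = field(default_factory=dict)
    n_carboxyl: int | None = None
    n_carbon: int | None = None
    n_nh2: int | None = None
    r_distance: float | None = None
    annotations: dict[str, Any] = field(default_factory=dict)

    def validate(self, schema: DescriptorDictionary = DEFAULT_DESCRIPTORS) -> None:
        if self.label not in LABELS:
            raise ValidationError(
                f"compound {self.serial_id} ({self.name}): unknown label "
                f"{self.label!r}; expected one of {LABELS}"
            )
        if self.k_d is not None and not self.k_d > 0:
            raise ValidationError(
                f"compound {self.serial_id} ({self.name}): k_d must be > 0, "
                f"got {self.k_d!r}"
            )
        if self.r_distance is not None:
            if not self.r_distance > 0:
                raise ValidationError(
                    f"compound {self.serial_id}: r_distance must be > 0"
                )
            if self.n_carboxyl is not None and self.n_carboxyl != 2:
                raise ValidationError(
                    f"compound {self.serial_id}: r_distance requires exactly "
                    f"two carboxyl groups (n_carboxyl={self.n_carboxyl})"
                )
        for key in ("n_carboxyl", "n_carbon", "n_nh2"):
            v = getattr(self, key)
            if v is not None and v < 0:
                raise ValidationError(
                    f"compound {self.serial_id}: {key} must be nonnegative"
                )
        for dname in self.descriptors:
            if dname not in schema:
                raise ValidationError(
                    f"compound {self.serial_id}: descriptor {dname!r} not in "
                    "the registered dictionary"
                )

    def value(self, name: str) -> float | None:
        """Resolve a descriptor or structural field by name."""
        if name in self.descriptors:
            return self.descriptors[name]
        if name in STRUCTURAL_COLUMNS:
            return getattr(self, name)
        if name == "k_d":
            return self.k_d
        return None


@dataclass
class LabeledTable:
    """Compounds x named descriptors with binary labels."""

    records: list[CompoundRecord]
    descriptor_names: tuple[str, ...] = ()
    schema: DescriptorDictionary = DEFAULT_DESCRIPTORS

    def __post_init__(self) -> None:
        self.descriptor_names = tuple(self.descriptor_names)

    def validate(self) -> "LabeledTable":
        ids = [r.serial_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate serial_ids: {dupes}")
        for rec in self.records:
            rec.validate(self.schema)
            for dname in self.descriptor_names:
                if dname not in rec.descriptors:
                    raise ValidationError(
                        f"compound {rec.serial_id} lacks descriptor {dname!r}"
                    )
        return self

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_attractant(self) -> int:
        return sum(r.label == "attractant" for r in self.records)

    @property
    def n_non_attractant(self) -> int:
        return sum(r.label == "non_attractant" for r in self.records)

    def labels_binary(self) -> np.ndarray:
        """1 for attractant, 0 for non-attractant; errors on 'unknown'."""
        out = np.empty(len(self.records), dtype=int)
        for i, r in enumerate(self.records):
            if r.label == "attractant":
                out[i] = 1
            elif r.label == "non_attractant":
                out[i] = 0
            else:
                raise ValidationError(
                    f"compound {r.serial_id} has label 'unknown'; a binary "
                    "label is required here"
                )
        return out

    def column(self, name: str) -> np.ndarray:
        vals = [r.value(name) for r in self.records]
        if any(v is None for v in vals):
            missing = [r.serial_id for r, v in zip(self.records, vals) if v is None]
            raise ValidationError(f"column {name!r} missing for compounds {missing}")
        return np.asarray(vals, dtype=float)

    def matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = tuple(names) if names is not None else self.descriptor_names
        return np.column_stack([self.column(n) for n in names]) if names else \
            np.empty((len(self.records), 0))

    def subset_rows(self, indices: Sequence[int]) -> "LabeledTable":
        return LabeledTable(
            records=[self.records[i] for i in indices],
            descriptor_names=self.descriptor_names,
            schema=self.schema,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, Any] = {
                "serial_id": r.serial_id,
                "name": r.name,
                "label": r.label,
                "k_d": r.k_d,
            }
            for d in self.descriptor_names:
                row[d] = r.descriptors[d]
            for s in STRUCTURAL_COLUMNS:
                row[s] = getattr(r, s)
            for k, v in r.annotations.items():
                row[k] = v
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CorrelationMatrix:
    """Symmetric rank-correlation matrix over named descriptors."""

    names: tuple[str, ...]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.rho = np.asarray(self.rho, dtype=float)

    def validate(self) -> "CorrelationMatrix":
        n = len(self.names)
        if self.rho.shape != (n, n):
            raise ValidationError(
                f"rho shape {self.rho.shape} does not match {n} names"
            )
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValidationError("rho must be symmetric")
        if np.any(np.abs(self.rho) > 1 + 1e-12):
            raise ValidationError("|rho| must be <= 1")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-12):
            raise ValidationError("rho diagonal must be exactly 1")
        return self

    def get(self, a: str, b: str) -> float:
        ia, ib = self.names.index(a), self.names.index(b)
        return float(self.rho[ia, ib])


@dataclass(frozen=True)
class FunctionalGroupAttribution:
    """q- of one compound attributed to the functional group carrying it."""

    compound_id: int
    group: str
    q_minus: float  # kJ/mol

    def __post_init__(self) -> None:
        if self.group not in FUNCTIONAL_GROUPS:
            raise ValidationError(
                f"group {self.group!r} not in {FUNCTIONAL_GROUPS}"
            )


@dataclass(frozen=True)
class GroupSummary:
    """Printed two-group summary for one descriptor (means +/- SD, sizes)."""

    descriptor: str
    unit: str
    attractant_mean: float
    attractant_sd: float
    attractant_n: int
    non_attractant_mean: float
    non_attractant_sd: float
    non_attractant_n: int
    p_printed: float
    d_printed: float


@dataclass(frozen=True)
class MisclassifiedCompound:
    serial_id: int
    name: str
    k_d: float | None
    n_carboxyl: int
    n_carbon: int | None


# --------------------------------------------------------------------------
# delimited-text I/O
# --------------------------------------------------------------------------

_RESERVED = ("serial_id", "name", "label", "k_d") + STRUCTURAL_COLUMNS


def _parse_float(cell: Any, row_label: Any, col: str) -> float:
    if isinstance(cell, str):
        cell = _normalize_minus(cell).strip()
    try:
        v = float(cell)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric value {cell!r} in row {row_label}, column {col!r}"
        ) from None
    if math.isnan(v):
        raise ParseError(f"missing value in row {row_label}, column {col!r}")
    return v


def _opt_float(cell: Any, row_label: Any, col: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    if isinstance(cell, str) and not cell.strip():
        return None
    return _parse_float(cell, row_label, col)


def _opt_int(cell: Any, row_label: Any, col: str) -> int | None:
    v = _opt_float(cell, row_label, col)
    if v is None:
        return None
    if v != int(v):
        raise ParseError(f"non-integer value {cell!r} in row {row_label}, column {col!r}")
    return int(v)


def read_table(
    path: str | Path,
    schema: DescriptorDictionary = DEFAULT_DESCRIPTORS,
) -> LabeledTable:
    """Read a compound table from delimited text (comma or tab).

    Header columns ``serial_id,name,label`` are required; ``k_d``, the four
    structural columns and any registered descriptor names are optional.
    Unknown columns are preserved per record in ``annotations``. Unicode
    minus signs (as printed in the source tables, e.g. ``6.E−08``) are
    normalized on ingest.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [canonical_descriptor_name(str(c)) for c in df.columns]
    for req in ("serial_id", "name", "label"):
        if req not in df.columns:
            raise ValidationError(f"missing required column {req!r} in {path}")

    descriptor_cols = tuple(c for c in df.columns if c in schema)
    extra_cols = [
        c for c in df.columns
        if c not in _RESERVED and c not in descriptor_cols
    ]

    records: list[CompoundRecord] = []
    for _, row in df.iterrows():
        sid = _opt_int(row["serial_id"], row["serial_id"], "serial_id")
        if sid is None:
            raise ParseError(f"missing serial_id in {path}")
        label = str(row["label"]).strip()
        if label not in LABELS:
            raise ValidationError(
                f"row {sid}: unknown label token {label!r}; expected one of {LABELS}"
            )
        descriptors = {
            c: _parse_float(row[c], sid, c) for c in descriptor_cols
        }
        annotations = {}
        for c in extra_cols:
            cell = row[c]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            if isinstance(cell, str) and not cell.strip():
                continue
            annotations[c] = _normalize_minus(cell).strip() if isinstance(cell, str) else cell
        rec = CompoundRecord(
            serial_id=sid,
            name=str(row["name"]).strip(),
            label=label,
            k_d=_opt_float(row.get("k_d"), sid, "k_d"),
            descriptors=descriptors,
            n_carboxyl=_opt_int(row.get("n_carboxyl"), sid, "n_carboxyl"),
            n_carbon=_opt_int(row.get("n_carbon"), sid, "n_carbon"),
            n_nh2=_opt_int(row.get("n_nh2"), sid, "n_nh2"),
            r_distance=_opt_float(row.get("r_distance"), sid, "r_distance"),
            annotations=annotations,
        )
        records.append(rec)

    return LabeledTable(records, descriptor_cols, schema).validate()


def write_table(table: LabeledTable, path: str | Path) -> None:
    """Write a LabeledTable as comma-separated text, fixed column order."""
    df = table.to_frame()
    lead = ["serial_id", "name", "label", "k_d"]
    cols = lead + list(table.descriptor_names) + list(STRUCTURAL_COLUMNS)
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(Path(path), index=False, columns=cols)


# --------------------------------------------------------------------------
# report round-tripping
# --------------------------------------------------------------------------

def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {"__kind__": type(obj).__name__}
        for f in dataclasses.fields(obj):
            out[f.name] = _to_jsonable(getattr(obj, f.name))
        return out
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


#: registry used by read_report to rebuild dataclasses from JSON
_REPORT_KINDS: dict[str, type] = {}


def register_report_kind(cls: type) -> type:
    _REPORT_KINDS[cls.__name__] = cls
    return cls


for _cls in (
    CompoundRecord,
    CorrelationMatrix,
    GroupSummary,
    MisclassifiedCompound,
    FunctionalGroupAttribution,
):
    register_report_kind(_cls)


def _from_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=float)
        if "__kind__" in obj:
            kind = obj["__kind__"]
            cls = _REPORT_KINDS.get(kind)
            if cls is None:
                raise ParseError(f"unknown report kind {kind!r}")
            kwargs = {
                k: _from_jsonable(v) for k, v in obj.items() if k != "__kind__"
            }
            fields = {f.name for f in dataclasses.fields(cls)}
            obj2 = cls(**{k: v for k, v in kwargs.items() if k in fields})
            # tuples serialize as lists; normalise per-field on access, not here
            return obj2
        return {k: _from_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_from_jsonable(v) for v in obj]
    return obj


def write_report(report: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a finished report (or list of reports) to json/CSV.

    JSON round-trips through :func:`read_report` bit-exactly for integer and
    text fields and to full repr precision for reals.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_to_jsonable(report), fh, indent=1)
    elif format in ("csv", "delimited", "delimited-text"):
        frame = _report_frame(report)
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def _report_frame(report: Any) -> pd.DataFrame:
    """Flatten a report into a DataFrame for delimited output."""
    if isinstance(report, LabeledTable):
        return report.to_frame()
    if dataclasses.is_dataclass(report) and not isinstance(report, type):
        # tabular sub-structure if present (e.g. SearchReport.results)
        d = _to_jsonable(report)
        d.pop("__kind__", None)
        for key, val in list(d.items()):
            if isinstance(val, list) and val and isinstance(val[0], dict):
                rows = []
                for item in val:
                    item = dict(item)
                    item.pop("__kind__", None)
                    rows.append({
                        k: (json.dumps(v) if isinstance(v, (list, dict)) else v)
                        for k, v in item.items()
                    })
                return pd.DataFrame(rows)
        return pd.DataFrame([{
            k: (json.dumps(v) if isinstance(v, (list, dict)) else v)
            for k, v in d.items()
        }])
    if isinstance(report, list):
        if not report:
            return pd.DataFrame()
        return pd.concat([_report_frame(r) for r in report], ignore_index=True)
    raise ValueError(f"cannot tabulate report of type {type(report).__name__}")


def read_report(path: str | Path) -> Any:
    """Inverse of :func:`write_report` for the JSON format."""
    with open(Path(path)) as fh:
        return _from_jsonable(json.load(fh))


# --------------------------------------------------------------------------
# packaged fixtures
# --------------------------------------------------------------------------

_FIXTURES = (
    "table1_correlations",
    "table2_summaries",
    "table3_misclassified",
    "table4_aspartate",
)


def _data_path(fname: str) -> Path:
    return Path(str(resources.files("chemoqsar").joinpath("data", fname)))


def fixture_notes() -> dict[str, str]:
    """Provenance notes for cells whose printed values are ambiguous."""
    with open(_data_path("fixture_notes.json")) as fh:
        return json.load(fh)


def load_fixture(name: str):
    """Load one of the packaged reference tables.

    Returns a :class:`CorrelationMatrix` (table1), a dict descriptor ->
    :class:`GroupSummary` (table2), a list of :class:`MisclassifiedCompound`
    (table3), or a :class:`LabeledTable` (table4).
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {_FIXTURES}")

    if name == "table1_correlations":
        df = pd.read_csv(_data_path("table1_correlations.csv"), index_col=0)
        names = tuple(canonical_descriptor_name(c) for c in df.columns)
        return CorrelationMatrix(names, df.to_numpy(dtype=float)).validate()

    if name == "table2_summaries":
        df = pd.read_csv(_data_path("table2_summaries.csv"))
        out: dict[str, GroupSummary] = {}
        for _, row in df.iterrows():
            gs = GroupSummary(
                descriptor=canonical_descriptor_name(row["descriptor"]),
                unit=row["unit"] if isinstance(row["unit"], str) else "",
                attractant_mean=float(row["attractant_mean"]),
                attractant_sd=float(row["attractant_sd"]),
                attractant_n=int(row["attractant_n"]),
                non_attractant_mean=float(row["non_attractant_mean"]),
                non_attractant_sd=float(row["non_attractant_sd"]),
                non_attractant_n=int(row["non_attractant_n"]),
                p_printed=float(row["p_printed"]),
                d_printed=float(row["d_printed"]),
            )
            out[gs.descriptor] = gs
        return out

    if name == "table3_misclassified":
        df = pd.read_csv(_data_path("table3_misclassified.csv"), dtype=str)
        out3: list[MisclassifiedCompound] = []
        for _, row in df.iterrows():
            out3.append(MisclassifiedCompound(
                serial_id=int(row["serial_id"]),
                name=row["name"],
                k_d=_opt_float(row["k_d"], row["serial_id"], "k_d"),
                n_carboxyl=int(row["n_carboxyl"]),
                n_carbon=_opt_int(row["n_carbon"], row["serial_id"], "n_carbon"),
            ))
        return out3

    # table4_aspartate
    return read_table(_data_path("table4_aspartate.csv"))
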