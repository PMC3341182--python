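"""Binary case-table data model and delimited-text I/O.

A case table holds, for N patient cases, a binary symptom matrix ``F``
(N x S, ``F[m, i] == 1`` iff symptom *i* was recorded present in case *m*)
and a binary syndrome matrix ``L`` (N x K, ``L[m, i] == 1`` iff syndrome
*i* was assigned to case *m*). Column roles travel in the header via the
prefixes ``sym:`` and ``syn:``; an optional sidecar schema (YAML/JSON
mapping column name -> role) overrides the prefixes for legacy headers.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SYMPTOM_PREFIX = "sym:"
SYNDROME_PREFIX = "syn:"

_ID_ROLE = "id"
_SYMPTOM_ROLE = "symptom"
_SYNDROME_ROLE = "syndrome"


class CaseTableError(ValueError):
    """Raised for malformed case tables or unreadable case-table files."""


@dataclass
class CaseTable:
    """Validated binary case table.

    Parameters
    ----------
    case_ids
        One opaque identifier per case (length N).
    symptom_names, syndrome_names
        Column names for ``F`` and ``L``. Must be unique and disjoint.
    F
        N x S matrix of {0, 1} symptom indicators.
    L
        N x K matrix of {0, 1} syndrome indicators. K = 0 is permitted
        for symptom-only association analysis.
    """

    case_ids: list[str]
    symptom_names: list[str]
    syndrome_names: list[str]
    F: np.ndarray
    L: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=np.int8)
        if self.L is None:
            self.L = np.zeros((self.F.shape[0], 0), dtype=np.int8)
        self.L = np.asarray(self.L, dtype=np.int8)
        if self.F.ndim != 2 or self.L.ndim != 2:
            raise CaseTableError("F and L must be 2-dimensional")
        n = self.F.shape[0]
        if n < 1:
            raise CaseTableError("a case table needs at least one case")
        if self.F.shape[1] < 1:
            raise CaseTableError("a case table needs at least one symptom column")
        if self.L.shape[0] != n:
            raise CaseTableError(
                f"F has {n} rows but L has {self.L.shape[0]}"
            )
        if len(self.case_ids) != n:
            raise CaseTableError(
                f"{len(self.case_ids)} case ids for {n} rows"
            )
        if len(self.symptom_names) != self.F.shape[1]:
            raise CaseTableError("symptom_names length does not match F")
        if len(self.syndrome_names) != self.L.shape[1]:
            raise CaseTableError("syndrome_names length does not match L")
        for mat, label in ((self.F, "symptom"), (self.L, "syndrome")):
            bad = (mat != 0) & (mat != 1)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise CaseTableError(
                    f"non-binary value in {label} matrix at row {r + 1}, "
                    f"column {c + 1}"
                )
        names = self.symptom_names + self.syndrome_names
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(x for x in names if x in seen or seen.add(x))  # type: ignore[func-returns-value]
            raise CaseTableError(
                f"symptom and syndrome names must be unique and disjoint; "
                f"duplicate: {dup!r}"
            )
        self.case_ids = [str(c) for c in self.case_ids]

    @property
    def n_cases(self) -> int:
        return self.F.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.F.shape[1]

    @property
    def n_syndromes(self) -> int:
        return self.L.shape[1]

    def block(self, which: str) -> tuple[list[str], np.ndarray]:
        """Return ``(names, matrix)`` for ``which`` in {'symptoms', 'syndromes'}."""
        if which == "symptoms":
            return self.symptom_names, self.F
        if which == "syndromes":
            return self.syndrome_names, self.L
        raise ValueError(f"unknown block {which!r}; use 'symptoms' or 'syndromes'")

    def syndrome_column(self, name: str) -> np.ndarray:
        try:
            j = self.syndrome_names.index(name)
        except ValueError:
            raise KeyError(f"unknown syndrome {name!r}") from None
        return self.L[:, j].astype(np.int8)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CaseTable):
            return NotImplemented
        return (
            self.case_ids == other.case_ids
            and self.symptom_names == other.symptom_names
            and self.syndrome_names == other.syndrome_names
            and np.array_equal(self.F, other.F)
            and np.array_equal(self.L, other.L)
        )


def _load_schema(schema: str | Path | dict | None) -> dict[str, str] | None:
    if schema is None:
        return None
    if isinstance(schema, dict):
        mapping = schema
    else:
        text = Path(schema).read_text(encoding="utf-8")
        if str(schema).endswith(".json"):
            mapping = json.loads(text)
        else:
            mapping = yaml.safe_load(text)
    out = {}
    for name, role in mapping.items():
        role = str(role).lower()
        if role not in (_ID_ROLE, _SYMPTOM_ROLE, _SYNDROME_ROLE):
            raise CaseTableError(
                f"schema role for column {name!r} must be "
                f"'id', 'symptom' or 'syndrome', got {role!r}"
            )
        out[str(name)] = role
    return out


def _detect_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_case_table(
    path: str | Path,
    schema: str | Path | dict | None = None,
    *,
    delimiter: str | None = None,
    impute_zero: bool = False,
) -> CaseTable:
    """Read a delimited binary case table.

    Column roles come from a sidecar ``schema`` (name -> 'id' | 'symptom'
    | 'syndrome') when given, otherwise from the ``sym:`` / ``syn:``
    header prefixes; a prefix-free first column is the case-id column.
    Cells must be 0 or 1; empty cells are a hard error unless
    ``impute_zero`` is set, in which case they are logged and mapped to 0
    (absent). Tab delimiters are auto-detected from the header line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or _detect_delimiter(path)
    with open(path, encoding="utf-8") as fh:
        raw_header = next(csv.reader(fh, delimiter=sep))
    if len(set(raw_header)) != len(raw_header):
        raise CaseTableError(f"{path}: duplicate column name in header")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[0] < 1:
        raise CaseTableError(f"{path}: no data rows")
    columns = [str(c) for c in df.columns]

    roles = _load_schema(schema)
    if roles is None:
        roles = {}
        for pos, col in enumerate(columns):
            if col.startswith(SYMPTOM_PREFIX):
                roles[col] = _SYMPTOM_ROLE
            elif col.startswith(SYNDROME_PREFIX):
                roles[col] = _SYNDROME_ROLE
            elif pos == 0:
                roles[col] = _ID_ROLE
            else:
                raise CaseTableError(
                    f"{path}: column {col!r} has no 'sym:'/'syn:' prefix and "
                    f"is not the leading id column; provide a schema"
                )
    missing = [c for c in columns if c not in roles]
    if missing:
        raise CaseTableError(f"{path}: schema does not cover columns {missing}")

    id_cols = [c for c in columns if roles[c] == _ID_ROLE]
    if len(id_cols) > 1:
        raise CaseTableError(f"{path}: more than one id column: {id_cols}")
    sym_cols = [c for c in columns if roles[c] == _SYMPTOM_ROLE]
    syn_cols = [c for c in columns if roles[c] == _SYNDROME_ROLE]

    def strip(col: str, prefix: str) -> str:
        return col[len(prefix):] if col.startswith(prefix) else col

    def parse_block(cols: list[str], label: str) -> np.ndarray:
        if not cols:
            return np.zeros((df.shape[0], 0), dtype=np.int8)
        imputed = 0
        out = np.empty((df.shape[0], len(cols)), dtype=np.int8)
        for j, col in enumerate(cols):
            vals = df[col].str.strip()
            for m, v in enumerate(vals):
                if v == "":
                    if impute_zero:
                        imputed += 1
                        out[m, j] = 0
                        continue
                    raise CaseTableError(
                        f"{path}: empty cell at data row {m + 1}, "
                        f"column {col!r} (use impute_zero to map to 0)"
                    )
                if v not in ("0", "1"):
                    raise CaseTableError(
                        f"{path}: non-binary value {v!r} at data row {m + 1}, "
                        f"column {col!r}"
                    )
                out[m, j] = int(v)
        if imputed:
            logger.info("imputed %d empty %s cells to 0 in %s", imputed, label, path)
        return out

    F = parse_block(sym_cols, "symptom")
    L = parse_block(syn_cols, "syndrome")
    if id_cols:
        case_ids = [str(v) for v in df[id_cols[0]]]
    else:
        case_ids = [str(i) for i in range(1, df.shape[0] + 1)]

    return CaseTable(
        case_ids=case_ids,
        symptom_names=[strip(c, SYMPTOM_PREFIX) for c in sym_cols],
        syndrome_names=[strip(c, SYNDROME_PREFIX) for c in syn_cols],
        F=F,
        L=L,
    )


def write_case_table(
    table: CaseTable, path: str | Path, *, delimiter: str = ","
) -> None:
    """Write ``table`` as delimited text re-readable by :func:`read_case_table`.

    Column roles are encoded with the ``sym:`` / ``syn:`` prefixes; the
    leading column holds case ids.
    """
    path = Path(path)
    data: dict[str, object] = {"case_id": table.case_ids}
    for j, name in enumerate(table.symptom_names):
        data[SYMPTOM_PREFIX + name] = table.F[:, j]
    for j, name in enumerate(table.syndrome_names):
        data[SYNDROME_PREFIX + name] = table.L[:, j]
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)
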