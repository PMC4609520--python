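"""Clinical record domain types, dataset I/O and the keyword-match featurizer.

A clinical record couples four feature groups with a categorical diagnosis:

* ``icd10`` — one-hot boolean vector over the disease label set (exactly one
  bit set per record);
* ``basic_info`` — real-valued patient attributes (age, gender code, job-type
  code, history, weight, height, ...);
* ``text_features`` — boolean keyword-match vector produced from free
  diagnosis text against a fixed :class:`KeywordDictionary`;
* ``acupoints`` — boolean multi-label vector of acupuncture points in the
  treatment plan;
* ``tcm_dx`` — a single categorical traditional-medicine diagnosis code.

Datasets are stored as plain CSV with a deterministic column order
(``icd10_0..``, ``basic_0..``, ``kw_0..``, ``acu_0..``, ``tcm_dx``) so that
``read_dataset(write_dataset(ds))`` is an identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SchemaError

__all__ = [
    "KeywordDictionary",
    "DatasetSchema",
    "ClinicalRecord",
    "Dataset",
    "normalize_text",
    "match_keywords",
    "read_dataset",
    "write_dataset",
]

_WHITESPACE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lowercase and collapse runs of whitespace to single spaces."""
    return _WHITESPACE.sub(" ", text.strip().lower())


@dataclass(frozen=True)
class KeywordDictionary:
    """An ordered dictionary of keywords defining text-feature positions.

    Entry order is fixed and defines the vector position of each keyword.
    Entries must be unique after :func:`normalize_text` normalization.
    """

    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ConfigurationError("keyword dictionary must not be empty")
        normed = [normalize_text(e) for e in self.entries]
        if any(not e for e in normed):
            raise ConfigurationError("keyword dictionary contains a blank entry")
        if len(set(normed)) != len(normed):
            raise ConfigurationError(
                "keyword dictionary entries are not unique after normalization"
            )
        object.__setattr__(self, "entries", tuple(normed))

    @property
    def size(self) -> int:
        return len(self.entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "KeywordDictionary":
        """Load a dictionary from a plain-text file, one keyword per line."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(tuple(line for line in lines if line.strip()))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.entries) + "\n", encoding="utf-8")


def match_keywords(text: str, dictionary: KeywordDictionary) -> np.ndarray:
    """Map free text to a boolean vector over dictionary entries.

    Element ``j`` is 1 iff entry ``j`` occurs as a substring of the
    normalized text.  Every entry is tested independently, so overlapping
    keywords may all fire.

    Parameters
    ----------
    text:
        Raw diagnosis/description text (any language, any whitespace).
    dictionary:
        The fixed keyword dictionary defining vector positions.

    Returns
    -------
    numpy.ndarray
        A ``uint8`` vector of length ``dictionary.size``.
    """
    normed = normalize_text(text)
    out = np.zeros(dictionary.size, dtype=np.uint8)
    if not normed:
        return out
    for j, entry in enumerate(dictionary.entries):
        if entry in normed:
            out[j] = 1
    return out


@dataclass(frozen=True)
class DatasetSchema:
    """Declared dimensions and label sets of a dataset."""

    n_icd10: int = 31
    n_basic: int = 11
    n_keywords: int = 4000
    n_acupoints: int = 53
    tcm_codes: tuple[int, ...] = tuple(range(21))

    def __post_init__(self) -> None:
        for name in ("n_icd10", "n_basic", "n_keywords", "n_acupoints"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be positive")
        if len(self.tcm_codes) == 0:
            raise SchemaError("tcm_codes must not be empty")
        if len(set(self.tcm_codes)) != len(self.tcm_codes):
            raise SchemaError("tcm_codes must be unique")
        object.__setattr__(self, "tcm_codes", tuple(int(c) for c in self.tcm_codes))

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return (self.n_icd10, self.n_basic, self.n_keywords, self.n_acupoints)


def _check_binary(vec: np.ndarray, name: str, length: int, row: object = None) -> np.ndarray:
    where = "" if row is None else f" (row {row})"
    arr = np.asarray(vec)
    if arr.shape != (length,):
        raise SchemaError(f"{name} has length {arr.shape}, expected ({length},){where}")
    if not np.isin(arr, (0, 1)).all():
        raise SchemaError(f"{name} contains non-binary values{where}")
    return arr.astype(np.uint8)


@dataclass
class ClinicalRecord:
    """One patient encounter.

    Invariants (enforced by :meth:`validate`): exactly one ICD-10 bit set,
    boolean vectors contain only {0, 1}, and all lengths match the schema.
    """

    icd10: np.ndarray
    basic_info: np.ndarray
    text_features: np.ndarray
    acupoints: np.ndarray
    tcm_dx: int

    @property
    def icd10_label(self) -> int:
        """Index of the single set ICD-10 bit."""
        return int(np.argmax(self.icd10))

    @property
    def acupoint_set(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.acupoints).tolist())

    def validate(self, schema: DatasetSchema, row: object = None) -> "ClinicalRecord":
        where = "" if row is None else f" (row {row})"
        self.icd10 = _check_binary(self.icd10, "icd10", schema.n_icd10, row)
        if int(self.icd10.sum()) != 1:
            raise SchemaError(
                f"icd10 must have exactly one flag set, found {int(self.icd10.sum())}{where}"
            )
        self.text_features = _check_binary(
            self.text_features, "text_features", schema.n_keywords, row
        )
        self.acupoints = _check_binary(self.acupoints, "acupoints", schema.n_acupoints, row)
        basic = np.asarray(self.basic_info, dtype=np.float64)
        if basic.shape != (schema.n_basic,):
            raise SchemaError(
                f"basic_info has shape {basic.shape}, expected ({schema.n_basic},){where}"
            )
        if not np.isfinite(basic).all():
            raise SchemaError(f"basic_info contains non-finite values{where}")
        self.basic_info = basic
        if int(self.tcm_dx) not in schema.tcm_codes:
            raise SchemaError(
                f"tcm_dx {self.tcm_dx} not in declared code set{where}"
            )
        self.tcm_dx = int(self.tcm_dx)
        return self


class Dataset:
    """An ordered collection of validated records sharing one schema."""

    def __init__(self, records: Sequence[ClinicalRecord], schema: DatasetSchema):
        self.schema = schema
        self.records = list(records)
        for i, rec in enumerate(self.records):
            rec.validate(schema, row=i)
        self._features: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[ClinicalRecord]:
        return iter(self.records)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """A new dataset holding the records at ``indices`` (order kept, duplicates allowed)."""
        return Dataset([self.records[int(i)] for i in indices], self.schema)

    # --- matrix views used by the learning modules -------------------------

    def feature_matrix(self) -> np.ndarray:
        """``(n, n_basic + n_keywords)`` float matrix: basic info then keyword bits."""
        if self._features is None:
            self._features = np.column_stack(
                [
                    np.array([r.basic_info for r in self.records], dtype=np.float64),
                    np.array([r.text_features for r in self.records], dtype=np.float64),
                ]
            ) if self.records else np.zeros((0, self.schema.n_basic + self.schema.n_keywords))
        return self._features

    def icd10_labels(self) -> np.ndarray:
        return np.array([r.icd10_label for r in self.records], dtype=np.int64)

    def tcm_labels(self) -> np.ndarray:
        return np.array([r.tcm_dx for r in self.records], dtype=np.int64)

    def acupoint_matrix(self) -> np.ndarray:
        return np.array([r.acupoints for r in self.records], dtype=np.uint8).reshape(
            len(self), self.schema.n_acupoints
        )

    def acupoint_sets(self) -> list[frozenset[int]]:
        return [r.acupoint_set for r in self.records]


def _column_names(schema: DatasetSchema) -> list[str]:
    return (
        [f"icd10_{i}" for i in range(schema.n_icd10)]
        + [f"basic_{i}" for i in range(schema.n_basic)]
        + [f"kw_{i}" for i in range(schema.n_keywords)]
        + [f"acu_{i}" for i in range(schema.n_acupoints)]
        + ["tcm_dx"]
    )


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset as CSV with a deterministic header and column order."""
    cols = _column_names(ds.schema)
    n1, nb, nk, na = ds.schema.dims
    rows = np.empty((len(ds), n1 + nb + nk + na + 1), dtype=object)
    for i, rec in enumerate(ds.records):
        rows[i, :n1] = rec.icd10
        rows[i, n1 : n1 + nb] = rec.basic_info
        rows[i, n1 + nb : n1 + nb + nk] = rec.text_features
        rows[i, n1 + nb + nk : -1] = rec.acupoints
        rows[i, -1] = rec.tcm_dx
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, lineterminator="\n")


def infer_schema(path: str | Path) -> DatasetSchema:
    """Recover a schema from a dataset file's header and its tcm_dx values."""
    header = pd.read_csv(path, nrows=0).columns.tolist()
    counts = {"icd10": 0, "basic": 0, "kw": 0, "acu": 0}
    for col in header:
        prefix = col.rsplit("_", 1)[0]
        if prefix in counts:
            counts[prefix] += 1
    tcm = pd.read_csv(path, usecols=["tcm_dx"])["tcm_dx"]
    codes = tuple(sorted(int(c) for c in tcm.unique())) if len(tcm) else (0,)
    return DatasetSchema(
        n_icd10=counts["icd10"],
        n_basic=counts["basic"],
        n_keywords=counts["kw"],
        n_acupoints=counts["acu"],
        tcm_codes=codes,
    )


def read_dataset(path: str | Path, schema: DatasetSchema | None = None) -> Dataset:
    """Read a dataset written by :func:`write_dataset`.

    When ``schema`` is omitted it is inferred from the file header (the
    tcm code set is taken from the observed values).  Row-level schema
    violations raise :class:`SchemaError` naming the offending row.
    """
    if schema is None:
        schema = infer_schema(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    expected = _column_names(schema)
    if frame.columns.tolist() != expected:
        raise SchemaError(
            f"column mismatch: file has {len(frame.columns)} columns, "
            f"schema declares {len(expected)}"
        )
    n1, nb, nk, na = schema.dims
    records = []
    for i, row in enumerate(frame.itertuples(index=False, name=None)):
        vals = np.asarray(row, dtype=object)
        rec = ClinicalRecord(
            icd10=vals[:n1].astype(np.float64),
            basic_info=vals[n1 : n1 + nb].astype(np.float64),
            text_features=vals[n1 + nb : n1 + nb + nk].astype(np.float64),
            acupoints=vals[n1 + nb + nk : -1].astype(np.float64),
            tcm_dx=int(vals[-1]),
        )
        rec.validate(schema, row=i)
        records.append(rec)
    return Dataset(records, schema)
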