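"""Descriptor-table I/O, bundled study data, and potency-unit arithmetic.

A QSAR descriptor table is a rectangular CSV: one row per compound, an id
column first, one or more response columns holding pIC50 values (missing
entries allowed), and numeric molecular-descriptor columns. This module
reads and validates such tables, converts between IC50 concentrations and
pIC50, and assembles fitting-ready design matrices.

All concentrations are held internally in molar units; bundled fixtures
store IC50 in nM with an explicit unit column and are converted on load.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Cell contents treated as a missing response value.
MISSING_SENTINELS = {"–", "-", "", "NA", "ND", "nan"}

#: Conversion factors to molar for the unit strings accepted in potency CSVs.
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


class DatasetError(ValueError):
    """Raised for malformed tables or infeasible model requests."""


def ic50_to_pic50(ic50: float) -> float:
    """Convert an IC50 in molar to pIC50 = -log10(IC50).

    Parameters
    ----------
    ic50 : float
        Half-maximal inhibitory concentration in molar units. Must be > 0.

    Returns
    -------
    float
        The pIC50 value; larger means more potent.
    """
    ic50 = float(ic50)
    if not ic50 > 0:
        raise DatasetError(f"IC50 must be positive, got {ic50!r}")
    return -math.log10(ic50)


def pic50_to_ic50(pic50: float) -> float:
    """Convert a pIC50 back to an IC50 in molar: 10**(-pIC50)."""
    pic50 = float(pic50)
    if not math.isfinite(pic50):
        raise DatasetError(f"pIC50 must be finite, got {pic50!r}")
    return 10.0 ** (-pic50)


@dataclass(frozen=True)
class PotencyRecord:
    """One measured potency: a compound against a kinase or cell line.

    ``ic50`` is in molar; ``pic50`` is derived as -log10(ic50).
    """

    compound_id: str
    target: str
    ic50: float
    pic50: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise DatasetError(f"IC50 must be positive, got {self.ic50!r}")
        object.__setattr__(self, "pic50", ic50_to_pic50(self.ic50))


@dataclass
class DescriptorTable:
    """A per-compound table of responses (pIC50, possibly missing) and descriptors.

    Invariants enforced at construction: unique compound ids, equal column
    lengths, and descriptor columns free of missing values.
    """

    compound_ids: list[str]
    responses: pd.DataFrame      # float columns, NaN = missing
    descriptors: pd.DataFrame    # float columns, no NaN

    def __post_init__(self) -> None:
        n = len(self.compound_ids)
        if len(set(self.compound_ids)) != n:
            dupes = sorted({c for c in self.compound_ids if self.compound_ids.count(c) > 1})
            raise DatasetError(f"duplicate compound ids: {dupes}")
        for df, label in ((self.responses, "response"), (self.descriptors, "descriptor")):
            if len(df) != n:
                raise DatasetError(f"{label} columns have length {len(df)}, expected {n}")
        if self.descriptors.isna().any().any():
            bad = [c for c in self.descriptors.columns if self.descriptors[c].isna().any()]
            raise DatasetError(f"descriptor columns contain missing values: {bad}")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def response_names(self) -> list[str]:
        return list(self.responses.columns)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.descriptors.columns)

    def to_frame(self) -> pd.DataFrame:
        """Full table as one DataFrame, id column first."""
        out = pd.concat([self.responses, self.descriptors], axis=1)
        out.insert(0, "compound", self.compound_ids)
        return out

    def to_json(self, path: str | Path) -> None:
        """Write a provenance JSON export: ids, column roles, values."""
        payload = {
            "compound_ids": self.compound_ids,
            "responses": {c: [None if pd.isna(v) else float(v) for v in self.responses[c]]
                          for c in self.responses.columns},
            "descriptors": {c: [float(v) for v in self.descriptors[c]]
                            for c in self.descriptors.columns},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def write_csv(self, path: str | Path) -> None:
        """Round-trippable CSV export (missing responses written as '-')."""
        frame = self.to_frame()
        frame.to_csv(path, index=False, na_rep="-")


@dataclass
class QsarDataset:
    """A fitting-ready matrix/response pair for one target.

    Rows with a missing response have been dropped; ``X`` is n x p with no
    missing values and ``y`` holds pIC50.
    """

    ids: list[str]
    descriptor_names: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape != (len(self.ids), len(self.descriptor_names)):
            raise DatasetError(
                f"X has shape {self.X.shape}, expected ({len(self.ids)}, {len(self.descriptor_names)})")
        if self.y.shape != (len(self.ids),):
            raise DatasetError(f"y has shape {self.y.shape}, expected ({len(self.ids)},)")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise DatasetError("X and y must not contain missing values")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def subset(self, names: Sequence[str]) -> "QsarDataset":
        """Dataset restricted to the named descriptor columns, order as given."""
        idx = [self._col(nm) for nm in names]
        return QsarDataset(self.ids, list(names), self.X[:, idx], self.y)

    def _col(self, name: str) -> int:
        try:
            return self.descriptor_names.index(name)
        except ValueError:
            raise DatasetError(f"unknown descriptor {name!r}; have {self.descriptor_names}") from None


def read_descriptor_table(
    path: str | Path,
    response_columns: Sequence[str] | None = None,
    id_column: str | None = None,
) -> DescriptorTable:
    """Read a descriptor table CSV.

    The first column is the compound id unless ``id_column`` names another.
    Columns listed in ``response_columns`` (default: every column whose name
    starts with ``pIC50``) are parsed as responses where the sentinels
    '–', '-', '', 'NA', 'ND' mean missing; all remaining columns must be
    fully numeric descriptors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DatasetError(f"{path}: no header") from None
    if raw.shape[1] < 2:
        raise DatasetError(f"{path}: expected id column plus data columns")

    id_column = id_column or raw.columns[0]
    ids = [s.strip() for s in raw[id_column]]
    if response_columns is None:
        response_columns = [c for c in raw.columns if c != id_column and c.startswith("pIC50")]
    missing_cols = set(response_columns) - set(raw.columns)
    if missing_cols:
        raise DatasetError(f"response columns not in file: {sorted(missing_cols)}")

    def parse_response(col: str) -> pd.Series:
        vals = []
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell in MISSING_SENTINELS:
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise DatasetError(
                        f"non-numeric response cell {cell!r} at row {ids[i]!r}, column {col!r}") from None
        return pd.Series(vals, dtype=float)

    def parse_descriptor(col: str) -> pd.Series:
        vals = []
        for i, cell in enumerate(raw[col]):
            try:
                vals.append(float(cell.strip()))
            except ValueError:
                raise DatasetError(
                    f"non-numeric descriptor cell {cell!r} at row {ids[i]!r}, column {col!r}") from None
        return pd.Series(vals, dtype=float)

    responses = pd.DataFrame({c: parse_response(c) for c in response_columns})
    descriptor_cols = [c for c in raw.columns if c != id_column and c not in response_columns]
    descriptors = pd.DataFrame({c: parse_descriptor(c) for c in descriptor_cols})
    return DescriptorTable(ids, responses, descriptors)


def build_qsar_dataset(
    table: DescriptorTable,
    response: str,
    descriptors: Sequence[str] | None = None,
) -> QsarDataset:
    """Assemble the design matrix and response for one target.

    Rows whose response is missing are dropped; descriptor order is
    preserved. Requires n >= p + 2 so the residual degrees of freedom for
    the standard error of estimate and F-statistic are positive.
    """
    if response not in table.responses.columns:
        raise DatasetError(f"unknown response column {response!r}; have {table.response_names}")
    names = list(descriptors) if descriptors is not None else table.descriptor_names
    unknown = [nm for nm in names if nm not in table.descriptors.columns]
    if unknown:
        raise DatasetError(f"unknown descriptor columns {unknown}; have {table.descriptor_names}")

    y = table.responses[response].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    n, p = int(keep.sum()), len(names)
    if n < p + 2:
        raise DatasetError(
            f"insufficient degrees of freedom: n={n} rows with {response!r} but p={p} descriptors "
            f"requires n >= p + 2")
    ids = [cid for cid, k in zip(table.compound_ids, keep) if k]
    X = table.descriptors[names].to_numpy(dtype=float)[keep]
    return QsarDataset(ids, names, X, y[keep])


def check_fixture_consistency(
    potencies: Sequence[PotencyRecord],
    table: DescriptorTable,
    response_by_target: dict[str, str] | None = None,
    tol: float = 5e-4,
) -> list[dict]:
    """Cross-check measured IC50s against the pIC50s printed in a descriptor table.

    For every potency record whose compound appears in the table and whose
    target maps to a response column, flag the pair if
    ``|round(-log10 IC50, 3) - printed pIC50| > tol``. An empty list means
    the two data sources are mutually consistent transcriptions.
    """
    if response_by_target is None:
        response_by_target = {"V600E-B-RAF": "pIC50_V600E", "RAF1": "pIC50_RAF1"}
    row_of = {cid: i for i, cid in enumerate(table.compound_ids)}
    discrepancies = []
    for rec in potencies:
        col = response_by_target.get(rec.target)
        if col is None or col not in table.responses.columns or rec.compound_id not in row_of:
            continue
        printed = table.responses[col].iloc[row_of[rec.compound_id]]
        if pd.isna(printed):
            continue
        derived = round(rec.pic50, 3)
        if abs(derived - float(printed)) > tol:
            discrepancies.append({
                "compound_id": rec.compound_id,
                "target": rec.target,
                "ic50_molar": rec.ic50,
                "derived_pic50": derived,
                "printed_pic50": float(printed),
            })
    return discrepancies


# ---------------------------------------------------------------------------
# Bundled study fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("qsarforge") / "data" / name)


def load_descriptor_table() -> DescriptorTable:
    """The bundled 22-compound descriptor table (6 descriptors, 2 pIC50 responses)."""
    return read_descriptor_table(_data_path("descriptors.csv"))


def load_kinase_potencies() -> list[PotencyRecord]:
    """Bundled cell-free kinase IC50 measurements, converted to molar."""
    df = pd.read_csv(_data_path("kinase_potency.csv"))
    return [
        PotencyRecord(r.compound, r.target, float(r.ic50) * _UNIT_TO_MOLAR[r.unit])
        for r in df.itertuples()
    ]


def load_kinase_panel() -> pd.DataFrame:
    """Bundled 30-kinase percent-inhibition panel for the lead compound at 1 uM."""
    return pd.read_csv(_data_path("kinase_panel.csv"))


def load_cell_potencies() -> pd.DataFrame:
    """Bundled antiproliferative IC50s (molar) on melanoma and normal skin lines."""
    df = pd.read_csv(_data_path("cell_potency.csv"))
    df["ic50_molar"] = [float(v) * _UNIT_TO_MOLAR[u] for v, u in zip(df.ic50, df.unit)]
    return df
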