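"""Phenotype / pedigree data model, file I/O, validation and data-edit rules.

The canonical in-memory container is a :class:`PhenotypeTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per egg record.  Row order is
stable: record *i* corresponds to residual ``e_i`` and leverage ``h_i``
throughout the package.

Edit rules mirror the study protocol: purebred hens need a minimum number of
repeated records (so that a permanent environmental effect is estimable),
purebred sires need a minimum number of usable daughters, and crossbred sires
need a minimum number of records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PUREBRED = "purebred"
CROSSBRED = "crossbred"

#: canonical phenotype-file columns
PHENO_COLUMNS = [
    "record_id", "population", "hen_id", "cage_id", "sire_id",
    "hatch_week", "laying_date", "line", "tier", "period", "age_weeks", "y",
]

REQUIRED_COLUMNS = ["population", "sire_id", "y"]

#: parent codes interpreted as "unknown"
MISSING_PARENT = {"", "0", "NA", "nan", "None"}


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ParseError(ValueError):
    """A value could not be parsed; carries the offending row index."""


@dataclass(frozen=True)
class PedigreeEntry:
    """One pedigree line: an animal and its (possibly unknown) parents."""

    id: str
    sire_id: str | None = None
    dam_id: str | None = None


@dataclass
class EditReport:
    """Tally of records removed by each edit rule."""

    n_raw: int = 0
    n_kept: int = 0
    n_removed_by_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = sum(self.n_removed_by_rule.values())
        if self.n_raw != self.n_kept + removed:
            raise ValueError(
                f"inconsistent edit report: {self.n_raw} != {self.n_kept} + {removed}"
            )


class PhenotypeTable:
    """Ordered collection of per-egg records with population/cage/hen/sire keys.

    Parameters
    ----------
    data:
        DataFrame with (a subset of) :data:`PHENO_COLUMNS`.  ``population``,
        ``sire_id`` and ``y`` are required; missing optional columns are added
        as all-missing.  Row order is preserved and the index reset.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        df = data.copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column: {col!r}")
        for col in PHENO_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df = df[PHENO_COLUMNS].reset_index(drop=True)
        for col in ("record_id", "population", "hen_id", "cage_id", "sire_id"):
            df[col] = df[col].astype("string")
        y = pd.to_numeric(df["y"], errors="coerce").astype(float)
        bad = np.flatnonzero(~np.isfinite(y.to_numpy()))
        if bad.size:
            raise ParseError(f"non-numeric or non-finite trait value at row {bad[0]}")
        df["y"] = y
        self.data = df
        if validate:
            self.validate()

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def populations(self) -> pd.Series:
        return self.data["population"]

    @property
    def is_purebred(self) -> np.ndarray:
        return (self.data["population"] == PUREBRED).to_numpy()

    @property
    def is_crossbred(self) -> np.ndarray:
        return (self.data["population"] == CROSSBRED).to_numpy()

    def subset(self, mask: np.ndarray) -> "PhenotypeTable":
        """Row subset preserving order; index reset (row i <-> e_i, h_i)."""
        return PhenotypeTable(self.data.loc[np.asarray(mask)], validate=False)

    def validate(self) -> None:
        """Check population tags and per-population key invariants."""
        df = self.data
        pops = set(df["population"].dropna().unique())
        unknown = pops - {PUREBRED, CROSSBRED}
        if unknown:
            raise SchemaError(f"unknown population labels: {sorted(unknown)}")
        pb = df["population"] == PUREBRED
        cb = df["population"] == CROSSBRED
        if (pb & df["hen_id"].isna()).any():
            i = int(np.flatnonzero((pb & df["hen_id"].isna()).to_numpy())[0])
            raise SchemaError(f"purebred record without hen_id at row {i}")
        if (cb & df["cage_id"].isna()).any():
            i = int(np.flatnonzero((cb & df["cage_id"].isna()).to_numpy())[0])
            raise SchemaError(f"crossbred record without cage_id at row {i}")
        if (cb & df["hen_id"].notna()).any():
            warnings.warn(
                "crossbred records carry hen_id; hen identity is ignored for "
                "crossbreds (eggs are attributable only to cage and sire)",
                stacklevel=2,
            )
        if df["sire_id"].isna().any():
            i = int(np.flatnonzero(df["sire_id"].isna().to_numpy())[0])
            raise SchemaError(f"record without sire_id at row {i}")

    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)


def _normalize_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in MISSING_PARENT else s


def load_pedigree(path: str | Path, sep: str | None = None) -> list[PedigreeEntry]:
    """Read a pedigree file with columns (id, sire, dam)."""
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for name in ("id", "sire", "dam"):
        if name not in cols:
            raise SchemaError(f"pedigree file lacks column {name!r}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            PedigreeEntry(
                id=str(row[cols["id"]]).strip(),
                sire_id=_normalize_parent(row[cols["sire"]]),
                dam_id=_normalize_parent(row[cols["dam"]]),
            )
        )
    return entries


def load_dataset(
    pheno_path: str | Path,
    ped_path: str | Path,
    schema: dict[str, str] | None = None,
    sep: str | None = None,
) -> tuple[PhenotypeTable, list[PedigreeEntry]]:
    """Load a phenotype CSV and a pedigree CSV.

    ``schema`` optionally maps canonical column names to the file's column
    names, e.g. ``{"y": "shell_color"}``.  Delimiter is sniffed (comma or tab)
    unless given.
    """
    df = pd.read_csv(pheno_path, sep=sep, engine="python")
    if schema:
        rename = {v: k for k, v in schema.items()}
        missing = [v for v in schema.values() if v not in df.columns]
        if missing:
            raise SchemaError(f"missing required column: {missing[0]!r}")
        df = df.rename(columns=rename)
    table = PhenotypeTable(df)
    pedigree = load_pedigree(ped_path, sep=sep)
    return table, pedigree


def apply_edit_rules(
    table: PhenotypeTable,
    min_records_per_hen: int = 5,
    min_daughters_per_sire_p: int = 40,
    min_records_per_sire_c: int = 40,
) -> tuple[PhenotypeTable, EditReport]:
    """Apply the data-edit rules and report per-rule removal counts.

    Order is fixed: the purebred hen rule runs first, then the purebred sire
    rule on the hen-filtered data (daughter counts are usable daughters), then
    the crossbred sire rule.  The operation is idempotent.
    """
    df = table.data
    n_raw = len(df)
    removed: dict[str, int] = {}

    pb = df["population"] == PUREBRED
    cb = df["population"] == CROSSBRED

    # rule 1: purebred hens with too few records
    counts = df.loc[pb].groupby("hen_id").size()
    bad_hens = set(counts[counts < min_records_per_hen].index)
    drop1 = pb & df["hen_id"].isin(bad_hens)
    removed["min_records_per_hen"] = int(drop1.sum())

    # rule 2: purebred sires with too few remaining daughters
    kept_pb = df.loc[pb & ~drop1]
    daughters = kept_pb.groupby("sire_id")["hen_id"].nunique()
    bad_sires_p = set(daughters[daughters < min_daughters_per_sire_p].index)
    drop2 = pb & ~drop1 & df["sire_id"].isin(bad_sires_p)
    removed["min_daughters_per_sire_p"] = int(drop2.sum())

    # rule 3: crossbred sires with too few records
    counts_c = df.loc[cb].groupby("sire_id").size()
    bad_sires_c = set(counts_c[counts_c < min_records_per_sire_c].index)
    drop3 = cb & df["sire_id"].isin(bad_sires_c)
    removed["min_records_per_sire_c"] = int(drop3.sum())

    keep = ~(drop1 | drop2 | drop3)
    if not keep.any():
        raise ValueError("all records filtered by edit rules")
    out = table.subset(keep.to_numpy())
    report = EditReport(n_raw=n_raw, n_kept=len(out), n_removed_by_rule=removed)
    return out, report
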