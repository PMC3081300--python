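"""Domain tables, validation and I/O for composite biodiversity index input data.

The engine consumes four long-format (tidy) tables:

``records``
    One row per elicited observation of an indicator in a major ecosystem,
    spatial unit and year: the observed mean together with its lower (25%)
    and upper (75%) quartiles, a data-source tag (monitoring / model /
    expert judgment) and the variable kind (continuous or discrete count).
    An optional ``duplication_group`` marks rows that share one elicited
    value copied across several localities.
``references``
    The reference state per (indicator, ecosystem, unit): the indicator's
    expected value in an ecologically sustainable system, the operational
    definition used to set it, and the scaling model chosen by the expert.
``meta``
    Indicator metadata, one row per (indicator, ecosystem) membership:
    the membership fraction (how strongly the indicator represents that
    ecosystem; fractions sum to one over ecosystems), the trophic /
    functional group, and the extra-representative flag.
``units``
    Spatial units, one row per (unit, ecosystem): total unit area and the
    ecosystem's area within the unit (km²).

Sparsity is first-class: a cell (indicator, ecosystem, unit, year) with no
record is treated as *absent* (documentation flag δ = 0) and contributes
nothing — neither value nor weight — to any index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: cell identity on the four index axes: (indicator, ecosystem, unit, year)
CellKey = tuple[str, str, str, int]

SOURCES = ("monitoring", "model", "expert")
VARIABLE_KINDS = ("continuous", "discrete")
SCALING_MODELS = ("optimal", "minimal", "maximal")
REFERENCE_DEFINITIONS = (
    "carrying_capacity",
    "max_sustainable",
    "past_knowledge",
    "precautionary",
    "pristine",
    "best_index",
    "traditional",
)

RECORD_COLUMNS = [
    "indicator_id", "ecosystem_id", "unit_id", "date",
    "mean_value", "q25", "q75", "source", "variable_kind", "duplication_group",
]
REFERENCE_COLUMNS = [
    "indicator_id", "ecosystem_id", "unit_id",
    "ref_value", "definition_tag", "scaling_model",
]
META_COLUMNS = [
    "indicator_id", "ecosystem_id", "membership", "group_id", "extra_representative",
]
UNIT_COLUMNS = ["unit_id", "total_area", "ecosystem_id", "ecosystem_area"]


class DatasetError(ValueError):
    """Raised when input tables violate the schema or an invariant."""


@dataclass(frozen=True)
class Dataset:
    """A validated bundle of the four input tables.

    Construct through :func:`load_dataset`, :func:`read_csv_dir` or
    :func:`read_json`, which validate invariants and referential integrity.
    """

    records: pd.DataFrame
    references: pd.DataFrame
    meta: pd.DataFrame
    units: pd.DataFrame
    dates: tuple[int, ...] = ()

    # -- convenience views -------------------------------------------------

    @property
    def indicator_ids(self) -> list[str]:
        return sorted(self.meta["indicator_id"].unique())

    @property
    def ecosystem_ids(self) -> list[str]:
        return sorted(self.units["ecosystem_id"].unique())

    @property
    def unit_ids(self) -> list[str]:
        return sorted(self.units["unit_id"].unique())

    def record_keys(self) -> list[CellKey]:
        """Keys of documented cells, in sorted order."""
        return sorted(
            (r.indicator_id, r.ecosystem_id, r.unit_id, int(r.date))
            for r in self.records.itertuples()
        )

    def duplication_groups(self) -> dict[CellKey, str]:
        """Map documented cell -> duplication group id (only cells in a group)."""
        out: dict[CellKey, str] = {}
        for r in self.records.itertuples():
            g = r.duplication_group
            if isinstance(g, str) and g:
                out[(r.indicator_id, r.ecosystem_id, r.unit_id, int(r.date))] = g
        return out

    def reference_for(self, indicator_id: str, ecosystem_id: str, unit_id: str) -> pd.Series:
        ref = self.references
        m = (
            (ref["indicator_id"] == indicator_id)
            & (ref["ecosystem_id"] == ecosystem_id)
            & (ref["unit_id"] == unit_id)
        )
        sub = ref[m]
        if len(sub) == 0:
            raise DatasetError(
                f"no reference state for (indicator={indicator_id}, "
                f"ecosystem={ecosystem_id}, unit={unit_id})"
            )
        return sub.iloc[0]

    def with_records(self, records: pd.DataFrame) -> "Dataset":
        """Return a copy with a replaced record table (re-validated)."""
        return load_dataset(records, self.references, self.meta, self.units,
                            dates=self.dates or None)


# ---------------------------------------------------------------------------
# validation


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatasetError(f"{name} table is missing columns {missing}")
    return df.loc[:, list(cols)].copy()


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    rec = _require_columns(records, RECORD_COLUMNS, "records")
    rec["date"] = rec["date"].astype(int)
    for col in ("mean_value", "q25", "q75"):
        rec[col] = rec[col].astype(float)
        if not np.isfinite(rec[col]).all():
            raise DatasetError(f"non-finite {col} in records")
        bad = rec[rec[col] < 0]
        if len(bad):
            r = bad.iloc[0]
            raise DatasetError(
                f"negative {col}={r[col]} for (indicator={r.indicator_id}, "
                f"ecosystem={r.ecosystem_id}, unit={r.unit_id}, date={r.date})"
            )
    bad = rec[rec["q25"] > rec["q75"]]
    if len(bad):
        r = bad.iloc[0]
        raise DatasetError(
            f"q25={r.q25} > q75={r.q75} for (indicator={r.indicator_id}, "
            f"ecosystem={r.ecosystem_id}, unit={r.unit_id}, date={r.date})"
        )
    bad = rec[~rec["source"].isin(SOURCES)]
    if len(bad):
        raise DatasetError(f"unknown source tag {bad.iloc[0]['source']!r}")
    bad = rec[~rec["variable_kind"].isin(VARIABLE_KINDS)]
    if len(bad):
        raise DatasetError(f"unknown variable_kind {bad.iloc[0]['variable_kind']!r}")
    dup = rec.duplicated(["indicator_id", "ecosystem_id", "unit_id", "date"])
    if dup.any():
        r = rec[dup].iloc[0]
        raise DatasetError(
            f"duplicate record for (indicator={r.indicator_id}, "
            f"ecosystem={r.ecosystem_id}, unit={r.unit_id}, date={r.date})"
        )
    # normalise missing duplication_group to None
    rec["duplication_group"] = [
        g if isinstance(g, str) and g else None for g in rec["duplication_group"]
    ]
    # rows in one duplication group are one elicitation: identical values
    grouped = rec[rec["duplication_group"].notna()]
    for g, sub in grouped.groupby("duplication_group"):
        for col in ("mean_value", "q25", "q75"):
            if sub[col].nunique() > 1:
                raise DatasetError(
                    f"duplication_group {g!r} has differing {col} values; "
                    "duplicated rows must share one elicited value"
                )
    return rec


def _validate_references(references: pd.DataFrame) -> pd.DataFrame:
    ref = _require_columns(references, REFERENCE_COLUMNS, "references")
    ref["ref_value"] = ref["ref_value"].astype(float)
    bad = ref[~(ref["ref_value"] > 0)]
    if len(bad):
        r = bad.iloc[0]
        raise DatasetError(
            f"reference value must be > 0, got {r.ref_value} for "
            f"(indicator={r.indicator_id}, ecosystem={r.ecosystem_id}, unit={r.unit_id})"
        )
    bad = ref[~ref["scaling_model"].isin(SCALING_MODELS)]
    if len(bad):
        raise DatasetError(f"unknown scaling_model {bad.iloc[0]['scaling_model']!r}")
    bad = ref[~ref["definition_tag"].isin(REFERENCE_DEFINITIONS)]
    if len(bad):
        raise DatasetError(f"unknown definition_tag {bad.iloc[0]['definition_tag']!r}")
    if ref.duplicated(["indicator_id", "ecosystem_id", "unit_id"]).any():
        raise DatasetError("duplicate reference row for one (indicator, ecosystem, unit)")
    return ref


def _validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    met = _require_columns(meta, META_COLUMNS, "meta")
    met["membership"] = met["membership"].astype(float)
    met["extra_representative"] = met["extra_representative"].astype(bool)
    if ((met["membership"] < 0) | (met["membership"] > 1)).any():
        raise DatasetError("membership fractions must lie in [0, 1]")
    if (met["group_id"].astype(str).str.len() == 0).any():
        raise DatasetError("group_id must be non-empty")
    sums = met.groupby("indicator_id")["membership"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-9]
    if len(bad):
        raise DatasetError(
            f"membership fractions of indicator {bad.index[0]!r} sum to "
            f"{bad.iloc[0]}, expected 1"
        )
    if met.duplicated(["indicator_id", "ecosystem_id"]).any():
        raise DatasetError("duplicate meta row for one (indicator, ecosystem)")
    return met


def _validate_units(units: pd.DataFrame) -> pd.DataFrame:
    un = _require_columns(units, UNIT_COLUMNS, "units")
    un["total_area"] = un["total_area"].astype(float)
    un["ecosystem_area"] = un["ecosystem_area"].astype(float)
    if not (un["total_area"] > 0).all():
        raise DatasetError("total_area must be > 0")
    if (un["ecosystem_area"] < 0).any():
        raise DatasetError("ecosystem_area must be >= 0")
    bad = un[un["ecosystem_area"] > un["total_area"] * (1 + 1e-12)]
    if len(bad):
        r = bad.iloc[0]
        raise DatasetError(
            f"ecosystem_area {r.ecosystem_area} exceeds total_area {r.total_area} "
            f"for unit {r.unit_id}"
        )
    if un.groupby("unit_id")["total_area"].nunique().gt(1).any():
        raise DatasetError("inconsistent total_area across rows of one unit")
    if un.duplicated(["unit_id", "ecosystem_id"]).any():
        raise DatasetError("duplicate units row for one (unit, ecosystem)")
    return un


def load_dataset(
    records: pd.DataFrame,
    references: pd.DataFrame,
    meta: pd.DataFrame,
    units: pd.DataFrame,
    dates: Iterable[int] | None = None,
) -> Dataset:
    """Validate the four tables and assemble a :class:`Dataset`.

    Checks every per-table invariant plus cross-table referential integrity:
    every documented record must have a reference state and indicator
    metadata for its ecosystem, and must point at a known spatial unit.

    ``dates`` optionally declares the full set of assessment years (the δ
    lattice); by default the years observed in ``records`` are used.
    """
    rec = _validate_records(records)
    ref = _validate_references(references)
    met = _validate_meta(meta)
    un = _validate_units(units)

    known_units = set(un["unit_id"])
    ref_keys = set(zip(ref["indicator_id"], ref["ecosystem_id"], ref["unit_id"]))
    meta_keys = set(zip(met["indicator_id"], met["ecosystem_id"]))
    for r in rec.itertuples():
        if r.unit_id not in known_units:
            raise DatasetError(f"record references unknown unit {r.unit_id!r}")
        if (r.indicator_id, r.ecosystem_id) not in meta_keys:
            raise DatasetError(
                f"no indicator metadata for (indicator={r.indicator_id}, "
                f"ecosystem={r.ecosystem_id})"
            )
        if (r.indicator_id, r.ecosystem_id, r.unit_id) not in ref_keys:
            raise DatasetError(
                f"no reference state for documented cell (indicator={r.indicator_id}, "
                f"ecosystem={r.ecosystem_id}, unit={r.unit_id}, date={r.date})"
            )

    if dates is None:
        date_tuple = tuple(sorted(rec["date"].unique().tolist()))
    else:
        date_tuple = tuple(sorted(int(d) for d in dates))
        undeclared = set(rec["date"]) - set(date_tuple)
        if undeclared:
            raise DatasetError(f"records carry undeclared dates {sorted(undeclared)}")

    return Dataset(
        records=rec.reset_index(drop=True),
        references=ref.reset_index(drop=True),
        meta=met.reset_index(drop=True),
        units=un.reset_index(drop=True),
        dates=date_tuple,
    )


# ---------------------------------------------------------------------------
# documentation flags (δ)


def documentation_flags(dataset: Dataset) -> pd.DataFrame:
    """The δ table over the full (indicator, ecosystem, unit, date) lattice.

    δ = 1 exactly where an observation record exists, 0 elsewhere; absence
    means "nothing reported", and such cells carry zero weight downstream.
    The lattice spans every (indicator, ecosystem) membership pair crossed
    with every spatial unit and every declared date.
    """
    pairs = dataset.meta[["indicator_id", "ecosystem_id"]].drop_duplicates()
    units = sorted(dataset.units["unit_id"].unique())
    dates = list(dataset.dates)
    rows = pairs.merge(pd.DataFrame({"unit_id": units}), how="cross")
    rows = rows.merge(pd.DataFrame({"date": dates}), how="cross")
    documented = set(dataset.record_keys())
    rows["delta"] = [
        1 if (r.indicator_id, r.ecosystem_id, r.unit_id, int(r.date)) in documented else 0
        for r in rows.itertuples()
    ]
    return rows.reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O: CSV directory and single-JSON dialects

_TABLE_FILES = {
    "records": "records.csv",
    "references": "references.csv",
    "meta": "meta.csv",
    "units": "units.csv",
}


def read_csv_dir(directory: str | Path, dates: Iterable[int] | None = None) -> Dataset:
    """Load a dataset from a directory of four CSV files.

    Expects ``records.csv``, ``references.csv``, ``meta.csv``, ``units.csv``
    (UTF-8, comma separator, ``.`` decimal, header row).
    """
    directory = Path(directory)
    frames = {}
    for name, fname in _TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            raise DatasetError(f"missing input file {path}")
        frames[name] = pd.read_csv(path)
    if "duplication_group" in frames["records"]:
        frames["records"]["duplication_group"] = frames["records"][
            "duplication_group"
        ].where(frames["records"]["duplication_group"].notna(), None)
    return load_dataset(
        frames["records"], frames["references"], frames["meta"], frames["units"],
        dates=dates,
    )


def write_csv_dir(dataset: Dataset, directory: str | Path) -> None:
    """Write the four tables as CSV files into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, fname in _TABLE_FILES.items():
        getattr(dataset, name).to_csv(directory / fname, index=False)


def read_json(path: str | Path, dates: Iterable[int] | None = None) -> Dataset:
    """Load a dataset from a single JSON document with four arrays."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    frames = {}
    for name in _TABLE_FILES:
        if name not in doc:
            raise DatasetError(f"JSON document missing array {name!r}")
        frames[name] = pd.DataFrame(doc[name])
        if name == "records" and "duplication_group" not in frames[name]:
            frames[name]["duplication_group"] = None
    return load_dataset(
        frames["records"], frames["references"], frames["meta"], frames["units"],
        dates=dates or doc.get("dates"),
    )


def _native(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return value


def write_json(dataset: Dataset, path: str | Path) -> None:
    """Write the dataset as a single JSON document (floats kept exact)."""
    doc = {
        name: [
            {k: _native(v) for k, v in row.items()}
            for row in getattr(dataset, name).to_dict(orient="records")
        ]
        for name in _TABLE_FILES
    }
    doc["dates"] = list(dataset.dates)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
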