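"""Domain types, CSV ingestion/validation and JSON result serialization.

The central container is :class:`SpecimenTable`: one row per fossil or extant
specimen, with group labels (temporal sample for fossils, lake x ecotype for
extant fish), stratigraphic age, the armour scores used by the association
tests, and the 16 morphological traits.  Trait metadata (count vs continuous,
whether a trait is size-corrected against standard length) lives in
:class:`TraitRegistry`.

Missing values are encoded as empty fields or ``"NA"`` on disk and as NaN in
memory; ``"NA"`` is written.  All numeric columns are float64 so that
missingness is uniform; count traits are validated to hold integral values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitSpec",
    "TraitRegistry",
    "SpecimenRecord",
    "SpecimenTable",
    "META_COLUMNS",
    "default_registry",
    "read_specimen_table",
    "write_results",
    "read_results",
    "to_jsonable",
]

#: Metadata columns preceding the trait columns in the CSV dialect.
META_COLUMNS = (
    "specimen_id",
    "dataset",
    "group",
    "sample_order",
    "age_years",
    "pelvic_score",
    "dorsal_spine_count",
)

TraitKind = Literal["count", "continuous"]


@dataclass(frozen=True)
class TraitSpec:
    """Metadata for one measured trait.

    ``size_correct`` marks continuous lengths that receive the allometric
    correction against standard length; the size covariate itself
    (``is_size_covariate``) is analyzed raw.
    """

    code: str
    kind: TraitKind
    size_correct: bool
    label: str
    is_size_covariate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("count", "continuous"):
            raise ValueError(f"unknown trait kind {self.kind!r} for {self.code!r}")
        if self.size_correct and self.kind != "continuous":
            raise ValueError(f"count trait {self.code!r} cannot be size-corrected")
        if self.size_correct and self.is_size_covariate:
            raise ValueError("the size covariate is never size-corrected")


@dataclass(frozen=True)
class TraitRegistry:
    """Ordered collection of :class:`TraitSpec` with a unique size covariate."""

    entries: tuple[TraitSpec, ...]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("trait codes must be unique")
        n_size = sum(e.is_size_covariate for e in self.entries)
        if n_size != 1:
            raise ValueError("exactly one trait must be the size covariate")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries)

    @property
    def size_covariate(self) -> str:
        return next(e.code for e in self.entries if e.is_size_covariate)

    @property
    def size_corrected_codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries if e.size_correct)

    @property
    def count_codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries if e.kind == "count")

    @property
    def continuous_codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries if e.kind == "continuous")

    def spec(self, code: str) -> TraitSpec:
        for e in self.entries:
            if e.code == code:
                return e
        raise KeyError(f"unknown trait code {code!r}")


def default_registry() -> TraitRegistry:
    """The 16-trait registry of the fossil series-K analysis.

    Anatomical labels are best-effort readings of the trait codes (the
    published code-to-anatomy mapping is in supplementary material not
    bundled here).
    """
    sc = [
        ("lps.sc", "pelvic spine length (size-corrected, mm)"),
        ("tpg.sc", "pelvic girdle length (size-corrected, mm)"),
        ("ds1.sc", "first dorsal spine length (size-corrected, mm)"),
        ("ds2.sc", "second dorsal spine length (size-corrected, mm)"),
        ("ds3.sc", "third dorsal spine length (size-corrected, mm)"),
        ("lpt.sc", "third-spine pterygiophore length (size-corrected, mm)"),
        ("ect.sc", "ectocoracoid length (size-corrected, mm)"),
        ("pmx.sc", "premaxilla ascending branch length (size-corrected, mm)"),
        ("cle.sc", "cleithrum length (size-corrected, mm)"),
    ]
    counts = [
        ("mds", "dorsal spine number"),
        ("mcv", "caudal vertebra number"),
        ("mpt", "pre-third-spine pterygiophore number"),
        ("maf", "anal fin ray number"),
        ("mdf", "dorsal fin ray number"),
        ("mav", "abdominal vertebra number"),
    ]
    entries = [TraitSpec(c, "continuous", True, lab) for c, lab in sc]
    entries += [TraitSpec(c, "count", False, lab) for c, lab in counts]
    entries.append(
        TraitSpec("stl", "continuous", False, "standard length (mm)", is_size_covariate=True)
    )
    return TraitRegistry(tuple(entries))


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen, view onto a :class:`SpecimenTable` row."""

    specimen_id: str
    dataset: Literal["fossil", "extant"]
    group: str
    sample_order: int | None
    age_years: float | None
    traits: dict[str, float]  # NaN encodes missing
    pelvic_score: float  # NaN encodes missing
    dorsal_spine_count: float  # NaN encodes missing


def _is_missing(v: Any) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass
class SpecimenTable:
    """Specimen-level trait table plus its trait registry.

    ``data`` holds one row per specimen with the :data:`META_COLUMNS` followed
    by one column per registry trait (float64, NaN = missing).  Construction
    validates the container invariants; statistical preconditions (e.g. at
    least two values per group) are enforced by the operations that need them.
    """

    data: pd.DataFrame
    registry: TraitRegistry
    provenance: str = ""
    #: raw measured lengths must be non-negative; size-corrected tables are
    #: residual-recentred and may hold negative values, so correction turns
    #: this check off
    validate_positive: bool = True

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        missing_cols = [c for c in META_COLUMNS if c not in df.columns]
        missing_cols += [c for c in self.registry.codes if c not in df.columns]
        if missing_cols:
            raise ValueError(f"missing required columns: {missing_cols}")

        ids = df["specimen_id"].astype(str)
        if ids.isna().any() or (ids == "").any():
            raise ValueError("specimen_id must be non-empty")
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate specimen_id: {dup!r}")

        bad_ds = set(df["dataset"].dropna().unique()) - {"fossil", "extant"}
        if bad_ds:
            raise ValueError(f"dataset must be 'fossil' or 'extant', got {sorted(bad_ds)}")

        for code in self.registry.codes:
            col = pd.to_numeric(df[code], errors="coerce")
            if col.isna().sum() > df[code].isna().sum():
                raise ValueError(f"non-numeric value in trait column {code!r}")
            df[code] = col.astype(float)
            vals = col.dropna()
            spec = self.registry.spec(code)
            if spec.kind == "count":
                if not np.allclose(vals, np.round(vals), atol=1e-9):
                    raise ValueError(f"count trait non-integer: {code}")
                if (vals < 0).any():
                    raise ValueError(f"negative count in trait {code}")
            else:
                if self.validate_positive and (vals < 0).any():
                    raise ValueError(f"negative length in trait {code}")

        for col in ("sample_order", "age_years", "pelvic_score", "dorsal_spine_count"):
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)

        ps = df["pelvic_score"].dropna()
        if ((ps < 0) | (ps > 3)).any():
            raise ValueError("pelvic_score out of admissible range [0, 3]")
        dsc = df["dorsal_spine_count"].dropna()
        if (~np.isclose(dsc, np.round(dsc))).any() or ((dsc < 0) | (dsc > 3)).any():
            raise ValueError("dorsal_spine_count out of admissible range {0, 1, 2, 3}")

        ages = df["age_years"].dropna()
        if (ages < 0).any():
            raise ValueError("age_years must be non-negative")

        # within a fossil series, age must increase strictly with sample order
        fossil = df[df["dataset"] == "fossil"]
        ordered = fossil.dropna(subset=["sample_order", "age_years"])
        if not ordered.empty:
            per_group = ordered.groupby("group")[["sample_order", "age_years"]].agg(["min", "max"])
            for col in ("sample_order", "age_years"):
                if not np.allclose(per_group[col]["min"], per_group[col]["max"]):
                    raise ValueError(f"{col} not constant within a fossil sample")
            seq = (
                ordered.groupby("group")[["sample_order", "age_years"]]
                .first()
                .sort_values("sample_order")
            )
            if not np.all(np.diff(seq["age_years"].to_numpy()) > 0):
                raise ValueError("age_years must strictly increase with sample_order")

    # -- accessors -----------------------------------------------------------

    @property
    def n_specimens(self) -> int:
        return len(self.data)

    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.data["group"]))

    def ordered_fossil_groups(self) -> list[str]:
        """Fossil sample labels sorted by sample_order."""
        fossil = self.data[self.data["dataset"] == "fossil"]
        seq = fossil.groupby("group")["sample_order"].first().sort_values()
        return list(seq.index)

    def group_age(self, group: str) -> float:
        sub = self.data[self.data["group"] == group]
        if sub.empty:
            raise KeyError(f"unknown group {group!r}")
        return float(sub["age_years"].iloc[0])

    def values(self, code: str, group: str | None = None, dropna: bool = True) -> np.ndarray:
        """Trait values, optionally restricted to one group."""
        if code not in self.data.columns:
            raise KeyError(f"unknown trait code {code!r}")
        sub = self.data if group is None else self.data[self.data["group"] == group]
        if group is not None and sub.empty:
            raise KeyError(f"unknown group {group!r}")
        v = sub[code].to_numpy(dtype=float)
        return v[~np.isnan(v)] if dropna else v

    @property
    def records(self) -> list[SpecimenRecord]:
        out = []
        for _, row in self.data.iterrows():
            so = row["sample_order"]
            age = row["age_years"]
            out.append(
                SpecimenRecord(
                    specimen_id=str(row["specimen_id"]),
                    dataset=row["dataset"],
                    group=str(row["group"]),
                    sample_order=None if _is_missing(so) else int(so),
                    age_years=None if _is_missing(age) else float(age),
                    traits={c: float(row[c]) for c in self.registry.codes},
                    pelvic_score=float(row["pelvic_score"]),
                    dorsal_spine_count=float(row["dorsal_spine_count"]),
                )
            )
        return out

    def copy(self) -> "SpecimenTable":
        return SpecimenTable(
            self.data.copy(), self.registry, self.provenance, self.validate_positive
        )

    def subset_groups(self, groups: Iterable[str]) -> "SpecimenTable":
        groups = list(groups)
        sub = self.data[self.data["group"].isin(groups)].copy()
        return SpecimenTable(sub, self.registry, self.provenance, self.validate_positive)

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        cols = list(META_COLUMNS) + list(self.registry.codes)
        # shortest round-trip float repr so re-reading is bit-identical
        self.data[cols].to_csv(
            path, index=False, na_rep="NA", float_format=lambda v: repr(float(v))
        )


def read_specimen_table(
    path: str | Path, registry: TraitRegistry, validate_positive: bool = True
) -> SpecimenTable:
    """Read and validate a specimen CSV.

    Missing values may be encoded as empty fields or ``"NA"``.  Rows with
    unparseable trait values raise (they are never silently dropped); input
    row order is preserved.  Pass ``validate_positive=False`` when reading a
    size-corrected table (corrected lengths may be negative).
    """
    df = pd.read_csv(
        path,
        dtype={"specimen_id": str, "dataset": str, "group": str},
        na_values=["NA", ""],
        keep_default_na=False,
        float_precision="round_trip",
    )
    required = list(META_COLUMNS) + list(registry.codes)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    return SpecimenTable(
        df, registry, provenance=f"read from {path}", validate_positive=validate_positive
    )


# -- JSON result serialization ----------------------------------------------


def to_jsonable(obj: Any) -> Any:
    """Convert results (dataclasses, arrays, NaN) to JSON-serializable form.

    Non-finite floats become ``null``; this convention is symmetric with
    NaN-as-missing in the tables.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return to_jsonable(obj.to_dict(orient="list"))
    return obj


def write_results(results: Any, path: str | Path) -> None:
    """Serialize a result object to JSON (full float precision, NaN -> null)."""
    payload = to_jsonable(results)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_results(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)
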