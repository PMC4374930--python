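"""Data model and CSV I/O for N₂O stable-isotope measurements.

A record holds the bulk nitrogen and oxygen isotope deltas of a single
N₂O measurement (per-mil vs. air-N₂ and VSMOW respectively), optionally
the ¹⁵N isotopomer deltas and their difference (the site preference),
plus the metadata the source filters need: where the sample sits in a
soil profile or water column, how concentrated or supersaturated it was,
and whether it is a direct report of emitted N₂O.

Deltas are carried as per-mil floats throughout; missing optional fields
are ``None``, never 0.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

__all__ = [
    "CATEGORIES",
    "DERIVED_CATEGORIES",
    "D18O_ATM_O2_VS_VSMOW",
    "ISOTOPOMER_TOL",
    "IsotopeRecord",
    "ParseReport",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "convert_d18O_reference",
    "site_preference",
    "bulk_from_isotopomers",
]

#: The eight source/reservoir categories of the global compilation.
CATEGORIES = (
    "Antarctic",
    "freshwater",
    "groundwater",
    "marine",
    "soil",
    "stratosphere",
    "troposphere",
    "urban_wastewater",
)

#: Labels produced by downstream pooling, valid on records but not
#: accepted from input files in strict mode.
DERIVED_CATEGORIES = ("continental",)

#: δ¹⁸O of atmospheric O₂ vs. VSMOW (per mil), the modern consensus
#: value, used to re-reference δ¹⁸O-N₂O reported against atmospheric O₂.
D18O_ATM_O2_VS_VSMOW = 23.88

#: Round-trip tolerance (per mil) for the SP / bulk / isotopomer identity.
ISOTOPOMER_TOL = 0.05

_CANONICAL_COLUMNS = (
    "category",
    "site",
    "reference",
    "d15N_bulk",
    "d18O",
    "d15N_alpha",
    "d15N_beta",
    "site_preference",
    "concentration_ppb",
    "saturation_pct",
    "depth_m",
    "flux",
    "is_emitted",
    "filter_note",
)

_NUMERIC_FIELDS = (
    "d15N_bulk",
    "d18O",
    "d15N_alpha",
    "d15N_beta",
    "site_preference",
    "concentration_ppb",
    "saturation_pct",
    "depth_m",
    "flux",
)

_NONNEGATIVE_FIELDS = ("concentration_ppb", "saturation_pct", "depth_m")


def _norm_header(name: str) -> str:
    """Normalize a column header: lowercase, δ→d, drop non-alphanumerics."""
    name = name.replace("δ", "d").replace("‰", "")
    return re.sub(r"[^a-z0-9]", "", name.lower())


# Header alias table: normalized header -> canonical field name.  The
# canonical spellings themselves always resolve.
COLUMN_ALIASES = {
    "category": "category",
    "site": "site",
    "sitedescription": "site",
    "location": "site",
    "reference": "reference",
    "citation": "reference",
    "ref": "reference",
    "d15n": "d15N_bulk",
    "d15nbulk": "d15N_bulk",
    "d15nn2o": "d15N_bulk",
    "d15nbulkn2o": "d15N_bulk",
    "d18o": "d18O",
    "d18on2o": "d18O",
    "d18ovsmow": "d18O",
    "d18ovssmow": "d18O",
    "d15nalpha": "d15N_alpha",
    "d15na": "d15N_alpha",
    "d15nalphan2o": "d15N_alpha",
    "d15nbeta": "d15N_beta",
    "d15nb": "d15N_beta",
    "d15nbetan2o": "d15N_beta",
    "sp": "site_preference",
    "sitepreference": "site_preference",
    "sitepref": "site_preference",
    "15nsitepreference": "site_preference",
    "concentrationppb": "concentration_ppb",
    "concentration": "concentration_ppb",
    "concppb": "concentration_ppb",
    "n2oppb": "concentration_ppb",
    "saturationpct": "saturation_pct",
    "saturation": "saturation_pct",
    "pctsaturation": "saturation_pct",
    "saturationpercent": "saturation_pct",
    "depthm": "depth_m",
    "depth": "depth_m",
    "flux": "flux",
    "n2oflux": "flux",
    "fluxweight": "flux",
    "isemitted": "is_emitted",
    "emitted": "is_emitted",
    "filternote": "filter_note",
    "filtercriteria": "filter_note",
    "criteria": "filter_note",
}


def _norm_category(label: str) -> str:
    return re.sub(r"[\s_]+", " ", label.strip().lower())


# Lenient-mode remapping of category labels (normalized form -> canonical).
CATEGORY_ALIASES = {
    "ocean": "marine",
    "oceanic": "marine",
    "seawater": "marine",
    "sea": "marine",
    "marine": "marine",
    "soil": "soil",
    "soils": "soil",
    "freshwater": "freshwater",
    "freshwaters": "freshwater",
    "river": "freshwater",
    "rivers": "freshwater",
    "lake": "freshwater",
    "lakes": "freshwater",
    "stream": "freshwater",
    "groundwater": "groundwater",
    "groundwaters": "groundwater",
    "ground water": "groundwater",
    "stratosphere": "stratosphere",
    "stratospheric": "stratosphere",
    "troposphere": "troposphere",
    "tropospheric": "troposphere",
    "antarctic": "Antarctic",
    "urban wastewater": "urban_wastewater",
    "wastewater": "urban_wastewater",
}


@dataclass
class IsotopeRecord:
    """One N₂O isotope measurement with filter metadata.

    All deltas are per mil; ``d15N_bulk`` vs. air-N₂, ``d18O`` vs. VSMOW.
    """

    category: str
    d15N_bulk: Optional[float] = None
    d18O: Optional[float] = None
    d15N_alpha: Optional[float] = None
    d15N_beta: Optional[float] = None
    site_preference: Optional[float] = None
    site: str = ""
    reference: str = ""
    concentration_ppb: Optional[float] = None
    saturation_pct: Optional[float] = None
    depth_m: Optional[float] = None
    flux: Optional[float] = None
    is_emitted: Optional[bool] = None
    filter_note: str = ""

    def validation_errors(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errors: list[str] = []
        if self.category not in CATEGORIES + DERIVED_CATEGORIES:
            errors.append(f"unknown category: {self.category!r}")
        if self.d15N_bulk is None and self.d18O is None:
            errors.append("no isotope delta (d15N_bulk and d18O both absent)")
        for name in _NONNEGATIVE_FIELDS:
            value = getattr(self, name)
            if value is not None and value < 0:
                errors.append(f"negative {name}: {value}")
        if self.d15N_alpha is not None and self.d15N_beta is not None:
            sp = site_preference(self.d15N_alpha, self.d15N_beta)
            bulk = bulk_from_isotopomers(self.d15N_alpha, self.d15N_beta)
            if (
                self.site_preference is not None
                and abs(self.site_preference - sp) > ISOTOPOMER_TOL
            ):
                errors.append(
                    "site_preference inconsistent with isotopomers "
                    f"({self.site_preference} vs {sp:.3f})"
                )
            if self.d15N_bulk is not None and abs(self.d15N_bulk - bulk) > ISOTOPOMER_TOL:
                errors.append(
                    f"d15N_bulk inconsistent with isotopomers ({self.d15N_bulk} vs {bulk:.3f})"
                )
        return errors

    def with_derived_isotopomer_fields(self) -> "IsotopeRecord":
        """Fill SP and bulk δ¹⁵N from α/β isotopomers where absent."""
        if self.d15N_alpha is None or self.d15N_beta is None:
            return self
        updates = {}
        if self.site_preference is None:
            updates["site_preference"] = site_preference(self.d15N_alpha, self.d15N_beta)
        if self.d15N_bulk is None:
            updates["d15N_bulk"] = bulk_from_isotopomers(self.d15N_alpha, self.d15N_beta)
        return replace(self, **updates) if updates else self


@dataclass
class ParseReport:
    """Provenance of a parsed dataset: counts and per-row rejection reasons."""

    path: str = ""
    rows_read: int = 0
    rows_rejected: int = 0
    reasons: list = field(default_factory=list)  # (row_index, reason) pairs

    def to_json(self) -> str:
        return json.dumps(
            {
                "path": self.path,
                "rows_read": self.rows_read,
                "rows_rejected": self.rows_rejected,
                "reasons": [{"row": r, "reason": m} for r, m in self.reasons],
            },
            indent=2,
        )


@dataclass
class Dataset:
    """Ordered collection of :class:`IsotopeRecord` with parse provenance."""

    records: list = field(default_factory=list)
    provenance: Optional[ParseReport] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IsotopeRecord]:
        return iter(self.records)

    def subset(self, category: str) -> "Dataset":
        return Dataset([r for r in self.records if r.category == category])

    def column(self, name: str, category: Optional[str] = None) -> list:
        """Non-missing values of one field, optionally for one category."""
        recs = self.records if category is None else self.subset(category).records
        return [getattr(r, name) for r in recs if getattr(r, name) is not None]

    def to_frame(self) -> pd.DataFrame:
        rows = [{c: getattr(r, c) for c in _CANONICAL_COLUMNS} for r in self.records]
        return pd.DataFrame(rows, columns=list(_CANONICAL_COLUMNS))


def site_preference(alpha: float, beta: float) -> float:
    """Site preference: δ¹⁵Nα − δ¹⁵Nβ (per mil).

    The α position is the central nitrogen of the linear NNO molecule,
    β the terminal one.
    """
    return alpha - beta


def bulk_from_isotopomers(alpha: float, beta: float) -> float:
    """Bulk δ¹⁵N as the mean of the two isotopomer deltas."""
    return (alpha + beta) / 2.0


def convert_d18O_reference(
    value: float, ref_offset: float = D18O_ATM_O2_VS_VSMOW
) -> float:
    """Re-express a δ¹⁸O value in a new reference frame.

    For a value reported vs. atmospheric O₂ and the offset of atmospheric
    O₂ vs. VSMOW, returns the value vs. VSMOW using the exact delta-scale
    shift ``value + offset + value*offset/1000``.

    Parameters
    ----------
    value : per mil, in the old reference frame; must exceed −1000.
    ref_offset : per mil, delta of the old reference vs. the new one.
    """
    if value <= -1000:
        raise ValueError("delta value must exceed -1000 per mil")
    return value + ref_offset + value * ref_offset / 1000.0


def _parse_float(cell: str) -> Optional[float]:
    text = cell.strip()
    if text == "" or text.lower() in ("na", "nan", "none"):
        return None
    value = float(text)  # may raise ValueError
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {text!r}")
    return value


def _parse_bool(cell: str) -> Optional[bool]:
    text = cell.strip().lower()
    if text in ("", "na", "nan", "none"):
        return None
    if text in ("true", "t", "yes", "y", "1", "1.0"):
        return True
    if text in ("false", "f", "no", "n", "0", "0.0"):
        return False
    raise ValueError(f"cannot interpret {cell!r} as a boolean")


def read_dataset(path, mode: str = "strict") -> Dataset:
    """Read an S1-schema CSV of isotope measurements.

    Column headers are resolved through :data:`COLUMN_ALIASES` (case,
    punctuation and the δ glyph are ignored).  Every well-formed row
    becomes an :class:`IsotopeRecord`; malformed rows are rejected with
    a reason recorded in the parse report, never silently dropped.

    Parameters
    ----------
    path : CSV file path (comma-delimited, UTF-8, header row).
    mode : ``"strict"`` rejects unknown category labels; ``"lenient"``
        remaps them through :data:`CATEGORY_ALIASES` first.

    Raises
    ------
    ValueError
        If the header lacks a category column or every delta column.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    colmap: dict[str, str] = {}
    for col in raw.columns:
        canonical = COLUMN_ALIASES.get(_norm_header(col))
        if canonical is not None and canonical not in colmap.values():
            colmap[col] = canonical
    present = set(colmap.values())
    missing = []
    if "category" not in present:
        missing.append("category")
    if not present & {"d15N_bulk", "d18O", "d15N_alpha", "d15N_beta"}:
        missing.append("at least one delta column (d15N_bulk/d18O/d15N_alpha/d15N_beta)")
    if missing:
        raise ValueError(f"missing mandatory columns: {', '.join(missing)}")

    report = ParseReport(path=str(path), rows_read=len(raw))
    records: list[IsotopeRecord] = []
    for idx, row in raw.iterrows():
        values: dict = {}
        row_errors: list[str] = []
        for col, canonical in colmap.items():
            cell = row[col]
            try:
                if canonical in _NUMERIC_FIELDS:
                    values[canonical] = _parse_float(cell)
                elif canonical == "is_emitted":
                    values[canonical] = _parse_bool(cell)
                else:
                    values[canonical] = cell.strip()
            except ValueError:
                row_errors.append(f"malformed value in column {canonical}: {cell!r}")
        if row_errors:
            report.reasons.append((int(idx), "; ".join(row_errors)))
            continue

        label = values.get("category", "")
        if label not in CATEGORIES:
            remapped = CATEGORY_ALIASES.get(_norm_category(label)) if mode == "lenient" else None
            if remapped is None:
                report.reasons.append((int(idx), f"unknown category: {label!r}"))
                continue
            values["category"] = remapped

        record = IsotopeRecord(**values).with_derived_isotopomer_fields()
        errors = record.validation_errors()
        if errors:
            report.reasons.append((int(idx), "; ".join(errors)))
            continue
        records.append(record)

    report.rows_rejected = len(report.reasons)
    return Dataset(records=records, provenance=report)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as a canonical-column CSV (round-trips losslessly)."""
    frame = dataset.to_frame()
    if dataset.records:
        frame["is_emitted"] = [
            "" if r.is_emitted is None else str(r.is_emitted) for r in dataset.records
        ]
    frame.to_csv(path, index=False)
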