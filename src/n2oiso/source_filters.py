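"""Filtering of N₂O source data and flux-weighted averaging.

Low-concentration soil and surface-water measurements are dominated by
mixing with tropospheric N₂O and say little about the source signature.
The filter retains, from the three flux-relevant categories (soil,
freshwater, marine), only measurements that demonstrably carry a source
signal:

(i)   direct reports of emitted N₂O (flux chambers etc.), regardless of
      flux strength — carried as the explicit ``is_emitted`` flag;
(ii)  soil-profile gas with N₂O concentration strictly above 650 ppb v/v
      (≈200 % of ambient);
(iii) dissolved N₂O in freshwater, or in the top 100 m of the ocean,
      strictly above 200 % saturation with respect to the atmosphere.

Records eligible for a criterion but missing the metadata it needs are
excluded and counted under "insufficient metadata" — never retained by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .isotope_data import Dataset, IsotopeRecord

__all__ = [
    "SOIL_CONC_THRESHOLD_PPB",
    "SATURATION_THRESHOLD_PCT",
    "MARINE_MAX_DEPTH_M",
    "SOURCE_CATEGORIES",
    "RetentionReport",
    "filter_source_subset",
    "pool_continental",
    "flux_weighted_average",
]

SOIL_CONC_THRESHOLD_PPB = 650.0
SATURATION_THRESHOLD_PCT = 200.0
MARINE_MAX_DEPTH_M = 100.0

#: Categories eligible for retention; everything else is dropped outright.
SOURCE_CATEGORIES = ("soil", "freshwater", "marine")


@dataclass
class RetentionReport:
    """Per-category kept/total counts plus insufficient-metadata tallies."""

    kept: dict = field(default_factory=dict)
    total: dict = field(default_factory=dict)
    insufficient_metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kept": dict(self.kept),
            "total": dict(self.total),
            "insufficient_metadata": dict(self.insufficient_metadata),
        }


def _retain(record: IsotopeRecord) -> tuple[bool, str]:
    """Decide retention for one record: (keep, reason-if-not-kept)."""
    if record.category not in SOURCE_CATEGORIES:
        return False, "category not eligible"
    if record.is_emitted is True:
        return True, ""
    if record.category == "soil":
        if record.concentration_ppb is None:
            return False, "insufficient metadata"
        if record.concentration_ppb > SOIL_CONC_THRESHOLD_PPB:
            return True, ""
        return False, "below concentration threshold"
    # freshwater / marine: dissolved-gas saturation criterion
    if record.saturation_pct is None:
        return False, "insufficient metadata"
    if record.saturation_pct <= SATURATION_THRESHOLD_PCT:
        return False, "below saturation threshold"
    if record.category == "marine":
        # absent depth is taken as a surface sample
        if record.depth_m is not None and record.depth_m > MARINE_MAX_DEPTH_M:
            return False, "below surface layer"
    return True, ""


def filter_source_subset(dataset: Dataset, with_report: bool = False):
    """Retain only records carrying a genuine source signal.

    Returns the filtered :class:`Dataset`, or ``(dataset, report)`` when
    ``with_report`` is true.  All thresholds are strict inequalities; the
    operation is idempotent.
    """
    report = RetentionReport()
    kept_records = []
    for record in dataset:
        cat = record.category
        report.total[cat] = report.total.get(cat, 0) + 1
        keep, reason = _retain(record)
        if keep:
            kept_records.append(record)
            report.kept[cat] = report.kept.get(cat, 0) + 1
        elif reason == "insufficient metadata":
            report.insufficient_metadata[cat] = report.insufficient_metadata.get(cat, 0) + 1
    filtered = Dataset(records=kept_records)
    if with_report:
        return filtered, report
    return filtered


def pool_continental(dataset: Dataset) -> Dataset:
    """Relabel soil and freshwater records as the pooled continental source.

    The continental source is operationally soil + freshwater; other
    categories pass through unchanged.  Idempotent.
    """
    pooled = [
        replace(r, category="continental") if r.category in ("soil", "freshwater") else r
        for r in dataset
    ]
    return Dataset(records=pooled)


def flux_weighted_average(values, weights) -> float:
    """Flux-weighted mean Σvᵢwᵢ / Σwᵢ.

    Raises
    ------
    ValueError
        On length mismatch, any negative weight, or all-zero weights.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    return float((v * w).sum() / total)
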