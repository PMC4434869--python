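"""The vimentin/keratin EMT index: per-cell ratios, cut-offs, classification.

The EMT (epithelial-to-mesenchymal transition) status of a cell is scored by
the ratio of its background-corrected mean vimentin intensity to mean keratin
intensity (vim/K). Reference cell lines anchor the scale: cells with ratios
up to the maximum observed in an epithelial reference line are "epithelial",
cells inside the range of a mesenchymal reference line are "mesenchymal", and
cells in between are "intermediate". With the reference ranges measured on
MCF-7 and Hs578T cytospins the cut-offs are 0.49 and [5.47, 38.88].

The ratio operation is generic over marker pairs, so vimentin/EpCAM or
fibronectin/keratin indices run through the same code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .records import CellRecord, ConfigError, CtcemtError


class CutoffError(CtcemtError):
    pass


class EMTClass(str, Enum):
    EPITHELIAL = "epithelial"
    INTERMEDIATE = "intermediate"
    MESENCHYMAL = "mesenchymal"

    @property
    def order(self) -> int:
        return ("epithelial", "intermediate", "mesenchymal").index(self.value)


@dataclass(frozen=True)
class EMTCutoffs:
    """Epithelial upper bound and mesenchymal band on the vim/K scale."""

    epithelial_upper: float
    mesenchymal_lower: float
    mesenchymal_upper: float

    def __post_init__(self) -> None:
        if not 0 <= self.epithelial_upper < self.mesenchymal_lower <= self.mesenchymal_upper:
            raise CutoffError(
                "need 0 <= epithelial_upper < mesenchymal_lower <= mesenchymal_upper, "
                f"got {self}"
            )


@dataclass
class RatioRecord:
    """Per-cell marker ratio with its EMT class.

    ``ratio`` is NaN (and ``defined`` False) when the denominator mean
    intensity lies below the floor — such cells are excluded from
    classification and counted in the QC summary. ``above_reference`` flags
    ratios beyond the mesenchymal reference maximum (still classified
    mesenchymal).
    """

    cell_id: str
    sample_id: str
    numerator_marker: str
    denominator_marker: str
    ratio: float
    defined: bool
    emt_class: EMTClass | None = None
    above_reference: bool = False


def compute_ratio(
    record: CellRecord,
    numerator: str = "vimentin",
    denominator: str = "keratin",
    denom_floor: float = 0.0,
) -> RatioRecord:
    """Per-cell marker mean-intensity ratio (CTCF/area units).

    Negative corrected mean intensities are clamped to 0 before division;
    a denominator below ``denom_floor`` makes the ratio undefined.
    """
    for marker in (numerator, denominator):
        if marker not in record.ctcf:
            raise ConfigError(
                f"cell {record.cell_id}: marker {marker!r} not measured "
                f"(has {sorted(record.ctcf)})"
            )
    num = max(record.mean_intensity[numerator], 0.0)
    den = max(record.mean_intensity[denominator], 0.0)
    if den < denom_floor or den == 0.0:
        return RatioRecord(
            record.cell_id, record.sample_id, numerator, denominator,
            float("nan"), defined=False,
        )
    return RatioRecord(
        record.cell_id, record.sample_id, numerator, denominator,
        num / den, defined=True,
    )


def derive_cutoffs(
    epithelial_ref_ratios: list[float] | np.ndarray,
    mesenchymal_ref_ratios: list[float] | np.ndarray,
) -> EMTCutoffs:
    """Cut-offs from reference ratio distributions.

    The epithelial upper bound is the maximum ratio observed in the
    epithelial reference cells; the mesenchymal band is the full range of the
    mesenchymal reference cells. Overlapping references leave the scheme
    undefined and raise.
    """
    epi = np.asarray(epithelial_ref_ratios, dtype=float)
    mes = np.asarray(mesenchymal_ref_ratios, dtype=float)
    if epi.size == 0 or mes.size == 0:
        raise CutoffError("reference ratio lists must be non-empty")
    if epi.max() >= mes.min():
        raise CutoffError(
            f"reference distributions overlap: max epithelial {epi.max()} >= "
            f"min mesenchymal {mes.min()}"
        )
    return EMTCutoffs(float(epi.max()), float(mes.min()), float(mes.max()))


def classify(ratio: float, cutoffs: EMTCutoffs) -> EMTClass:
    """Place one vim/K ratio on the EMT scale.

    The epithelial boundary value itself is epithelial ("up to" includes the
    endpoint); ratios at or above the mesenchymal lower bound are mesenchymal,
    including those beyond the reference maximum.
    """
    if not math.isfinite(ratio) or ratio < 0:
        raise ConfigError(f"ratio must be finite and >= 0, got {ratio}")
    if ratio <= cutoffs.epithelial_upper:
        return EMTClass.EPITHELIAL
    if ratio >= cutoffs.mesenchymal_lower:
        return EMTClass.MESENCHYMAL
    return EMTClass.INTERMEDIATE


def classify_records(
    records: list[RatioRecord], cutoffs: EMTCutoffs
) -> list[RatioRecord]:
    """Classify every defined-ratio record in place (returns the same list)."""
    for rec in records:
        if rec.defined:
            rec.emt_class = classify(rec.ratio, cutoffs)
            rec.above_reference = rec.ratio > cutoffs.mesenchymal_upper
    return records


def summarize_classes(records: list[RatioRecord]) -> pd.DataFrame:
    """Counts and proportions per EMT class, per sample and pooled.

    Proportions are over defined-ratio cells; undefined ratios appear in the
    ``n_undefined`` QC column. Empty input yields an empty table.
    """
    classes = [c.value for c in EMTClass]
    cols = (
        ["n_cells", "n_undefined"]
        + [f"n_{c}" for c in classes]
        + [f"prop_{c}" for c in classes]
    )
    if not records:
        return pd.DataFrame(columns=cols)
    if any(r.defined and r.emt_class is None for r in records):
        raise ConfigError("records must be classified before summarizing")
    rows = {}
    samples = sorted({r.sample_id for r in records})
    for key, subset in [("pooled", records)] + [
        (s, [r for r in records if r.sample_id == s]) for s in samples
    ]:
        defined = [r for r in subset if r.defined]
        counts = {
            c: sum(1 for r in defined if r.emt_class.value == c) for c in classes
        }
        n_def = len(defined)
        row = {
            "n_cells": len(subset),
            "n_undefined": len(subset) - n_def,
        }
        row.update({f"n_{c}": counts[c] for c in classes})
        row.update(
            {f"prop_{c}": (counts[c] / n_def if n_def else 0.0) for c in classes}
        )
        rows[key] = row
    return pd.DataFrame.from_dict(rows, orient="index")[cols]


def default_denom_floor(epithelial_ref_records: list[CellRecord]) -> float:
    """Denominator floor: 1% of the epithelial reference median keratin mean intensity."""
    med = float(
        np.median([r.mean_intensity["keratin"] for r in epithelial_ref_records])
    )
    return 0.01 * med
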