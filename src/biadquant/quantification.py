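"""Ratiometric BiAD quantification.

The relative BiAD signal of a spot is the background-subtracted BiAD-channel
(IFP2.0) mean intensity divided by the background-subtracted marker-channel
(YPet) mean intensity of the same ROI; the per-cell value is the arithmetic
mean over that cell's spots.  Because the marker amplitude scales with the
local sgRNA-repeat copy number while the BiAD amplitude scales with both copy
number and modification occupancy, the ratio cancels copy number and reports
modification occupancy times detector efficiency.

Negative corrected BiAD values (spot dimmer than the nuclear BiAD background)
are preserved, not clamped: clamping would bias the binding-deficient-mutant
null upward and invalidate the WT-vs-mutant contrast.

Two further normalisations mirror the published analyses: per-spot division
by the within-cell mean over active-X (Xa) spots for allelic enrichment, and
per-cell division by the mean of a control-detector condition within each
treatment arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ExclusionError
from .io import CellImage, ChannelRole
from .segmentation import NucleusRegion, SpotRegion

__all__ = [
    "ALLELE_XI",
    "ALLELE_XA",
    "ALLELE_UNLABELED",
    "SpotQuant",
    "CellQuant",
    "ExperimentTable",
    "background_subtract",
    "spot_relative_biad",
    "cell_mean_biad",
    "classify_alleles",
    "normalize_to_xa",
    "normalize_to_control",
    "spot_qc_summary",
]

ALLELE_XI = "Xi"
ALLELE_XA = "Xa"
ALLELE_UNLABELED = "unlabeled"

#: default guard on the ratio denominator, as a fraction of the marker dynamic range
EPS_FRACTION = 1e-6


@dataclass
class SpotQuant:
    """Quantified spot: background-subtracted intensities and the BiAD/marker ratio."""

    spot_id: int
    corrected_marker: float
    corrected_biad: float
    relative_biad: float
    area: int
    allele: str = ALLELE_UNLABELED
    valid: bool = True
    xa_normalized: float | None = None


@dataclass
class CellQuant:
    """Per-cell aggregate: mean relative BiAD over spots plus experiment labels."""

    cell_id: str
    condition: str
    mean_relative_biad: float
    spot_count: int
    spots: list[SpotQuant] = field(default_factory=list)
    treatment: str = "none"
    replicate: str = "1"
    control_normalized: float | None = None


def background_subtract(spot_mean: float, nuclear_mean: float) -> float:
    """Subtract the nuclear mean from the spot mean; negatives are preserved."""
    return float(spot_mean) - float(nuclear_mean)


def spot_relative_biad(
    spot: SpotRegion,
    nucleus: NucleusRegion,
    eps: float = 1e-9,
) -> SpotQuant:
    """Compute a spot's relative BiAD signal.

    ``corrected = spot mean - nuclear mean`` per channel, then
    ``relative_biad = corrected_biad / corrected_marker``.  A spot whose
    corrected marker intensity falls below ``eps`` (no real marker enrichment
    over the nuclear background) is marked invalid and excluded from
    aggregation rather than producing an unstable ratio.
    """
    for role in (ChannelRole.MARKER, ChannelRole.BIAD):
        if role not in spot.mean_intensity or role not in nucleus.mean_intensity:
            raise ConfigurationError(f"channel {role} missing from ROI measurements")
    corr_marker = background_subtract(
        spot.mean_intensity[ChannelRole.MARKER], nucleus.mean_intensity[ChannelRole.MARKER]
    )
    corr_biad = background_subtract(
        spot.mean_intensity[ChannelRole.BIAD], nucleus.mean_intensity[ChannelRole.BIAD]
    )
    if corr_marker < eps:
        return SpotQuant(
            spot_id=spot.spot_id,
            corrected_marker=corr_marker,
            corrected_biad=corr_biad,
            relative_biad=math.nan,
            area=spot.area,
            valid=False,
        )
    return SpotQuant(
        spot_id=spot.spot_id,
        corrected_marker=corr_marker,
        corrected_biad=corr_biad,
        relative_biad=corr_biad / corr_marker,
        area=spot.area,
    )


def eps_for_image(image: CellImage) -> float:
    """Denominator guard: 1e-6 of the marker channel's dynamic range."""
    marker = image.marker()
    return EPS_FRACTION * float(marker.max() - marker.min())


def cell_mean_biad(
    spots: list[SpotQuant],
    cell_id: str,
    condition: str,
    treatment: str = "none",
    replicate: str = "1",
) -> CellQuant:
    """Average the relative BiAD signal over a cell's valid spots.

    Negative per-spot ratios participate in the mean.  A cell with zero valid
    spots is excluded with reason ``no_valid_spots``.
    """
    valid = [s for s in spots if s.valid]
    if not valid:
        raise ExclusionError("no_valid_spots", f"cell {cell_id}: no valid spots")
    return CellQuant(
        cell_id=cell_id,
        condition=condition,
        treatment=treatment,
        replicate=replicate,
        mean_relative_biad=float(np.mean([s.relative_biad for s in valid])),
        spot_count=len(valid),
        spots=spots,
    )


def classify_alleles(
    spots: list[SpotRegion],
    stain_mask: np.ndarray,
    overlap_fraction_min: float = 0.5,
) -> list[str]:
    """Label each spot Xi or Xa by overlap with the stain territory mask.

    A spot is Xi when the fraction of its pixels inside the stain mask is at
    least ``overlap_fraction_min`` (inclusive boundary), otherwise Xa.
    """
    stain_mask = np.asarray(stain_mask, dtype=bool)
    labels = []
    for spot in spots:
        overlap = float(np.logical_and(spot.mask, stain_mask).sum()) / float(spot.area)
        labels.append(ALLELE_XI if overlap >= overlap_fraction_min else ALLELE_XA)
    return labels


def normalize_to_xa(cell: CellQuant, eps: float = 1e-9) -> CellQuant:
    """Divide each spot's relative BiAD by the cell's mean over Xa spots.

    After normalisation the Xa spots of the cell average exactly 1.0.  Cells
    without both an Xa and an Xi spot, or with a degenerate Xa mean, are
    excluded from allelic analysis.
    """
    valid = [s for s in cell.spots if s.valid]
    xa = [s for s in valid if s.allele == ALLELE_XA]
    xi = [s for s in valid if s.allele == ALLELE_XI]
    if not xa:
        raise ExclusionError("no_xa_spot", f"cell {cell.cell_id}: no Xa-labeled spot")
    if not xi:
        raise ExclusionError("no_xi_spot", f"cell {cell.cell_id}: no Xi-labeled spot")
    xa_mean = float(np.mean([s.relative_biad for s in xa]))
    if xa_mean <= eps:
        raise ExclusionError(
            "degenerate_xa_mean", f"cell {cell.cell_id}: mean Xa signal {xa_mean} <= eps"
        )
    new_spots = [
        replace(s, xa_normalized=(s.relative_biad / xa_mean if s.valid else None))
        for s in cell.spots
    ]
    return replace(cell, spots=new_spots)


@dataclass
class ExperimentTable:
    """Tidy collection of per-cell quantifications; the unit of statistical analysis."""

    rows: list[CellQuant]

    def __post_init__(self) -> None:
        ids = [r.cell_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate cell_id in experiment table")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def conditions(self) -> list[str]:
        return sorted({r.condition for r in self.rows})

    def values(self, condition: str, column: str = "mean_relative_biad",
               treatment: str | None = None) -> np.ndarray:
        """Per-cell values for one condition (optionally one treatment arm)."""
        out = [
            getattr(r, column)
            for r in self.rows
            if r.condition == condition and (treatment is None or r.treatment == treatment)
        ]
        return np.asarray(out, dtype=float)

    def to_cell_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [r.cell_id for r in self.rows],
                "condition": [r.condition for r in self.rows],
                "treatment": [r.treatment for r in self.rows],
                "replicate": [r.replicate for r in self.rows],
                "mean_relative_biad": [r.mean_relative_biad for r in self.rows],
                "spot_count": [r.spot_count for r in self.rows],
                "control_normalized": [r.control_normalized for r in self.rows],
            }
        )

    def to_spot_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            for s in r.spots:
                recs.append(
                    {
                        "cell_id": r.cell_id,
                        "spot_id": s.spot_id,
                        "condition": r.condition,
                        "treatment": r.treatment,
                        "replicate": r.replicate,
                        "corrected_marker": s.corrected_marker,
                        "corrected_biad": s.corrected_biad,
                        "relative_biad": s.relative_biad,
                        "allele": "" if s.allele == ALLELE_UNLABELED else s.allele,
                        "area": s.area,
                        "valid": s.valid,
                        "xa_normalized": s.xa_normalized,
                    }
                )
        return pd.DataFrame(recs)

    @classmethod
    def from_frames(cls, cells: pd.DataFrame,
                    spots: pd.DataFrame | None = None) -> "ExperimentTable":
        spot_groups: dict[str, list[SpotQuant]] = {}
        if spots is not None and len(spots):
            for _, row in spots.iterrows():
                allele = row.get("allele")
                if allele is None or (isinstance(allele, float) and math.isnan(allele)) \
                        or allele == "":
                    allele = ALLELE_UNLABELED
                xa_norm = row.get("xa_normalized")
                if xa_norm is not None and isinstance(xa_norm, float) and math.isnan(xa_norm):
                    xa_norm = None
                spot_groups.setdefault(str(row["cell_id"]), []).append(
                    SpotQuant(
                        spot_id=int(row["spot_id"]),
                        corrected_marker=float(row["corrected_marker"]),
                        corrected_biad=float(row["corrected_biad"]),
                        relative_biad=float(row["relative_biad"]),
                        area=int(row["area"]),
                        allele=str(allele),
                        valid=bool(row.get("valid", True)),
                        xa_normalized=xa_norm,
                    )
                )
        rows = []
        for _, row in cells.iterrows():
            ctrl = row.get("control_normalized")
            if ctrl is not None and isinstance(ctrl, float) and math.isnan(ctrl):
                ctrl = None
            rows.append(
                CellQuant(
                    cell_id=str(row["cell_id"]),
                    condition=str(row["condition"]),
                    treatment=str(row["treatment"]),
                    replicate=str(row["replicate"]),
                    mean_relative_biad=float(row["mean_relative_biad"]),
                    spot_count=int(row["spot_count"]),
                    spots=spot_groups.get(str(row["cell_id"]), []),
                    control_normalized=ctrl,
                )
            )
        return cls(rows=rows)


def normalize_to_control(
    table: ExperimentTable,
    control_condition: str,
    eps: float = 1e-9,
    min_control_cells: int = 3,
) -> ExperimentTable:
    """Normalise per-cell values to the mean of the control-detector condition,
    separately within each treatment arm.

    After normalisation, control cells average exactly 1.0 in every arm.  An
    arm whose control mean is not above ``eps`` signals a degenerate control
    and normalisation is refused for the whole call.
    """
    arms = sorted({r.treatment for r in table.rows})
    arm_means: dict[str, float] = {}
    for arm in arms:
        ctrl = [
            r.mean_relative_biad
            for r in table.rows
            if r.treatment == arm and r.condition == control_condition
        ]
        if len(ctrl) < min_control_cells:
            raise ConfigurationError(
                f"treatment arm {arm!r} has {len(ctrl)} control "
                f"({control_condition!r}) cells; need >= {min_control_cells}"
            )
        mean = float(np.mean(ctrl))
        if mean <= eps:
            raise ExclusionError(
                "degenerate_control",
                f"arm {arm!r}: control mean {mean} <= eps; normalization refused",
            )
        arm_means[arm] = mean
    rows = [
        replace(r, control_normalized=r.mean_relative_biad / arm_means[r.treatment])
        for r in table.rows
    ]
    return ExperimentTable(rows=rows)


def spot_qc_summary(table: ExperimentTable) -> pd.DataFrame:
    """Per-condition spot-count histogram (0..6) and spot-area summary.

    Reported alongside BiAD results so that detector contrasts can be checked
    against segmentation artifacts (differences in spot area or count would
    confound the ratio comparison).
    """
    recs = []
    for condition in table.conditions:
        cells = [r for r in table.rows if r.condition == condition]
        counts = [r.spot_count for r in cells]
        areas = [s.area for r in cells for s in r.spots if s.valid]
        rec = {
            "condition": condition,
            "n_cells": len(cells),
            "mean_spot_count": float(np.mean(counts)) if counts else 0.0,
            "mean_spot_area": float(np.mean(areas)) if areas else math.nan,
            "median_spot_area": float(np.median(areas)) if areas else math.nan,
        }
        for k in range(0, 7):
            rec[f"count_{k}"] = int(sum(c == k for c in counts))
        recs.append(rec)
    return pd.DataFrame(recs)
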