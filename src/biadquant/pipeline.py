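"""End-to-end orchestration: images (real or simulated) -> experiment table -> statistics.

Every run is driven by a declarative configuration and a sample sheet that
assigns each cell image its condition, treatment arm, replicate and —
optionally — manual per-cell thresholds.  Cells that cannot be quantified are
never silently dropped: the QC report partitions every input cell into
``analyzed`` or ``excluded`` with a machine-readable reason code
(``no_nucleus``, ``no_spots``, ``no_valid_spots``, ...).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import BiadError, ConfigurationError, ExclusionError, SegmentationError
from .io import CellImage, ChannelRole, load_stack, max_intensity_projection
from .quantification import (
    ALLELE_XA,
    ALLELE_XI,
    CellQuant,
    ExperimentTable,
    cell_mean_biad,
    classify_alleles,
    eps_for_image,
    normalize_to_control,
    normalize_to_xa,
    spot_relative_biad,
)
from .segmentation import (
    MAX_SPOTS_DEFAULT,
    MIN_SPOT_AREA_DEFAULT,
    ThresholdPair,
    auto_thresholds,
    detect_spots,
    segment_nucleus,
)
from .simulate import SimulationConfig, SimulatedCell, simulate_experiment
from .stats import GroupComparison, compare_multi_groups, compare_two_groups

logger = logging.getLogger("biadquant")

__all__ = [
    "QuantifyOptions",
    "QCReport",
    "quantify_cell",
    "run_quantify",
    "run_quantify_images",
    "run_compare",
    "run_simulate",
]


class QuantifyOptions(BaseModel):
    """Tunable settings for the quantification pass."""

    max_spots: int = MAX_SPOTS_DEFAULT
    min_spot_area: int = MIN_SPOT_AREA_DEFAULT
    spot_quantile: float = 0.995  # auto spot threshold: within-nucleus marker quantile
    exclude_spot_pixels_from_nuclear_mean: bool = False
    allelic: bool = False  # classify spots Xi/Xa from the stain channel
    stain_overlap_min: float = 0.5


@dataclass
class QCReport:
    """Per-cell quantification outcome; exclusions carry reason codes."""

    records: list[dict] = field(default_factory=list)

    def add(self, cell_id: str, status: str, reason: str = "",
            thresholds: ThresholdPair | None = None) -> None:
        self.records.append(
            {
                "cell_id": cell_id,
                "status": status,
                "reason": reason,
                "nucleus_threshold": thresholds.nucleus_threshold if thresholds else np.nan,
                "spot_threshold": thresholds.spot_threshold if thresholds else np.nan,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def n_analyzed(self) -> int:
        return sum(r["status"] == "analyzed" for r in self.records)

    @property
    def n_excluded(self) -> int:
        return sum(r["status"] == "excluded" for r in self.records)


def quantify_cell(
    image: CellImage,
    thresholds: ThresholdPair | None,
    condition: str,
    treatment: str = "none",
    replicate: str = "1",
    options: QuantifyOptions | None = None,
) -> CellQuant:
    """Quantify one cell image; raises on QC failures (caller records reasons).

    With ``thresholds=None``, thresholds are derived automatically (Otsu
    nucleus, high marker quantile for spots) and logged, since per-cell
    threshold provenance is the main manual step of this kind of analysis.
    """
    options = options or QuantifyOptions()
    if thresholds is None:
        thresholds = auto_thresholds(image, spot_quantile=options.spot_quantile)
    logger.info(
        "cell %s: thresholds nucleus=%.3f spot=%.3f (%s)",
        image.cell_id, thresholds.nucleus_threshold, thresholds.spot_threshold,
        thresholds.method,
    )
    nucleus = segment_nucleus(image, thresholds)
    spots = detect_spots(
        image, nucleus, thresholds,
        max_spots=options.max_spots, min_spot_area=options.min_spot_area,
    )
    if not spots:
        raise ExclusionError("no_spots", f"cell {image.cell_id}: no qualifying spots")

    if options.exclude_spot_pixels_from_nuclear_mean:
        from .segmentation import measure_region

        spot_union = np.zeros(image.shape, dtype=bool)
        for s in spots:
            spot_union |= s.mask
        bg_mask = nucleus.mask & ~spot_union
        if bg_mask.any():
            nucleus.mean_intensity = measure_region(image, bg_mask)

    eps = eps_for_image(image)
    quants = [spot_relative_biad(s, nucleus, eps=eps) for s in spots]
    if options.allelic:
        if ChannelRole.STAIN not in image.channels:
            raise ConfigurationError(
                f"cell {image.cell_id}: allelic analysis requested but no STAIN channel"
            )
        from skimage.filters import threshold_otsu

        stain = image.channels[ChannelRole.STAIN]
        stain_mask = (stain >= threshold_otsu(stain)) & nucleus.mask
        for q, lab in zip(quants, classify_alleles(
                spots, stain_mask, overlap_fraction_min=options.stain_overlap_min)):
            q.allele = lab
    return cell_mean_biad(quants, image.cell_id, condition,
                          treatment=treatment, replicate=replicate)


def run_quantify(
    cells: Sequence[tuple[str, CellImage]],
    sample_sheet: pd.DataFrame,
    options: QuantifyOptions | None = None,
) -> tuple[ExperimentTable, QCReport]:
    """Quantify a set of in-memory cell images against a sample sheet.

    The sheet must resolve every ``cell_id``; manual thresholds are taken from
    ``nucleus_threshold`` / ``spot_threshold`` columns when present, otherwise
    derived automatically per cell.
    """
    options = options or QuantifyOptions()
    sheet = sample_sheet.set_index("cell_id")
    missing = [cid for cid, _ in cells if cid not in sheet.index]
    if missing:
        raise ConfigurationError(f"sample sheet does not resolve cell ids: {missing}")

    rows: list[CellQuant] = []
    qc = QCReport()
    for cell_id, image in cells:
        meta = sheet.loc[cell_id]
        thresholds = None
        if "nucleus_threshold" in meta.index and pd.notna(meta["nucleus_threshold"]):
            thresholds = ThresholdPair(
                float(meta["nucleus_threshold"]), float(meta["spot_threshold"])
            )
        try:
            cq = quantify_cell(
                image,
                thresholds,
                condition=str(meta["condition"]),
                treatment=str(meta.get("treatment", "none")),
                replicate=str(meta.get("replicate", "1")),
                options=options,
            )
        except SegmentationError:
            qc.add(cell_id, "excluded", "no_nucleus", thresholds)
            continue
        except ExclusionError as exc:
            qc.add(cell_id, "excluded", exc.reason, thresholds)
            continue
        rows.append(cq)
        qc.add(cell_id, "analyzed", thresholds=thresholds)
    return ExperimentTable(rows=rows), qc


def run_quantify_images(
    image_dir: str | Path,
    sample_sheet_path: str | Path,
    channel_map: Sequence[ChannelRole],
    options: QuantifyOptions | None = None,
) -> tuple[ExperimentTable, QCReport]:
    """Quantify on-disk TIFF stacks listed in a sample sheet CSV."""
    image_dir = Path(image_dir)
    sheet = pd.read_csv(sample_sheet_path)
    if "cell_id" not in sheet.columns:
        raise ConfigurationError("sample sheet needs a cell_id column")
    cells = []
    for _, row in sheet.iterrows():
        fname = row.get("file", f"{row['cell_id']}.ome.tif")
        stack = load_stack(image_dir / str(fname), channel_map)
        cells.append((str(row["cell_id"]),
                      max_intensity_projection(stack, cell_id=str(row["cell_id"]))))
    return run_quantify(cells, sheet, options=options)


def run_compare(
    table: ExperimentTable,
    mode: Literal["per_cell", "allelic", "control_normalized"] = "per_cell",
    control_condition: str | None = None,
    variant: str = "welch",
) -> list[GroupComparison]:
    """Run the figure-style group comparison for an experiment table.

    ``per_cell``: conditions compared on per-cell mean relative BiAD
    (t test for two conditions, ANOVA + Tukey for three or more).
    ``allelic``: Xi vs Xa spots on per-spot Xa-normalised values, pooled over
    cells (each cell contributes its Xi spot(s) and Xa spots anchored at 1).
    ``control_normalized``: per-cell values first divided by the control
    detector's mean within each treatment arm, then treatment arms compared.
    """
    if mode == "per_cell":
        conds = table.conditions
        if len(conds) < 2:
            raise ConfigurationError("need >= 2 conditions to compare")
        if len(conds) == 2:
            a, b = (table.values(c) for c in conds)
            return [compare_two_groups(a, b, variant=variant, labels=(conds[0], conds[1]))]
        return [compare_multi_groups({c: table.values(c) for c in conds})]

    if mode == "allelic":
        xi_vals, xa_vals = [], []
        for row in table.rows:
            try:
                norm = normalize_to_xa(row)
            except ExclusionError:
                continue
            for s in norm.spots:
                if not s.valid or s.xa_normalized is None:
                    continue
                (xi_vals if s.allele == ALLELE_XI else xa_vals).append(s.xa_normalized)
        if len(xi_vals) < 2 or len(xa_vals) < 2:
            raise ConfigurationError("not enough labelled spots for allelic comparison")
        return [compare_two_groups(xi_vals, xa_vals, variant=variant,
                                   labels=(ALLELE_XI, ALLELE_XA))]

    if mode == "control_normalized":
        if control_condition is None:
            raise ConfigurationError("control_normalized mode needs control_condition")
        normed = normalize_to_control(table, control_condition)
        arms = sorted({r.treatment for r in normed.rows})
        test_rows = [r for r in normed.rows if r.condition != control_condition]
        groups = {
            arm: [r.control_normalized for r in test_rows if r.treatment == arm]
            for arm in arms
        }
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            raise ConfigurationError("need >= 2 treatment arms with test-condition cells")
        if len(groups) == 2:
            (la, va), (lb, vb) = groups.items()
            return [compare_two_groups(va, vb, variant=variant, labels=(la, lb))]
        return [compare_multi_groups(groups)]

    raise ConfigurationError(f"unknown comparison mode {mode!r}")


def run_simulate(
    configs: dict[str, SimulationConfig],
    n_cells: int,
    outdir: str | Path,
    n_replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate an experiment to disk and write a JSON run manifest."""
    outdir = Path(outdir)
    cells, sheet, truth = simulate_experiment(
        configs, n_cells, outdir=outdir, n_replicates=n_replicates, seed=seed
    )
    resolved = {name: cfg.model_dump(mode="json") for name, cfg in configs.items()}
    blob = json.dumps(resolved, sort_keys=True).encode()
    manifest = {
        "n_cells_per_condition": n_cells,
        "n_replicates": n_replicates,
        "seed": seed,
        "conditions": resolved,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return sheet
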