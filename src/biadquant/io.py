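"""Image and table I/O.

Reads single- and multi-channel TIFF / OME-TIFF z-stacks, reduces them to 2D
working images by maximum-intensity projection, and binds channels to semantic
roles (locus marker, BiAD/BiFC signal, immunostain, nuclear counterstain).
Channel binding is always explicit via a user-supplied channel map, never
inferred from acquisition metadata, because metadata conventions vary between
microscopes and export software.

Intensities are held as float64 internally after load so that downstream
background subtraction cannot overflow or wrap; the original bit depth is
retained as metadata only.  Pixel coordinates are 0-based ``(row, col)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import ConfigurationError

__all__ = [
    "ChannelRole",
    "ZStack",
    "CellImage",
    "validate_channel_map",
    "load_stack",
    "max_intensity_projection",
    "write_quant_table",
    "read_quant_table",
]


class ChannelRole(str, enum.Enum):
    """Semantic role of an acquisition channel.

    MARKER   -- full-length fluorophore labelling the target locus (YPet).
    BIAD     -- reconstituted split-fluorophore BiFC signal (IFP2.0).
    STAIN    -- optional immunostain channel (e.g. H3K27me3 for Xi identification).
    NUCSTAIN -- optional nuclear counterstain (DAPI).
    """

    MARKER = "marker"
    BIAD = "biad"
    STAIN = "stain"
    NUCSTAIN = "nucstain"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def validate_channel_map(channel_map: Sequence[ChannelRole]) -> tuple[ChannelRole, ...]:
    """Validate a channel-role ordering: exactly one MARKER, no duplicate roles."""
    roles = tuple(ChannelRole(r) for r in channel_map)
    if len(set(roles)) != len(roles):
        raise ConfigurationError(f"duplicate channel roles in map: {[str(r) for r in roles]}")
    if sum(r is ChannelRole.MARKER for r in roles) != 1:
        raise ConfigurationError("channel map must contain exactly one MARKER channel")
    return roles


@dataclass
class ZStack:
    """A multi-channel z-stack: per role a 3D ``(z, y, x)`` float array.

    All channels share identical dimensions and intensities are non-negative.
    """

    channels: dict[ChannelRole, np.ndarray]
    z_spacing: float = 0.5  # micrometres between planes
    bit_depth: int = 16

    def __post_init__(self) -> None:
        shapes = {r: c.shape for r, c in self.channels.items()}
        if not shapes:
            raise ConfigurationError("ZStack requires at least one channel")
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ConfigurationError(f"channel planes must be 3D (z, y, x); got shape {first}")
        if any(s != first for s in shapes.values()):
            raise ConfigurationError(f"channel shape mismatch: {shapes}")
        for role, plane in self.channels.items():
            if np.any(plane < 0):
                raise ConfigurationError(f"negative intensities in channel {role}")

    @property
    def n_planes(self) -> int:
        return next(iter(self.channels.values())).shape[0]


@dataclass
class CellImage:
    """A single cell's 2D working image: one plane per channel role."""

    channels: dict[ChannelRole, np.ndarray]
    pixel_size: float = 0.1  # micrometres per pixel
    cell_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if ChannelRole.MARKER not in self.channels:
            raise ConfigurationError("CellImage requires a MARKER channel")
        shapes = {r: c.shape for r, c in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 2 or any(s != first for s in shapes.values()):
            raise ConfigurationError(f"channel planes must be 2D and congruent: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[ChannelRole.MARKER].shape

    def marker(self) -> np.ndarray:
        return self.channels[ChannelRole.MARKER]


def _axes_to_czyx(data: np.ndarray, axes: str, n_channels: int) -> np.ndarray:
    """Reshape a tifffile array with known axes labels into (C, Z, Y, X)."""
    axes = axes.upper().replace("S", "C")
    # Some writers label the stack dimension 'I' (image sequence) or 'Q' (unknown);
    # treat it as the channel axis when its extent matches the channel map, else as z.
    for unknown in ("I", "Q"):
        if unknown in axes:
            dim = data.shape[axes.index(unknown)]
            repl = "C" if ("C" not in axes and dim == n_channels) else "Z"
            axes = axes.replace(unknown, repl)
    if not set(axes) <= {"C", "Z", "Y", "X"}:
        raise ConfigurationError(f"unsupported TIFF axes {axes!r}")
    # Insert missing singleton axes.
    for missing in ("C", "Z"):
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(data, order)


def _infer_czyx(data: np.ndarray, n_channels: int) -> np.ndarray:
    """Fallback layout inference when the file carries no usable axes metadata."""
    if data.ndim == 2:
        return data[np.newaxis, np.newaxis]
    if data.ndim == 3:
        if data.shape[0] == n_channels:
            return data[:, np.newaxis]
        if n_channels == 1:
            return data[np.newaxis]
        raise ConfigurationError(
            f"cannot bind 3D array of shape {data.shape} to {n_channels} channel roles"
        )
    if data.ndim == 4:
        if data.shape[0] == n_channels:
            return data
        if data.shape[1] == n_channels:  # (Z, C, Y, X) page interleaving
            return np.transpose(data, (1, 0, 2, 3))
        raise ConfigurationError(
            f"cannot bind 4D array of shape {data.shape} to {n_channels} channel roles"
        )
    raise ConfigurationError(f"unsupported TIFF dimensionality {data.ndim}")


def load_stack(path: str | Path, channel_map: Sequence[ChannelRole],
               z_spacing: float = 0.5) -> ZStack:
    """Read a TIFF/OME-TIFF into a :class:`ZStack` with channels bound per ``channel_map``.

    A plain 2D file yields a single-plane stack.  The number of channels in the
    file must equal ``len(channel_map)``; a mismatch raises
    :class:`~biadquant.errors.ConfigurationError`.
    """
    roles = validate_channel_map(channel_map)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = np.asarray(series.asarray())
            axes = series.axes
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / not a TIFF
        raise OSError(f"could not read TIFF {path}: {exc}") from exc

    bit_depth = int(data.dtype.itemsize * 8) if data.dtype.kind in "ui" else 16
    try:
        czyx = _axes_to_czyx(data, axes, len(roles)) if axes else _infer_czyx(data, len(roles))
    except ConfigurationError:
        czyx = _infer_czyx(data, len(roles))
    if czyx.shape[0] != len(roles):
        raise ConfigurationError(
            f"file {path.name} has {czyx.shape[0]} channels but the channel map "
            f"names {len(roles)} roles"
        )
    channels = {role: czyx[i].astype(np.float64) for i, role in enumerate(roles)}
    return ZStack(channels=channels, z_spacing=z_spacing, bit_depth=bit_depth)


def max_intensity_projection(stack: ZStack, cell_id: str = "",
                             pixel_size: float = 0.1) -> CellImage:
    """Collapse a z-stack to 2D: each output pixel is the maximum over z, per channel."""
    if stack.n_planes < 1:
        raise ConfigurationError("cannot project an empty stack")
    channels = {role: planes.max(axis=0) for role, planes in stack.channels.items()}
    return CellImage(
        channels=channels,
        cell_id=cell_id,
        pixel_size=pixel_size,
        metadata={"bit_depth": stack.bit_depth, "n_planes": stack.n_planes,
                  "z_spacing": stack.z_spacing},
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_quant_table(table, path: str | Path, spots_path: str | Path | None = None) -> None:
    """Write an :class:`~biadquant.quantification.ExperimentTable` to CSV.

    One row per cell; if ``spots_path`` is given a long-format per-spot table is
    written as well.  Missing allele labels become empty fields, never dropped
    rows.  Round-trips losslessly through :func:`read_quant_table`.
    """
    df = table.to_cell_frame()
    if df.empty:
        raise ValueError("refusing to write an empty experiment table")
    df.to_csv(path, index=False)
    if spots_path is not None:
        table.to_spot_frame().to_csv(spots_path, index=False)


def read_quant_table(path: str | Path, spots_path: str | Path | None = None):
    """Read tables written by :func:`write_quant_table` back into an ExperimentTable."""
    import pandas as pd

    from .quantification import ExperimentTable

    cells = pd.read_csv(path)
    spots = pd.read_csv(spots_path) if spots_path is not None else None
    return ExperimentTable.from_frames(cells, spots)
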