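"""Reading and writing image stacks, plate layouts and result tables.

A *field* is one imaged position in one well: two fluorescence channels
(acid-stable donor, e.g. TOLLES; acid-labile acceptor, e.g. YPet) times a
z-stack of planes.  Raw detector data are 12-bit intensities stored in
16-bit TIFF containers; ``bit_depth`` is metadata, never the container
width.  Stacks are written as OME-TIFF so axes and channel names travel
with the pixels; on read, axis order is taken from OME metadata when
present, else from ImageJ-style metadata, else the caller must state the
stored channel order explicitly — storage order is never silently guessed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "FieldStack",
    "PlateLayout",
    "WellEntry",
    "FormatError",
    "LayoutError",
    "CHANNEL_ROLES",
    "channel_role",
    "read_field_stack",
    "write_field_stack",
    "read_plate_layout",
    "write_plate_layout",
    "write_ratio_map_image",
    "read_ratio_map_image",
    "write_results_table",
    "RATIO_SENTINEL",
]

#: sentinel stored for invalid ratio pixels in float-TIFF output (below 0,
#: outside the attainable ratio range [0, r_cap])
RATIO_SENTINEL = -1.0

#: recognized channel labels, mapped to their chemical role.  "stable" is
#: the acid-resistant channel that survives the autolysosome; "labile" is
#: quenched at lysosomal pH.
CHANNEL_ROLES = {
    "tolles": "stable",
    "cfp": "stable",
    "mrfp": "stable",
    "rfp": "stable",
    "acid_stable": "stable",
    "stable": "stable",
    "ypet": "labile",
    "yfp": "labile",
    "gfp": "labile",
    "acid_labile": "labile",
    "labile": "labile",
}


class FormatError(ValueError):
    """Raised when an image file's structure cannot be interpreted safely."""


class LayoutError(ValueError):
    """Raised when a plate layout file fails validation."""


def channel_role(name: str) -> str:
    """Map a channel label to ``"stable"`` or ``"labile"``."""
    try:
        return CHANNEL_ROLES[name.strip().lower()]
    except KeyError:
        raise FormatError(
            f"unrecognized channel label {name!r}; known labels: "
            + ", ".join(sorted(CHANNEL_ROLES))
        ) from None


@dataclass
class FieldStack:
    """One imaging field: ``pixels`` indexed (channel, z, y, x).

    Channel axis is always ordered (acid_stable, acid_labile) in memory,
    regardless of how the file stored it.
    """

    pixels: np.ndarray
    channel_names: tuple[str, str]
    z_step_um: float = 1.5
    bit_depth: int = 12
    well_id: str = ""
    field_id: int = 1
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise FormatError(
                f"pixels must be (channel, z, y, x); got ndim={self.pixels.ndim}"
            )
        if self.pixels.shape[0] != 2:
            raise FormatError(
                f"exactly 2 channels required; got {self.pixels.shape[0]}"
            )
        if self.pixels.shape[1] < 1:
            raise FormatError("z count must be >= 1")
        if self.pixels.size and self.pixels.min() < 0:
            raise FormatError("negative intensities are not valid detector data")
        limit = 2**self.bit_depth - 1
        if self.pixels.size and self.pixels.max() > limit:
            raise FormatError(
                f"intensity {self.pixels.max()} exceeds 2^{self.bit_depth}-1"
            )
        if channel_role(self.channel_names[0]) != "stable" or (
            channel_role(self.channel_names[1]) != "labile"
        ):
            raise FormatError(
                "channel_names must be (acid_stable, acid_labile); got "
                f"{self.channel_names}"
            )
        if self.field_id < 1:
            raise FormatError("field_id must be >= 1")

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    @property
    def stable(self) -> np.ndarray:
        """(z, y, x) planes of the acid-stable channel."""
        return self.pixels[0]

    @property
    def labile(self) -> np.ndarray:
        """(z, y, x) planes of the acid-labile channel."""
        return self.pixels[1]

    @property
    def saturation_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class WellEntry:
    well_id: str
    condition: str
    genotype: str = ""
    replicate: int = 1


@dataclass
class PlateLayout:
    """Maps wells to experimental conditions/genotypes/replicates."""

    entries: list[WellEntry]
    conditions: list[str]
    reference_condition: str
    channels: tuple[str, str] = ("TOLLES", "YPet")
    z_step_um: float = 1.5

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.well_id in seen:
                raise LayoutError(f"duplicate well_id {e.well_id!r} in layout")
            seen.add(e.well_id)
            if e.condition not in self.conditions:
                raise LayoutError(
                    f"well {e.well_id}: condition {e.condition!r} not listed "
                    f"in conditions {self.conditions}"
                )
        if self.reference_condition not in self.conditions:
            raise LayoutError(
                f"reference_condition {self.reference_condition!r} not in "
                f"conditions {self.conditions}"
            )

    def entry(self, well_id: str) -> WellEntry:
        for e in self.entries:
            if e.well_id == well_id:
                return e
        raise KeyError(well_id)

    @property
    def wells(self) -> list[str]:
        return [e.well_id for e in self.entries]


# ---------------------------------------------------------------------------
# Stack I/O


def write_field_stack(stack: FieldStack, path: str | Path) -> Path:
    """Write a FieldStack as OME-TIFF (uint16 container, CZYX)."""
    path = Path(path)
    data = np.ascontiguousarray(stack.pixels.astype(np.uint16))
    meta = {
        "axes": "CZYX",
        "Channel": {"Name": list(stack.channel_names)},
        "PhysicalSizeZ": stack.z_step_um,
        "PhysicalSizeZUnit": "µm",
        "SignificantBits": stack.bit_depth,
        "Description": json.dumps(
            {
                "bit_depth": stack.bit_depth,
                "well_id": stack.well_id,
                "field_id": stack.field_id,
            }
        ),
    }
    if stack.pixel_size_um is not None:
        meta["PhysicalSizeX"] = stack.pixel_size_um
        meta["PhysicalSizeY"] = stack.pixel_size_um
    tifffile.imwrite(path, data, ome=True, photometric="minisblack", metadata=meta)
    return path


def _axes_and_names(tf: tifffile.TiffFile) -> tuple[str, list[str] | None]:
    series = tf.series[0]
    axes = series.axes.upper()
    names: list[str] | None = None
    if tf.is_ome and tf.ome_metadata:
        m = re.findall(r'<Channel[^>]*Name="([^"]+)"', tf.ome_metadata)
        if m:
            names = m
    return axes, names


def read_field_stack(
    path: str | Path,
    channel_order: Sequence[str] | None = None,
    axes: str | None = None,
) -> FieldStack:
    """Read a two-channel z-stack TIFF into canonical (stable, labile) order.

    Parameters
    ----------
    path:
        TIFF or OME-TIFF file with >= 2 channels.
    channel_order:
        Labels of the channels *as stored* (e.g. ``("YPet", "TOLLES")``).
        Required when the file itself carries no channel names; when the
        file does name its channels, the embedded names win.
    axes:
        Explicit axis string (e.g. ``"CZYX"``) for files whose metadata does
        not disambiguate axes.  Never guessed.
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    with tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes, names = _axes_and_names(tf)
        use_axes = (axes or file_axes).upper()
        if len(use_axes) != data.ndim:
            raise FormatError(
                f"{path.name}: axis string {use_axes!r} does not match data "
                f"ndim {data.ndim}"
            )
        if "C" not in use_axes:
            # a bare 2-D/3-D gray image has no channel axis to interpret
            raise FormatError(
                f"{path.name}: no channel axis (axes={use_axes!r}); a "
                "two-channel stack is required"
            )
        if any(a not in "CZYX" for a in use_axes):
            bad = [a for a in use_axes if a not in "CZYX"][0]
            if use_axes[use_axes.index(bad)] == bad and data.shape[
                use_axes.index(bad)
            ] == 1:
                data = np.squeeze(data, axis=use_axes.index(bad))
                use_axes = use_axes.replace(bad, "", 1)
            else:
                raise FormatError(
                    f"{path.name}: unsupported axis {bad!r} in {use_axes!r}"
                )
        order = [use_axes.index(a) for a in "CZYX" if a in use_axes]
        data = np.transpose(data, order)
        if "Z" not in use_axes:
            data = data[:, None]  # single plane -> z count 1
        if data.shape[0] < 2:
            raise FormatError(
                f"{path.name}: found {data.shape[0]} channel(s) on axis C; "
                "two channels (acid_stable, acid_labile) are required"
            )
        if data.shape[0] > 2:
            raise FormatError(
                f"{path.name}: {data.shape[0]} channels; exactly 2 expected"
            )

        stored = names or (list(channel_order) if channel_order else None)
        if stored is None:
            raise FormatError(
                f"{path.name}: file carries no channel names; pass "
                "channel_order=(stored_ch0, stored_ch1)"
            )
        roles = [channel_role(n) for n in stored[:2]]
        if set(roles) != {"stable", "labile"}:
            raise FormatError(
                f"{path.name}: channel labels {stored[:2]} do not contain one "
                "acid-stable and one acid-labile channel"
            )
        if roles[0] == "labile":
            data = data[::-1]
            stored = stored[:2][::-1]

        bit_depth, well_id, field_id = 12, "", 1
        z_step = 1.5
        ome_xml = tf.ome_metadata if tf.is_ome else None
        desc_sources = [tf.pages[0].description or ""]
        if ome_xml:
            desc_sources.append(ome_xml)
            mz = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', ome_xml)
            if mz:
                z_step = float(mz.group(1))
            mb = re.search(r'SignificantBits="(\d+)"', ome_xml)
            if mb:
                bit_depth = int(mb.group(1))
        for desc in desc_sources:
            m = re.search(r'\{[^{}]*&quot;bit_depth&quot;[^{}]*\}|\{[^{}]*"bit_depth"[^{}]*\}', desc)
            if m:
                try:
                    extra = json.loads(m.group(0).replace("&quot;", '"'))
                    bit_depth = int(extra.get("bit_depth", bit_depth))
                    well_id = str(extra.get("well_id", well_id))
                    field_id = int(extra.get("field_id", field_id))
                    break
                except (json.JSONDecodeError, TypeError, ValueError):
                    pass

    return FieldStack(
        pixels=data,
        channel_names=(stored[0], stored[1]),
        z_step_um=z_step,
        bit_depth=bit_depth,
        well_id=well_id,
        field_id=field_id,
    )


# ---------------------------------------------------------------------------
# Plate layout


def read_plate_layout(path: str | Path) -> PlateLayout:
    """Parse a YAML plate layout.

    Expected keys: ``wells`` (list of mappings with well/condition/
    genotype/replicate), ``conditions``, ``reference_condition``, and
    optionally ``channels`` and ``z_step_um``.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "wells" not in doc:
        raise LayoutError(f"{path.name}: layout must be a mapping with 'wells'")
    entries = []
    for row in doc["wells"]:
        entries.append(
            WellEntry(
                well_id=str(row["well"]),
                condition=str(row["condition"]),
                genotype=str(row.get("genotype", "")),
                replicate=int(row.get("replicate", 1)),
            )
        )
    conditions = [str(c) for c in doc.get("conditions", [])]
    if not conditions:
        # preserve first-appearance order
        conditions = list(dict.fromkeys(e.condition for e in entries))
    reference = str(doc.get("reference_condition", conditions[0]))
    channels = tuple(doc.get("channels", ("TOLLES", "YPet")))
    return PlateLayout(
        entries=entries,
        conditions=conditions,
        reference_condition=reference,
        channels=(str(channels[0]), str(channels[1])),
        z_step_um=float(doc.get("z_step_um", 1.5)),
    )


def write_plate_layout(layout: PlateLayout, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "channels": list(layout.channels),
        "z_step_um": layout.z_step_um,
        "conditions": list(layout.conditions),
        "reference_condition": layout.reference_condition,
        "wells": [
            {
                "well": e.well_id,
                "condition": e.condition,
                "genotype": e.genotype,
                "replicate": e.replicate,
            }
            for e in layout.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# Ratio-map and table output


def write_ratio_map_image(ratio_map, path: str | Path) -> Path:
    """Write a ratio map as float32 TIFF plus an 8-bit pseudo-color PNG.

    Invalid pixels are stored as ``RATIO_SENTINEL`` (< 0) in the float TIFF
    and rendered black in the PNG.  Valid values round-trip within float32
    precision.
    """
    import imageio.v3 as iio
    from matplotlib import colormaps

    path = Path(path)
    plane = np.where(
        ratio_map.valid, ratio_map.ratio.astype(np.float32), np.float32(RATIO_SENTINEL)
    )
    tifffile.imwrite(path, plane.astype(np.float32))

    r_cap = float(ratio_map.params.get("r_cap", max(plane.max(), 1.0)))
    norm = np.clip(plane / r_cap, 0.0, 1.0)
    rgb = (colormaps["magma"](norm)[..., :3] * 255).astype(np.uint8)
    rgb[~ratio_map.valid] = 0
    iio.imwrite(path.with_suffix(".png"), rgb)
    return path


def read_ratio_map_image(path: str | Path) -> np.ndarray:
    """Reload the float-TIFF plane written by :func:`write_ratio_map_image`."""
    return tifffile.imread(Path(path))


RESULT_COLUMNS = [
    "well_id",
    "field_id",
    "condition",
    "replicate",
    "threshold",
    "index",
    "denominator_area_px",
    "rejected",
    "reject_reason",
]


def write_results_table(rows: Iterable[dict], path: str | Path) -> Path:
    """Write per-field results as CSV with a stable header.

    Floats are written with 9 significant digits.  An empty row list still
    produces a header-only file (with a warning) so downstream joins do not
    break.
    """
    import warnings

    path = Path(path)
    rows = list(rows)
    if not rows:
        warnings.warn(f"no result rows; writing header-only table to {path}")
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    else:
        df = pd.DataFrame(rows)
        lead = [c for c in RESULT_COLUMNS if c in df.columns]
        df = df[lead + [c for c in df.columns if c not in lead]]
    df.to_csv(path, index=False, float_format="%.9g")
    return path
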