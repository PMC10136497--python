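"""Synthetic two-channel z-stack fields with known ground truth.

The generator emulates an SRAI-type reporter imaged by widefield
microscopy so that every pipeline stage can be exercised against exact
truth.  The generative model, per field:

* cells are random convex (elliptical) footprints;
* inside each footprint a smoothed random mesh mimics the reticular ER
  texture where the probe lives;
* neutral probe pixels emit (donor ``alpha * A``, acceptor ``beta * A``):
  FRET is modelled only as a static donor attenuation ``alpha`` in neutral
  compartments — a declared simulator convention, not a measured constant;
* quenched (autolysosomal) regions are punctate patches where the
  acceptor drops to background while the donor recovers to the full
  amplitude ``A``;
* dual-positive (autophagosomal) puncta are small spots bright in both
  channels at the neutral ratio;
* each z-plane is blurred with a defocus sigma growing away from the
  sharpest plane ``z*``; Poisson shot noise then Gaussian read noise are
  applied and intensities quantized to the detector bit depth.

Truth quantities (quenched-area fraction, puncta coordinates and classes,
cell count, backgrounds, ``z*``) come from the generator's own mask
arithmetic, so downstream estimates can be compared to exact expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_io import (
    FieldStack,
    PlateLayout,
    WellEntry,
    write_field_stack,
    write_plate_layout,
)

__all__ = [
    "SimParams",
    "FieldTruth",
    "SimField",
    "PlateData",
    "generate_field",
    "generate_plate",
    "generate_spot_field",
    "ER_PHAGY_DESIGN",
    "LC3B_DESIGN",
    "DESIGN_PRESETS",
]


@dataclass
class SimParams:
    """Study conditions for one simulated field.

    Defaults describe a desk-scale rendering of the acquisition layout:
    128 x 128 fields (a crop of a full camera frame), 5 z-steps of 1.5 µm,
    12-bit intensities.  ``amplitude`` is the probe emission in detector
    units before the FRET factors; backgrounds and noise levels are chosen
    so foreground sits far above the noise floor, as in a well-exposed
    100-500 ms widefield exposure.
    """

    shape: tuple[int, int] = (128, 128)
    n_z: int = 5
    n_cells: int = 8
    texture_fill: float = 0.55  # fraction of each footprint carrying probe
    amplitude: float = 600.0  # probe emission amplitude, detector units
    alpha: float = 0.4  # FRET donor attenuation in neutral compartments
    beta: float = 1.0  # acceptor gain in neutral compartments
    quenched_fraction: float = 0.05  # target area fraction f of probe area
    quenched_radius: tuple[float, float] = (2.0, 4.0)  # px, ~0.3-0.7 µm radius
    n_dual_puncta: int = 4  # autophagosomal (dual-positive) spots per field
    dual_radius: tuple[float, float] = (1.5, 2.5)
    background: tuple[float, float] = (100.0, 100.0)  # (donor, acceptor) offsets
    photon_scale: float = 1.0  # Poisson events per detector unit
    read_sigma: float = 3.0  # Gaussian read noise, detector units
    blur_sigma0: float = 0.5  # in-focus PSF sigma, px
    blur_dsigma: float = 0.7  # extra blur per z-step away from z*
    z_star: int | None = None  # sharpest plane; default = central slice
    bit_depth: int = 12
    z_step_um: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.quenched_fraction < 1.0):
            raise ValueError("quenched_fraction must be in [0, 1)")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        limit = 2**self.bit_depth - 1
        peak = max(self.background) + 1.6 * self.amplitude * max(1.0, self.beta)
        if peak > limit:
            raise ValueError(
                f"amplitude/background reach {peak:.0f} > detector limit {limit}"
            )


@dataclass
class FieldTruth:
    """Exact per-field ground truth from the generator's mask arithmetic."""

    quenched_fraction: float  # quenched px / probe-footprint px
    probe_area_px: int
    quenched_area_px: int
    quenched_centers: list[tuple[float, float]]
    dual_centers: list[tuple[float, float]]
    cell_count: int
    background: tuple[float, float]
    z_star: int
    probe_mask: np.ndarray = dc_field(repr=False, default=None)
    quenched_mask: np.ndarray = dc_field(repr=False, default=None)


@dataclass
class SimField:
    well_id: str
    field_id: int
    condition: str
    genotype: str
    replicate: int
    stack: FieldStack
    truth: FieldTruth


@dataclass
class PlateData:
    fields: list[SimField]
    layout: PlateLayout
    design: dict

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well_id": f.well_id,
                    "field_id": f.field_id,
                    "condition": f.condition,
                    "genotype": f.genotype,
                    "replicate": f.replicate,
                    "quenched_fraction": f.truth.quenched_fraction,
                    "probe_area_px": f.truth.probe_area_px,
                    "quenched_area_px": f.truth.quenched_area_px,
                    "cell_count": f.truth.cell_count,
                    "z_star": f.truth.z_star,
                }
                for f in self.fields
            ]
        )


def _cell_footprints(shape, n_cells, rng) -> np.ndarray:
    """Union of random ellipses (convex cell outlines)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    footprint = np.zeros(shape, dtype=bool)
    for _ in range(n_cells):
        cy = rng.uniform(8, h - 8)
        cx = rng.uniform(8, w - 8)
        a = rng.uniform(11, 20)
        b = rng.uniform(11, 20)
        th = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        footprint |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return footprint


def _disk(shape, cy, cx, r) -> np.ndarray:
    h, w = shape
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return out


def _plant_quenched(tex: np.ndarray, target_px: int, radius, rng):
    """Disk-shaped quenched patches inside the texture, trimmed so the
    planted pixel count hits ``target_px`` exactly (when attainable)."""
    quenched = np.zeros_like(tex)
    centers: list[tuple[float, float]] = []
    coords = np.argwhere(tex)
    if target_px <= 0 or coords.size == 0:
        return quenched, centers
    count = 0
    for _ in range(10000):
        if count >= target_px:
            break
        cy, cx = coords[rng.integers(len(coords))]
        r = rng.uniform(*radius)
        disk = _disk(tex.shape, cy, cx, r) & tex & ~quenched
        new = np.argwhere(disk)
        if new.size == 0:
            continue
        need = target_px - count
        if len(new) > need:
            d2 = (new[:, 0] - cy) ** 2 + (new[:, 1] - cx) ** 2
            new = new[np.argsort(d2, kind="stable")[:need]]
        quenched[new[:, 0], new[:, 1]] = True
        centers.append((float(cy), float(cx)))
        count += len(new)
    return quenched, centers


def generate_field(
    params: SimParams | None = None, rng: np.random.Generator | None = None
) -> tuple[FieldStack, FieldTruth]:
    """Render one field and its exact ground truth.

    With a fixed ``params.seed`` (and no external ``rng``) output is
    bit-identical across runs.
    """
    p = params or SimParams()
    p.validate()
    if rng is None:
        rng = np.random.default_rng(p.seed)
    shape = tuple(p.shape)
    z_star = p.z_star if p.z_star is not None else (p.n_z - 1) // 2

    footprint = _cell_footprints(shape, p.n_cells, rng)
    # reticular texture: smoothed noise thresholded inside the footprint
    mesh = gaussian_filter(rng.standard_normal(shape), 1.2)
    if footprint.any():
        cut = np.quantile(mesh[footprint], 1.0 - p.texture_fill)
        tex = footprint & (mesh > cut)
    else:
        tex = footprint
    # mild smooth amplitude variation across the probe
    amp_var = 1.0 + 0.25 * np.tanh(gaussian_filter(rng.standard_normal(shape), 4.0) * 2)

    dual = np.zeros(shape, dtype=bool)
    dual_centers: list[tuple[float, float]] = []
    fp_coords = np.argwhere(footprint)
    for _ in range(p.n_dual_puncta):
        if fp_coords.size == 0:
            break
        cy, cx = fp_coords[rng.integers(len(fp_coords))]
        r = rng.uniform(*p.dual_radius)
        dual |= _disk(shape, cy, cx, r)
        dual_centers.append((float(cy), float(cx)))

    probe = tex | dual
    probe_px = int(probe.sum())
    target_q = int(round(p.quenched_fraction * probe_px))
    quenched, q_centers = _plant_quenched(tex & ~dual, target_q, p.quenched_radius, rng)
    q_px = int(quenched.sum())
    neutral = probe & ~quenched

    amp = p.amplitude * amp_var
    b_t, b_y = p.background
    donor = np.full(shape, b_t, dtype=np.float64)
    acceptor = np.full(shape, b_y, dtype=np.float64)
    donor[neutral] += p.alpha * amp[neutral]
    donor[dual] += 0.5 * p.alpha * amp[dual]  # puncta brighter than mesh
    donor[quenched] += amp[quenched]
    acceptor[neutral] += p.beta * amp[neutral]
    acceptor[dual] += 0.5 * p.beta * amp[dual]

    stack = np.empty((2, p.n_z) + shape, dtype=np.float64)
    for z in range(p.n_z):
        sigma = p.blur_sigma0 + p.blur_dsigma * abs(z - z_star)
        stack[0, z] = gaussian_filter(donor, sigma)
        stack[1, z] = gaussian_filter(acceptor, sigma)

    counts = rng.poisson(stack * p.photon_scale) / p.photon_scale
    counts = counts + rng.normal(0.0, p.read_sigma, size=counts.shape)
    limit = 2**p.bit_depth - 1
    pixels = np.clip(np.rint(counts), 0, limit).astype(np.uint16)

    field = FieldStack(
        pixels=pixels,
        channel_names=("TOLLES", "YPet"),
        z_step_um=p.z_step_um,
        bit_depth=p.bit_depth,
    )
    truth = FieldTruth(
        quenched_fraction=(q_px / probe_px) if probe_px else 0.0,
        probe_area_px=probe_px,
        quenched_area_px=q_px,
        quenched_centers=q_centers,
        dual_centers=dual_centers,
        cell_count=p.n_cells,
        background=(b_t, b_y),
        z_star=z_star,
        probe_mask=probe,
        quenched_mask=quenched,
    )
    return field, truth


# ---------------------------------------------------------------------------
# Plate designs

#: general ER-phagy design: starvation (EBSS) drives a large quenched
#: fraction; untreated shows low basal flux; lysosomal block (BafA1 during
#: starvation) and loss of a core autophagy gene abolish it.
ER_PHAGY_DESIGN: dict[str, dict] = {
    "untreated": {"quenched_fraction": 0.04},
    "EBSS": {"quenched_fraction": 0.30},
    "EBSS+BafA1": {"quenched_fraction": 0.004},
    "dAtg7": {"quenched_fraction": 0.004, "genotype": "sgAtg7"},
}

#: bulk-autophagy reporter design: BafA1 alone blocks flux but accumulates
#: dual-positive autophagosomes (no quenched puncta).
LC3B_DESIGN: dict[str, dict] = {
    "untreated": {"quenched_fraction": 0.08},
    "EBSS": {"quenched_fraction": 0.35},
    "BafA1": {"quenched_fraction": 0.004, "n_dual_puncta": 20},
    "dAtg7": {"quenched_fraction": 0.004, "genotype": "sgAtg7"},
}

DESIGN_PRESETS: dict[str, dict[str, dict]] = {
    "er-phagy": ER_PHAGY_DESIGN,
    "lc3b": LC3B_DESIGN,
}

#: relative SD of the per-replicate biological variation applied to the
#: planted quenched fraction
REPLICATE_CV = 0.08


def generate_plate(
    design: Mapping[str, dict] | str = "er-phagy",
    n_replicates: int = 3,
    n_fields: int = 6,
    base: SimParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PlateData:
    """Simulate a plate: one well per (condition, replicate).

    Per-field RNG streams are keyed by (seed, well index, field index) so
    any single field is independently reproducible.  A mild multiplicative
    replicate effect (CV 8%) perturbs each replicate's quenched fraction,
    mimicking biological replicate scatter.  With ``out_dir`` set, stacks
    are written as OME-TIFFs alongside ``layout.yaml`` and ``truth.csv``.
    """
    if isinstance(design, str):
        design = DESIGN_PRESETS[design]
    base = base or SimParams()
    conditions = list(design)
    entries: list[WellEntry] = []
    fields: list[SimField] = []
    for ci, cond in enumerate(conditions):
        overrides = dict(design[cond])
        genotype = overrides.pop("genotype", "sgControl")
        for rep in range(1, n_replicates + 1):
            well_idx = ci * n_replicates + (rep - 1)
            well_id = f"{chr(65 + rep - 1)}{ci + 1}"
            entries.append(
                WellEntry(
                    well_id=well_id, condition=cond, genotype=genotype, replicate=rep
                )
            )
            rep_rng = np.random.default_rng([seed, well_idx])
            f_nominal = overrides.get("quenched_fraction", base.quenched_fraction)
            f_rep = float(
                np.clip(f_nominal * (1.0 + REPLICATE_CV * rep_rng.standard_normal()),
                        0.0, 0.9)
            )
            params = replace(base, **{**overrides, "quenched_fraction": f_rep})
            for fi in range(1, n_fields + 1):
                rng = np.random.default_rng([seed, well_idx, fi])
                stack, truth = generate_field(params, rng=rng)
                stack.well_id = well_id
                stack.field_id = fi
                fields.append(
                    SimField(
                        well_id=well_id,
                        field_id=fi,
                        condition=cond,
                        genotype=genotype,
                        replicate=rep,
                        stack=stack,
                        truth=truth,
                    )
                )
    layout = PlateLayout(
        entries=entries,
        conditions=conditions,
        reference_condition=conditions[0],
        channels=("TOLLES", "YPet"),
        z_step_um=base.z_step_um,
    )
    plate = PlateData(fields=fields, layout=layout, design=dict(design))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for f in plate.fields:
            write_field_stack(f.stack, out_dir / f"{f.well_id}_f{f.field_id:02d}.tif")
        write_plate_layout(layout, out_dir / "layout.yaml")
        plate.truth_frame().to_csv(
            out_dir / "truth.csv", index=False, float_format="%.9g"
        )
    return plate


def generate_spot_field(
    shape: tuple[int, int] = (256, 256),
    n_quenched: int = 20,
    n_neutral: int = 0,
    amplitude: float = 100.0,
    noise_sigma: float = 0.0,
    background: tuple[float, float] = (100.0, 100.0),
    spot_sigma: float = 2.0,
    min_sep: float = 14.0,
    n_cells: int = 25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Flat-background two-channel field with isolated Gaussian spots.

    Quenched spots are bright only in the acid-stable channel; neutral
    spots are equally bright in both (ratio ~1).  Spot centres keep a
    minimum separation so detection truth is unambiguous.  Returns
    ``(stable_plane, labile_plane, truth)`` with truth carrying spot
    coordinates, classes and the nominal cell count.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = int(4 * spot_sigma) + 2
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_quenched + n_neutral and attempts < 20000:
        attempts += 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append((cy, cx))
    if len(centers) < n_quenched + n_neutral:
        raise ValueError("could not place spots with the requested separation")

    yy, xx = np.mgrid[0:h, 0:w]
    stable = np.full(shape, background[0], dtype=np.float64)
    labile = np.full(shape, background[1], dtype=np.float64)
    classes = ["quenched"] * n_quenched + ["neutral"] * n_neutral
    for (cy, cx), klass in zip(centers, classes):
        g = amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * spot_sigma**2)
        )
        stable += g
        if klass == "neutral":
            labile += g
    if noise_sigma > 0:
        stable = stable + rng.normal(0.0, noise_sigma, shape)
        labile = labile + rng.normal(0.0, noise_sigma, shape)
    truth = {
        "centers": centers,
        "classes": classes,
        "n_cells": n_cells,
        "background": background,
        "spot_sigma": spot_sigma,
        "amplitude": amplitude,
        "noise_sigma": noise_sigma,
    }
    return stable, labile, truth
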