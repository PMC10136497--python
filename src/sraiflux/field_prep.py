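"""Turn a raw two-channel z-stack into one analysis plane per channel.

Manual protocols for this assay are interactive: the operator picks the best focal
plane, rejects poor-quality fields and chooses a background region of
interest.  This module automates all three with deterministic defaults
(focus metric, projection window, scalar background estimation,
saturation handling) while keeping manual overrides available, so whole
plates can be processed reproducibly in batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np

from .image_io import FieldStack

__all__ = [
    "PreparedField",
    "focus_score",
    "select_best_slice",
    "z_project",
    "estimate_background",
    "saturation_mask",
    "robust_noise_sigma",
    "prepare_field",
    "PrepConfig",
]


@dataclass
class PrepConfig:
    """Defaults for field preparation.

    Quantification defaults to the single best-focus slice
    (``n_slices=1``): the protocol's only z-related user input is choosing
    the slice where cells are in best focus, and projecting defocused
    planes into the analysis image inflates the probe-area denominator.
    Z-projections (conventionally 5 steps, for display and QC) are
    available via ``n_slices``/``projection``.
    """

    focus_channel: Literal["stable", "labile"] = "stable"
    n_slices: int = 1
    projection: Literal["max", "mean"] = "max"
    background_strategy: Literal["percentile", "darkest_tile", "manual_roi"] = (
        "darkest_tile"
    )
    background_q: float = 1.0
    background_tile: int = 32
    background_roi: tuple[int, int, int, int] | None = None  # (y0, x0, h, w)
    max_saturated_frac: float = 0.01


@dataclass
class PreparedField:
    """One analysis plane per channel plus the per-field scalars.

    ``background_stable``/``background_labile`` are the scalar offsets
    subtracted before any ratio arithmetic (single-ROI-style subtraction;
    no flat-field correction).  ``saturation_mask`` is True wherever either
    channel hit the detector ceiling in any plane of the projection window.
    """

    stable_plane: np.ndarray
    labile_plane: np.ndarray
    background_stable: float
    background_labile: float
    saturation_mask: np.ndarray
    chosen_z: int | str
    qc: dict = dc_field(default_factory=lambda: {"rejected": False, "reason": ""})

    def __post_init__(self) -> None:
        if self.stable_plane.shape != self.labile_plane.shape:
            raise ValueError("channel planes must share one shape")
        if self.saturation_mask.shape != self.stable_plane.shape:
            raise ValueError("saturation_mask shape must equal plane shape")
        if self.background_stable < 0 or self.background_labile < 0:
            raise ValueError("backgrounds must be >= 0")

    def reject(self, reason: str) -> None:
        self.qc["rejected"] = True
        self.qc["reason"] = (
            reason if not self.qc["reason"] else self.qc["reason"] + "; " + reason
        )

    @property
    def rejected(self) -> bool:
        return bool(self.qc["rejected"])


def focus_score(plane: np.ndarray) -> float:
    """Normalized variance var(I)/mean(I)^2 — scale-free sharpness.

    Higher is sharper; a constant (or all-zero) plane scores 0.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size == 0:
        raise ValueError("empty plane")
    mean = plane.mean()
    if mean == 0.0:
        return 0.0
    return float(plane.var() / mean**2)


def select_best_slice(stack: FieldStack, channel: str = "stable") -> int:
    """Index of the sharpest z-plane by normalized variance.

    Ties break toward the central slice, then the lower index.
    """
    planes = stack.stable if channel == "stable" else stack.labile
    scores = np.array([focus_score(p) for p in planes])
    center = (len(scores) - 1) / 2.0
    best = np.flatnonzero(scores == scores.max())
    # among tied maxima: closest to center, then lowest index
    return int(min(best, key=lambda z: (abs(z - center), z)))


def _window(z_best: int, n_slices: int, n_z: int) -> tuple[int, int]:
    n = min(n_slices, n_z)
    start = z_best - n // 2
    start = max(0, min(start, n_z - n))
    return start, start + n


def z_project(
    stack: FieldStack,
    n_slices: int = 5,
    method: Literal["max", "mean"] = "max",
    channel: str = "stable",
) -> tuple[np.ndarray, np.ndarray, int, tuple[int, int]]:
    """Project an ``n_slices`` window centred on the best-focus slice.

    The same window (clipped at stack edges) is used for both channels.
    Returns ``(stable_plane, labile_plane, chosen_z, (z0, z1))``.
    """
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    z_best = select_best_slice(stack, channel=channel)
    z0, z1 = _window(z_best, n_slices, stack.n_z)
    reduce = np.max if method == "max" else np.mean
    stable = reduce(stack.stable[z0:z1].astype(np.float64), axis=0)
    labile = reduce(stack.labile[z0:z1].astype(np.float64), axis=0)
    return stable, labile, z_best, (z0, z1)


def estimate_background(
    plane: np.ndarray,
    strategy: Literal["percentile", "darkest_tile", "manual_roi"] = "percentile",
    q: float = 1.0,
    tile: int = 32,
    roi: tuple[int, int, int, int] | None = None,
) -> float:
    """Scalar background estimate for one channel plane.

    percentile
        the ``q``-th intensity percentile (default q=1).
    darkest_tile
        mean of the ``tile`` × ``tile`` window with the lowest mean
        (sliding window).
    manual_roi
        mean within the ``(y0, x0, h, w)`` rectangle.

    The estimate is clamped to be >= 0.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size == 0:
        raise ValueError("empty plane")
    if strategy == "percentile":
        bg = float(np.percentile(plane, q))
    elif strategy == "darkest_tile":
        from scipy.ndimage import uniform_filter

        k = min(tile, *plane.shape)
        means = uniform_filter(plane, size=k, mode="constant", cval=0.0)
        h = k // 2
        y1 = plane.shape[0] - (k - 1 - h)
        x1 = plane.shape[1] - (k - 1 - h)
        interior = means[h:y1, h:x1]  # windows fully inside the plane
        bg = float(interior.min())
    elif strategy == "manual_roi":
        if roi is None:
            raise ValueError("manual_roi requires roi=(y0, x0, h, w)")
        y0, x0, h, w = roi
        if (
            y0 < 0
            or x0 < 0
            or h < 1
            or w < 1
            or y0 + h > plane.shape[0]
            or x0 + w > plane.shape[1]
        ):
            raise ValueError(f"roi {roi} out of bounds for plane {plane.shape}")
        bg = float(plane[y0 : y0 + h, x0 : x0 + w].mean())
    else:
        raise ValueError(f"unknown background strategy {strategy!r}")
    return max(bg, 0.0)


def saturation_mask(data: np.ndarray, bit_depth: int = 12) -> np.ndarray:
    """True wherever intensity reached the detector ceiling 2^bit_depth - 1.

    For arrays with a leading channel and/or z axis the mask is collapsed
    over those axes: a pixel saturated in either channel or any plane is
    flagged.
    """
    limit = 2**bit_depth - 1
    sat = np.asarray(data) >= limit
    while sat.ndim > 2:
        sat = sat.any(axis=0)
    return sat


def robust_noise_sigma(plane: np.ndarray, background: float) -> float:
    """Noise scale from below-background residuals: 1.4826 * MAD.

    Pixels below the scalar background carry (half of) the noise
    distribution but no signal, so their absolute residuals give a
    signal-free noise estimate.  Falls back to the MAD of the whole plane
    when nothing lies below background.
    """
    plane = np.asarray(plane, dtype=np.float64)
    resid = plane - background
    below = -resid[resid < 0]
    if below.size == 0:
        med = np.median(plane)
        below = np.abs(plane - med)
    return float(1.4826 * np.median(below))


def prepare_field(stack: FieldStack, config: PrepConfig | None = None) -> PreparedField:
    """Run focus selection, projection, background and saturation QC."""
    cfg = config or PrepConfig()
    n = min(cfg.n_slices, stack.n_z)
    stable, labile, z_best, (z0, z1) = z_project(
        stack, n_slices=n, method=cfg.projection, channel=cfg.focus_channel
    )
    sat = saturation_mask(stack.pixels[:, z0:z1], bit_depth=stack.bit_depth)

    kwargs = dict(
        strategy=cfg.background_strategy,
        q=cfg.background_q,
        tile=cfg.background_tile,
        roi=cfg.background_roi,
    )
    b_t = estimate_background(stable, **kwargs)
    b_y = estimate_background(labile, **kwargs)

    prepared = PreparedField(
        stable_plane=stable,
        labile_plane=labile,
        background_stable=b_t,
        background_labile=b_y,
        saturation_mask=sat,
        chosen_z=z_best if n == 1 else "projection",
    )
    sat_frac = float(sat.mean())
    if sat_frac > cfg.max_saturated_frac:
        prepared.reject(f"saturated fraction {sat_frac:.3f} > {cfg.max_saturated_frac}")
    if stable.max() == 0 and labile.max() == 0:
        prepared.reject("empty field (all-zero planes)")
    elif b_t >= stable.max() or b_y >= labile.max():
        prepared.reject("no signal above background")
    return prepared
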