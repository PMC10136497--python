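"""The TOLLES:YPet index — probe segmentation, ratio map, threshold sweep.

The index for one field at threshold *t* is the area fraction

    Index(t) = |{p in M : R(p) > t}| / |M|,

where M is the set of pixels the reporter occupies (the probe mask) and
R(p) = (I_T(p) - b_T) / max(I_Y(p) - b_Y, eps) is the per-pixel ratio of
background-subtracted acid-stable (T) over acid-labile (Y) intensity,
capped at ``r_cap``.  In neutral compartments FRET keeps the donor dim and
the acceptor bright, so R is well below 1; in autolysosomes the acceptor
is quenched to background level and R rails at the cap.  Swept across
thresholds (default 0.5–4 in steps of 0.5) the index reads out how much of
the reporter pool has reached the acidic compartment — the flux proxy.

Segmentation of M is deliberately the union of per-channel robust
thresholds: neutral reticulum is bright in the acceptor channel while
autolysosomes are bright only in the donor channel, so either channel
alone undercounts the probe area.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.morphology import remove_small_objects

from .field_prep import PreparedField, robust_noise_sigma

__all__ = [
    "RatioMap",
    "IndexResult",
    "DEFAULT_THRESHOLDS",
    "probe_mask",
    "ratio_map",
    "tolles_ypet_index",
    "index_sweep",
    "quantify_field",
    "calibrate_threshold",
    "IndexConfig",
    "EmptyFieldError",
]

#: default threshold sweep (ratio units)
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


class EmptyFieldError(ValueError):
    """No valid probe pixels — the index is undefined for this field."""


@dataclass
class IndexConfig:
    """Tunables for segmentation and the ratio construction."""

    k_sigma: float = 3.0  # per-channel threshold in robust noise units
    min_obj_px: int = 9  # smallest connected component kept (8-connectivity)
    epsilon: float = 1.0  # division guard, detector units
    r_cap: float = 10.0  # ratio ceiling; quenched pixels rail here
    ratio_smooth_sigma: float = 0.8  # sub-PSF Gaussian before the division
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    min_area_px: int = 500  # QC: reject fields with less probe area
    max_area_frac: float = 0.95  # QC: reject near-full-field masks

    def validate(self) -> None:
        ts = tuple(self.thresholds)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"thresholds must be strictly ascending: {ts}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if ts and self.r_cap <= max(ts):
            raise ValueError(
                f"r_cap={self.r_cap} must exceed the largest sweep threshold "
                f"{max(ts)} (the index would saturate artifactually)"
            )


@dataclass
class RatioMap:
    """Per-pixel ratio with validity mask.

    ``ratio`` holds R(p) on valid pixels and a negative sentinel elsewhere;
    ``valid`` is the probe mask minus saturated pixels.
    """

    ratio: np.ndarray
    valid: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if self.ratio.shape != self.valid.shape:
            raise ValueError("ratio and valid must share a shape")

    @property
    def values(self) -> np.ndarray:
        """Ratios of valid pixels only (1-D)."""
        return self.ratio[self.valid]


@dataclass
class IndexResult:
    """Index(t) for one field across the sweep, plus provenance and QC."""

    well_id: str
    field_id: int
    condition: str
    thresholds: tuple[float, ...]
    index: tuple[float, ...]
    denominator_area_px: int
    replicate: int = 1
    median_ratio: float = float("nan")  # median R over valid pixels (QC)
    qc: dict = dc_field(default_factory=lambda: {"rejected": False, "reason": ""})

    @property
    def rejected(self) -> bool:
        return bool(self.qc.get("rejected", False))

    def at(self, t: float) -> float:
        return self.index[self.thresholds.index(t)]

    def to_rows(self) -> list[dict]:
        return [
            {
                "well_id": self.well_id,
                "field_id": self.field_id,
                "condition": self.condition,
                "replicate": self.replicate,
                "threshold": t,
                "index": v,
                "denominator_area_px": self.denominator_area_px,
                "rejected": self.rejected,
                "reject_reason": self.qc.get("reason", ""),
            }
            for t, v in zip(self.thresholds, self.index)
        ]


def probe_mask(prepared: PreparedField, config: IndexConfig | None = None) -> np.ndarray:
    """Segment the probe-occupied area M.

    A pixel belongs to M when either background-subtracted channel exceeds
    ``k_sigma`` robust noise scales (1.4826 * MAD of below-background
    residuals), excluding saturated pixels; connected components smaller
    than ``min_obj_px`` (8-connectivity) are dropped.  An empty mask flags
    the field rejected rather than raising.
    """
    cfg = config or IndexConfig()
    s, y = prepared.stable_plane, prepared.labile_plane
    b_t, b_y = prepared.background_stable, prepared.background_labile
    sig_t = robust_noise_sigma(s, b_t)
    sig_y = robust_noise_sigma(y, b_y)
    mask = ((s - b_t) > cfg.k_sigma * sig_t) | ((y - b_y) > cfg.k_sigma * sig_y)
    mask &= ~prepared.saturation_mask
    if cfg.min_obj_px > 1:
        # keep components of at least min_obj_px pixels (8-connectivity)
        mask = remove_small_objects(mask, max_size=cfg.min_obj_px - 1, connectivity=2)
    if not mask.any():
        prepared.reject("empty probe mask")
    return mask


def ratio_map(
    prepared: PreparedField,
    mask: np.ndarray,
    epsilon: float = 1.0,
    r_cap: float = 10.0,
    smooth_sigma: float = 0.8,
) -> RatioMap:
    """Per-pixel TOLLES/YPet ratio on background-subtracted intensities.

    The numerator is clamped at 0 below background; the denominator is
    floored at ``epsilon`` so acceptor-quenched pixels rail at ``r_cap``
    instead of overflowing.  Both planes are first smoothed with a
    sub-PSF Gaussian (``smooth_sigma``, in px): a pixelwise quotient of
    two independently noisy channels is heavy-tailed wherever the signal
    is weak, and averaging below the optical resolution suppresses those
    spurious high ratios without resolving away real structure.  Set
    ``smooth_sigma=0`` for a raw pixelwise ratio.
    """
    from scipy.ndimage import gaussian_filter

    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if r_cap <= 0:
        raise ValueError("r_cap must be > 0")
    stable = prepared.stable_plane
    labile = prepared.labile_plane
    if smooth_sigma > 0:
        stable = gaussian_filter(stable, smooth_sigma)
        labile = gaussian_filter(labile, smooth_sigma)
    num = np.clip(stable - prepared.background_stable, 0.0, None)
    den = np.maximum(labile - prepared.background_labile, epsilon)
    ratio = np.minimum(num / den, r_cap)
    valid = np.asarray(mask, dtype=bool) & ~prepared.saturation_mask
    from .image_io import RATIO_SENTINEL

    ratio = np.where(valid, ratio, RATIO_SENTINEL)
    return RatioMap(
        ratio=ratio,
        valid=valid,
        params={
            "epsilon": epsilon,
            "r_cap": r_cap,
            "smooth_sigma": smooth_sigma,
            "b_T": prepared.background_stable,
            "b_Y": prepared.background_labile,
        },
    )


def tolles_ypet_index(rmap: RatioMap, t: float) -> float:
    """Index(t): fraction of valid probe pixels with ratio strictly above t.

    Ties (R == t) count only toward the denominator.
    """
    n = int(rmap.valid.sum())
    if n == 0:
        raise EmptyFieldError("no valid probe pixels; index undefined")
    return float(np.count_nonzero(rmap.values > t)) / n


def index_sweep(
    rmap: RatioMap,
    thresholds: tuple[float, ...] | list[float] = DEFAULT_THRESHOLDS,
    *,
    well_id: str = "",
    field_id: int = 1,
    condition: str = "",
    replicate: int = 1,
    qc: dict | None = None,
) -> IndexResult:
    """Index(t) across an ascending threshold sweep.

    Computed from one sort of the valid ratios, so the per-threshold values
    agree exactly with independent per-threshold counting and are
    non-increasing in t by construction.
    """
    ts = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"thresholds must be strictly ascending: {ts}")
    r_cap = rmap.params.get("r_cap")
    if r_cap is not None and ts and max(ts) >= r_cap:
        raise ValueError(
            f"largest threshold {max(ts)} must be below r_cap={r_cap}"
        )
    n = int(rmap.valid.sum())
    if n == 0:
        raise EmptyFieldError("no valid probe pixels; index undefined")
    vals = np.sort(rmap.values)
    # strictly-above count via right-side rank
    above = n - np.searchsorted(vals, ts, side="right")
    index = tuple(float(a) / n for a in above)
    return IndexResult(
        well_id=well_id,
        field_id=field_id,
        condition=condition,
        replicate=replicate,
        thresholds=ts,
        index=index,
        denominator_area_px=n,
        median_ratio=float(vals[n // 2]),
        qc=qc if qc is not None else {"rejected": False, "reason": ""},
    )


def quantify_field(
    stack,
    *,
    prep_config=None,
    index_config: IndexConfig | None = None,
    condition: str = "",
    replicate: int = 1,
) -> tuple[PreparedField, RatioMap | None, IndexResult]:
    """Full per-field pipeline: prepare, segment, ratio, sweep, QC.

    Rejected fields still return an IndexResult (all-NaN indices, QC flags
    set) so the results table keeps one row per field per threshold.
    """
    from .field_prep import prepare_field

    cfg = index_config or IndexConfig()
    cfg.validate()
    prepared = prepare_field(stack, prep_config)
    rmap = None
    if not prepared.rejected:
        mask = probe_mask(prepared, cfg)
        area = int(mask.sum())
        if area and area < cfg.min_area_px:
            prepared.reject(f"probe area {area} px < min_area_px {cfg.min_area_px}")
        elif area > cfg.max_area_frac * mask.size:
            prepared.reject(
                f"probe area {area} px > {cfg.max_area_frac:.0%} of field"
            )
        if not prepared.rejected:
            rmap = ratio_map(
                prepared, mask, cfg.epsilon, cfg.r_cap, cfg.ratio_smooth_sigma
            )

    if rmap is not None:
        result = index_sweep(
            rmap,
            cfg.thresholds,
            well_id=stack.well_id,
            field_id=stack.field_id,
            condition=condition,
            replicate=replicate,
            qc=prepared.qc,
        )
    else:
        result = IndexResult(
            well_id=stack.well_id,
            field_id=stack.field_id,
            condition=condition,
            replicate=replicate,
            thresholds=tuple(cfg.thresholds),
            index=tuple(float("nan") for _ in cfg.thresholds),
            denominator_area_px=0,
            qc=prepared.qc,
        )
    return prepared, rmap, result


def calibrate_threshold(
    positive: list[IndexResult],
    negative: list[IndexResult],
    thresholds: tuple[float, ...] | None = None,
    max_leak: float = 0.02,
    neutral_margin: float = 2.0,
) -> float:
    """Pick the sweep threshold separating positive from negative controls.

    The reporting threshold for an experiment is fixed empirically from
    control conditions (e.g. starvation vs. lysosomal block).  A useful
    threshold must sit well between the neutral-reporter ratio mode and
    the quenched ratios railed at the cap, so a sweep threshold is
    admissible when

    * it clears the neutral population: t >= ``neutral_margin`` times the
      negative control's median probe-pixel ratio, and
    * the negative control's mean index is at or below ``max_leak`` — the
      negative index is the pixel-classification false-positive area.

    Among admissible thresholds the *smallest* is returned: the index is
    non-increasing in t, so once specificity is secured every further
    increase only erodes genuinely quenched area (sensitivity).  If no
    threshold is admissible, the one with the lowest negative-control
    mean index wins.
    """
    pos = [r for r in positive if not r.rejected]
    neg = [r for r in negative if not r.rejected]
    if not pos or not neg:
        raise ValueError("need at least one accepted field per control group")
    ts = thresholds or pos[0].thresholds
    neutral_ratio = float(np.nanmedian([r.median_ratio for r in neg]))
    floor = neutral_margin * neutral_ratio if np.isfinite(neutral_ratio) else 0.0
    stats = [(float(t), float(np.mean([r.at(t) for r in neg]))) for t in ts]
    admissible = [s for s in stats if s[0] >= floor and s[1] <= max_leak]
    if admissible:
        return min(admissible, key=lambda s: s[0])[0]
    return min(stats, key=lambda s: s[1])[0]
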