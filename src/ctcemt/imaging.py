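"""Cell segmentation and Corrected Total Cell Fluorescence (CTCF) measurement.

Segmentation is nucleus-seeded: Otsu threshold on the DAPI channel, connected
components, then a fixed dilation of each nucleus to capture cytoplasmic
signal, with overlaps resolved by nearest-nucleus assignment so regions stay
disjoint. Per region and channel,

    CTCF = IntegratedDensity - Area * MeanBackground

where the background is estimated from pixels outside every region. Negative
CTCF values (regions dimmer than background) are preserved. CTCs are the
DAPI-positive, CD45-negative records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import expand_labels
from sklearn.cluster import KMeans

from .records import CellRecord, ConfigError, CtcemtError

logger = logging.getLogger(__name__)


class SegmentationError(CtcemtError):
    pass


class BackgroundError(CtcemtError):
    pass


@dataclass(frozen=True)
class QuantConfig:
    """Tunables of segmentation, background estimation and CTC identification."""

    nuclear_threshold_method: str = "otsu"
    dilation_px: int = 5
    min_cell_area: int = 50
    max_cell_area: int = 5000
    background_estimator: str = "median"  # or "boxes"
    n_background_boxes: int = 5
    background_box_size: int = 16
    cd45_negativity_quantile: float = 0.05
    # raw region-mean DAPI must exceed this multiple of background; the
    # nuclear stain is diluted over the dilated whole-cell region, so the
    # factor is deliberately below the nucleus-only contrast
    dapi_positivity_factor: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.min_cell_area < self.max_cell_area:
            raise ConfigError("need 0 < min_cell_area < max_cell_area")
        if not 0.0 < self.cd45_negativity_quantile < 1.0:
            raise ConfigError("cd45_negativity_quantile must be in (0, 1)")
        if self.dilation_px < 0:
            raise ConfigError("dilation_px must be >= 0")


@dataclass
class CellRegion:
    """A segmented cell: disjoint pixel set with integer (row, col) coords."""

    region_id: int
    coords: np.ndarray  # (n, 2) int array of (row, col)

    @property
    def area(self) -> int:
        return int(self.coords.shape[0])

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.coords[:, 0].mean()), float(self.coords[:, 1].mean())

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


def segment_cells(
    image: np.ndarray,
    config: QuantConfig = QuantConfig(),
    channel_names: tuple[str, ...] = ("dapi", "keratin", "vimentin", "cd45"),
) -> list[CellRegion]:
    """Segment cells from the nuclear channel of a (C, H, W) image stack.

    Returns disjoint regions (nuclei dilated by ``config.dilation_px``,
    nearest-nucleus tie-break) with area inside
    ``[min_cell_area, max_cell_area]``. A blank image yields an empty list.
    """
    if image.ndim != 3:
        raise ConfigError("expected a (channels, H, W) image stack")
    if "dapi" not in channel_names:
        raise ConfigError("image has no 'dapi' (nuclear) channel")
    dapi = image[channel_names.index("dapi")]
    if np.ptp(dapi) == 0:
        return []
    if config.nuclear_threshold_method != "otsu":
        raise ConfigError(
            f"unknown nuclear_threshold_method {config.nuclear_threshold_method!r}"
        )
    nuclei = dapi > threshold_otsu(dapi)
    labels = cc_label(nuclei, connectivity=2)
    if labels.max() == 0:
        return []
    expanded = expand_labels(labels, distance=config.dilation_px)
    regions = []
    for rid in range(1, int(expanded.max()) + 1):
        coords = np.argwhere(expanded == rid)
        if config.min_cell_area <= coords.shape[0] <= config.max_cell_area:
            regions.append(CellRegion(region_id=rid, coords=coords))
    return regions


def estimate_background(
    channel: np.ndarray,
    regions: list[CellRegion],
    method: str = "median",
    n_boxes: int = 5,
    box_size: int = 16,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean background intensity of a channel, excluding all cell regions.

    ``median``: median over every non-region pixel. ``boxes``: mean over
    ``n_boxes`` square patches sampled away from the regions, emulating the
    manual background-box workflow of interactive image analysis.
    """
    outside = np.ones(channel.shape, dtype=bool)
    for r in regions:
        outside[r.coords[:, 0], r.coords[:, 1]] = False
    if not outside.any():
        raise BackgroundError("regions cover the whole image")
    if method == "median":
        return float(np.median(channel[outside]))
    if method == "boxes":
        rng = np.random.default_rng(0) if rng is None else rng
        h, w = channel.shape
        if h < box_size or w < box_size:
            raise BackgroundError("image smaller than background box")
        means = []
        for _ in range(10_000):
            r0 = int(rng.integers(0, h - box_size + 1))
            c0 = int(rng.integers(0, w - box_size + 1))
            if outside[r0 : r0 + box_size, c0 : c0 + box_size].all():
                means.append(float(channel[r0 : r0 + box_size, c0 : c0 + box_size].mean()))
                if len(means) == n_boxes:
                    return float(np.mean(means))
        raise BackgroundError("could not place background boxes clear of regions")
    raise ConfigError(f"unknown background estimator {method!r}")


def compute_ctcf(region: CellRegion, channel: np.ndarray, background: float) -> float:
    """CTCF of one region in one channel: pixel sum minus area x background."""
    if region.area == 0:
        raise ConfigError("empty region")
    if background < 0:
        raise ConfigError("background must be >= 0")
    total = float(channel[region.coords[:, 0], region.coords[:, 1]].sum())
    return total - region.area * background


def quantify_image(
    image: np.ndarray,
    config: QuantConfig = QuantConfig(),
    channel_names: tuple[str, ...] = ("dapi", "keratin", "vimentin", "cd45"),
    sample_id: str = "sample",
) -> tuple[list[CellRecord], dict[str, float]]:
    """Segment and measure every cell of a multi-channel image.

    Returns ``(records, backgrounds)``; each record carries per-channel CTCF
    and the DAPI/CD45 identity flags set by :func:`identify_ctcs`'s rules
    (the records themselves are all returned, flagged, not filtered).
    """
    regions = segment_cells(image, config, channel_names)
    backgrounds = {
        name: estimate_background(
            image[channel_names.index(name)],
            regions,
            method=config.background_estimator,
            n_boxes=config.n_background_boxes,
            box_size=config.background_box_size,
        )
        for name in channel_names
    }
    records = []
    for i, region in enumerate(regions):
        ctcf = {
            name: compute_ctcf(region, image[channel_names.index(name)], backgrounds[name])
            for name in channel_names
        }
        records.append(
            CellRecord(
                cell_id=f"{sample_id}-{i:04d}",
                sample_id=sample_id,
                area=float(region.area),
                ctcf=ctcf,
            )
        )
    _flag_records(records, config, backgrounds)
    return records, backgrounds


def _flag_records(
    records: list[CellRecord], config: QuantConfig, backgrounds: dict[str, float]
) -> None:
    """Set DAPI-positivity and CD45-negativity flags in place.

    DAPI-positive: raw mean nuclear-channel intensity above
    ``dapi_positivity_factor x background`` (records store the corrected
    mean, so the test is ``corrected > (factor - 1) x background``).

    CD45-negative: two-class (KMeans) split of corrected CD45 mean intensity;
    a cell is negative when below the ``cd45_negativity_quantile`` quantile of
    the bright class. When the two classes are not separated (or there are
    fewer than 2 cells) the same absolute raw-intensity rule as for DAPI is
    applied to CD45 instead.
    """
    if not records:
        return
    bg_dapi = backgrounds.get("dapi", 0.0)
    bg_cd45 = backgrounds.get("cd45", 0.0)
    excess = config.dapi_positivity_factor - 1.0
    for rec in records:
        rec.is_dapi_positive = rec.mean_intensity["dapi"] > excess * bg_dapi

    cd45 = np.array([rec.mean_intensity["cd45"] for rec in records])
    threshold = None
    if len(records) >= 2 and np.ptp(cd45) > 0:
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(cd45.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
        bright = int(np.argmax(centers))
        within = np.concatenate(
            [cd45[km.labels_ == j] - centers[j] for j in (0, 1)]
        )
        # KMeans splits even unimodal data (center gap ~2.7 within-SDs); only
        # trust the 2-class split when the gap clearly exceeds that.
        if abs(centers[1] - centers[0]) > 4.0 * max(float(within.std()), 1e-12):
            bright_vals = cd45[km.labels_ == bright]
            threshold = float(np.quantile(bright_vals, config.cd45_negativity_quantile))
            # bright-cluster membership overrides the quantile guard (the
            # guard protects against borderline dim-cluster cells, not the
            # tail of the bright population), and "negative" additionally
            # requires near-background staining in absolute terms
            abs_thr = excess * bg_cd45 if bg_cd45 > 0 else np.inf
            for rec, val, lab in zip(records, cd45, km.labels_):
                rec.is_cd45_negative = bool(
                    lab != bright and val < threshold and val < abs_thr
                )
            return
    logger.warning(
        "CD45 two-class split not separable; falling back to absolute "
        "threshold of %.1f x background",
        config.dapi_positivity_factor,
    )
    threshold = excess * bg_cd45
    for rec in records:
        rec.is_cd45_negative = rec.mean_intensity["cd45"] < threshold


def identify_ctcs(
    records: list[CellRecord],
    config: QuantConfig = QuantConfig(),
    backgrounds: dict[str, float] | None = None,
) -> list[CellRecord]:
    """Return the CTCs (DAPI-positive and CD45-negative), preserving order.

    If the records are not yet flagged, ``backgrounds`` must be given so the
    flags can be computed here.
    """
    if any(r.is_ctc is None for r in records):
        if backgrounds is None:
            raise ConfigError("unflagged records: backgrounds required")
        _flag_records(records, config, backgrounds)
    return [r for r in records if r.is_ctc]
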