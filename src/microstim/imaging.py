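"""Synthetic two-channel microscopy rendering and ratio quantification.

Renders cell records into a nuclear-stain channel (bright nuclear disks)
and a reporter channel (cytoplasm disk with the nuclear region overwritten
at nuclear intensity), then recovers per-cell nuclear/cytoplasmic ratios by
Otsu segmentation of the nuclear channel and annulus sampling of the
reporter channel — a minimal, configurable stand-in for a full
image-cytometry pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import expand_labels

from .synthetic import CELL_COLUMNS

__all__ = [
    "ImagePair",
    "render_images",
    "segment_nuclei",
    "quantify_images",
    "NUCLEUS_RADIUS_UM",
    "CYTOPLASM_RADIUS_UM",
]

logger = logging.getLogger(__name__)

NUCLEUS_RADIUS_UM = 5.0
CYTOPLASM_RADIUS_UM = 9.0
ANNULUS_WIDTH_UM = 3.0
DEFAULT_PIXEL_SIZE_UM = 0.65
NUCLEAR_STAIN_INTENSITY = 3000.0
BACKGROUND_INTENSITY = 8.0
MIN_NUCLEUS_AREA_UM2 = 25.0
MAX_NUCLEUS_AREA_UM2 = 400.0


@dataclass(frozen=True)
class ImagePair:
    """Two-channel grayscale field of view (nuclear stain + reporter)."""

    nuclear: np.ndarray
    reporter: np.ndarray
    pixel_size_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nuclear.shape != self.reporter.shape:
            raise ValueError("channel dimensions must match")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def to_tiff(self, path) -> None:
        """Write as a 2-page 16-bit TIFF (page 1 nuclear, page 2 reporter)."""
        stack = np.stack(
            [
                np.clip(self.nuclear, 0, 65535).astype(np.uint16),
                np.clip(self.reporter, 0, 65535).astype(np.uint16),
            ]
        )
        tifffile.imwrite(path, stack, metadata={"pixel_size_um": self.pixel_size_um})

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> "ImagePair":
        stack = tifffile.imread(path)
        if stack.ndim != 3 or stack.shape[0] < 2:
            raise ValueError("expected a multi-page TIFF with nuclear + reporter pages")
        return cls(
            nuclear=stack[0].astype(float),
            reporter=stack[1].astype(float),
            pixel_size_um=pixel_size_um,
        )


def _paint_disk(img: np.ndarray, cx: float, cy: float, radius_px: float, value: float) -> None:
    """Overwrite a disk centred at (cx, cy) in pixel coordinates."""
    h, w = img.shape
    x0 = max(int(np.floor(cx - radius_px)) - 1, 0)
    x1 = min(int(np.ceil(cx + radius_px)) + 2, w)
    y0 = max(int(np.floor(cy - radius_px)) - 1, 0)
    y1 = min(int(np.ceil(cy + radius_px)) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    img[y0:y1, x0:x1][mask] = value


def render_images(
    cells: pd.DataFrame,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise_level: float = 1.0,
    seed: int | None = 0,
    field_width_um: float | None = None,
    field_height_um: float | None = None,
) -> ImagePair:
    """Render cell records into a synthetic two-channel image pair.

    Nuclei are bright disks (radius 5 um) in the nuclear channel.  The
    reporter channel paints a cytoplasm disk (radius 9 um) at the record's
    cytoplasmic intensity with the nuclear disk overwritten at nuclear
    intensity, so the painted nuclear/cytoplasmic ratio equals the
    record's ratio by construction.  Poisson shot noise is applied with
    photon scale 1/noise_level (``noise_level=0`` disables noise).
    Deterministic given ``seed``.
    """
    if not (0.2 <= pixel_size_um <= 2.0):
        raise ValueError("pixel_size_um must be within [0.2, 2] um/px")
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    if field_width_um is None:
        field_width_um = float(cells["x_um"].max()) + 3 * CYTOPLASM_RADIUS_UM if len(cells) else 100.0
    if field_height_um is None:
        field_height_um = float(cells["y_um"].max()) + 3 * CYTOPLASM_RADIUS_UM if len(cells) else 100.0
    w = int(np.ceil(field_width_um / pixel_size_um))
    h = int(np.ceil(field_height_um / pixel_size_um))
    nuclear = np.full((h, w), BACKGROUND_INTENSITY, dtype=float)
    reporter = np.full((h, w), BACKGROUND_INTENSITY, dtype=float)

    if len(cells):
        xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        tree = cKDTree(xy)
        pairs = tree.query_pairs(2 * NUCLEUS_RADIUS_UM)
        n_overlapping = len({i for pair in pairs for i in pair})
        if len(cells) > 1 and n_overlapping / len(cells) > 0.5:
            logger.warning(
                "more than half of rendered nuclei overlap (%d of %d within %g um)",
                n_overlapping,
                len(cells),
                2 * NUCLEUS_RADIUS_UM,
            )
        r_nuc = NUCLEUS_RADIUS_UM / pixel_size_um
        r_cyt = CYTOPLASM_RADIUS_UM / pixel_size_um
        for row in cells.itertuples():
            cx = row.x_um / pixel_size_um
            cy = row.y_um / pixel_size_um
            _paint_disk(reporter, cx, cy, r_cyt, row.cyt_intensity)
        for row in cells.itertuples():
            cx = row.x_um / pixel_size_um
            cy = row.y_um / pixel_size_um
            _paint_disk(nuclear, cx, cy, r_nuc, NUCLEAR_STAIN_INTENSITY)
            _paint_disk(reporter, cx, cy, r_nuc, row.nuc_intensity)

    if noise_level > 0:
        rng = np.random.default_rng(seed)
        scale = 1.0 / noise_level
        nuclear = rng.poisson(nuclear * scale) / scale
        reporter = rng.poisson(reporter * scale) / scale
    return ImagePair(nuclear=nuclear, reporter=reporter, pixel_size_um=pixel_size_um)


def segment_nuclei(
    nuclear_channel: np.ndarray, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> tuple[np.ndarray, pd.DataFrame]:
    """Otsu threshold + connected components + nucleus-size filter.

    Returns the integer-labeled mask and a centroid table (label, x_um,
    y_um, area_um2).  A blank (constant) image yields zero labels.
    """
    img = np.asarray(nuclear_channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    empty = pd.DataFrame(columns=["label", "x_um", "y_um", "area_um2"])
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=int), empty
    mask = img > threshold_otsu(img)
    labels = cc_label(mask)
    px_area = pixel_size_um**2
    out = np.zeros_like(labels)
    rows = []
    next_label = 0
    for prop in regionprops(labels):
        area_um2 = prop.area * px_area
        if not (MIN_NUCLEUS_AREA_UM2 <= area_um2 <= MAX_NUCLEUS_AREA_UM2):
            continue
        next_label += 1
        out[labels == prop.label] = next_label
        cy, cx = prop.centroid
        rows.append(
            {
                "label": next_label,
                "x_um": cx * pixel_size_um,
                "y_um": cy * pixel_size_um,
                "area_um2": area_um2,
            }
        )
    table = pd.DataFrame(rows, columns=empty.columns) if rows else empty
    return out, table


def quantify_images(pair: ImagePair) -> pd.DataFrame:
    """Per-nucleus reporter quantification into the standard per-cell table.

    Nuclear intensity is the mean reporter signal inside the nucleus mask;
    cytoplasmic intensity the mean in an annulus obtained by expanding the
    nucleus outward by 3 um, excluding all nuclear pixels (ring territory
    between abutting cells is split by proximity, so a neighbor's pixels
    are never counted).  Cells whose annulus is empty are flagged
    ``excluded`` and should be dropped from ratio statistics.
    """
    labels, table = segment_nuclei(pair.nuclear, pair.pixel_size_um)
    n = len(table)
    if n == 0:
        out = pd.DataFrame(columns=CELL_COLUMNS + ["excluded"])
        return out
    expand_px = ANNULUS_WIDTH_UM / pair.pixel_size_um
    expanded = expand_labels(labels, distance=expand_px)
    ring = np.where(labels == 0, expanded, 0)
    reporter = pair.reporter

    rows = []
    for row in table.itertuples():
        nuc_mask = labels == row.label
        ring_mask = ring == row.label
        nuc_mean = float(reporter[nuc_mask].mean())
        if ring_mask.any():
            cyt_mean = float(reporter[ring_mask].mean())
            ratio = nuc_mean / cyt_mean
            excluded = False
        else:
            cyt_mean = np.nan
            ratio = np.nan
            excluded = True
        rows.append(
            {
                "cell_id": row.label - 1,
                "x_um": row.x_um,
                "y_um": row.y_um,
                "nuc_intensity": nuc_mean,
                "cyt_intensity": cyt_mean,
                "nuc_cyt_ratio": ratio,
                "conc_nM": np.nan,
                "ground_truth": pd.NA,
                "called": pd.NA,
                "n_neighbors": pd.NA,
                "experiment_id": "",
                "excluded": excluded,
            }
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS + ["excluded"])
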