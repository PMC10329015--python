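"""Channel preprocessing, composite-channel feature segmentation, per-cell
quantification and a simple argmax phenotyper.

Percentile convention: all percentiles/quantiles in this package use linear
interpolation between order statistics (numpy's default), and the test
oracles share that convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as grey_closing, disk

from .containers import ClassMap, LabelMask, MultiplexImage, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CAP_PERCENTILE = 99.7  # standard cap before segmentation/display


def cap_percentile(image: MultiplexImage, q: float = DEFAULT_CAP_PERCENTILE) -> MultiplexImage:
    """Clip each channel at its own q-th percentile (default 99.7).

    Caps the hot-pixel tail of ion-count channels before segmentation or
    display; idempotent.
    """
    if not 0 < q <= 100:
        raise ValidationError("q must be in (0, 100]")
    out = {}
    for name, arr in image.channels.items():
        cap = np.percentile(arr, q)
        out[name] = np.minimum(arr, cap)
    return image.with_channels(out)


def normalize_tile_by_dsdna(
    image: MultiplexImage, dsdna_channel: str = "dsDNA", min_nonzero_frac: float = 0.01
) -> MultiplexImage:
    """Divide every channel by the median of the tile's nonzero dsDNA pixels.

    Removes cross-tile sensitivity fluctuations so anchoring profiles can be
    pooled across tiles.  The median is taken over *nonzero* pixels: count
    channels are zero-inflated and the raw median would often be 0.
    """
    if dsdna_channel not in image:
        raise ValidationError(
            f"channel {dsdna_channel!r} not present; have {image.channel_names}"
        )
    ds = image[dsdna_channel]
    nz = ds[ds > 0]
    if nz.size == 0:
        raise ValidationError(f"{dsdna_channel} channel is all zero; cannot normalize")
    if nz.size < min_nonzero_frac * ds.size:
        warnings.warn(
            f"only {nz.size / ds.size:.2%} of {dsdna_channel} pixels are nonzero; "
            "tile normalization may be unstable",
            stacklevel=2,
        )
    divisor = float(np.median(nz))
    return image.map_channels(lambda a: a / divisor)


def composite(
    image: MultiplexImage,
    markers: Sequence[str],
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Weighted pixelwise sum of channels (e.g. GLUT1 + vWF + Fibrinogen
    for vessels)."""
    if weights is None:
        weights = [1.0] * len(markers)
    if len(weights) != len(markers):
        raise ValidationError("weights must match markers in length")
    unknown = [m for m in markers if m not in image]
    if unknown:
        raise ValidationError(f"unknown markers {unknown}; have {image.channel_names}")
    out = np.zeros(image.shape, dtype=float)
    for m, w in zip(markers, weights):
        out += float(w) * image[m]
    return out


@dataclass
class SegmentationParams:
    """Blur/threshold/close/size-filter chain for non-nuclear features."""

    blur_sigma_px: float = 2.0
    threshold: "str | float" = "otsu"  # 'otsu' or an absolute value
    min_size_px: int = 25
    closing_radius_px: int = 1

    def __post_init__(self):
        if self.blur_sigma_px < 0 or self.min_size_px < 0 or self.closing_radius_px < 0:
            raise ValidationError("segmentation parameters must be nonnegative")


def segment_features(comp: np.ndarray, params: SegmentationParams | None = None) -> LabelMask:
    """Segment a composite channel into labelled objects.

    Gaussian blur -> threshold (Otsu or absolute) -> morphological closing
    -> 8-connected components -> drop objects smaller than ``min_size_px``.
    Labels are consecutive from 1 in raster order of each object's first
    pixel.  An empty foreground yields an empty mask (logged), not an error.
    """
    params = params or SegmentationParams()
    comp = np.asarray(comp, dtype=float)
    if (comp < 0).any():
        raise ValidationError("composite must be nonnegative")
    smoothed = (
        ndimage.gaussian_filter(comp, params.blur_sigma_px)
        if params.blur_sigma_px > 0
        else comp
    )
    if params.threshold == "otsu":
        if np.ptp(smoothed) == 0:
            logger.info("constant composite: empty foreground")
            return LabelMask(np.zeros(comp.shape, dtype=np.int32))
        thr = threshold_otsu(smoothed)
    else:
        thr = float(params.threshold)
    fg = smoothed > thr
    if params.closing_radius_px > 0:
        fg = grey_closing(fg, disk(params.closing_radius_px))
    if not fg.any():
        logger.info("empty foreground after thresholding")
        return LabelMask(np.zeros(comp.shape, dtype=np.int32))
    labels = cc_label(fg, connectivity=2)
    # size filter, then relabel consecutively; skimage assigns labels in
    # raster order of first pixel, and np.unique preserves that ordering
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= params.min_size_px)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return LabelMask(remap[labels])


def quantify_cells(image: MultiplexImage, cell_mask: LabelMask) -> pd.DataFrame:
    """Per-cell table: label, area, centroid, per-marker mean counts.

    Marker means appear as ``mean_<marker>`` columns.  An empty mask yields
    an empty table with the full header.
    """
    if cell_mask.shape != image.shape:
        raise ValidationError(
            f"mask shape {cell_mask.shape} does not match image {image.shape}"
        )
    labels = cell_mask.labels
    cols = ["label", "area_px", "centroid_row", "centroid_col"] + [
        f"mean_{m}" for m in image.channel_names
    ]
    if labels.size == 0:
        return pd.DataFrame(columns=cols)
    data = cell_mask.data
    areas = ndimage.sum_labels(np.ones_like(data), data, labels)
    centroids = np.array(ndimage.center_of_mass(np.ones_like(data), data, labels))
    out = {
        "label": labels,
        "area_px": areas.astype(int),
        "centroid_row": centroids[:, 0],
        "centroid_col": centroids[:, 1],
    }
    for name, arr in image.channels.items():
        out[f"mean_{name}"] = ndimage.mean(arr, data, labels)
    return pd.DataFrame(out, columns=cols)


def assign_classes_argmax(
    source: "pd.DataFrame | MultiplexImage",
    class_markers: Mapping[str, Sequence[str]],
) -> "pd.Series | ClassMap":
    """Assign each cell (table) or pixel (image) to the class with the
    largest summed marker signal.

    A deliberately simple stand-in for clustering-based phenotyping: ties
    break toward the first declared class, zero-signal entries stay
    unassigned (label 0 / empty string).
    """
    for cls, markers in class_markers.items():
        if not markers:
            raise ValidationError(f"class {cls!r} has an empty marker list")
    names = list(class_markers)

    if isinstance(source, MultiplexImage):
        h, w = source.shape
        scores = np.zeros((len(names), h, w))
        for i, cls in enumerate(names):
            for m in class_markers[cls]:
                if m not in source:
                    raise ValidationError(f"class {cls!r} references unknown marker {m!r}")
                scores[i] += source[m]
        best = np.argmax(scores, axis=0)  # first maximal index = declaration order
        total = scores.sum(axis=0)
        out = np.where(total > 0, best + 1, 0).astype(np.int32)
        return ClassMap(out, {i + 1: cls for i, cls in enumerate(names)})

    table = source
    score_cols = np.zeros((len(table), len(names)))
    for i, cls in enumerate(names):
        for m in class_markers[cls]:
            col = f"mean_{m}" if f"mean_{m}" in table.columns else m
            if col not in table.columns:
                raise ValidationError(f"class {cls!r} references unknown marker {m!r}")
            score_cols[:, i] += table[col].to_numpy(dtype=float)
    best = np.argmax(score_cols, axis=1)
    total = score_cols.sum(axis=1)
    assigned = np.where(total > 0, np.array(names, dtype=object)[best], "")
    return pd.Series(assigned, index=table.index, name="phenotype")
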