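"""Expansion-fold estimation, line-scan profiles, 16-84% edge resolution
and per-FOV channel sums.

Three independent fold estimators mirror the standard quantification
strategies for gel expansion: (1) *linear* — ratios of matched landmark
pair distances pre/post expansion, (2) *area* — square root of the tissue
area ratio, (3) *segmentation* — square root of the cell-size-distribution
ratio.  On an isotropically expanded sample all three agree with the true
linear fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist

from .containers import LabelMask, MultiplexImage, ValidationError


@dataclass
class LandmarkPairs:
    """Matched feature coordinates in a pre- and a post-expansion image."""

    pre: np.ndarray  # (n, 2) row/col px
    post: np.ndarray  # (n, 2) row/col px
    pixel_size_pre_um: float = 1.0
    pixel_size_post_um: float = 1.0

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape or self.pre.ndim != 2 or self.pre.shape[1] != 2:
            raise ValidationError("pre and post must be matched (n, 2) coordinate arrays")
        if not (np.isfinite(self.pre).all() and np.isfinite(self.post).all()):
            raise ValidationError("landmark coordinates must be finite")
        if len(self.pre) < 2:
            raise ValidationError("need at least 2 matched landmarks")


@dataclass
class FoldEstimate:
    method: str  # linear | area | segmentation
    fold: float
    dispersion: float  # sd across pairs/replicates where defined, else 0
    n: int

    def __post_init__(self):
        if self.fold <= 0:
            raise ValidationError("fold must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")


def fold_linear(pairs: LandmarkPairs) -> FoldEstimate:
    """Linear fold from all pairwise landmark distances.

    For every unordered landmark pair the physical post/pre distance ratio
    is computed; the estimate is the mean ratio with its sd.  Coincident
    pre-landmarks are skipped with a warning.
    """
    d_pre = pdist(pairs.pre) * pairs.pixel_size_pre_um
    d_post = pdist(pairs.post) * pairs.pixel_size_post_um
    ok = d_pre > 1e-12
    if not ok.all():
        warnings.warn(
            f"skipped {np.count_nonzero(~ok)} coincident pre-landmark pairs",
            stacklevel=2,
        )
    if not ok.any():
        raise ValidationError("all pre-landmark pairs are coincident")
    ratios = d_post[ok] / d_pre[ok]
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return FoldEstimate("linear", float(ratios.mean()), sd, int(ratios.size))


def _physical_area(mask: LabelMask, pixel_size_um: float) -> float:
    n = int(np.count_nonzero(mask.data))
    if n == 0:
        raise ValidationError("mask is empty")
    return n * pixel_size_um**2


def fold_area(
    mask_pre: LabelMask,
    mask_post: LabelMask,
    pixel_size_pre_um: float = 1.0,
    pixel_size_post_um: float = 1.0,
) -> FoldEstimate:
    """Linear fold as the square root of the physical tissue-area ratio."""
    a_pre = _physical_area(mask_pre, pixel_size_pre_um)
    a_post = _physical_area(mask_post, pixel_size_post_um)
    return FoldEstimate("area", float(np.sqrt(a_post / a_pre)), 0.0, 1)


def fold_segmentation(
    cells_pre: pd.DataFrame,
    cells_post: pd.DataFrame,
    statistic: str = "median",
    pixel_size_pre_um: float = 1.0,
    pixel_size_post_um: float = 1.0,
    min_cells: int = 20,
) -> FoldEstimate:
    """Linear fold from the cell-size distributions of two segmentations.

    ``sqrt(statistic(post areas) / statistic(pre areas))`` in physical
    units, with the statistic either the median (default, robust to
    segmentation tails) or the mean.
    """
    if statistic not in ("median", "mean"):
        raise ValidationError("statistic must be 'median' or 'mean'")
    if len(cells_pre) < min_cells or len(cells_post) < min_cells:
        raise ValidationError(
            f"need at least {min_cells} cells in each table, got "
            f"{len(cells_pre)} / {len(cells_post)}"
        )
    stat = np.median if statistic == "median" else np.mean
    a_pre = stat(cells_pre["area_px"].to_numpy() * pixel_size_pre_um**2)
    a_post = stat(cells_post["area_px"].to_numpy() * pixel_size_post_um**2)
    return FoldEstimate(
        "segmentation", float(np.sqrt(a_post / a_pre)), 0.0, min(len(cells_pre), len(cells_post))
    )


@dataclass
class LineProfile:
    """Intensity samples along a straight scan line.

    Positions are physical micrometres in the pre-expansion convention
    (pixel distance x pixel size / expansion fold).
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    positions_um: np.ndarray
    intensities: np.ndarray
    channel: str

    @property
    def length_um(self) -> float:
        return float(self.positions_um[-1] - self.positions_um[0])


def line_profile(
    image: MultiplexImage,
    channel: str,
    p0: tuple[float, float],
    p1: tuple[float, float],
    interpolation: str = "linear",
) -> LineProfile:
    """Sample a channel along the segment ``p0 -> p1`` at unit-pixel spacing.

    Bilinear interpolation by default (nearest behind a flag); the number
    of samples is ``floor(|p1 - p0|) + 1``.
    """
    if channel not in image:
        raise ValidationError(f"unknown channel {channel!r}")
    h, w = image.shape
    for name, (r, c) in (("p0", p0), ("p1", p1)):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValidationError(f"endpoint {name}={(r, c)} lies outside the image")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    dist = float(np.hypot(*(p1 - p0)))
    n = int(np.floor(dist)) + 1
    t = np.linspace(0.0, dist, n) if n > 1 else np.array([0.0])
    unit = (p1 - p0) / dist if dist > 0 else np.zeros(2)
    pts = p0[None, :] + t[:, None] * unit[None, :]
    order = 1 if interpolation == "linear" else 0
    vals = ndimage.map_coordinates(
        image[channel].astype(float), pts.T, order=order, mode="nearest"
    )
    positions = t * image.pixel_size_um / image.expansion_fold
    return LineProfile(tuple(p0), tuple(p1), positions, vals, channel)


@dataclass
class ResolutionEstimate:
    distances_um: np.ndarray
    mean_um: float
    sd_um: float
    n_scans: int


class EdgeProfileError(ValueError):
    """Raised when a line profile does not contain a usable single edge."""


def resolution_16_84(
    profile: LineProfile, plateau_frac: float = 0.10
) -> float:
    """16-84% edge-spread distance of a single-edge line profile.

    The low/high plateaus are the means of the first and last
    ``plateau_frac`` of samples; the crossings of
    ``low + 0.16 (high - low)`` and ``low + 0.84 (high - low)`` are located
    by linear interpolation and their separation returned in physical
    units.  For a Gaussian-blurred edge this distance equals ~2 sigma.
    Invariant to affine intensity transforms of the profile.
    """
    y = np.asarray(profile.intensities, dtype=float)
    x = np.asarray(profile.positions_um, dtype=float)
    n = y.size
    k = max(int(round(plateau_frac * n)), 1)
    if n < 2 * k + 2:
        raise EdgeProfileError("profile too short for plateau estimation")
    a, b = y[:k].mean(), y[-k:].mean()
    if a == b:
        raise EdgeProfileError("plateaus are equal: no edge in profile")
    if a > b:  # orient low -> high
        y = y[::-1]
        x = x[::-1] * -1  # keep positions increasing after flip
        x = x - x[0]
        a, b = b, a
    lo, hi = a, b
    # a usable profile crosses the mid-level exactly once (single edge)
    s = np.sign(y - (lo + 0.5 * (hi - lo)))
    s = s[s != 0]
    n_cross = int(np.count_nonzero(np.diff(s)))
    if n_cross != 1:
        raise EdgeProfileError(
            f"profile crosses the mid-level {n_cross} times; expected a single edge"
        )

    def crossing(level: float) -> float:
        above = y >= level
        idx = np.flatnonzero(above)
        if idx.size == 0 or idx[0] == 0:
            raise EdgeProfileError(
                f"profile never crosses the {level:.3g} level from below"
            )
        i = idx[0]
        x0, x1 = x[i - 1], x[i]
        y0, y1 = y[i - 1], y[i]
        return float(x0 + (level - y0) / (y1 - y0) * (x1 - x0))

    x16 = crossing(lo + 0.16 * (hi - lo))
    x84 = crossing(lo + 0.84 * (hi - lo))
    if x84 < x16:
        raise EdgeProfileError("profile is non-monotone between the 16% and 84% levels")
    return abs(x84 - x16)


def summarize_resolution(distances_um) -> ResolutionEstimate:
    d = np.asarray(
        [resolution_16_84(p) if isinstance(p, LineProfile) else float(p) for p in distances_um]
    )
    if d.size < 1:
        raise ValidationError("need at least one scan")
    if (d <= 0).any():
        raise ValidationError("16-84% distances must be positive")
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return ResolutionEstimate(d, float(d.mean()), sd, int(d.size))


def sum_channels(fovs, channels) -> pd.DataFrame:
    """Total ion counts per FOV per channel (signal-retention QC)."""
    rows = []
    for fov in fovs:
        missing = [c for c in channels if c not in fov]
        if missing:
            raise ValidationError(f"FOV {fov.fov_id!r} lacks channels {missing}")
        rows.append(
            {"fov_id": fov.fov_id, **{c: float(fov[c].sum()) for c in channels}}
        )
    return pd.DataFrame(rows, columns=["fov_id", *channels])


def screen_success_percent(n_passed: int, n_total: int) -> float:
    """Percentage of antibody clones passing a validation screen."""
    if n_total <= 0 or n_passed < 0 or n_passed > n_total:
        raise ValidationError("need 0 <= n_passed <= n_total with n_total > 0")
    return 100.0 * n_passed / n_total
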