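"""Deformation quantification between paired images: background
subtraction, landmark detection, affine + nonrigid alignment, and the
RMS-of-pairwise-distance-change curve versus measurement length.

The registration here is a self-contained multi-resolution SSD optimizer:
phase correlation initialises the translation, Powell refinement estimates
the full affine, and an optional nonrigid stage block-matches a coarse
control grid and spline-interpolates the offsets to a dense displacement
field.  An externally computed displacement field can be supplied in place
of estimation.

The affine stage removes global pose and scale; the nonrigid field
supplies point correspondence, so the residual pairwise distance changes
measure local distortion only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.interpolate import RectBivariateSpline
from scipy.spatial.distance import pdist
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation
from skimage.transform import rescale

from .containers import ValidationError
from .phantoms import WarpField

DEFAULT_ROLLING_BALL_RADIUS = 50  # px
DEFAULT_BIN_WIDTH_UM = 12.15
DEFAULT_N_BINS = 100
RECOMMENDED_MIN_LANDMARKS = 30


class RegistrationError(RuntimeError):
    pass


def rolling_ball_background(image: np.ndarray, radius_px: int = DEFAULT_ROLLING_BALL_RADIUS) -> np.ndarray:
    """Subtract a rolling-ball background (grayscale opening with a flat
    disk of the given radius); output floored at zero."""
    if radius_px < 1:
        raise ValidationError("radius_px must be >= 1")
    image = np.asarray(image, dtype=float)
    background = ndimage.grey_opening(image, footprint=disk(radius_px))
    return np.clip(image - background, 0.0, None)


@dataclass
class LandmarkSet:
    points: np.ndarray  # (n, 2) row/col px
    source: str = ""
    pixel_size_um: float = 1.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("points must be an (n, 2) array")


def detect_landmarks(
    image: np.ndarray,
    min_distance_px: float = 10.0,
    threshold_rel: float = 0.2,
    smooth_sigma_px: float = 2.0,
    source: str = "",
    pixel_size_um: float = 1.0,
) -> LandmarkSet:
    """Bright local maxima of the smoothed image, greedily thinned.

    Candidates above ``threshold_rel`` times the global maximum are kept in
    descending-intensity (then raster) order, each suppressing later
    candidates within ``min_distance_px``.
    """
    img = ndimage.gaussian_filter(np.asarray(image, dtype=float), smooth_sigma_px)
    if img.max(initial=0.0) <= 0:
        raise ValidationError("blank image: no landmarks; lower threshold_rel")
    mx = ndimage.maximum_filter(img, size=3, mode="nearest")
    cand = np.argwhere((img == mx) & (img >= threshold_rel * img.max()))
    if cand.size == 0:
        raise ValidationError("no landmarks found; lower threshold_rel")
    vals = img[cand[:, 0], cand[:, 1]]
    # descending intensity, ties in raster order (stable sort on raster-ordered argwhere)
    order = np.argsort(-vals, kind="stable")
    cand = cand[order]
    kept: list[np.ndarray] = []
    for p in cand:
        if all(np.hypot(*(p - q)) >= min_distance_px for q in kept):
            kept.append(p)
    return LandmarkSet(np.array(kept, dtype=float), source=source, pixel_size_um=pixel_size_um)


@dataclass
class AffineTransform2D:
    """Maps fixed-image coordinates to moving-image coordinates:
    ``y = M @ x + t`` with x, y as (row, col)."""

    matrix: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def from_params(cls, p: np.ndarray) -> "AffineTransform2D":
        return cls(np.array([[p[0], p[1]], [p[2], p[3]]]), np.array([p[4], p[5]]))

    def params(self) -> np.ndarray:
        return np.array([*self.matrix.ravel(), *self.translation])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.matrix.T + self.translation

    @property
    def scale(self) -> float:
        """Isotropic scale component (sqrt of |det|)."""
        return float(np.sqrt(abs(np.linalg.det(self.matrix))))


def _warp_affine(moving: np.ndarray, tf: AffineTransform2D, shape) -> np.ndarray:
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    pts = tf.apply(np.stack([rr.ravel(), cc.ravel()], axis=1))
    return ndimage.map_coordinates(
        moving, [pts[:, 0].reshape(h, w), pts[:, 1].reshape(h, w)], order=1, mode="nearest"
    )


def _ssd(fixed: np.ndarray, moving: np.ndarray, tf: AffineTransform2D) -> float:
    return float(np.mean((fixed - _warp_affine(moving, tf, fixed.shape)) ** 2))


@dataclass
class RegistrationResult:
    affine: AffineTransform2D
    field: WarpField | None
    registered: np.ndarray
    diagnostics: dict

    @property
    def translation(self) -> np.ndarray:
        return self.affine.translation


def _fit_affine(fixed: np.ndarray, moving: np.ndarray, levels=(4, 2, 1)) -> tuple[AffineTransform2D, dict]:
    # translation init by phase correlation at full resolution
    shift, _, _ = phase_cross_correlation(fixed, moving, upsample_factor=10, normalization=None)
    # moving(x + s) ~= fixed(x) when moving is fixed shifted by -s; the pull
    # convention wants y = x + t with t = -shift
    tf = AffineTransform2D(np.eye(2), -np.asarray(shift, dtype=float))
    loss0 = _ssd(fixed, moving, AffineTransform2D.identity())
    history = [loss0]
    for lv in levels:
        if lv > 1:
            f = rescale(fixed, 1.0 / lv, anti_aliasing=True, preserve_range=True)
            m = rescale(moving, 1.0 / lv, anti_aliasing=True, preserve_range=True)
            # coordinates scale with the level; center-free convention keeps
            # the matrix unchanged and divides the translation
            tf_lv = AffineTransform2D(tf.matrix.copy(), tf.translation / lv)
        else:
            f, m = fixed, moving
            tf_lv = tf

        def loss(p):
            return _ssd(f, m, AffineTransform2D.from_params(p))

        res = optimize.minimize(
            loss, tf_lv.params(), method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000},
        )
        tf_lv = AffineTransform2D.from_params(res.x)
        tf = AffineTransform2D(tf_lv.matrix, tf_lv.translation * lv)
        history.append(_ssd(fixed, moving, tf))
    if history[-1] > history[0] * (1 + 1e-9) and history[0] > 0:
        raise RegistrationError(
            f"affine optimization did not reduce the SSD loss: {history}"
        )
    return tf, {"ssd_history": history}


def _fit_nonrigid(
    fixed: np.ndarray,
    resampled: np.ndarray,
    control_spacing_px: float,
    upsample: int = 50,
    n_iter: int = 6,
) -> WarpField:
    """Iterative block-matching on a control grid, spline-interpolated to
    all pixels.

    ``resampled`` is the moving image already pulled through the affine, so
    the estimated field is the residual (nonrigid) displacement in fixed
    coordinates.  Each iteration phase-correlates windows around the
    control points between the fixed image and the current correction of
    ``resampled``, accumulates the offsets, and re-corrects; the fixed
    point of this scheme is the exact forward displacement of the content.
    """
    h, w = fixed.shape
    half = int(control_spacing_px)
    grid_r = np.arange(half, h - half + 1, int(control_spacing_px), dtype=float)
    grid_c = np.arange(half, w - half + 1, int(control_spacing_px), dtype=float)
    if grid_r.size < 2 or grid_c.size < 2:
        raise RegistrationError("image too small for the requested control spacing")
    kr = min(3, grid_r.size - 1)
    kc = min(3, grid_c.size - 1)
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")

    dr = np.zeros((h, w))
    dc = np.zeros((h, w))
    cur = resampled
    resid = [float(np.sqrt(np.mean((cur - fixed) ** 2)))]
    for _ in range(n_iter):
        offsets = np.zeros((grid_r.size, grid_c.size, 2))
        for i, r in enumerate(grid_r):
            for j, c in enumerate(grid_c):
                r0, r1 = int(r - half), int(r + half)
                c0, c1 = int(c - half), int(c + half)
                fwin = fixed[r0:r1, c0:c1]
                mwin = cur[r0:r1, c0:c1]
                if fwin.std() == 0 or mwin.std() == 0:
                    continue
                shift, _, _ = phase_cross_correlation(
                    fwin, mwin, upsample_factor=upsample, normalization=None
                )
                # window content displaced by d relative to fixed gives shift ~= -d
                offsets[i, j] = -np.asarray(shift)
        dr += RectBivariateSpline(grid_r, grid_c, offsets[:, :, 0], kx=kr, ky=kc)(rows, cols)
        dc += RectBivariateSpline(grid_r, grid_c, offsets[:, :, 1], kx=kr, ky=kc)(rows, cols)
        cur = ndimage.map_coordinates(resampled, [rr + dr, cc + dc], order=1, mode="nearest")
        resid.append(float(np.sqrt(np.mean((cur - fixed) ** 2))))
    if resid[-1] > resid[0] * (1 + 1e-9) and resid[0] > 0:
        raise RegistrationError(
            f"nonrigid refinement did not reduce the residual: {resid}"
        )
    mag = float(np.hypot(dr, dc).max(initial=0.0))
    return WarpField(d_row=dr, d_col=dc, max_magnitude_px=mag,
                     control_spacing_px=float(control_spacing_px))


def register(
    fixed: np.ndarray,
    moving: np.ndarray,
    stage: str = "affine+nonrigid",
    control_spacing_px: float = 16.0,
    known_field: WarpField | None = None,
    upsample: int = 50,
    n_iter: int = 6,
) -> RegistrationResult:
    """Align ``moving`` onto ``fixed``.

    The affine stage minimises the mean squared intensity difference over a
    resolution pyramid; the nonrigid stage estimates a smooth residual
    displacement field on a control grid.  Passing ``known_field`` skips
    all estimation and uses the supplied ground-truth field with an
    identity affine (escape hatch for externally registered pairs).
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValidationError("fixed and moving must share one shape")
    if stage not in ("affine", "affine+nonrigid"):
        raise ValidationError("stage must be 'affine' or 'affine+nonrigid'")

    if known_field is not None:
        return RegistrationResult(
            affine=AffineTransform2D.identity(),
            field=known_field,
            registered=moving,
            diagnostics={"mode": "external-field"},
        )

    tf, diag = _fit_affine(fixed, moving)
    resampled = _warp_affine(moving, tf, fixed.shape)
    field = None
    if stage == "affine+nonrigid":
        field = _fit_nonrigid(
            fixed, resampled, control_spacing_px, upsample=upsample, n_iter=n_iter
        )
    return RegistrationResult(affine=tf, field=field, registered=resampled, diagnostics=diag)


@dataclass
class DistortionCurve:
    """RMS pairwise-distance change binned by measurement length."""

    bin_edges_um: np.ndarray  # (n_bins + 1,)
    rms_um: np.ndarray  # (n_bins,), NaN where no pairs
    n_pairs: np.ndarray  # (n_bins,)
    sd_um: np.ndarray | None = None  # across replicates, after aggregation

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "bin_center_um": self.bin_centers_um,
                "rms_um": self.rms_um,
                "n_pairs": self.n_pairs,
            }
        )
        if self.sd_um is not None:
            out["sd_um"] = self.sd_um
        return out


def rms_vs_length(
    landmarks_pre: LandmarkSet,
    mapped_post: np.ndarray,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    n_bins: int = DEFAULT_N_BINS,
) -> DistortionCurve:
    """RMS of absolute pairwise-distance changes, binned by pre distance.

    ``mapped_post`` holds the affine-aligned post positions in
    correspondence with ``landmarks_pre`` (same count and order); for every
    unordered pair the change ``|L - L'|`` between pre and post physical
    distances is binned by ``L`` into ``n_bins`` bins of ``bin_width_um``.
    """
    if bin_width_um <= 0:
        raise ValidationError("bin_width_um must be positive")
    pre = landmarks_pre.points
    post = np.asarray(mapped_post, dtype=float)
    if post.shape != pre.shape:
        raise ValidationError("mapped_post must match landmarks_pre in count and order")
    if len(pre) < 2:
        raise ValidationError("need at least 2 landmarks")
    if len(pre) < RECOMMENDED_MIN_LANDMARKS:
        warnings.warn(
            f"only {len(pre)} landmarks; >= {RECOMMENDED_MIN_LANDMARKS} recommended",
            stacklevel=2,
        )
    px = landmarks_pre.pixel_size_um
    L = pdist(pre) * px
    Lp = pdist(post) * px
    err = np.abs(L - Lp)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_um
    idx = np.floor(L / bin_width_um).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    rms = np.full(n_bins, np.nan)
    npairs = np.zeros(n_bins, dtype=int)
    sums = np.bincount(idx[ok], weights=err[ok] ** 2, minlength=n_bins)
    cnts = np.bincount(idx[ok], minlength=n_bins)
    nz = cnts > 0
    rms[nz] = np.sqrt(sums[nz] / cnts[nz])
    npairs[:] = cnts
    return DistortionCurve(bin_edges_um=edges, rms_um=rms, n_pairs=npairs)


def aggregate_curves(curves) -> DistortionCurve:
    """Mean +/- sd of replicate RMS curves per bin; empty bins of a
    replicate are excluded from that bin's aggregation."""
    curves = list(curves)
    if not curves:
        raise ValidationError("need at least one curve")
    edges = curves[0].bin_edges_um
    for c in curves[1:]:
        if c.bin_edges_um.shape != edges.shape or not np.allclose(c.bin_edges_um, edges):
            raise ValidationError("curves have mismatched binning")
    stack = np.stack([c.rms_um for c in curves])
    counts = np.stack([c.n_pairs for c in curves])
    valid = counts > 0
    nrep = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(nrep > 0, np.nansum(np.where(valid, stack, 0.0), axis=0) / np.maximum(nrep, 1), np.nan)
        dev = np.where(valid, (stack - mean) ** 2, 0.0)
        sd = np.where(nrep > 1, np.sqrt(dev.sum(axis=0) / np.maximum(nrep - 1, 1)), 0.0)
        sd = np.where(nrep > 0, sd, np.nan)
    return DistortionCurve(
        bin_edges_um=edges,
        rms_um=mean,
        n_pairs=counts.sum(axis=0),
        sd_um=sd,
    )


def distortion_curve(
    fixed: np.ndarray,
    moving: np.ndarray | None = None,
    known_field: WarpField | None = None,
    pixel_size_um: float = 1.0,
    background_radius_px: int | None = DEFAULT_ROLLING_BALL_RADIUS,
    landmark_kwargs: dict | None = None,
    control_spacing_px: float = 16.0,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    n_bins: int = DEFAULT_N_BINS,
    border_margin_px: float | None = None,
    include_affine: bool = False,
) -> tuple[DistortionCurve, RegistrationResult, LandmarkSet]:
    """End-to-end distortion measurement for one image pair.

    Background-subtract, detect landmarks on the fixed image, register
    (or accept a known field), displace the landmarks through the residual
    nonrigid field, and bin the pairwise distance changes.

    Landmarks closer than ``border_margin_px`` (default: the control
    spacing) to the image border are dropped: the estimated field is only
    supported inside the control grid.  With ``include_affine`` the mapped
    positions additionally pass through the fitted affine, so the curve
    measures the *total* distance change rather than the residual
    (nonrigid) one — appropriate when the pair is known to share a mount.
    """
    fixed = np.asarray(fixed, dtype=float)
    if background_radius_px:
        fixed_bg = rolling_ball_background(fixed, background_radius_px)
    else:
        fixed_bg = fixed
    lm = detect_landmarks(fixed_bg, pixel_size_um=pixel_size_um, **(landmark_kwargs or {}))
    margin = control_spacing_px if border_margin_px is None else border_margin_px
    if margin > 0:
        h, w = fixed.shape
        p = lm.points
        keep = (
            (p[:, 0] >= margin)
            & (p[:, 0] <= h - 1 - margin)
            & (p[:, 1] >= margin)
            & (p[:, 1] <= w - 1 - margin)
        )
        lm = LandmarkSet(p[keep], source=lm.source, pixel_size_um=lm.pixel_size_um)
    if known_field is not None:
        reg = register(fixed, fixed if moving is None else moving, known_field=known_field)
    else:
        if moving is None:
            raise ValidationError("need either a moving image or a known_field")
        mv = rolling_ball_background(np.asarray(moving, float), background_radius_px) if background_radius_px else moving
        reg = register(fixed_bg, mv, stage="affine+nonrigid", control_spacing_px=control_spacing_px)
    if reg.field is not None:
        mapped = reg.field.displace_points(lm.points)
    else:
        mapped = lm.points
    if include_affine:
        mapped = reg.affine.apply(mapped)
    curve = rms_vs_length(lm, mapped, bin_width_um=bin_width_um, n_bins=n_bins)
    return curve, reg, lm
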