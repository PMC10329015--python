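"""Synthetic phantom generation with known ground truth.

Everything the measurement modules assume about real data is emulated here
with analytically known structure: circular vessel cross-sections carrying
concentric marker layers at known signed radial offsets, packed nuclear
fields with controllable size distributions, Poisson ion-count noise, known
expansion rescaling, and smooth nonlinear warp fields of bounded magnitude.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from skimage.transform import resize

from .containers import LabelMask, MultiplexImage, ValidationError


@dataclass
class Vessel:
    """One circular vessel cross-section.

    The vessel *object* (what segmentation would find) is the lumen disc
    dilated by the wall thickness, i.e. a disc of radius
    ``lumen_radius_px + wall_thickness_px``.
    """

    center: tuple[float, float]  # (row, col), px
    lumen_radius_px: float
    wall_thickness_px: float

    @property
    def object_radius_px(self) -> float:
        return self.lumen_radius_px + self.wall_thickness_px


@dataclass
class Layer:
    """A concentric marker layer around the vessel object boundary.

    ``offset_px`` is the signed radial offset of the layer centre measured
    outward from the object boundary (negative = inside the object).  The
    layer occupies the annulus of signed boundary distance
    ``[offset - thickness/2, offset + thickness/2]`` with mean intensity
    ``amplitude`` counts/px.
    """

    marker: str
    offset_px: float
    thickness_px: float
    amplitude: float


@dataclass
class PhantomSpec:
    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 0.39
    vessels: list[Vessel] = field(default_factory=list)
    layers: list[Layer] = field(default_factory=list)
    background_rate: float = 0.0
    seed: int = 0
    border_safe: bool = True

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.background_rate < 0:
            raise ValidationError("background_rate must be >= 0")
        names = [la.marker for la in self.layers]
        if len(set(names)) != len(names):
            raise ValidationError("layer marker names must be unique")
        for la in self.layers:
            if la.thickness_px <= 0:
                raise ValidationError(f"layer {la.marker!r}: thickness must be > 0")
            if la.amplitude < 0:
                raise ValidationError(f"layer {la.marker!r}: amplitude must be >= 0")
        for i, v in enumerate(self.vessels):
            if v.lumen_radius_px <= 0 or v.wall_thickness_px <= 0:
                raise ValidationError(f"vessel {i}: radii must be positive")
            if self.border_safe:
                r, c = v.center
                R = v.object_radius_px
                if (
                    r - R < 0
                    or c - R < 0
                    or r + R > self.height_px - 1
                    or c + R > self.width_px - 1
                ):
                    raise ValidationError(
                        f"vessel {i} violates border_safe: disc of radius "
                        f"{R:.1f} at {(r, c)} exits the image"
                    )


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def signed_boundary_distance(obj: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Signed distance from the object boundary.

    Positive outside the object, negative inside (the ring-index
    convention of the anchoring analysis).  ``metric='chessboard'`` uses
    the chessboard distance, which is the metric induced by unit dilation
    with a 3x3 square structuring element — layers defined in it land on
    exact anchoring step indices.
    """
    obj = obj.astype(bool)
    if metric == "euclidean":
        outside = ndimage.distance_transform_edt(~obj)
        inside = ndimage.distance_transform_edt(obj)
    elif metric == "chessboard":
        outside = ndimage.distance_transform_cdt(~obj, metric="chessboard")
        inside = ndimage.distance_transform_cdt(obj, metric="chessboard")
    else:
        raise ValidationError("metric must be 'euclidean' or 'chessboard'")
    return (outside - inside).astype(float)


def make_vessel_phantom(
    spec: PhantomSpec, noise: bool = False, metric: str = "euclidean"
) -> tuple[MultiplexImage, LabelMask, dict[str, float]]:
    """Render a vessel phantom with concentric marker layers.

    Returns the multichannel image (expected counts, or Poisson samples if
    ``noise``), the vessel label mask, and the ground-truth map of marker
    name to signed radial offset.  ``metric`` selects the signed-distance
    metric in which the layer offsets are interpreted.
    """
    spec.validate()
    shape = (spec.height_px, spec.width_px)
    labels = np.zeros(shape, dtype=np.int32)
    per_vessel_sdist = []
    for i, v in enumerate(spec.vessels):
        disc = _disc_mask(shape, v.center, v.object_radius_px)
        overlap = labels[disc]
        if (overlap > 0).any():
            j = int(overlap[overlap > 0][0]) - 1
            raise ValidationError(f"vessel {i} overlaps vessel {j}")
        labels[disc] = i + 1
        per_vessel_sdist.append(signed_boundary_distance(disc, metric=metric))

    channels: dict[str, np.ndarray] = {}
    for la in spec.layers:
        img = np.full(shape, float(spec.background_rate))
        lo = la.offset_px - la.thickness_px / 2.0
        hi = la.offset_px + la.thickness_px / 2.0
        for sdist in per_vessel_sdist:
            img[(sdist >= lo) & (sdist <= hi)] = la.amplitude
        channels[la.marker] = img
    if not channels:
        # layer-free spec still yields one background channel so the image
        # container is non-empty
        channels["background"] = np.full(shape, float(spec.background_rate))

    image = MultiplexImage(
        channels, pixel_size_um=spec.pixel_size_um, fov_id=f"phantom-{spec.seed}"
    )
    if noise:
        image = add_poisson_noise(image, seed=spec.seed)
    truth = {la.marker: la.offset_px for la in spec.layers}
    return image, LabelMask(labels), truth


def grid_vessel_centers(
    n: int, shape: tuple[int, int], spacing_px: float, margin_px: float
) -> list[tuple[float, float]]:
    """Lay out up to ``n`` vessel centers on a regular grid inside a margin."""
    h, w = shape
    rows = np.arange(margin_px, h - margin_px + 1e-9, spacing_px)
    cols = np.arange(margin_px, w - margin_px + 1e-9, spacing_px)
    centers = [(float(r), float(c)) for r in rows for c in cols]
    if len(centers) < n:
        raise ValidationError(
            f"grid of spacing {spacing_px} fits only {len(centers)} vessels, "
            f"{n} requested"
        )
    return centers[:n]


def make_cell_field(
    n_cells: int,
    shape: tuple[int, int],
    mean_area_px: float = 100.0,
    area_cv: float = 0.3,
    seed: int = 0,
    nuclear_amplitudes: dict[str, float] | None = None,
    max_retries_per_cell: int = 200,
) -> tuple[MultiplexImage, LabelMask]:
    """Pack circular nuclei with lognormal areas into an image.

    The returned image carries nuclear channels (default ``HistoneH3`` and
    ``dsDNA``) that are positive exactly on cell pixels (noise-free expected
    counts); apply :func:`add_poisson_noise` to obtain count realisations.
    Placement is rejection sampling with bounded retries; if fewer than
    ``n_cells`` fit, a warning is issued and the mask holds fewer labels.
    """
    if n_cells < 0:
        raise ValidationError("n_cells must be >= 0")
    h, w = shape
    if n_cells * mean_area_px >= 0.5 * h * w:
        raise ValidationError(
            f"infeasible packing: {n_cells} cells x {mean_area_px} px exceeds "
            f"half the image area {h * w}"
        )
    rng = np.random.default_rng(seed)
    if area_cv > 0:
        sigma2 = np.log1p(area_cv**2)
        mu = np.log(mean_area_px) - sigma2 / 2.0
        areas = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_cells)
    else:
        areas = np.full(n_cells, float(mean_area_px))
    radii = np.sqrt(areas / np.pi)

    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    placed = 0
    for radius in radii:
        ok = False
        for _ in range(max_retries_per_cell):
            r = rng.uniform(radius, h - 1 - radius)
            c = rng.uniform(radius, w - 1 - radius)
            disc = _disc_mask(shape, (r, c), radius)
            if not (occupied & disc).any():
                placed += 1
                labels[disc] = placed
                occupied |= disc
                ok = True
                break
        if not ok:
            warnings.warn(
                f"placed only {placed} of {n_cells} cells after bounded retries",
                stacklevel=2,
            )
            break

    nuclear_amplitudes = nuclear_amplitudes or {"HistoneH3": 50.0, "dsDNA": 100.0}
    fg = labels > 0
    channels = {
        name: np.where(fg, float(amp), 0.0) for name, amp in nuclear_amplitudes.items()
    }
    image = MultiplexImage(channels, fov_id=f"cells-{seed}")
    return image, LabelMask(labels)


def apply_scale(
    obj: "MultiplexImage | LabelMask",
    fold: float,
    interpolation: Literal["nearest", "linear"] = "linear",
):
    """Rescale an image or mask by a known linear expansion fold.

    The pixel grid grows by ``fold``; ``pixel_size_um`` is unchanged (the
    grid pitch is an instrument property) while the ``expansion_fold``
    annotation is multiplied.  Masks must use nearest-neighbour
    interpolation so label identities survive.
    """
    if fold < 1:
        raise ValidationError("fold must be >= 1")
    if isinstance(obj, LabelMask):
        if interpolation != "nearest":
            raise ValidationError("label masks must be scaled with interpolation='nearest'")
        out_shape = tuple(int(round(fold * s)) for s in obj.shape)
        data = resize(
            obj.data, out_shape, order=0, preserve_range=True, anti_aliasing=False
        ).astype(obj.data.dtype)
        return LabelMask(data)
    order = 0 if interpolation == "nearest" else 1
    out_shape = tuple(int(round(fold * s)) for s in obj.shape)
    channels = {
        name: resize(
            arr.astype(float), out_shape, order=order, preserve_range=True,
            anti_aliasing=False,
        )
        for name, arr in obj.channels.items()
    }
    return MultiplexImage(
        channels,
        pixel_size_um=obj.pixel_size_um,
        expansion_fold=obj.expansion_fold * fold,
        fov_id=obj.fov_id,
    )


@dataclass
class WarpField:
    """Dense 2-D displacement field (row, col offsets in px).

    The convention is *forward*: content at point ``p`` of the source image
    appears near ``p + d(p)`` in the warped image, and
    :meth:`displace_points` maps source landmarks accordingly.  For the
    smooth, small-amplitude fields used here the pull-sampling in
    :func:`apply_warp` is consistent with this to first order.
    """

    d_row: np.ndarray
    d_col: np.ndarray
    max_magnitude_px: float
    control_points: np.ndarray | None = None  # (n_r, n_c, 2) control offsets
    control_spacing_px: float | None = None

    def __post_init__(self):
        if self.d_row.shape != self.d_col.shape:
            raise ValidationError("displacement planes must share one shape")
        mag = np.hypot(self.d_row, self.d_col)
        if mag.max(initial=0.0) > self.max_magnitude_px + 1e-9:
            raise ValidationError("displacement exceeds declared max_magnitude_px")

    @property
    def shape(self) -> tuple[int, int]:
        return self.d_row.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.d_row, self.d_col)

    def displace_points(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) source positions through the field (bilinear sample)."""
        pts = np.asarray(points, dtype=float)
        coords = pts.T  # (2, n) as (rows, cols)
        dr = ndimage.map_coordinates(self.d_row, coords, order=1, mode="nearest")
        dc = ndimage.map_coordinates(self.d_col, coords, order=1, mode="nearest")
        return pts + np.stack([dr, dc], axis=1)


def make_smooth_warp(
    shape: tuple[int, int],
    control_spacing_px: float = 32.0,
    amplitude_px: float = 3.0,
    seed: int = 0,
) -> WarpField:
    """Draw a C1-smooth random displacement field of bounded magnitude.

    Random offsets on a coarse control grid are interpolated by a bicubic
    spline to every pixel; the dense field is then rescaled so its maximum
    displacement magnitude equals ``amplitude_px`` (or is zero).
    """
    if control_spacing_px < 4:
        raise ValidationError("control_spacing_px must be >= 4")
    if amplitude_px < 0:
        raise ValidationError("amplitude_px must be >= 0")
    h, w = shape
    rng = np.random.default_rng(seed)
    # control grid with one knot beyond each border so the spline covers
    # the full pixel range
    gr = np.arange(-control_spacing_px, h + 2 * control_spacing_px, control_spacing_px)
    gc = np.arange(-control_spacing_px, w + 2 * control_spacing_px, control_spacing_px)
    ctrl = rng.uniform(-1.0, 1.0, size=(gr.size, gc.size, 2))
    if amplitude_px == 0:
        dr = np.zeros(shape)
        dc = np.zeros(shape)
        ctrl[:] = 0.0
    else:
        rows = np.arange(h, dtype=float)
        cols = np.arange(w, dtype=float)
        kr = min(3, gr.size - 1)
        kc = min(3, gc.size - 1)
        dr = RectBivariateSpline(gr, gc, ctrl[:, :, 0], kx=kr, ky=kc)(rows, cols)
        dc = RectBivariateSpline(gr, gc, ctrl[:, :, 1], kx=kr, ky=kc)(rows, cols)
        mag = np.hypot(dr, dc).max()
        if mag > 0:
            scale = amplitude_px / mag
            dr *= scale
            dc *= scale
            ctrl *= scale
    return WarpField(
        d_row=dr,
        d_col=dc,
        max_magnitude_px=float(amplitude_px),
        control_points=ctrl,
        control_spacing_px=float(control_spacing_px),
    )


def apply_warp(
    image: MultiplexImage,
    fld: WarpField,
    interpolation: Literal["nearest", "linear"] = "linear",
) -> MultiplexImage:
    """Resample an image through a displacement field by reverse mapping.

    Output pixel ``x`` samples the input at ``x - d(x)``, so features move
    *forward* by approximately ``+d``.
    """
    if fld.shape != image.shape:
        raise ValidationError(
            f"warp field shape {fld.shape} does not match image {image.shape}"
        )
    h, w = image.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    coords = np.stack([rr - fld.d_row, cc - fld.d_col])
    order = 0 if interpolation == "nearest" else 1
    channels = {
        name: np.clip(
            ndimage.map_coordinates(arr.astype(float), coords, order=order, mode="nearest"),
            0.0,
            None,
        )
        for name, arr in image.channels.items()
    }
    return image.with_channels(channels)


def add_poisson_noise(image: MultiplexImage, seed: int = 0) -> MultiplexImage:
    """Sample each pixel of each channel from Poisson(expected counts)."""
    rng = np.random.default_rng(seed)
    channels = {}
    for name, arr in image.channels.items():
        if (arr < 0).any():
            raise ValidationError(f"channel {name!r} has negative expected counts")
        channels[name] = rng.poisson(arr).astype(np.float64)
    return image.with_channels(channels)
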