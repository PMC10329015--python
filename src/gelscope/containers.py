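"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* coordinates are ``(row, col)``, 0-based, with pixel centers at integer
  positions;
* physical distances are ``pixel distance * pixel_size_um``;
* "pre-expansion" distances are additionally divided by ``expansion_fold``
  (the scale-bar convention of expansion-gel imaging, where the acquired
  grid lives in expanded-gel space but biology is reported at tissue scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_2d(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr


class MultiplexImage:
    """A stack of named ion-count channels on one shared pixel grid.

    Parameters
    ----------
    channels
        Ordered mapping of marker name to a 2-D non-negative array of
        (expected or observed) ion counts per pixel.
    pixel_size_um
        Physical pixel pitch of the acquisition grid, in micrometres per
        pixel (gel-space for expanded samples).
    expansion_fold
        Linear magnification of the gel relative to the original tissue;
        1.0 for unexpanded samples.
    fov_id
        Free-form identifier of the field of view.
    """

    def __init__(
        self,
        channels: Mapping[str, np.ndarray],
        pixel_size_um: float = 1.0,
        expansion_fold: float = 1.0,
        fov_id: str = "fov",
    ):
        if pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if expansion_fold < 1:
            raise ValidationError("expansion_fold must be >= 1")
        self._channels: dict[str, np.ndarray] = {}
        shape = None
        for name, arr in channels.items():
            arr = _check_2d(arr, f"channel {name!r}")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValidationError(
                    f"channel {name!r} has shape {arr.shape}, expected {shape}"
                )
            if np.isnan(arr).any():
                raise ValidationError(f"channel {name!r} contains NaN pixels")
            if (arr < 0).any():
                raise ValidationError(f"channel {name!r} contains negative counts")
            self._channels[name] = arr
        if shape is None:
            raise ValidationError("MultiplexImage needs at least one channel")
        self.pixel_size_um = float(pixel_size_um)
        self.expansion_fold = float(expansion_fold)
        self.fov_id = str(fov_id)

    # -- mapping-ish surface -------------------------------------------------
    @property
    def channel_names(self) -> list[str]:
        return list(self._channels)

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return self._channels

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self._channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self._channels:
            raise KeyError(
                f"channel {name!r} not present; have {self.channel_names}"
            )
        return self._channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self._channels

    def __iter__(self):
        return iter(self._channels)

    def with_channels(self, channels: Mapping[str, np.ndarray]) -> "MultiplexImage":
        """Return a copy carrying ``channels`` and this image's metadata."""
        return MultiplexImage(
            channels,
            pixel_size_um=self.pixel_size_um,
            expansion_fold=self.expansion_fold,
            fov_id=self.fov_id,
        )

    def map_channels(self, fn) -> "MultiplexImage":
        return self.with_channels({k: fn(v) for k, v in self._channels.items()})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        h, w = self.shape
        return (
            f"<MultiplexImage {self.fov_id!r} {len(self._channels)} channels "
            f"{h}x{w} px, {self.pixel_size_um} um/px, fold {self.expansion_fold}>"
        )


class LabelMask:
    """Integer-labelled objects on a pixel grid; 0 is background."""

    def __init__(self, data: np.ndarray):
        data = _check_2d(data, "label mask")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValidationError(
                f"label mask must be integer-typed, got {data.dtype}"
            )
        if (data < 0).any():
            raise ValidationError("label mask contains negative labels")
        self.data = data

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of the positive labels present."""
        u = np.unique(self.data)
        return u[u > 0]

    def __eq__(self, other):  # mask == label gives a boolean array, like ndarray
        return self.data == other

    def __hash__(self):
        return id(self)

    def area(self, label: int) -> int:
        return int(np.count_nonzero(self.data == label))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<LabelMask {self.shape} with {self.labels.size} objects>"


class ClassMap:
    """Per-pixel class assignment with a class-id -> name dictionary.

    0 means unassigned; every nonzero pixel value must be declared in
    ``class_names``.
    """

    def __init__(self, data: np.ndarray, class_names: Mapping[int, str]):
        data = _check_2d(data, "class map")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValidationError("class map must be integer-typed")
        if (data < 0).any():
            raise ValidationError("class map contains negative ids")
        self.class_names = {int(k): str(v) for k, v in class_names.items()}
        present = set(np.unique(data).tolist()) - {0}
        undeclared = present - set(self.class_names)
        if undeclared:
            raise ValidationError(
                f"class map contains undeclared class ids {sorted(undeclared)}"
            )
        self.data = data

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def mask_of(self, class_name: str) -> np.ndarray:
        ids = [k for k, v in self.class_names.items() if v == class_name]
        if not ids:
            raise KeyError(f"unknown class {class_name!r}")
        return np.isin(self.data, ids)


@dataclass
class Panel:
    """Antibody panel table: marker name, mass tag and a free-text role."""

    markers: list[str]
    mass_tags: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.markers)) != len(self.markers):
            dup = [m for m in self.markers if self.markers.count(m) > 1]
            raise ValidationError(f"duplicate markers in panel: {sorted(set(dup))}")
        if not self.mass_tags:
            self.mass_tags = [""] * len(self.markers)
        if not self.roles:
            self.roles = [""] * len(self.markers)
        if not (len(self.markers) == len(self.mass_tags) == len(self.roles)):
            raise ValidationError("panel columns must have equal length")


def as_label_array(mask: "LabelMask | np.ndarray") -> np.ndarray:
    """Accept either a LabelMask or a bare integer array."""
    if isinstance(mask, LabelMask):
        return mask.data
    return LabelMask(np.asarray(mask)).data


def as_bool_object(mask, object_id: int) -> np.ndarray:
    arr = as_label_array(mask)
    obj = arr == object_id
    if not obj.any():
        raise ValidationError(f"object id {object_id} not present in mask")
    return obj
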