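"""On-disk formats: FOV directories of single-channel TIFFs, masks, class
maps and CSV tables.

A FOV directory holds one grayscale TIFF per channel named
``<marker>.tiff``, a ``panel.csv`` with columns ``marker,mass_tag,role``,
and a ``fov.json`` with ``pixel_size_um``, ``expansion_fold`` and
``fov_id``.  Channel order follows panel order.  CSV files are UTF-8,
comma-separated, header row, ``.`` decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import ClassMap, LabelMask, MultiplexImage, Panel, ValidationError

PANEL_NAME = "panel.csv"
META_NAME = "fov.json"


def _channel_path(directory: Path, marker: str) -> Path:
    return directory / f"{marker}.tiff"


def write_fov(image: MultiplexImage, directory: str | Path, panel: Panel | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if panel is None:
        panel = Panel(markers=image.channel_names)
    missing = set(image.channel_names) - set(panel.markers)
    if missing:
        raise ValidationError(f"panel lacks rows for channels {sorted(missing)}")
    pd.DataFrame(
        {"marker": panel.markers, "mass_tag": panel.mass_tags, "role": panel.roles}
    ).to_csv(directory / PANEL_NAME, index=False)
    with open(directory / META_NAME, "w") as fh:
        json.dump(
            {
                "pixel_size_um": image.pixel_size_um,
                "expansion_fold": image.expansion_fold,
                "fov_id": image.fov_id,
            },
            fh,
            indent=2,
        )
    for name, arr in image.channels.items():
        if np.issubdtype(arr.dtype, np.integer) or np.all(arr == np.floor(arr)):
            save = arr.astype(np.uint32)
        else:
            save = arr.astype(np.float32)
        tifffile.imwrite(_channel_path(directory, name), save)


def read_fov(directory: str | Path) -> MultiplexImage:
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"FOV directory {directory} does not exist")
    panel_path = directory / PANEL_NAME
    if not panel_path.exists():
        raise ValidationError(f"FOV directory {directory} lacks {PANEL_NAME}")
    panel = pd.read_csv(panel_path)
    if "marker" not in panel.columns:
        raise ValidationError(f"{PANEL_NAME} needs a 'marker' column")
    markers = [str(m) for m in panel["marker"]]
    if len(set(markers)) != len(markers):
        raise ValidationError("panel markers are not unique")

    tiffs = {p.stem for p in directory.glob("*.tiff")} | {
        p.stem for p in directory.glob("*.tif")
    }
    # mask TIFFs may sit beside the channels; they are not channels
    tiffs = {t for t in tiffs if not t.endswith("_mask")}
    orphans = sorted(tiffs - set(markers))
    missing = sorted(set(markers) - tiffs)
    if orphans or missing:
        raise ValidationError(
            f"panel/TIFF mismatch in {directory}: TIFFs without a panel row "
            f"{orphans}, panel rows without a TIFF {missing}"
        )

    meta = {"pixel_size_um": 1.0, "expansion_fold": 1.0, "fov_id": directory.name}
    meta_path = directory / META_NAME
    if meta_path.exists():
        with open(meta_path) as fh:
            loaded = json.load(fh)
        meta.update({k: loaded[k] for k in meta if k in loaded})

    channels: dict[str, np.ndarray] = {}
    shape = None
    for marker in markers:
        path = _channel_path(directory, marker)
        if not path.exists():
            path = directory / f"{marker}.tif"
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise ValidationError(f"{path.name} is not a single-plane grayscale TIFF")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValidationError(
                f"{path.name} has shape {arr.shape}, siblings have {shape}"
            )
        if np.isnan(arr.astype(float)).any():
            raise ValidationError(f"{path.name} contains NaN pixels")
        if (arr < 0).any():
            raise ValidationError(f"{path.name} contains negative counts")
        channels[marker] = arr
    return MultiplexImage(channels, **meta)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    data = mask.data
    dtype = np.uint16 if data.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(Path(path), data.astype(dtype))


def read_mask(path: str | Path) -> LabelMask:
    arr = tifffile.imread(Path(path))
    if np.issubdtype(arr.dtype, np.floating):
        raise ValidationError(f"{path}: float TIFF offered as a label mask")
    return LabelMask(arr.astype(np.int64))


def write_classmap(cmap: ClassMap, path: str | Path) -> None:
    """Class map as integer TIFF plus a JSON sidecar of class names."""
    path = Path(path)
    tifffile.imwrite(path, cmap.data.astype(np.uint16))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({str(k): v for k, v in cmap.class_names.items()}, fh, indent=2)


def read_classmap(path: str | Path) -> ClassMap:
    path = Path(path)
    arr = tifffile.imread(path)
    if np.issubdtype(arr.dtype, np.floating):
        raise ValidationError(f"{path}: float TIFF offered as a class map")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValidationError(f"class map {path} lacks its {sidecar.name} sidecar")
    with open(sidecar) as fh:
        names = {int(k): v for k, v in json.load(fh).items()}
    return ClassMap(arr.astype(np.int64), names)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_warp_field(field, path: str | Path) -> None:
    """Displacement-field exchange format: two-plane 32-bit float TIFF."""
    planes = np.stack([field.d_row, field.d_col]).astype(np.float32)
    tifffile.imwrite(Path(path), planes)


def read_warp_field(path: str | Path):
    from .phantoms import WarpField

    planes = tifffile.imread(Path(path)).astype(float)
    if planes.ndim != 3 or planes.shape[0] != 2:
        raise ValidationError(f"{path}: expected a two-plane displacement TIFF")
    mag = float(np.hypot(planes[0], planes[1]).max(initial=0.0))
    return WarpField(d_row=planes[0], d_col=planes[1], max_magnitude_px=mag)
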