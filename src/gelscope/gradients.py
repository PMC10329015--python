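"""Long-axis marker gradients across tissue strips.

For a long stitched acquisition (e.g. a 1x16 strip spanning gray to white
matter), channel counts are summed perpendicular to the long axis,
min-max normalised between the 5% and 95% quantiles, and averaged in
overlapping sliding windows (default 200 positions sliding by 50) with
95% confidence intervals across the positions inside each window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MultiplexImage, ValidationError

DEFAULT_Q_LOW = 5.0
DEFAULT_Q_HIGH = 95.0
DEFAULT_WINDOW = 200
DEFAULT_STRIDE = 50


@dataclass
class AxisProfile:
    """Per-channel vectors of counts summed perpendicular to the long axis."""

    values: pd.DataFrame  # index = position along long axis, columns = channels
    axis: int  # 0: long axis runs along rows; 1: along columns
    normalized: bool = False

    @property
    def length(self) -> int:
        return len(self.values)


def perpendicular_sum(
    image: MultiplexImage, channels: Sequence[str] | None = None, axis: int = 1
) -> AxisProfile:
    """Sum each channel perpendicular to the long axis.

    ``axis=1`` (default) treats columns as the long axis and sums down each
    column; ``axis=0`` sums across each row.
    """
    if axis not in (0, 1):
        raise ValidationError("axis must be 0 or 1")
    channels = list(channels) if channels is not None else image.channel_names
    missing = [c for c in channels if c not in image]
    if missing:
        raise ValidationError(f"unknown channels {missing}")
    sums = {c: image[c].sum(axis=0 if axis == 1 else 1) for c in channels}
    df = pd.DataFrame(sums)
    df.index.name = "position_px"
    return AxisProfile(values=df, axis=axis)


def quantile_minmax(
    profile: AxisProfile, q_low: float = DEFAULT_Q_LOW, q_high: float = DEFAULT_Q_HIGH
) -> AxisProfile:
    """Min-max normalise each channel between its q_low and q_high
    percentile values (values outside [0, 1] are kept, not clipped)."""
    if not 0 <= q_low < q_high <= 100:
        raise ValidationError("need 0 <= q_low < q_high <= 100")
    out = {}
    for c in profile.values.columns:
        x = profile.values[c].to_numpy(dtype=float)
        lo = np.percentile(x, q_low)
        hi = np.percentile(x, q_high)
        if hi == lo:
            raise ValidationError(
                f"channel {c!r} is constant between the {q_low}% and {q_high}% quantiles"
            )
        out[c] = (x - lo) / (hi - lo)
    df = pd.DataFrame(out, index=profile.values.index)
    return AxisProfile(values=df, axis=profile.axis, normalized=True)


@dataclass
class WindowProfile:
    """Sliding-window means with confidence intervals.

    ``table`` has one row per (window, channel): window center position,
    normalised mean and its 95% CI across the window's positions.
    """

    table: pd.DataFrame
    window: int
    stride: int

    @property
    def n_windows(self) -> int:
        return self.table["window"].nunique()

    def channel(self, name: str) -> pd.DataFrame:
        return self.table[self.table["channel"] == name].reset_index(drop=True)


def sliding_windows(
    profile: AxisProfile, window: int = DEFAULT_WINDOW, stride: int = DEFAULT_STRIDE
) -> WindowProfile:
    """Average an axis profile in overlapping windows.

    Window count is ``floor((L - window)/stride) + 1``; the CI is
    ``mean +/- 1.96 sd/sqrt(window)`` across the positions inside the
    window.
    """
    L = profile.length
    if L < window:
        raise ValidationError(f"profile length {L} is shorter than the window {window}")
    n_win = (L - window) // stride + 1
    rows = []
    positions = profile.values.index.to_numpy()
    for wi in range(n_win):
        s = wi * stride
        e = s + window
        center = float(positions[s:e].mean())
        for c in profile.values.columns:
            x = profile.values[c].to_numpy(dtype=float)[s:e]
            m = float(x.mean())
            sd = float(x.std(ddof=1))
            half = 1.96 * sd / np.sqrt(window)
            rows.append(
                {
                    "window": wi,
                    "center_px": center,
                    "channel": c,
                    "mean": m,
                    "ci_low": m - half,
                    "ci_high": m + half,
                }
            )
    return WindowProfile(table=pd.DataFrame(rows), window=window, stride=stride)
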