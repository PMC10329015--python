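"""Independent brute-force oracles shared across test modules."""

import numpy as np
from scipy import ndimage


def chessboard_rings_oracle(obj, k_min, k_max):
    """Step rings as exact chessboard-distance level sets, independent of
    the dilation/erosion implementation under test."""
    outside = ndimage.distance_transform_cdt(~obj, metric="chessboard")
    inside = ndimage.distance_transform_cdt(obj, metric="chessboard")
    rings = {}
    for k in range(1, k_max + 1):
        rings[k] = (outside == k) & ~obj
    for k in range(1, -k_min + 1):
        rings[-k] = (inside == k) & obj
    return rings
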