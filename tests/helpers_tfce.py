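"""Shared brute-force TFCE oracle for equivalence testing."""

import numpy as np
from scipy import ndimage

from lcquant.core import RegionMask


def brute_force_tfce(arr, E=0.5, H=2.0, n_steps=100, connectivity=26):
    """Independent oracle: explicit threshold loop + flood-fill labelling."""
    arr = np.asarray(arr, dtype=float)
    hmax = arr.max()
    out = np.zeros_like(arr)
    if hmax <= 0:
        return out
    dh = hmax / n_steps
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    for k in range(1, n_steps + 1):
        h = dh * k
        labels, n_lab = ndimage.label(arr >= h, structure=structure)
        for lab in range(1, n_lab + 1):
            members = labels == lab
            out[members] += members.sum() ** E * h**H * dh
    return out


def full_mask(shape):
    return RegionMask(shape, np.argwhere(np.ones(shape)))
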