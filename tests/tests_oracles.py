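"""Independent brute-force oracles shared across test modules.

Kept separate from the production code paths on purpose: these are naive,
exhaustive implementations used only to validate the optimized kernels.
"""

import numpy as np


def brute_force_expand_margin(mask, spacing, margins):
    """Exhaustive anisotropic-distance margin expansion.

    A voxel is included iff its center lies within the ellipsoidal metric
    (semi-axes = margins) of some input voxel center.
    """
    src = np.argwhere(mask) * np.asarray(spacing)
    out = np.zeros_like(mask, dtype=bool)
    margins = np.asarray(margins, dtype=float)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * np.asarray(spacing)
        d = np.abs(src - p)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(margins > 0, d / margins,
                              np.where(d == 0, 0.0, np.inf))
        if np.any((scaled**2).sum(axis=1) <= 1.0 + 1e-12):
            out[idx] = True
    return out
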