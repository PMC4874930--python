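"""Segmentation agreement metrics and summary arithmetic."""
from __future__ import annotations

import numpy as np

from .errors import GridMismatchError, PetsegError
from .volume_io import LabelVolume


def _as_mask(x) -> np.ndarray:
    if isinstance(x, LabelVolume):
        return x.data > 0
    return np.asarray(x) > 0


def dice(a, b) -> float:
    """Dice overlap D = 2|A ∩ B| / (|A| + |B|) of two binary masks."""
    if isinstance(a, LabelVolume) and isinstance(b, LabelVolume):
        if not a.same_grid(b):
            raise GridMismatchError("Dice requires masks on the same grid")
    ma, mb = _as_mask(a), _as_mask(b)
    if ma.shape != mb.shape:
        raise GridMismatchError("Dice requires masks of the same shape")
    na, nb = int(ma.sum()), int(mb.sum())
    if na == 0 and nb == 0:
        raise PetsegError("Dice is undefined for two empty masks")
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def relative_improvement(new: float, old: float) -> float:
    """Percent change 100*(new - old)/old (e.g. agreement improvement)."""
    if old == 0:
        raise ZeroDivisionError("relative improvement undefined for old == 0")
    return 100.0 * (new - old) / old


def time_reduction(old: float, new: float) -> float:
    """Percent reduction 100*(old - new)/old (e.g. segmentation time saved)."""
    if old == 0:
        raise ZeroDivisionError("time reduction undefined for old == 0")
    return 100.0 * (old - new) / old


def majority_vote(masks) -> np.ndarray:
    """Voxelwise majority fusion of binary masks.

    A simple substitute for EM-based reference fusion (STAPLE): a voxel is
    foreground when more than half of the raters mark it.
    """
    arrs = [_as_mask(m) for m in masks]
    if not arrs:
        raise PetsegError("majority_vote needs at least one mask")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise GridMismatchError("masks must share a shape")
    votes = np.sum(arrs, axis=0)
    return votes * 2 > len(arrs)
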