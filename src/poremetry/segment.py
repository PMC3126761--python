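"""Phase segmentation: alginate vs cavity, with a minimum-lumen-area filter.

The preprocessed micrograph is binarized (Otsu by default) into the
electron-dense alginate phase and the cavity (lumen) phase. Phase polarity
is auto-detected: the phase whose largest connected component is biggest is
taken to be the alginate matrix, because the matrix is the one connected
fibril network. Cavities smaller than a physical area cutoff (275 nm^2 by
default) are then reassigned to alginate.

Connectivity convention: cavities are labeled 4-connected, alginate is
treated 8-connected — the standard complementary pairing that avoids
topological paradoxes on a square grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateImageError, InvalidParameterError
from .preprocess import CalibratedImage

logger = logging.getLogger(__name__)

#: Minimum accepted lumen (cavity) area in nm^2.
DEFAULT_MIN_LUMEN_AREA_NM2 = 275.0

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class PhaseMask:
    """Binary alginate/cavity segmentation with labeled cavity components.

    Attributes
    ----------
    mask:
        Boolean raster, True = alginate (fibril) phase, False = cavity.
    pixel_pitch_nm:
        Inherited physical calibration.
    labels:
        Integer raster of 4-connected cavity components (0 on alginate).
    min_lumen_area_nm2:
        The area cutoff that has been applied (0 if not yet filtered).
    threshold:
        Intensity threshold used by :func:`binarize`.
    polarity:
        'dark' if alginate is the darker phase, 'bright' otherwise.
    """

    mask: np.ndarray
    pixel_pitch_nm: float
    labels: np.ndarray
    min_lumen_area_nm2: float = 0.0
    threshold: float | None = None
    polarity: str | None = None

    def __post_init__(self):
        if self.pixel_pitch_nm <= 0:
            raise InvalidParameterError("pixel_pitch_nm must be positive")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.shape != self.labels.shape:
            raise InvalidParameterError("mask and labels must share a shape")

    @property
    def n_lumina(self) -> int:
        return int(self.labels.max())

    @property
    def cavity(self) -> np.ndarray:
        return ~self.mask


def _largest_component_size(phase: np.ndarray) -> int:
    lab, n = ndimage.label(phase, structure=_STRUCT_8)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def _label_cavities(mask: np.ndarray) -> np.ndarray:
    labels, _ = ndimage.label(~mask, structure=_STRUCT_4)
    return labels


def binarize(img: CalibratedImage, method: str = "otsu",
             threshold: float | None = None,
             polarity: str = "auto") -> PhaseMask:
    """Partition an image into alginate and cavity phases by thresholding.

    Parameters
    ----------
    method:
        'otsu' (default) or 'fixed' (requires ``threshold``).
    polarity:
        'auto' assigns the phase with the largest connected component to
        alginate; 'dark' / 'bright' force the darker / brighter phase.
    """
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if lo == hi:
        raise DegenerateImageError("image has a single intensity; cannot threshold")
    if method == "otsu":
        thr = float(threshold_otsu(px))
    elif method == "fixed":
        if threshold is None:
            raise InvalidParameterError("method='fixed' requires a threshold")
        if not (lo <= threshold <= hi):
            raise InvalidParameterError(
                f"fixed threshold {threshold} outside image range [{lo}, {hi}]")
        thr = float(threshold)
    else:
        raise InvalidParameterError(f"unknown threshold method {method!r}")

    bright = px > thr
    if polarity == "auto":
        alginate_is_dark = _largest_component_size(~bright) > _largest_component_size(bright)
    elif polarity in ("dark", "bright"):
        alginate_is_dark = polarity == "dark"
    else:
        raise InvalidParameterError(f"unknown polarity {polarity!r}")

    alginate = ~bright if alginate_is_dark else bright
    return PhaseMask(
        mask=alginate,
        pixel_pitch_nm=img.pixel_pitch_nm,
        labels=_label_cavities(alginate),
        threshold=thr,
        polarity="dark" if alginate_is_dark else "bright",
    )


def filter_small_lumina(pm: PhaseMask,
                        min_lumen_area_nm2: float = DEFAULT_MIN_LUMEN_AREA_NM2) -> PhaseMask:
    """Reassign cavity components below the physical area cutoff to alginate.

    A component is removed iff ``area_px * pitch^2 < min_lumen_area_nm2``
    (strict); at the default pitch of 2.34 nm/px this removes lumina of
    <= 50 px (273.8 nm^2) and keeps 51 px (279.3 nm^2). Remaining labels
    are re-indexed contiguously. Idempotent.
    """
    if min_lumen_area_nm2 < 0:
        raise InvalidParameterError("min_lumen_area_nm2 must be non-negative")
    area_px = np.bincount(pm.labels.ravel())
    area_nm2 = area_px * pm.pixel_pitch_nm ** 2
    small = np.flatnonzero(area_nm2 < min_lumen_area_nm2)
    small = small[small > 0]  # label 0 is alginate
    mask = pm.mask.copy()
    if small.size:
        mask[np.isin(pm.labels, small)] = True
    labels = _label_cavities(mask)
    if labels.max() == 0 and pm.n_lumina > 0:
        warnings.warn("all cavities fell below the minimum lumen area; "
                      "mask is now entirely alginate")
    return replace(pm, mask=mask, labels=labels,
                   min_lumen_area_nm2=float(min_lumen_area_nm2))


def exclude_region(pm: PhaseMask, region: np.ndarray) -> PhaseMask:
    """Remove a region (e.g. a delineated cell body) from the matrix phase.

    Region pixels become cavity, so distance measurements see only the
    remaining alginate as walls; cavity labels are recomputed. Skeleton
    samples falling inside the region are excluded downstream by the
    interface profiler (their interface depth is 0).
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != pm.mask.shape:
        raise InvalidParameterError("region and mask dimensions differ")
    mask = pm.mask & ~region
    return replace(pm, mask=mask, labels=_label_cavities(mask))


def segment(img: CalibratedImage, method: str = "otsu",
            threshold: float | None = None, polarity: str = "auto",
            min_lumen_area_nm2: float = DEFAULT_MIN_LUMEN_AREA_NM2) -> PhaseMask:
    """Binarize then apply the minimum-lumen-area filter."""
    return filter_small_lumina(binarize(img, method, threshold, polarity),
                               min_lumen_area_nm2)
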