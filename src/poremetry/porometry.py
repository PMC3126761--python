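"""Core pore/fibril metrology on segmented micrographs.

The measurement chain is: exact Euclidean distance transform (EDT) of the
phase of interest, a one-pixel-wide skeleton through the local maxima of
the EDT, and one radius sample per skeleton pixel — the EDT value there,
scaled by the pixel pitch. Half the wall-to-wall distance across a cavity,
sampled on its center axis, is the *relative pore radius* (rpr); the same
measurement on the alginate phase along fibril axes is the *fibril-like
radius* (flr). Samples are aggregated into frequency tables and into the
standard percent-frequency bin schemes:

- ``rpr_table1``: rpr <= 10, 10-20, 20-25, 25-40, 40-70, > 70 nm
- ``flr_table2``: flr <= 2.34, 2.34-4.68, 4.68-7.02, 7.02-9.36, > 9.36 nm

Bin boundaries are right-closed — a sample exactly at an edge goes to the
lower class, matching the "rpr <= 10" convention of the first class — so
no sample is ever dropped at a boundary.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import thin

from .errors import DegenerateMaskError, InvalidParameterError
from .segment import PhaseMask

#: Inner bin edges (nm) for relative pore radii.
RPR_TABLE1_EDGES = (10.0, 20.0, 25.0, 40.0, 70.0)
#: Inner bin edges (nm) for fibril-like radii (multiples of the 2.34 nm pitch).
FLR_TABLE2_EDGES = (2.34, 4.68, 7.02, 9.36)

#: EDT ridge tolerance (px): a pixel is on the skeleton ridge if its EDT is
#: within this of the 3x3 neighbourhood maximum. 0.5 px absorbs the
#: quantization jitter of discrete-grid distances along a center axis.
RIDGE_TOL_PX = 0.5


@dataclass(frozen=True)
class DistanceMap:
    """Shortest distances (px) from each target-phase pixel to the other phase.

    ``values`` is 0 on the complementary phase. ``phase`` records whether
    the target was the cavity ('pore') or the alginate ('fibril') phase.
    """

    values: np.ndarray
    pixel_pitch_nm: float
    phase: str = "pore"

    @property
    def target(self) -> np.ndarray:
        return self.values > 0


@dataclass(frozen=True)
class RadiusSampleSet:
    """Per-skeleton-pixel radius measurements for one phase.

    ``radii_px`` holds the raw EDT values; coordinates are (row, col) per
    sample. ``frequency_table`` counts how often each quantized radius
    value recurs (values are quantized to 0.01 px, the natural granularity
    of exact EDT values, before scaling to nm).
    """

    phase: str
    radii_px: np.ndarray
    coords: np.ndarray
    pixel_pitch_nm: float

    @property
    def n(self) -> int:
        return int(self.radii_px.size)

    @property
    def radii_nm(self) -> np.ndarray:
        return self.radii_px * self.pixel_pitch_nm

    @property
    def frequency_table(self) -> Counter:
        return Counter(np.round(self.radii_px, 2) * self.pixel_pitch_nm)

    def modal_radius_px(self) -> float:
        if self.n == 0:
            raise InvalidParameterError("empty sample set has no mode")
        vals, counts = np.unique(np.round(self.radii_px, 2), return_counts=True)
        return float(vals[np.argmax(counts)])


@dataclass(frozen=True)
class BinnedDistribution:
    """Percent-frequency histogram over radius classes.

    ``bin_edges_nm`` are the inner edges; the first class is (0, e1] and
    the last (eK, inf). ``percent`` sums to 100 up to rounding.
    """

    bin_edges_nm: tuple[float, ...]
    percent: np.ndarray
    n_samples: int

    def __post_init__(self):
        edges = tuple(float(e) for e in self.bin_edges_nm)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise InvalidParameterError("bin edges must be strictly increasing")
        object.__setattr__(self, "bin_edges_nm", edges)
        object.__setattr__(self, "percent", np.asarray(self.percent, dtype=np.float64))
        if self.percent.size != len(edges) + 1:
            raise InvalidParameterError("need one percentage per class (n_edges + 1)")

    @property
    def labels(self) -> list[str]:
        e = self.bin_edges_nm
        out = [f"<= {e[0]:g}"]
        out += [f"{a:g} - {b:g}" for a, b in zip(e, e[1:])]
        out.append(f"> {e[-1]:g}")
        return out


def distance_transform(pm: PhaseMask, target_phase: str = "pore") -> DistanceMap:
    """Exact (Euclidean, not chamfer) distance transform of one phase.

    For ``target_phase='pore'`` each cavity pixel gets its shortest distance
    to the nearest alginate pixel center; 'fibril' operates on the inverted
    mask.
    """
    if target_phase not in ("pore", "fibril"):
        raise InvalidParameterError(f"unknown target phase {target_phase!r}")
    target = ~pm.mask if target_phase == "pore" else pm.mask
    if target.all() or not target.any():
        raise DegenerateMaskError(
            f"mask contains a single phase; cannot measure {target_phase} distances")
    values = ndimage.distance_transform_edt(target)
    return DistanceMap(values=values, pixel_pitch_nm=pm.pixel_pitch_nm,
                       phase=target_phase)


def _ridge(values: np.ndarray, target: np.ndarray, tol: float = RIDGE_TOL_PX) -> np.ndarray:
    neighbourhood_max = ndimage.maximum_filter(values, size=3, mode="constant")
    return target & (values >= neighbourhood_max - tol)


def extract_skeleton(dmap: DistanceMap, pm: PhaseMask) -> np.ndarray:
    """One-pixel-wide center axis through the local maxima of the EDT.

    The skeleton is the set of target-phase pixels whose EDT value is a
    local maximum with respect to the surrounding complementary phase
    (3x3 neighbourhood, 0.5 px plateau tolerance), topologically thinned
    to one-pixel width. Where two center rows tie (even-width slits) the
    thinning keeps the lexicographically first — a deterministic,
    seed-independent tie-break. Every labeled cavity component is
    guaranteed at least one skeleton pixel (its EDT argmax) even if the
    ridge filter left none.
    """
    if dmap.values.shape != pm.mask.shape:
        raise InvalidParameterError("distance map and mask must share a shape")
    target = dmap.target
    skeleton = thin(_ridge(dmap.values, target))

    if dmap.phase == "pore":
        component_labels = pm.labels
    else:
        component_labels, _ = ndimage.label(
            pm.mask, structure=ndimage.generate_binary_structure(2, 2))
    n_comp = int(component_labels.max())
    if n_comp:
        has_skel = np.zeros(n_comp + 1, dtype=bool)
        has_skel[np.unique(component_labels[skeleton])] = True
        for lab in np.flatnonzero(~has_skel[1:]) + 1:
            inside = component_labels == lab
            flat = np.flatnonzero(inside.ravel())
            best = flat[np.argmax(dmap.values.ravel()[flat])]
            skeleton.ravel()[best] = True
    return skeleton


def measure_radii(dmap: DistanceMap, skeleton: np.ndarray,
                  pitch_nm: float | None = None) -> RadiusSampleSet:
    """One radius sample per skeleton pixel: the EDT value there, in px/nm."""
    if pitch_nm is None:
        pitch_nm = dmap.pixel_pitch_nm
    if pitch_nm <= 0:
        raise InvalidParameterError("pitch_nm must be positive")
    skeleton = np.asarray(skeleton, dtype=bool)
    if skeleton.shape != dmap.values.shape:
        raise InvalidParameterError("skeleton and distance map must share a shape")
    if skeleton.sum() and not (skeleton <= dmap.target).all():
        raise InvalidParameterError("skeleton must lie inside the target phase")
    coords = np.argwhere(skeleton)
    if coords.size == 0:
        warnings.warn("empty skeleton: returning an empty sample set")
    radii = dmap.values[skeleton]
    return RadiusSampleSet(phase=dmap.phase, radii_px=radii, coords=coords,
                           pixel_pitch_nm=float(pitch_nm))


def _resolve_edges(scheme) -> tuple[float, ...]:
    if scheme == "rpr_table1":
        return RPR_TABLE1_EDGES
    if scheme == "flr_table2":
        return FLR_TABLE2_EDGES
    edges = tuple(float(e) for e in np.atleast_1d(scheme))
    if len(edges) < 1:
        raise InvalidParameterError("custom scheme needs at least one edge")
    return edges


def bin_values(values_nm: np.ndarray, scheme="rpr_table1") -> BinnedDistribution:
    """Bin radius values (nm) into percent frequencies; right-closed classes."""
    values_nm = np.asarray(values_nm, dtype=np.float64)
    if values_nm.size == 0:
        raise InvalidParameterError("cannot bin an empty sample set")
    edges = _resolve_edges(scheme)
    # right-closed: value v goes to the first class whose upper edge >= v
    idx = np.searchsorted(edges, values_nm, side="left")
    counts = np.bincount(idx, minlength=len(edges) + 1)
    percent = 100.0 * counts / values_nm.size
    return BinnedDistribution(bin_edges_nm=edges, percent=percent,
                              n_samples=int(values_nm.size))


def bin_distribution(samples: RadiusSampleSet, scheme="rpr_table1") -> BinnedDistribution:
    """Percent-frequency distribution of a sample set over a bin scheme."""
    return bin_values(samples.radii_nm, scheme)


@dataclass(frozen=True)
class DistributionComparison:
    """Per-bin absolute differences (percentage points) between two distributions."""

    bin_edges_nm: tuple[float, ...]
    per_bin_abs_diff: np.ndarray = field(repr=False)
    max_abs_diff: float = 0.0
    argmax_bin: int = 0


def compare_distributions(a: BinnedDistribution,
                          b: BinnedDistribution) -> DistributionComparison:
    """Absolute per-bin discrepancy, in percentage points, plus the maximum."""
    if a.bin_edges_nm != b.bin_edges_nm:
        raise InvalidParameterError("distributions use different bin edges")
    diff = np.abs(a.percent - b.percent)
    return DistributionComparison(bin_edges_nm=a.bin_edges_nm,
                                  per_bin_abs_diff=diff,
                                  max_abs_diff=float(diff.max()),
                                  argmax_bin=int(diff.argmax()))


def total_variation_distance(a: BinnedDistribution, b: BinnedDistribution) -> float:
    """TV distance in [0, 1] between two binned distributions (same edges)."""
    if a.bin_edges_nm != b.bin_edges_nm:
        raise InvalidParameterError("distributions use different bin edges")
    return float(0.5 * np.abs(a.percent - b.percent).sum() / 100.0)


def measure_phase(pm: PhaseMask, phase: str = "pore") -> RadiusSampleSet:
    """Convenience chain: distance transform, skeleton, radius samples."""
    dmap = distance_transform(pm, phase)
    skeleton = extract_skeleton(dmap, pm)
    return measure_radii(dmap, skeleton)
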