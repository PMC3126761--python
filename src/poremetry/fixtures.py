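"""Synthetic TEM-like phantoms and isotherms with known ground truth.

Every downstream stage of the metrology is testable closed-loop against
these generators: slit and disc cavities with exactly known gap widths, a
random fibril-network phantom emulating the fibrillar hydrogel matrix seen
in section, a cell phantom with a densified halo around a disc-shaped cell,
and forward-modeled BET / mesopore isotherms.

Ground-truth gap widths for irregular cavities are defined as twice the
nearest-wall distance at cavity medial points — the same quantity the
measurement chain estimates — but computed through an independent route:
a KD-tree nearest-neighbour search against the wall pixels rather than the
grid distance transform used by the pipeline. A scanline (row/column run
length) oracle is also provided for rectilinear phantoms.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import thin

from .errors import DegeneratePhantomError, InvalidParameterError
from .physisorption import (Isotherm, harkins_jura_t_nm, kelvin_radius_nm,
                            monolayer_capacity_mol_per_g,
                            N2_LIQUID_MOLAR_VOLUME)
from .preprocess import DEFAULT_PITCH_NM

#: Rendered intensity levels: alginate is the electron-dense (dark) phase.
DEFAULT_CONTRAST = (60.0, 180.0)
#: Additive Gaussian noise sd of the default rendering (0-255 scale).
DEFAULT_NOISE_SD = 12.0
#: Amplitude (intensity units) and correlation scale (px) of the bias field.
DEFAULT_INHOMOGENEITY = (20.0, 200.0)
#: Default nominal fibril widths (px) and their probabilities; chosen so the
#: fibril-radius distribution is dominated by the first two 2.34 nm classes,
#: as in stained alginate sections.
DEFAULT_FIBRIL_WIDTHS = ((2, 0.50), (3, 0.30), (4, 0.15), (5, 0.05))
#: Default network density: fibril centerline length (px) per px^2 of canvas.
#: Scale-invariant — the drawn alginate area fraction (~0.2 at the default
#: widths) does not depend on the canvas size.
DEFAULT_FIBRIL_LENGTH_DENSITY = 0.10
#: Mean fibril length as a fraction of the canvas diagonal (lengths are
#: drawn uniformly on [0.3, 1.0] of the diagonal).
_MEAN_LENGTH_FRAC = 0.65


@dataclass(frozen=True)
class Phantom:
    """A synthetic micrograph with ground truth.

    ``truth_mask`` is True on the alginate phase. ``rendered`` starts as the
    clean two-level image (alginate dark) and is replaced by
    :func:`render_tem`. ``truth_gaps`` holds wall-to-wall gap widths (nm)
    with multiplicities, one per cavity medial point;
    ``truth_fibril_widths`` the nominal drawn fibril widths (nm). Cell
    phantoms additionally carry ``cell_mask`` and near/far-field gap
    distributions relative to the cell boundary.
    """

    truth_mask: np.ndarray
    rendered: np.ndarray
    pixel_pitch_nm: float
    truth_gaps: np.ndarray
    truth_fibril_widths: np.ndarray
    seed: int | None = None
    cell_mask: np.ndarray | None = None
    truth_gaps_near: np.ndarray | None = None
    truth_gaps_far: np.ndarray | None = None
    halo_depth_nm: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "truth_mask", np.asarray(self.truth_mask, bool))
        object.__setattr__(self, "rendered", np.asarray(self.rendered, np.float64))
        object.__setattr__(self, "truth_gaps",
                           np.asarray(self.truth_gaps, np.float64))
        object.__setattr__(self, "truth_fibril_widths",
                           np.asarray(self.truth_fibril_widths, np.float64))
        if self.rendered.shape != self.truth_mask.shape:
            raise InvalidParameterError("rendered and truth_mask shapes differ")
        if self.cell_mask is not None:
            cm = np.asarray(self.cell_mask, bool)
            if cm.shape != self.truth_mask.shape:
                raise InvalidParameterError("cell_mask shape differs from truth_mask")
            object.__setattr__(self, "cell_mask", cm)
        if (self.truth_gaps <= 0).any() or (self.truth_fibril_widths <= 0).any():
            raise InvalidParameterError("truth gaps and fibril widths must be positive")
        if self.pixel_pitch_nm <= 0:
            raise InvalidParameterError("pixel_pitch_nm must be positive")

    @property
    def truth_rpr_nm(self) -> np.ndarray:
        """Ground-truth relative pore radii: half the gap widths."""
        return self.truth_gaps / 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth_mask.shape


def _two_level(mask: np.ndarray, contrast=DEFAULT_CONTRAST) -> np.ndarray:
    fg, bg = contrast
    return np.where(mask, float(fg), float(bg))


# ---------------------------------------------------------------------------
# Independent ground-truth gap measurement


def _kdtree_wall_distance(mask: np.ndarray) -> np.ndarray:
    """Distance (px) from each cavity pixel to the nearest alginate pixel.

    Brute-force in spirit: a KD-tree nearest-neighbour query against every
    wall pixel, sharing nothing with the grid distance transform of the
    measurement path.
    """
    walls = np.argwhere(mask)
    cavities = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=np.float64)
    if walls.size == 0 or cavities.size == 0:
        return out
    dist, _ = cKDTree(walls).query(cavities, k=1)
    out[tuple(cavities.T)] = dist
    return out


def _medial_points(dist: np.ndarray, target: np.ndarray, tol: float = 0.5) -> np.ndarray:
    """Local-maxima ridge of a distance field, thinned to one-pixel width."""
    mx = ndimage.maximum_filter(dist, size=3, mode="constant")
    return thin(target & (dist >= mx - tol))


def truth_gap_radii(mask: np.ndarray, pixel_pitch_nm: float):
    """Ground-truth cavity radii (nm) at medial points, plus their coordinates.

    Returns (radii_nm, coords); the gap width at a medial point is twice the
    radius. Computed via the KD-tree route on the clean mask.
    """
    dist = _kdtree_wall_distance(mask)
    pts = _medial_points(dist, ~mask)
    coords = np.argwhere(pts)
    return dist[pts] * pixel_pitch_nm, coords


def gap_widths_scanline(mask: np.ndarray, pixel_pitch_nm: float) -> np.ndarray:
    """Second gap oracle for rectilinear cavities: per-medial-point minimum of
    the horizontal and vertical cavity run lengths (nm)."""
    cav = ~mask

    def run_lengths(c):
        out = np.zeros(c.shape, dtype=np.int64)
        for i, row in enumerate(c):
            j = 0
            n = len(row)
            while j < n:
                if row[j]:
                    k = j
                    while k < n and row[k]:
                        k += 1
                    out[i, j:k] = k - j
                    j = k
                else:
                    j += 1
        return out

    runs = np.minimum(run_lengths(cav), run_lengths(cav.T).T)
    dist = _kdtree_wall_distance(mask)
    pts = _medial_points(dist, cav)
    return runs[pts] * pixel_pitch_nm


# ---------------------------------------------------------------------------
# Deterministic phantoms


def generate_slit_phantom(width_px: int, length_px: int = 128, wall_px: int = 20,
                          pixel_pitch_nm: float = DEFAULT_PITCH_NM) -> Phantom:
    """One straight rectangular cavity of ``width_px`` between two walls."""
    if width_px < 1 or length_px < 1 or wall_px < 1:
        raise InvalidParameterError("slit dimensions must be positive")
    if pixel_pitch_nm <= 0:
        raise InvalidParameterError("pixel_pitch_nm must be positive")
    mask = np.ones((length_px, width_px + 2 * wall_px), dtype=bool)
    mask[:, wall_px:wall_px + width_px] = False
    return Phantom(truth_mask=mask, rendered=_two_level(mask),
                   pixel_pitch_nm=pixel_pitch_nm,
                   truth_gaps=np.array([width_px * pixel_pitch_nm]),
                   truth_fibril_widths=np.array([wall_px * pixel_pitch_nm] * 2))


def generate_disc_phantom(radius_px: int,
                          pixel_pitch_nm: float = DEFAULT_PITCH_NM,
                          image_px: tuple[int, int] | None = None) -> Phantom:
    """One circular cavity of ``radius_px`` in a solid alginate field."""
    if radius_px < 2:
        raise InvalidParameterError("radius_px must be >= 2")
    if image_px is None:
        side = 4 * radius_px + 9
        image_px = (side, side)
    h, w = image_px
    if 2 * radius_px + 2 > min(h, w):
        raise InvalidParameterError("disc does not fit inside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h // 2, w // 2
    cavity = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
    mask = ~cavity
    return Phantom(truth_mask=mask, rendered=_two_level(mask),
                   pixel_pitch_nm=pixel_pitch_nm,
                   truth_gaps=np.array([2.0 * radius_px * pixel_pitch_nm]),
                   truth_fibril_widths=np.array([radius_px * pixel_pitch_nm]))


# ---------------------------------------------------------------------------
# Random fibril networks


def _draw_fibrils(shape, segments, widths):
    """Union of thick segments: pixels within width/2 of each centerline.

    Returns (mask, touched): ``touched[i]`` is True where fibril i's
    centerline crosses the canvas.
    """
    mask = np.zeros(shape, dtype=bool)
    touched = np.zeros(len(segments), dtype=bool)
    for w in np.unique(widths):
        lines = np.zeros(shape, dtype=bool)
        for i, ((r0, c0, r1, c1), wi) in enumerate(zip(segments, widths)):
            if wi != w:
                continue
            n = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
            rr = np.round(np.linspace(r0, r1, n)).astype(int)
            cc = np.round(np.linspace(c0, c1, n)).astype(int)
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            touched[i] = bool(ok.any())
            lines[rr[ok], cc[ok]] = True
        if lines.any():
            dist = ndimage.distance_transform_edt(~lines)
            mask |= dist <= w / 2.0
    return mask, touched


def _sample_segments(rng, shape, count, width_dist):
    """Sample thick segments whose coverage is stationary over the canvas.

    Centers are drawn from a margin-enlarged region (margin = the maximum
    half-length) so line coverage does not thin toward the frame borders;
    ``count`` is the nominal number per canvas area, and the draw count is
    scaled by the area ratio to keep the in-canvas density.
    """
    h, w = shape
    diag = float(np.hypot(h, w))
    margin = 0.5 * diag
    n_draw = max(count, round(count * (h + 2 * margin) * (w + 2 * margin) / (h * w)))
    widths = rng.choice([wd for wd, _ in width_dist], size=n_draw,
                        p=[pr for _, pr in width_dist])
    segs = []
    for _ in range(n_draw):
        cy = rng.uniform(-margin, h + margin)
        cx = rng.uniform(-margin, w + margin)
        theta = rng.uniform(0, np.pi)
        length = rng.uniform(0.3, 1.0) * diag
        dy, dx = 0.5 * length * np.sin(theta), 0.5 * length * np.cos(theta)
        segs.append((cy - dy, cx - dx, cy + dy, cx + dx))
    return segs, widths


def generate_fibril_network(image_px: tuple[int, int] = (512, 512),
                            fibril_count: int | None = None,
                            fibril_width_px_dist=DEFAULT_FIBRIL_WIDTHS,
                            pixel_pitch_nm: float = DEFAULT_PITCH_NM,
                            seed: int = 0) -> Phantom:
    """Random network of straight thick segments on a cavity background.

    ``fibril_width_px_dist`` is a sequence of (width_px, probability) pairs.
    ``fibril_count`` defaults to a scale-invariant centerline density of
    0.10 px of fibril axis per pixel of canvas, which at the default widths
    covers roughly a fifth of the frame with alginate and yields the
    small-gap-dominated cavity statistics typical of hydrogel sections.
    """
    h, w = image_px
    if fibril_count is None:
        diag = float(np.hypot(h, w))
        fibril_count = max(2, round(
            DEFAULT_FIBRIL_LENGTH_DENSITY * h * w / (_MEAN_LENGTH_FRAC * diag)))
    if fibril_count < 2:
        raise InvalidParameterError("fibril_count must be >= 2")
    width_dist = tuple((int(wd), float(pr)) for wd, pr in fibril_width_px_dist)
    if any(wd < 1 for wd, _ in width_dist):
        raise InvalidParameterError("fibril widths must be >= 1 px")
    rng = np.random.default_rng(seed)
    segs, widths = _sample_segments(rng, (h, w), fibril_count, width_dist)
    mask, touched = _draw_fibrils((h, w), segs, widths)
    if not (~mask).any():
        raise DegeneratePhantomError("fibril density left no cavity pixels")
    if not mask.any():
        raise DegeneratePhantomError("no fibril pixels landed on the canvas")
    gaps_nm, _ = truth_gap_radii(mask, pixel_pitch_nm)
    return Phantom(truth_mask=mask, rendered=_two_level(mask),
                   pixel_pitch_nm=pixel_pitch_nm,
                   truth_gaps=2.0 * gaps_nm,
                   truth_fibril_widths=np.asarray(widths)[touched] * pixel_pitch_nm,
                   seed=seed)


# ---------------------------------------------------------------------------
# TEM-style rendering


def render_tem(phantom: Phantom, noise_sd: float = DEFAULT_NOISE_SD,
               inhomogeneity_amplitude: float = DEFAULT_INHOMOGENEITY[0],
               inhomogeneity_scale_px: float = DEFAULT_INHOMOGENEITY[1],
               contrast=DEFAULT_CONTRAST, seed: int = 0) -> Phantom:
    """Corrupt the two-level phase image with a bias field and noise.

    The bias field is heavily smoothed seeded Gaussian noise, rescaled to
    standard deviation ``inhomogeneity_amplitude``; additive pixel noise has
    sd ``noise_sd``. The result is clipped to [0, 255]. With zero amplitude
    and zero noise the rendering is exactly the two-level image.
    """
    fg, bg = contrast
    if fg == bg:
        raise InvalidParameterError("contrast levels must differ")
    if noise_sd < 0 or inhomogeneity_amplitude < 0 or inhomogeneity_scale_px <= 0:
        raise InvalidParameterError("noise/inhomogeneity parameters out of range")
    rng = np.random.default_rng(seed)
    base = _two_level(phantom.truth_mask, (fg, bg))
    out = base
    if inhomogeneity_amplitude > 0:
        raw = rng.standard_normal(base.shape)
        smooth = ndimage.gaussian_filter(raw, inhomogeneity_scale_px, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            out = out + inhomogeneity_amplitude * (smooth - smooth.mean()) / sd
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, base.shape)
    if noise_sd > 0 or inhomogeneity_amplitude > 0:
        out = np.clip(out, 0.0, 255.0)
    return replace(phantom, rendered=out)


# ---------------------------------------------------------------------------
# Cell-interface phantom


def _small_fraction(radii_nm, threshold_nm=10.0) -> float:
    radii_nm = np.asarray(radii_nm)
    return float((radii_nm <= threshold_nm).mean()) if radii_nm.size else np.nan


def generate_cell_phantom(cell_radius_px: int = 70, halo_depth_nm: float = 40.0,
                          halo_small_pore_boost: float = 0.3,
                          image_px: tuple[int, int] = (512, 512),
                          fibril_count: int | None = None,
                          fibril_width_px_dist=DEFAULT_FIBRIL_WIDTHS,
                          pixel_pitch_nm: float = DEFAULT_PITCH_NM,
                          seed: int = 0) -> Phantom:
    """Fibril network around a solid disc-shaped cell, densified in a halo.

    Within ``halo_depth_nm`` of the cell boundary, short extra fibrils are
    added until the truth-mask small-pore fraction (rpr <= 10 nm) exceeds
    the far-field fraction by ``halo_small_pore_boost``; the recorded
    near/far-field ground-truth gap distributions are measured on the final
    mask. With boost 0 the matrix is statistically uniform.
    """
    if not 0.0 <= halo_small_pore_boost <= 1.0:
        raise InvalidParameterError("halo_small_pore_boost must be in [0, 1]")
    if halo_depth_nm <= 0 or halo_depth_nm > 400:
        raise InvalidParameterError("halo_depth_nm must be in (0, 400]")
    h, w = image_px
    if 2 * cell_radius_px + 4 > min(h, w):
        raise InvalidParameterError("cell does not fit inside the image")
    rng = np.random.default_rng(seed)
    base = generate_fibril_network(image_px, fibril_count, fibril_width_px_dist,
                                   pixel_pitch_nm, seed=int(rng.integers(2 ** 31)))
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h // 2, w // 2
    cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius_px ** 2
    mask = base.truth_mask | cell
    depth_px = ndimage.distance_transform_edt(~cell)
    depth_nm = depth_px * pixel_pitch_nm
    halo_px = halo_depth_nm / pixel_pitch_nm

    def zone_radii(m):
        # open-cell definition: the cell body is excluded from the matrix,
        # so gap radii are measured to fibril walls only — matching the
        # interface measurement protocol
        radii, coords = truth_gap_radii(m & ~cell, pixel_pitch_nm)
        d = depth_nm[tuple(coords.T)]
        outside = d > 0
        return (radii[outside], d[outside])

    def boost_estimate(radii, d):
        near = radii[d <= halo_depth_nm]
        far = radii[d > halo_depth_nm]
        return _small_fraction(near) - _small_fraction(far)

    radii, d = zone_radii(mask)
    if halo_small_pore_boost > 0:
        for _ in range(40):
            est = boost_estimate(radii, d)
            if np.isfinite(est) and est >= halo_small_pore_boost:
                break
            k = int(np.clip(np.ceil((halo_small_pore_boost - max(est, 0.0)) * 60), 4, 24))
            lines = np.zeros((h, w), dtype=bool)
            for _ in range(k):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(cell_radius_px + 1, cell_radius_px + halo_px)
                py, px = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
                theta = rng.uniform(0, np.pi)
                length = rng.uniform(1.5, 3.0) * halo_px
                dy, dx = 0.5 * length * np.sin(theta), 0.5 * length * np.cos(theta)
                n = int(max(abs(2 * dy), abs(2 * dx))) + 1
                rr = np.round(np.linspace(py - dy, py + dy, n)).astype(int)
                cc = np.round(np.linspace(px - dx, px + dx, n)).astype(int)
                ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                lines[rr[ok], cc[ok]] = True
            if lines.any():
                dist = ndimage.distance_transform_edt(~lines)
                mask |= dist <= 1.0
                mask |= cell
            radii, d = zone_radii(mask)
    near = radii[d <= halo_depth_nm]
    far = radii[d > halo_depth_nm]
    return Phantom(truth_mask=mask, rendered=_two_level(mask),
                   pixel_pitch_nm=pixel_pitch_nm,
                   truth_gaps=2.0 * radii,
                   truth_fibril_widths=base.truth_fibril_widths,
                   seed=seed, cell_mask=cell,
                   truth_gaps_near=2.0 * near, truth_gaps_far=2.0 * far,
                   halo_depth_nm=halo_depth_nm)


def truth_depth_profile(phantom: Phantom, depth_edges_nm=None,
                        scheme="rpr_table1"):
    """Ground-truth depth profile of a cell phantom.

    Radii come from the KD-tree truth route on the clean mask (cell region
    open, matching the measurement protocol); depths from the distance to
    the cell mask. Serves as the matched geometric baseline for
    depth-effect tests on the measured profile.
    """
    from .interface_profile import (DEFAULT_DEPTH_EDGES_NM,
                                    interface_distance_map, profile_by_depth)
    from .porometry import RadiusSampleSet

    if phantom.cell_mask is None:
        raise InvalidParameterError("phantom has no cell mask")
    if depth_edges_nm is None:
        depth_edges_nm = DEFAULT_DEPTH_EDGES_NM
    pitch = phantom.pixel_pitch_nm
    radii_nm, coords = truth_gap_radii(phantom.truth_mask & ~phantom.cell_mask,
                                       pitch)
    inside = phantom.cell_mask[tuple(coords.T)]
    samples = RadiusSampleSet(phase="pore", radii_px=radii_nm[~inside] / pitch,
                              coords=coords[~inside], pixel_pitch_nm=pitch)
    idmap = interface_distance_map(phantom.cell_mask, pitch)
    return profile_by_depth(samples, idmap, depth_edges_nm, scheme)


# ---------------------------------------------------------------------------
# Synthetic isotherms


def generate_bet_isotherm(S_true_m2_per_g: float, C_bet: float = 80.0,
                          p_grid=None, seed: int = 0,
                          noise_rel: float = 0.0) -> Isotherm:
    """Adsorption branch following the two-parameter BET equation.

    Monolayer capacity is derived from ``S_true_m2_per_g`` via the 0.162 nm^2
    molecular cross-section; optional multiplicative Gaussian noise of
    relative sd ``noise_rel``. 245 and 532 m^2/g are realistic presets for
    0.8% and 1.4% w/v alginate microcapsules.
    """
    if S_true_m2_per_g <= 0:
        raise InvalidParameterError("S_true_m2_per_g must be positive")
    if C_bet <= 1:
        raise InvalidParameterError("C_bet must exceed 1")
    if p_grid is None:
        p_grid = np.linspace(0.01, 0.30, 30)
    p = np.asarray(p_grid, dtype=np.float64)
    if (p <= 0).any() or (p >= 1).any():
        raise InvalidParameterError("p_grid must lie strictly in (0, 1)")
    n_m = monolayer_capacity_mol_per_g(S_true_m2_per_g)
    n = n_m * C_bet * p / ((1.0 - p) * (1.0 + (C_bet - 1.0) * p))
    if noise_rel < 0:
        raise InvalidParameterError("noise_rel must be >= 0")
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        n = n * (1.0 + noise_rel * rng.standard_normal(n.shape))
        n = np.maximum(n, 0.0)
    return Isotherm(adsorption=np.column_stack([p, n]))


def lognormal_psd(mode_nm: float = 15.0, sigma_log: float = 0.35,
                  total_volume_cm3_per_g: float = 0.5, n_points: int = 60,
                  r_min_nm: float = 1.5, r_max_nm: float = 80.0):
    """Log-normal pore-size density sampled on a log-spaced radius grid.

    Returns (radii_nm, incremental_volumes_cm3_per_g) with the density's
    mode at ``mode_nm``.
    """
    r = np.geomspace(r_min_nm, r_max_nm, n_points)
    mu = np.log(mode_nm) + sigma_log ** 2  # mode of a log-normal: exp(mu - s^2)
    pdf = np.exp(-0.5 * ((np.log(r) - mu) / sigma_log) ** 2) / r
    v = pdf * np.gradient(r)
    v *= total_volume_cm3_per_g / v.sum()
    return r, v


def generate_mesopore_isotherm(radii_nm, volumes_cm3_per_g, p_grid=None,
                               temperature_K: float = 77.0) -> Isotherm:
    """Forward model: isotherm of a bundle of cylindrical mesopores.

    On the desorption branch a pore of radius r is liquid-full while
    r <= r_kelvin(p) + t(p) (hemispherical meniscus) and otherwise carries
    an adsorbed film of thickness t(p) on its wall; on the adsorption branch
    condensation follows the cylindrical-sleeve Kelvin radius (half the
    hemispherical one), producing a type-IV/H3-style hysteresis loop.
    """
    r = np.asarray(radii_nm, dtype=np.float64)
    v = np.asarray(volumes_cm3_per_g, dtype=np.float64)
    if r.size != v.size or r.size == 0:
        raise InvalidParameterError("radii and volumes must be equal-length, nonempty")
    if p_grid is None:
        # 0.30 -> 0.99, densified toward saturation where the Kelvin radius
        # changes fastest (as physisorption analyzers schedule their points)
        p_grid = 1.0 - np.geomspace(0.70, 0.01, 80)
    p = np.asarray(p_grid, dtype=np.float64)

    def branch(kelvin_scale):
        t = harkins_jura_t_nm(p)
        rk = kelvin_radius_nm(p, temperature_K) * kelvin_scale
        v_liq = np.empty_like(p)
        for i in range(p.size):
            filled = r <= rk[i] + t[i]
            film = ~filled & (r > t[i])
            frac_film = np.zeros_like(r)
            frac_film[film] = 1.0 - ((r[film] - t[i]) / r[film]) ** 2
            v_liq[i] = v[filled].sum() + (v * frac_film).sum()
        return np.column_stack([p, v_liq / N2_LIQUID_MOLAR_VOLUME])

    return Isotherm(adsorption=branch(0.5), desorption=branch(1.0),
                    temperature_K=temperature_K)


# ---------------------------------------------------------------------------
# Serialization


def write_phantom(phantom: Phantom, out_dir) -> None:
    """Write rasters as TIFF and ground truth as JSON into ``out_dir``."""
    import json
    from pathlib import Path

    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "truth_mask.tif",
                     phantom.truth_mask.astype(np.uint8) * 255)
    tifffile.imwrite(out / "rendered.tif",
                     np.clip(phantom.rendered, 0, 255).astype(np.uint8))
    if phantom.cell_mask is not None:
        tifffile.imwrite(out / "cell_mask.tif",
                         phantom.cell_mask.astype(np.uint8) * 255)
    truth = {
        "pixel_pitch_nm": phantom.pixel_pitch_nm,
        "seed": phantom.seed,
        "truth_gaps_nm": phantom.truth_gaps.tolist(),
        "truth_fibril_widths_nm": phantom.truth_fibril_widths.tolist(),
    }
    if phantom.truth_gaps_near is not None:
        truth["truth_gaps_near_nm"] = phantom.truth_gaps_near.tolist()
        truth["truth_gaps_far_nm"] = phantom.truth_gaps_far.tolist()
        truth["halo_depth_nm"] = phantom.halo_depth_nm
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
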