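"""BET surface area and BJH pore-size distribution from N2 isotherms.

Cross-validation route for the image-based porometry: a nitrogen
adsorption-desorption isotherm measured at 77 K is reduced to

- a BET specific surface area, from the linearized multilayer-adsorption
  equation over relative pressures 0.05-0.2, with 0.162 nm^2 per adsorbed
  N2 molecule, and
- a BJH mesopore size distribution, from the desorption branch via the
  Kelvin equation plus a Harkins-Jura adsorbed-film thickness curve with
  the classic cylindrical-pore core-to-pore correction.

The BJH volume-percent distribution can be binned on the same radius
classes as the image-derived number-percent distribution for a direct
per-bin comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (InsufficientDataError, InvalidFitError,
                     InvalidParameterError)
from .porometry import BinnedDistribution, bin_values

AVOGADRO = 6.02214076e23
GAS_CONSTANT = 8.31446  # J / (mol K)
#: Cross-sectional area of one adsorbed N2 molecule (nm^2).
N2_CROSS_SECTION_NM2 = 0.162
#: Molar volume of liquid N2 at 77 K (cm^3/mol).
N2_LIQUID_MOLAR_VOLUME = 34.68
#: Surface tension of liquid N2 at 77 K (N/m).
N2_SURFACE_TENSION = 8.85e-3
#: Molar volume of an ideal gas at STP (cm^3/mol), for cm^3(STP)/g inputs.
STP_MOLAR_VOLUME = 22414.0


def _as_branch(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=np.float64)
    if a.size == 0:
        return a.reshape(0, 2)
    if a.ndim != 2 or a.shape[1] != 2:
        raise InvalidParameterError("branch must be an (N, 2) array of (p_rel, amount)")
    return a


@dataclass(frozen=True)
class Isotherm:
    """N2 sorption isotherm: (p/p0, amount adsorbed in mol/g) per branch.

    Relative pressures must lie strictly in (0, 1) and be monotone
    increasing within each branch (desorption data are stored sorted by
    increasing pressure too; the analysis walks them downward).
    """

    adsorption: np.ndarray
    desorption: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    temperature_K: float = 77.0
    cross_section_nm2: float = N2_CROSS_SECTION_NM2

    def __post_init__(self):
        for name in ("adsorption", "desorption"):
            br = _as_branch(getattr(self, name))
            if br.size:
                p = br[:, 0]
                if (p <= 0).any() or (p >= 1).any():
                    raise InvalidParameterError(
                        f"{name}: relative pressures must lie strictly in (0, 1)")
                if (np.diff(p) <= 0).any():
                    raise InvalidParameterError(
                        f"{name}: relative pressures must be strictly increasing")
                if (br[:, 1] < 0).any():
                    raise InvalidParameterError(f"{name}: amounts must be >= 0")
            object.__setattr__(self, name, br)


def convert_amount_to_mol(amount, units: str) -> np.ndarray:
    """Convert adsorbed amounts to mol/g from 'mol/g', 'mmol/g' or 'cm3stp/g'."""
    amount = np.asarray(amount, dtype=np.float64)
    key = units.strip().lower().replace(" ", "").replace("^", "")
    if key in ("mol/g",):
        return amount
    if key in ("mmol/g",):
        return amount * 1e-3
    if key in ("cm3stp/g", "cm3(stp)/g", "ml(stp)/g", "mlstp/g"):
        return amount / STP_MOLAR_VOLUME
    raise InvalidParameterError(f"unknown amount units {units!r}")


def write_isotherm_csv(iso: Isotherm, path, units: str = "mmol/g") -> None:
    """Write an isotherm as CSV: '# units: <u>' header, then branch,p_rel,amount."""
    scale = {"mmol/g": 1e3, "mol/g": 1.0, "cm3stp/g": STP_MOLAR_VOLUME}[units]
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        fh.write("branch,p_rel,amount\n")
        for name, br in (("ads", iso.adsorption), ("des", iso.desorption)):
            for p, n in br:
                fh.write(f"{name},{p:.8g},{n * scale:.8g}\n")


def read_isotherm_csv(path) -> Isotherm:
    """Read the 3-column isotherm CSV written by :func:`write_isotherm_csv`."""
    import pandas as pd

    units = "mmol/g"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "units:" in first:
                units = first.split("units:", 1)[1].strip()
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    branches = {}
    for name in ("ads", "des"):
        sub = df[df["branch"] == name].sort_values("p_rel")
        branches[name] = np.column_stack(
            [sub["p_rel"].to_numpy(),
             convert_amount_to_mol(sub["amount"].to_numpy(), units)])
    return Isotherm(adsorption=branches["ads"], desorption=branches["des"])


# ---------------------------------------------------------------------------
# BET


@dataclass(frozen=True)
class BetResult:
    """BET fit output: specific surface area plus fit diagnostics."""

    surface_area_m2_per_g: float
    c_constant: float
    monolayer_mol_per_g: float
    r_squared: float
    n_points: int
    pressure_window: tuple[float, float]


def monolayer_capacity_mol_per_g(surface_area_m2_per_g: float,
                                 cross_section_nm2: float = N2_CROSS_SECTION_NM2) -> float:
    """Invert area = n_m * N_A * sigma (sigma in nm^2 -> 1e-18 m^2)."""
    return surface_area_m2_per_g / (AVOGADRO * cross_section_nm2 * 1e-18)


def bet_surface_area(iso: Isotherm, p_lo: float = 0.05, p_hi: float = 0.2) -> BetResult:
    """BET specific surface area from adsorption data in [p_lo, p_hi].

    Fits the linearized form x / (n (1 - x)) = 1/(n_m C) + (C-1)/(n_m C) x
    with x = p/p0; the monolayer capacity n_m comes from slope + intercept
    and the area is n_m * N_A * cross-section. Requires >= 3 points in the
    window and C > 0 for a valid fit.
    """
    br = iso.adsorption
    sel = (br[:, 0] >= p_lo) & (br[:, 0] <= p_hi) & (br[:, 1] > 0)
    if sel.sum() < 3:
        raise InsufficientDataError(
            f"only {int(sel.sum())} adsorption points in [{p_lo}, {p_hi}]; need >= 3")
    x = br[sel, 0]
    n = br[sel, 1]
    y = x / (n * (1.0 - x))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
    n_m = 1.0 / (slope + intercept)
    c = slope / intercept + 1.0 if intercept != 0 else np.inf
    diagnostics = {"slope": float(slope), "intercept": float(intercept),
                   "r_squared": float(r2), "n_points": int(sel.sum())}
    if not np.isfinite(n_m) or n_m <= 0 or c <= 0:
        raise InvalidFitError(
            f"BET fit gave non-physical parameters (C={c:.3g}, n_m={n_m:.3g})",
            diagnostics=diagnostics)
    area = n_m * AVOGADRO * iso.cross_section_nm2 * 1e-18
    return BetResult(surface_area_m2_per_g=float(area), c_constant=float(c),
                     monolayer_mol_per_g=float(n_m), r_squared=float(r2),
                     n_points=int(sel.sum()), pressure_window=(p_lo, p_hi))


# ---------------------------------------------------------------------------
# Kelvin / thickness models and BJH


def kelvin_radius_nm(p_rel, temperature_K: float = 77.0) -> np.ndarray:
    """Kelvin core radius (nm) for a hemispherical meniscus (desorption)."""
    p_rel = np.asarray(p_rel, dtype=np.float64)
    k = 2.0 * N2_SURFACE_TENSION * N2_LIQUID_MOLAR_VOLUME * 1e-6 / (
        GAS_CONSTANT * temperature_K)  # meters
    return k * 1e9 / np.log(1.0 / p_rel)


def harkins_jura_t_nm(p_rel) -> np.ndarray:
    """Harkins-Jura statistical film thickness (nm) for N2 at 77 K."""
    p_rel = np.asarray(p_rel, dtype=np.float64)
    return 0.1 * np.sqrt(13.99 / (0.034 - np.log10(p_rel)))


_THICKNESS_MODELS = {"harkins_jura": harkins_jura_t_nm}


@dataclass(frozen=True)
class BjhResult:
    """BJH output: pore radii (nm) with incremental liquid volumes (cm^3/g).

    ``pore_radius_nm`` is the mean pore radius of each desorption step;
    ``step_radius_bounds_nm`` the (upper, lower) pore radii the step spans.
    """

    pore_radius_nm: np.ndarray
    incremental_volume_cm3_per_g: np.ndarray
    step_radius_bounds_nm: np.ndarray
    cumulative_area_m2_per_g: float

    @property
    def total_volume_cm3_per_g(self) -> float:
        return float(self.incremental_volume_cm3_per_g.sum())

    @property
    def volume_density_cm3_per_g_nm(self) -> np.ndarray:
        """dV/dr per step — the grid-independent size density."""
        widths = np.abs(self.step_radius_bounds_nm[:, 0]
                        - self.step_radius_bounds_nm[:, 1])
        return self.incremental_volume_cm3_per_g / np.maximum(widths, 1e-12)

    def modal_radius_nm(self) -> float:
        """Radius at the maximum of the volume density dV/dr."""
        if self.pore_radius_nm.size == 0:
            raise InvalidParameterError("empty BJH distribution has no mode")
        return float(self.pore_radius_nm[np.argmax(self.volume_density_cm3_per_g_nm)])

    def binned(self, scheme="rpr_table1") -> BinnedDistribution:
        """Volume-percent distribution over the image-analysis radius classes."""
        w = self.incremental_volume_cm3_per_g
        if w.sum() <= 0:
            raise InvalidParameterError("no pore volume to bin")
        # expand to a weighted histogram via bin_values on repeated samples is
        # wasteful; bin directly with the same right-closed convention
        edges = bin_values(np.array([1.0]), scheme).bin_edges_nm
        idx = np.searchsorted(edges, self.pore_radius_nm, side="left")
        percent = np.zeros(len(edges) + 1)
        np.add.at(percent, idx, w)
        percent *= 100.0 / w.sum()
        return BinnedDistribution(bin_edges_nm=edges, percent=percent,
                                  n_samples=int(self.pore_radius_nm.size))


def bjh_distribution(iso: Isotherm, thickness_model: str = "harkins_jura",
                     branch: str = "desorption", p_min: float = 0.30,
                     p_max: float = 0.995) -> BjhResult:
    """Classic BJH recursion on the desorption branch.

    Walking the branch from the highest relative pressure downward, each
    pressure step empties the cores of pores whose Kelvin radius falls in
    the step and thins the adsorbed film in all previously emptied pores.
    The core-to-pore conversion assumes cylindrical pores:
    r_pore = r_kelvin + t(p), with the standard (r_p / (r_k + dt))^2 volume
    correction and film-area bookkeeping.
    """
    if branch != "desorption":
        raise InvalidParameterError("BJH is defined here on the desorption branch")
    if thickness_model not in _THICKNESS_MODELS:
        raise InvalidParameterError(f"unknown thickness model {thickness_model!r}")
    t_of_p = _THICKNESS_MODELS[thickness_model]
    br = iso.desorption
    sel = (br[:, 0] >= p_min) & (br[:, 0] <= p_max)
    if sel.sum() < 5:
        raise InsufficientDataError(
            f"need >= 5 desorption points in [{p_min}, {p_max}], have {int(sel.sum())}")
    p = br[sel, 0][::-1]           # descending pressure
    v_liq = br[sel, 1][::-1] * N2_LIQUID_MOLAR_VOLUME  # cm^3 liquid / g
    if (np.diff(v_liq) > 1e-12).any():
        raise InvalidParameterError("desorption branch is not monotone in amount")

    r_k = kelvin_radius_nm(p, iso.temperature_K)
    t = t_of_p(p)
    r_p = r_k + t

    radii, volumes, bounds = [], [], []
    sum_area_m2 = 0.0           # film area of pores already emptied
    sum_av = 0.0                # sum of A_j * (1 - t/r_p_j) style terms
    kept_radii = []
    kept_areas = []
    for i in range(len(p) - 1):
        dv = v_liq[i] - v_liq[i + 1]
        dt_nm = t[i] - t[i + 1]
        if dv <= 0:
            continue
        r_k_avg = 0.5 * (r_k[i] + r_k[i + 1])
        t_avg = 0.5 * (t[i] + t[i + 1])
        r_p_avg = 0.5 * (r_p[i] + r_p[i + 1])
        # film volume desorbed from previously emptied pores this step
        film_cm3 = 0.0
        for rj, aj in zip(kept_radii, kept_areas):
            film_cm3 += dt_nm * aj * ((rj - t_avg) / rj) * 1e-3  # nm * m^2/g -> cm^3/g
        core = dv - film_cm3
        if core <= 0:
            continue
        scale = (r_p_avg / (r_k_avg + dt_nm)) ** 2
        vp = scale * core
        radii.append(r_p_avg)
        volumes.append(vp)
        bounds.append((r_p[i], r_p[i + 1]))
        area = 2e3 * vp / r_p_avg  # cylinder: A = 2 V / r, in m^2/g
        kept_radii.append(r_p_avg)
        kept_areas.append(area)
        sum_area_m2 += area
    if not radii:
        warnings.warn("BJH found no mesopore volume in the analysis window")
    return BjhResult(pore_radius_nm=np.asarray(radii),
                     incremental_volume_cm3_per_g=np.asarray(volumes),
                     step_radius_bounds_nm=np.asarray(bounds).reshape(-1, 2),
                     cumulative_area_m2_per_g=float(sum_area_m2))


def classify_hysteresis(iso: Isotherm, p_lo: float = 0.4, p_hi: float = 0.95,
                        rel_tol: float = 0.02) -> bool:
    """True if the sorption loop is hysteretic in ``p_lo < p/p0 < p_hi``.

    Interpolates both branches onto a common pressure grid and reports
    whether the desorption branch exceeds the adsorption branch by more
    than ``rel_tol`` (relative to the adsorption amount) anywhere in the
    window — the signature of a type-IV loop.
    """
    if iso.adsorption.size == 0 or iso.desorption.size == 0:
        raise InvalidParameterError("both branches are required")
    grid = np.linspace(p_lo, p_hi, 101)
    ads = np.interp(grid, iso.adsorption[:, 0], iso.adsorption[:, 1])
    des = np.interp(grid, iso.desorption[:, 0], iso.desorption[:, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        gap = np.where(ads > 0, (des - ads) / ads, 0.0)
    return bool(np.nanmax(gap) > rel_tol)
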