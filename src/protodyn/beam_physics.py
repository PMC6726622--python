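"""Analytic proton transport in homogeneous media.

Relativistic Bethe mass stopping power with Bragg additivity over the
elemental composition, continuous-slowing-down (CSDA) ranges, depth-energy
via the residual-range method, depth-dose curves with a Gaussian entrance
energy spread, and the fluence-to-dose conversion D = Phi * (S/rho).

Units: energies MeV, depths mm, densities g/cm^3, mass stopping power
MeV cm^2 g^-1, ranges g cm^-2, dose-per-fluence Gy per (proton cm^-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ._peaks import parabolic_peak
from .errors import DegenerateInputError, DomainError, InputError

# physical constants (CODATA 2018)
ELECTRON_MASS_MEV = 0.51099895000
PROTON_MASS_MEV = 938.27208816
K_BETHE = 0.307075            # 4 pi N_A r_e^2 m_e c^2, MeV cm^2 mol^-1
MEV_PER_G_TO_GY = 1.602176634e-10   # 1 MeV/g in Gy

ENERGY_MIN_MEV = 0.05         # validity floor; constant extrapolation below
ENERGY_MAX_MEV = 250.0

# Z, atomic mass (g/mol), mean excitation energy I (eV) per element
_ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "Na": (11, 22.990, 149.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "K": (19, 39.098, 190.0),
    "Ca": (20, 40.078, 191.0),
}


@dataclass(frozen=True)
class Medium:
    """Homogeneous stopping medium defined by elemental mass fractions.

    ``mean_excitation_energy`` may be given explicitly (condensed-phase
    I-values, e.g. 75 eV for liquid water); when omitted it is derived by
    Bragg additivity on ln(I) over the elements.
    """

    name: str
    density: float                       # g/cm^3
    composition: tuple[tuple[str, float], ...]
    mean_excitation_energy: float | None = None   # eV

    def __post_init__(self):
        if self.density <= 0:
            raise InputError(f"density must be positive, got {self.density}")
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise InputError(f"mass fractions sum to {total}, expected 1")
        for sym, w in self.composition:
            if sym not in _ELEMENTS:
                raise InputError(f"unknown element {sym!r}")
            if w < 0:
                raise InputError(f"negative mass fraction for {sym}")
        if self.mean_excitation_energy is not None and self.mean_excitation_energy <= 0:
            raise InputError("mean excitation energy must be positive")

    @property
    def z_over_a(self) -> float:
        """Effective <Z/A> in mol/g (mass-fraction weighted)."""
        return sum(w * _ELEMENTS[s][0] / _ELEMENTS[s][1] for s, w in self.composition)

    @property
    def i_value_ev(self) -> float:
        """Mean excitation energy in eV (explicit, or ln-additivity)."""
        if self.mean_excitation_energy is not None:
            return self.mean_excitation_energy
        num = sum(
            w * _ELEMENTS[s][0] / _ELEMENTS[s][1] * np.log(_ELEMENTS[s][2])
            for s, w in self.composition
        )
        return float(np.exp(num / self.z_over_a))


def _from_formula(counts: dict[str, int]) -> tuple[tuple[str, float], ...]:
    mass = {s: n * _ELEMENTS[s][1] for s, n in counts.items()}
    total = sum(mass.values())
    return tuple((s, m / total) for s, m in mass.items())


#: Built-in media library.
MEDIA: dict[str, Medium] = {
    "water": Medium("water", 1.00, _from_formula({"H": 2, "O": 1}), 75.0),
    "DMSO": Medium("DMSO", 1.10, _from_formula({"C": 2, "H": 6, "O": 1, "S": 1})),
    "polystyrene": Medium("polystyrene", 1.06, _from_formula({"C": 8, "H": 8}), 68.7),
    # dry gelatin, collagen-like elemental make-up
    "gelatin": Medium(
        "gelatin", 1.35,
        (("H", 0.066), ("C", 0.455), ("N", 0.167), ("O", 0.303), ("S", 0.009)),
    ),
    # ICRU-like four-component soft tissue
    "soft_tissue": Medium(
        "soft_tissue", 1.04,
        (("H", 0.101), ("C", 0.111), ("N", 0.026), ("O", 0.762)),
        72.3,
    ),
}


@dataclass(frozen=True)
class ProtonBeam:
    """Monodirectional proton beam entering the sample."""

    entrance_energy: float                     # MeV
    energy_spread_fwhm_fraction: float = 0.001
    fluence_rate: float = 8.0e8                # protons cm^-2 s^-1
    lateral_fwhm: float = 10.0                 # mm

    def __post_init__(self):
        if self.entrance_energy <= 0:
            raise InputError("entrance energy must be positive")
        if not (0.0 <= self.energy_spread_fwhm_fraction <= 0.05):
            raise InputError("energy spread FWHM fraction must lie in [0, 0.05]")
        if self.fluence_rate < 0:
            raise InputError("fluence rate must be non-negative")


@dataclass
class DepthDoseCurve:
    """Depth-dose curve per unit entrance fluence."""

    depth_grid: np.ndarray          # mm, increasing from 0
    dose_per_fluence: np.ndarray    # Gy per (proton cm^-2)
    medium: Medium
    energy: np.ndarray | None = None   # mean proton energy at depth, MeV

    def __post_init__(self):
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        self.dose_per_fluence = np.asarray(self.dose_per_fluence, dtype=float)
        if self.depth_grid.size != self.dose_per_fluence.size:
            raise InputError("depth grid and dose arrays differ in length")


def _check_energy(energy):
    e = np.asarray(energy, dtype=float)
    if np.any(e < ENERGY_MIN_MEV) or np.any(e > ENERGY_MAX_MEV):
        raise DomainError(
            f"energy outside validity window [{ENERGY_MIN_MEV}, {ENERGY_MAX_MEV}] MeV"
        )


def _beta2_gamma2(energy_mev):
    gamma = 1.0 + np.asarray(energy_mev, dtype=float) / PROTON_MASS_MEV
    beta2 = 1.0 - 1.0 / gamma**2
    return beta2, gamma**2


def _bethe(energy_mev, z_over_a: float, i_ev: float):
    """Bethe mass stopping power, no shell/Barkas/density corrections."""
    beta2, gamma2 = _beta2_gamma2(energy_mev)
    i_mev = i_ev * 1e-6
    arg = 2.0 * ELECTRON_MASS_MEV * beta2 * gamma2 / i_mev
    bracket = np.log(arg) - beta2
    # guard against unphysical negative bracket just above the floor
    bracket = np.maximum(bracket, 1e-3)
    return K_BETHE * z_over_a / beta2 * bracket


def mass_stopping_power(medium: Medium, energy) -> float | np.ndarray:
    """Mass stopping power S/rho in MeV cm^2 g^-1.

    Bragg additivity: with the medium's effective <Z/A> and ln-additive
    I-value this equals the mass-fraction weighted sum of elemental Bethe
    values.  Valid for 0.05 <= E <= 250 MeV.
    """
    _check_energy(energy)
    out = _bethe(energy, medium.z_over_a, medium.i_value_ev)
    return float(out) if np.isscalar(energy) else out


def _stopping_for_range(medium: Medium, energy):
    """S/rho with constant extrapolation below the validity floor."""
    e = np.maximum(np.asarray(energy, dtype=float), ENERGY_MIN_MEV)
    return _bethe(e, medium.z_over_a, medium.i_value_ev)


@dataclass
class StoppingPowerTable:
    """Log-spaced range-energy table for one medium."""

    medium: Medium
    energy_grid: np.ndarray = field(init=False)     # MeV
    s_over_rho: np.ndarray = field(init=False)      # MeV cm^2 g^-1
    csda_range: np.ndarray = field(init=False)      # g cm^-2

    n_points: int = 4000

    def __post_init__(self):
        self.energy_grid = np.geomspace(ENERGY_MIN_MEV, ENERGY_MAX_MEV, self.n_points)
        self.s_over_rho = _bethe(
            self.energy_grid, self.medium.z_over_a, self.medium.i_value_ev
        )
        # residual range below the floor: constant-S extrapolation
        r0 = ENERGY_MIN_MEV / self.s_over_rho[0]
        self.csda_range = r0 + cumulative_trapezoid(
            1.0 / self.s_over_rho, self.energy_grid, initial=0.0
        )

    def range_of(self, energy) -> float | np.ndarray:
        scalar = np.isscalar(energy)
        e = np.asarray(energy, dtype=float)
        _check_energy(e)
        out = np.exp(
            np.interp(np.log(e), np.log(self.energy_grid), np.log(self.csda_range))
        )
        return float(out) if scalar else out

    def energy_of_range(self, rng) -> float | np.ndarray:
        """Invert the range-energy table; 0 below the table floor."""
        scalar = np.isscalar(rng)
        r = np.asarray(rng, dtype=float)
        out = np.zeros_like(r)
        ok = r > self.csda_range[0]
        if np.any(ok):
            out[ok] = np.exp(
                np.interp(
                    np.log(r[ok]), np.log(self.csda_range), np.log(self.energy_grid)
                )
            )
        return float(out) if scalar else out


_TABLE_CACHE: dict[int, StoppingPowerTable] = {}


def _table(medium: Medium) -> StoppingPowerTable:
    key = id(medium)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = StoppingPowerTable(medium)
    return _TABLE_CACHE[key]


def csda_range(medium: Medium, energy: float) -> float:
    """CSDA range in g cm^-2: integral of dE'/(S/rho) from 0 to E."""
    _check_energy(energy)
    return _table(medium).range_of(energy)


def energy_at_depth(beam: ProtonBeam, medium: Medium, depth) -> float | np.ndarray:
    """Proton energy at depth (mm) via the residual-range method.

    Solves R(E0) - z*rho = R(E(z)); saturates at 0 at and beyond the end
    of range.
    """
    scalar = np.isscalar(depth)
    z = np.asarray(depth, dtype=float)
    if np.any(z < 0):
        raise InputError("depth must be non-negative")
    tbl = _table(medium)
    residual = tbl.range_of(beam.entrance_energy) - z / 10.0 * medium.density
    out = np.where(residual > 0, tbl.energy_of_range(np.maximum(residual, 1e-300)), 0.0)
    # depth 0 must return the entrance energy exactly, not its interpolant
    out = np.where(z == 0.0, beam.entrance_energy, out)
    return float(out) if scalar else out


_GH_NODES = 21

#: Bohr-like range straggling, sigma as a fraction of the CSDA range.
STRAGGLING_FRACTION = 0.012


def _invert_range(csda: np.ndarray, e_grid: np.ndarray, rng: np.ndarray) -> np.ndarray:
    """Energy whose range equals ``rng`` on an arbitrary range table."""
    out = np.zeros_like(rng)
    ok = rng > csda[0]
    if np.any(ok):
        out[ok] = np.exp(
            np.interp(np.log(rng[ok]), np.log(csda), np.log(e_grid))
        )
    return out


def _cell_edges(z: np.ndarray) -> np.ndarray:
    mid = 0.5 * (z[1:] + z[:-1])
    return np.concatenate(([z[0]], mid, [z[-1] + 0.5 * (z[-1] - z[-2])]))


def _deposition_profile(
    csda: np.ndarray,
    e_grid: np.ndarray,
    r0_nodes: np.ndarray,
    weights: np.ndarray,
    z_mm: np.ndarray,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-averaged energy deposition (MeV/g per proton cm^-2 fluence,
    before Gy conversion) and mean proton energy on the grid, averaged
    over a set of entrance-range nodes.

    Dose in each cell is (E(z_left) - E(z_right)) / (rho * dz), which
    telescopes to exact energy conservation over a grid spanning the range.
    """
    edges_cm = _cell_edges(z_mm) / 10.0
    dz_cm = np.diff(edges_cm)
    dep = np.zeros_like(z_mm)
    mean_energy = np.zeros_like(z_mm)
    for r0, w in zip(r0_nodes, weights):
        res_edges = np.maximum(r0 - edges_cm * rho, 1e-300)
        e_edges = _invert_range(csda, e_grid, res_edges)
        dep += w * (e_edges[:-1] - e_edges[1:]) / (dz_cm * rho)
        res_nodes = np.maximum(r0 - z_mm / 10.0 * rho, 1e-300)
        mean_energy += w * _invert_range(csda, e_grid, res_nodes)
    return np.maximum(dep, 0.0), mean_energy


def _range_nodes(
    tbl: StoppingPowerTable,
    entrance_energy: float,
    energy_spread_fwhm_fraction: float,
    straggling_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes over the entrance range, combining the entrance
    energy spread (propagated through dR/dE) with range straggling."""
    r0 = tbl.range_of(entrance_energy)
    sigma_e = entrance_energy * energy_spread_fwhm_fraction / (
        2.0 * np.sqrt(2.0 * np.log(2.0))
    )
    dr_de = 1.0 / _bethe(entrance_energy, tbl.medium.z_over_a, tbl.medium.i_value_ev)
    sigma_r = np.hypot(sigma_e * dr_de, straggling_fraction * r0)
    if sigma_r == 0:
        return np.array([r0]), np.array([1.0])
    x, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    return r0 + sigma_r * x, w / w.sum()


def depth_dose(
    beam: ProtonBeam,
    medium: Medium,
    depth_grid,
    straggling_fraction: float = STRAGGLING_FRACTION,
) -> DepthDoseCurve:
    """Depth-dose curve per unit fluence.

    The Gaussian entrance energy spread and a Gaussian range straggling
    term (sigma = ``straggling_fraction`` of the entrance range) are
    combined in quadrature and averaged with a deterministic 21-node
    Gauss-Hermite rule.  Energy is conserved: rho * integral(D) dz per
    proton equals the entrance energy when the grid spans the full range.
    """
    z = np.asarray(depth_grid, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise InputError("depth grid needs at least two points")
    if z[0] != 0 or np.any(np.diff(z) <= 0):
        raise InputError("depth grid must start at 0 and be strictly increasing")

    tbl = _table(medium)
    nodes, weights = _range_nodes(
        tbl, beam.entrance_energy, beam.energy_spread_fwhm_fraction,
        straggling_fraction,
    )
    dep, mean_energy = _deposition_profile(
        tbl.csda_range, tbl.energy_grid, nodes, weights, z, medium.density
    )
    return DepthDoseCurve(
        z, dep * MEV_PER_G_TO_GY, medium, energy=mean_energy
    )


def stopping_table(medium: Medium) -> StoppingPowerTable:
    """The cached range-energy table for a medium."""
    return _table(medium)


def dose_rate(fluence_rate: float, s_over_rho: float) -> float:
    """Dose rate in Gy/s from D = Phi * (S/rho)."""
    if fluence_rate < 0 or s_over_rho < 0:
        raise InputError("fluence rate and stopping power must be non-negative")
    return fluence_rate * s_over_rho * MEV_PER_G_TO_GY


def exposure_time_for_dose(dose_gy: float, rate_gy_per_s: float) -> float:
    """Irradiation time (s) to deliver a target dose at a constant rate."""
    if dose_gy < 0:
        raise InputError("dose must be non-negative")
    if rate_gy_per_s <= 0:
        raise InputError("dose rate must be positive")
    return dose_gy / rate_gy_per_s


def bragg_peak_depth(curve: DepthDoseCurve) -> float:
    """Depth of maximum dose (mm), parabolic sub-grid interpolation."""
    if curve.depth_grid.size == 0:
        raise DegenerateInputError("empty curve")
    return parabolic_peak(curve.depth_grid, curve.dose_per_fluence)
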