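"""Type-II singlet-oxygen photokinetics.

Two-pathway photobleaching model: a singlet-oxygen-mediated channel
(scavengeable by DABCO) and a direct ionisation channel (proton mode only).
The parent sensitiser P and its fluorescent photoproduct Q obey

    dP/dt = -(k_so + k_ion) P
    dQ/dt = eta * k_so * P - degradation_ratio * (k_so + k_ion) * Q

with k_so = sigma_so * excitation_rate * q(DABCO) and
k_ion = sigma_ion * fluence_rate (zero under light excitation).
q(DABCO) = tau_eff / tau_0 in (0, 1] is the singlet-oxygen survival factor
under collisional scavenging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.optimize import least_squares

from .errors import IdentifiabilityError, InputError

#: default singlet-oxygen lifetimes (s)
SO_LIFETIME_ACETONE_D6 = 1046e-6
SO_LIFETIME_WATER = 3.45e-6

BOOTSTRAP_SEED = 20190904
ODE_RTOL = 1e-8


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the two-pathway bleaching/photoproduct system."""

    so_lifetime: float = SO_LIFETIME_WATER       # s
    dabco_kq: float = 5e8                        # M^-1 s^-1
    dabco_conc: float = 0.0                      # M
    sigma_so: float = 0.0    # bleaching per unit 1O2 exposure
    sigma_ion: float = 0.0   # bleaching per unit proton fluence
    eta: float = 1.0         # photoproduct branching fraction
    degradation_ratio: float = 1.0   # photoproduct-vs-parent bleaching ratio

    def __post_init__(self):
        for name in ("so_lifetime", "dabco_kq", "dabco_conc", "sigma_so",
                     "sigma_ion", "eta", "degradation_ratio"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.eta > 1.0:
            raise InputError("eta must not exceed 1")

    @property
    def quench_factor(self) -> float:
        """tau_eff / tau_0: fraction of singlet oxygen surviving DABCO."""
        return 1.0 / (1.0 + self.dabco_kq * self.dabco_conc * self.so_lifetime)


@dataclass
class KineticTrace:
    """Normalised parent / photoproduct fluorescence versus exposure."""

    time_grid: np.ndarray
    parent_fluorescence: np.ndarray
    photoproduct_fluorescence: np.ndarray
    mode: str = "light"              # "light" | "proton"
    dabco_conc: float = 0.0
    excitation_rate: float = 1.0
    fluence_rate: float = 1.0

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.parent_fluorescence = np.asarray(self.parent_fluorescence, dtype=float)
        self.photoproduct_fluorescence = np.asarray(
            self.photoproduct_fluorescence, dtype=float
        )
        if self.mode not in ("light", "proton"):
            raise InputError(f"unknown mode {self.mode!r}")


def singlet_oxygen_yield(
    excitation_rate: float, params: KineticParams, isc_yield: float = 1.0
) -> float:
    """Steady-state singlet-oxygen level (arbitrary units).

    Proportional to excitation_rate * isc_yield * tau_eff with
    1/tau_eff = 1/so_lifetime + dabco_kq * dabco_conc; monotone decreasing
    in the DABCO concentration.
    """
    if excitation_rate < 0:
        raise InputError("excitation rate must be non-negative")
    tau_eff = 1.0 / (1.0 / params.so_lifetime + params.dabco_kq * params.dabco_conc)
    return excitation_rate * isc_yield * tau_eff


def _rates(mode: str, params: KineticParams,
           excitation_rate: float, fluence_rate: float) -> tuple[float, float]:
    k_so = params.sigma_so * excitation_rate * params.quench_factor
    k_ion = params.sigma_ion * fluence_rate if mode == "proton" else 0.0
    return k_so, k_ion


def _closed_form(t, k_so, k_ion, eta, dr):
    """Constant-rate solution of the P/Q system."""
    k = k_so + k_ion
    p = np.exp(-k * t)
    a = eta * k_so
    b = dr * k
    if a == 0:
        q = np.zeros_like(t)
    elif abs(b - k) < 1e-12 * max(k, 1.0):
        q = a * t * np.exp(-k * t)
    else:
        q = a / (b - k) * (np.exp(-k * t) - np.exp(-b * t))
    return p, q


def simulate_bleaching(
    mode: str,
    params: KineticParams,
    exposure_grid,
    excitation_rate: float = 1.0,
    fluence_rate: float = 1.0,
    method: str = "ode",
) -> KineticTrace:
    """Integrate the bleaching/photoproduct system over an exposure grid.

    ``method="ode"`` uses an adaptive solver (rtol 1e-8); ``"analytic"``
    evaluates the constant-rate closed form (the two agree to solver
    tolerance and the analytic path is used inside fitting loops).
    """
    t = np.asarray(exposure_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise InputError("exposure grid must increase strictly from 0")
    if mode not in ("light", "proton"):
        raise InputError(f"unknown mode {mode!r}")
    k_so, k_ion = _rates(mode, params, excitation_rate, fluence_rate)

    if method == "analytic":
        p, q = _closed_form(t, k_so, k_ion, params.eta, params.degradation_ratio)
    else:
        k = k_so + k_ion
        b = params.degradation_ratio * k

        def rhs(_t, y):
            return [-k * y[0], params.eta * k_so * y[0] - b * y[1]]

        sol = solve_ivp(
            rhs, (t[0], t[-1]), [1.0, 0.0], t_eval=t,
            rtol=ODE_RTOL, atol=1e-12, method="LSODA",
        )
        p, q = sol.y[0], sol.y[1]

    return KineticTrace(
        t, p, np.maximum(q, 0.0), mode=mode,
        dabco_conc=params.dabco_conc,
        excitation_rate=excitation_rate, fluence_rate=fluence_rate,
    )


def fit_parent_decay_rate(trace: KineticTrace) -> float:
    """Exponential decay rate of the parent channel (log-linear LSQ)."""
    p = trace.parent_fluorescence
    if np.any(p <= 0):
        raise InputError("parent fluorescence must stay positive")
    if np.any(np.diff(p) > 1e-9):
        raise InputError("parent trace must be non-increasing")
    t = trace.time_grid
    # slope of ln P vs t through the origin (P(0) = 1 by normalisation)
    denom = float(np.sum(t * t))
    if denom == 0:
        raise InputError("degenerate time grid")
    return float(-np.sum(t * np.log(p)) / denom)


def deconvolve_photoproduct(
    observed: KineticTrace, params: KineticParams
) -> np.ndarray:
    """Cumulative photoproduct formation, corrected for its own destruction.

    Assumes the photoproduct degrades like the parent (scaled by
    ``degradation_ratio``): G(t) = Q(t) + k_deg * integral(Q) with
    k_deg = degradation_ratio * fitted parent decay rate.  G is the
    cumulative formation; it is non-decreasing.
    """
    k_parent = fit_parent_decay_rate(observed)
    k_deg = params.degradation_ratio * k_parent
    q = observed.photoproduct_fluorescence
    t = observed.time_grid
    g = q + k_deg * cumulative_trapezoid(q, t, initial=0.0)
    return g


@dataclass
class KineticFit:
    params: KineticParams
    residual_rms: float
    stderr: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    free_names: tuple = ()


#: floor for the relative-residual weighting (avoids exploding weights
#: where the photoproduct signal is near zero)
RESIDUAL_FLOOR = 0.05


def _model_residuals(theta, free_names, base, traces):
    """Relative residuals: fluorescence noise scales with the signal, so
    weighting by the model value makes the LSQ estimator near-efficient."""
    params = replace(base, **dict(zip(free_names, np.maximum(theta, 0.0))))
    res = []
    for tr in traces:
        p_run = replace(params, dabco_conc=tr.dabco_conc)
        sim = simulate_bleaching(
            tr.mode, p_run, tr.time_grid,
            excitation_rate=tr.excitation_rate, fluence_rate=tr.fluence_rate,
            method="analytic",
        )
        res.append(
            (sim.parent_fluorescence - tr.parent_fluorescence)
            / np.maximum(sim.parent_fluorescence, RESIDUAL_FLOOR)
        )
        res.append(
            (sim.photoproduct_fluorescence - tr.photoproduct_fluorescence)
            / np.maximum(sim.photoproduct_fluorescence, RESIDUAL_FLOOR)
        )
    return np.concatenate(res)


def fit_kinetics(
    traces: list[KineticTrace],
    fixed: KineticParams | None = None,
    free: tuple[str, ...] = ("sigma_so", "sigma_ion"),
    n_bootstrap: int = 30,
    seed: int = BOOTSTRAP_SEED,
) -> KineticFit:
    """Least-squares estimation of free kinetic parameters from traces.

    Requires conditions that make the free parameters identifiable:
    ``sigma_ion`` needs at least one proton-mode trace, and separating
    ``sigma_so`` from ``sigma_ion`` needs DABCO contrast or a light-mode
    trace.  Uncertainty comes from a seeded wild (Rademacher) residual
    bootstrap; ``ci95`` is the normal-approximation interval
    estimate +/- 1.96 * bootstrap SD.
    """
    if len(traces) < 2:
        raise IdentifiabilityError("need at least two traces (conditions)")
    modes = {tr.mode for tr in traces}
    dabco = {tr.dabco_conc > 0 for tr in traces}
    if "sigma_ion" in free and "proton" not in modes:
        raise IdentifiabilityError(
            "sigma_ion is unidentifiable without a proton-mode trace"
        )
    if "sigma_so" in free and "sigma_ion" in free:
        if modes == {"proton"} and len(dabco) == 1:
            raise IdentifiabilityError(
                "sigma_so/sigma_ion cannot be separated: add a DABCO or "
                "light-mode condition"
            )
    base = fixed if fixed is not None else KineticParams()

    x0 = np.array([max(getattr(base, n), 0.05) for n in free])
    sol = least_squares(
        _model_residuals, x0, args=(free, base, traces),
        bounds=(0.0, np.inf), xtol=1e-12, ftol=1e-12,
    )
    best = dict(zip(free, sol.x))
    resid = sol.fun
    rms = float(np.sqrt(np.mean(resid**2)))

    boot: dict[str, list[float]] = {n: [] for n in free}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        fitted_parts = []
        params_hat = replace(base, **best)
        for tr in traces:
            p_run = replace(params_hat, dabco_conc=tr.dabco_conc)
            sim = simulate_bleaching(
                tr.mode, p_run, tr.time_grid,
                excitation_rate=tr.excitation_rate, fluence_rate=tr.fluence_rate,
                method="analytic",
            )
            fitted_parts.append((sim.parent_fluorescence, sim.photoproduct_fluorescence))
        # per-point residuals of the best fit, in trace order
        resid_parts = [
            (p_hat - tr.parent_fluorescence, q_hat - tr.photoproduct_fluorescence)
            for (p_hat, q_hat), tr in zip(fitted_parts, traces)
        ]
        for _ in range(n_bootstrap):
            # wild bootstrap: Rademacher-weighted own-position residuals,
            # robust to the heteroscedastic (signal-proportional) noise
            resampled = []
            for (p_hat, q_hat), (rp, rq), tr in zip(
                fitted_parts, resid_parts, traces
            ):
                n = tr.time_grid.size
                vp = rng.choice([-1.0, 1.0], size=n)
                vq = rng.choice([-1.0, 1.0], size=n)
                resampled.append(
                    KineticTrace(
                        tr.time_grid,
                        np.clip(p_hat + vp * rp, 1e-9, None),
                        np.maximum(q_hat + vq * rq, 0.0),
                        mode=tr.mode, dabco_conc=tr.dabco_conc,
                        excitation_rate=tr.excitation_rate,
                        fluence_rate=tr.fluence_rate,
                    )
                )
            bsol = least_squares(
                _model_residuals, sol.x, args=(free, base, resampled),
                bounds=(0.0, np.inf), xtol=1e-10, ftol=1e-10,
            )
            for n_, v in zip(free, bsol.x):
                boot[n_].append(float(v))

    stderr = {n: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
              for n, v in boot.items()}
    ci95 = {
        n: (best[n] - 1.96 * stderr[n], best[n] + 1.96 * stderr[n])
        if np.isfinite(stderr[n]) else (float("nan"), float("nan"))
        for n in free
    }
    return KineticFit(
        params=replace(base, **best),
        residual_rms=rms, stderr=stderr, ci95=ci95, free_names=tuple(free),
    )


@dataclass
class PhosphorescenceRatio:
    value: float
    lower_bound: bool = False   # True when the quenched band is absent


def phosphorescence_ratio(
    emission_with_quenching,
    emission_without,
    n_bands: int = 2,
) -> PhosphorescenceRatio:
    """Ratio of integrated phosphorescence bands (unquenched / quenched).

    Both spectra are decomposed into Gaussian bands (the phosphorescence
    band is the reddest one); the ratio of band areas is returned.  When
    the quenched band is absent the ratio is reported as a lower bound.
    """
    from .spectra import band_decompose

    a = emission_with_quenching
    b = emission_without
    if not np.array_equal(a.wavelength, b.wavelength):
        raise InputError("spectra must share a wavelength grid")
    fit_q = band_decompose(a, n_bands)
    fit_u = band_decompose(b, n_bands)
    area_q = fit_q.bands[-1][2]
    area_u = fit_u.bands[-1][2]
    if area_q <= 0 or area_q < 1e-12 * max(area_u, 1.0):
        # quenched band not detectable: report a floor-limited lower bound
        floor = max(area_q, 1e-12 * max(area_u, 1.0))
        return PhosphorescenceRatio(float(area_u / floor), lower_bound=True)
    ratio = area_u / area_q
    return PhosphorescenceRatio(float(ratio))
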