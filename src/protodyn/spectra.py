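"""Emission-spectrum handling: I/O, despiking, background subtraction,
band decomposition and proton-versus-photon spectral matching.

CCD registrations under proton irradiation carry sparse high-amplitude
spikes (scintillation artefacts of the ionising radiation); ``despike``
removes them with a running-median / robust-z filter before any
quantitative comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .errors import AnalysisError, InputError

DESPIKE_WINDOW = 7
DESPIKE_Z = 6.0


@dataclass
class EmissionSpectrum:
    wavelength: np.ndarray          # nm, strictly increasing
    intensity: np.ndarray           # counts
    channel: str = "visible"        # "visible" | "nir"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.size != self.intensity.size:
            raise InputError("wavelength and intensity lengths differ")
        if np.any(np.diff(self.wavelength) <= 0):
            raise InputError("wavelength grid must be strictly increasing")

    def copy_with(self, intensity: np.ndarray) -> "EmissionSpectrum":
        return EmissionSpectrum(
            self.wavelength.copy(), np.asarray(intensity, dtype=float),
            channel=self.channel, metadata=dict(self.metadata),
        )


def read_spectrum(path: str | Path, channel: str = "visible") -> EmissionSpectrum:
    """Read a two-column (wavelength_nm, intensity) CSV, header optional."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected at least two columns")
    cols = list(df.columns)
    try:
        float(cols[0])
    except ValueError:
        pass
    else:   # headerless file: first row was data
        df = pd.read_csv(path, header=None)
    return EmissionSpectrum(
        df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), channel=channel
    )


def write_spectrum(spectrum: EmissionSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength, "intensity": spectrum.intensity}
    ).to_csv(path, index=False)


def despike(
    spectrum: EmissionSpectrum,
    window: int = DESPIKE_WINDOW,
    z_threshold: float = DESPIKE_Z,
    floor_fraction: float = 0.01,
) -> EmissionSpectrum:
    """Remove radiation-induced CCD spikes.

    Points deviating from the running median by more than ``z_threshold``
    robust standard deviations (1.4826 * MAD of the deviations) are
    replaced with the local median.  An absolute deviation floor of
    ``floor_fraction`` of the spectrum's dynamic range keeps the smooth
    curvature of noise-free bands (where the MAD collapses to ~0) from
    being flagged.  Iterated to a fixed point, so the operation is
    idempotent.
    """
    if window < 3 or window % 2 == 0:
        raise InputError("window must be odd and >= 3")
    if window > spectrum.intensity.size:
        raise InputError("window longer than spectrum")
    y = spectrum.intensity.astype(float).copy()
    for _ in range(10):
        med = median_filter(y, size=window, mode="nearest")
        dev = y - med
        scale = 1.4826 * np.median(np.abs(dev))
        threshold = z_threshold * scale + floor_fraction * np.ptp(y)
        if threshold == 0:
            break
        bad = np.abs(dev) > threshold
        if not np.any(bad):
            break
        y[bad] = med[bad]
    return spectrum.copy_with(y)


def subtract_background(
    sample: EmissionSpectrum,
    dark: EmissionSpectrum,
    solvent: EmissionSpectrum | None = None,
) -> EmissionSpectrum:
    """Dark-current and (optionally) solvent-contribution subtraction.

    Returns sample - dark - (solvent - dark) when a solvent spectrum is
    given, else sample - dark.
    """
    if not np.array_equal(sample.wavelength, dark.wavelength):
        raise InputError("sample and dark spectra on different grids")
    out = sample.intensity - dark.intensity
    if solvent is not None:
        if not np.array_equal(sample.wavelength, solvent.wavelength):
            raise InputError("sample and solvent spectra on different grids")
        out = out - (solvent.intensity - dark.intensity)
    return sample.copy_with(out)


def spectral_match(a: EmissionSpectrum, b: EmissionSpectrum) -> float:
    """Similarity in [-1, 1] between two emission spectra.

    Pearson correlation of despiked, area-normalised intensities on the
    common wavelength grid; requires at least 50 nm of overlap.
    """
    lo = max(a.wavelength[0], b.wavelength[0])
    hi = min(a.wavelength[-1], b.wavelength[-1])
    if hi - lo < 50.0:
        raise InputError(f"spectral overlap {hi - lo:.1f} nm < 50 nm")
    a_c = despike(a)
    b_c = despike(b)
    mask = (a_c.wavelength >= lo) & (a_c.wavelength <= hi)
    grid = a_c.wavelength[mask]
    ya = a_c.intensity[mask]
    yb = np.interp(grid, b_c.wavelength, b_c.intensity)

    def _area_norm(y):
        area = np.trapezoid(np.abs(y), grid)
        return y / area if area > 0 else y

    r, _ = pearsonr(_area_norm(ya), _area_norm(yb))
    return float(r)


@dataclass
class BandFit:
    """Result of a Gaussian band decomposition.

    ``aic``/``bic`` support model comparison across band counts; BIC's
    stronger penalty is the better over-fitting detector at typical
    spectrum lengths.
    """

    bands: list[tuple[float, float, float]]   # (centre nm, sigma nm, area)
    residual_rms: float
    aic: float
    bic: float
    n_bands: int


def _gauss_sum(x, theta):
    n = theta.size // 3
    y = np.zeros_like(x)
    for i in range(n):
        amp, c, s = theta[3 * i: 3 * i + 3]
        y = y + amp * np.exp(-0.5 * ((x - c) / s) ** 2)
    return y


def band_decompose(spectrum: EmissionSpectrum, n_bands: int) -> BandFit:
    """Least-squares Gaussian mixture decomposition of an emission spectrum.

    Bands are returned sorted by centre as (centre, sigma, area); the fit
    residual RMS and an AIC value are reported so over-fitting (more bands
    than the data support) can be detected by model comparison.
    """
    if n_bands < 1:
        raise InputError("n_bands must be >= 1")
    x = spectrum.wavelength
    y = spectrum.intensity
    span = x[-1] - x[0]

    # initial guesses from the most prominent local maxima
    peaks, props = find_peaks(y, prominence=0.02 * max(np.ptp(y), 1e-30))
    order = np.argsort(props["prominences"])[::-1] if peaks.size else np.array([], int)
    centres = list(x[peaks[order[:n_bands]]])
    while len(centres) < n_bands:
        centres.append(x[0] + span * (len(centres) + 0.5) / n_bands)
    centres.sort()

    theta0, lb, ub = [], [], []
    amp0 = max(y.max(), 1e-12)
    for c in centres:
        theta0 += [max(float(np.interp(c, x, y)), 1e-9 * amp0), c,
                   span / (6.0 * n_bands)]
        lb += [0.0, x[0] - span, 1e-3]
        ub += [10.0 * amp0, x[-1] + span, span]
    sol = least_squares(
        lambda th: _gauss_sum(x, th) - y,
        np.asarray(theta0), bounds=(np.asarray(lb), np.asarray(ub)),
        xtol=1e-12, ftol=1e-12,
    )
    if not sol.success:
        raise AnalysisError(f"band fit failed to converge: {sol.message}")
    rss = float(np.sum(sol.fun**2))
    n = x.size
    k = 3 * n_bands
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    bic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
    bands = []
    for i in range(n_bands):
        amp, c, s = sol.x[3 * i: 3 * i + 3]
        bands.append((float(c), float(s), float(amp * s * np.sqrt(2.0 * np.pi))))
    bands.sort(key=lambda b: b[0])
    return BandFit(bands=bands, residual_rms=float(np.sqrt(rss / n)),
                   aic=float(aic), bic=float(bic), n_bands=n_bands)
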