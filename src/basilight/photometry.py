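"""Spectral band integration and photometric unit conversions.

Greenhouse supplemental-lighting work runs on a handful of photometric
bookkeeping steps: integrating a lamp's spectral photon flux over wavebands
(PPFD over 400-700 nm, or 400-800 nm when far-red is counted as
photosynthetically active), converting instantaneous photon flux to daily
light integrals and on to energy, and forming the red:far-red ratio that
drives shade-avoidance responses.  This module holds those primitives.

Units follow horticultural convention throughout: spectral photon flux in
umol m-2 s-1 nm-1, band photon flux (PPFD) in umol m-2 s-1, daily light
integrals (DLI) in mol m-2 d-1, and daily light energy in MJ m-2 d-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BandIntegral",
    "ENERGY_PER_MOL_PAR",
    "integrate_band",
    "red_farred_ratio",
    "ppfd_to_dli",
    "dli_to_ppfd",
    "dli_to_energy",
    "energy_to_dli",
    "transmission_factor",
    "sl_nl_ratio",
    "read_environment_csv",
    "write_environment_csv",
]

#: Energy content of one mole of PAR photons under a typical broadband
#: horticultural spectrum, MJ mol-1 (Thimijan-Heins conversion factor).
ENERGY_PER_MOL_PAR = 0.219

#: Default red and far-red wavebands for the R:FR ratio (nm), the narrow
#: 10 nm bands centred on 660 and 730 nm used in the phytochrome literature.
RED_BAND = (655.0, 665.0)
FARRED_BAND = (725.0, 735.0)

ENVIRONMENT_COLUMNS = [
    "day",
    "mean_temp_C",
    "natural_dli_700",
    "natural_dli_800",
    "photoperiod_h",
]


@dataclass(frozen=True)
class Spectrum:
    """A spectral photon flux distribution on an instrument wavelength grid.

    Parameters
    ----------
    wavelength_nm
        Strictly ascending wavelengths (nm).
    photon_flux
        Spectral photon flux density at each grid point
        (umol m-2 s-1 nm-1); non-negative.
    """

    wavelength_nm: np.ndarray
    photon_flux: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        fl = np.asarray(self.photon_flux, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectrum needs at least two grid points")
        if fl.shape != wl.shape:
            raise ValueError("wavelength and flux grids differ in length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(fl < 0):
            raise ValueError("photon flux must be non-negative")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "photon_flux", fl)

    def scaled(self, factor: float) -> "Spectrum":
        """Return a copy with the flux multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return Spectrum(self.wavelength_nm, self.photon_flux * factor)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        """Read a two-column ``wavelength_nm,photon_flux`` CSV."""
        df = pd.read_csv(path)
        missing = {"wavelength_nm", "photon_flux"} - set(df.columns)
        if missing:
            raise ValueError(
                f"spectrum CSV {path} missing columns: {sorted(missing)}"
            )
        return cls(df["wavelength_nm"].to_numpy(), df["photon_flux"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelength_nm, "photon_flux": self.photon_flux}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BandIntegral:
    """Photon flux integrated over one waveband (umol m-2 s-1)."""

    band_low_nm: float
    band_high_nm: float
    value: float

    def __post_init__(self) -> None:
        if not self.band_low_nm < self.band_high_nm:
            raise ValueError("band_low_nm must be below band_high_nm")
        if self.value < 0:
            raise ValueError("band integral cannot be negative")


def integrate_band(spectrum: Spectrum, low_nm: float, high_nm: float) -> BandIntegral:
    """Trapezoidal integral of spectral photon flux over ``[low_nm, high_nm]``.

    The integral is taken on the native instrument grid, with the band edges
    inserted by linear interpolation; no resampling.  Result in
    umol m-2 s-1.

    Raises
    ------
    ValueError
        If the band limits are inverted or the spectrum does not cover the
        requested band.
    """
    if not low_nm < high_nm:
        raise ValueError("low_nm must be below high_nm")
    wl = spectrum.wavelength_nm
    if low_nm < wl[0] or high_nm > wl[-1]:
        raise ValueError(
            f"spectrum covers [{wl[0]:g}, {wl[-1]:g}] nm; "
            f"band [{low_nm:g}, {high_nm:g}] nm is outside coverage"
        )
    inside = (wl > low_nm) & (wl < high_nm)
    grid = np.concatenate(([low_nm], wl[inside], [high_nm]))
    flux = np.interp(grid, wl, spectrum.photon_flux)
    value = float(np.trapezoid(flux, grid))
    return BandIntegral(low_nm, high_nm, max(value, 0.0))


def red_farred_ratio(
    spectrum: Spectrum,
    red_band: tuple[float, float] = RED_BAND,
    farred_band: tuple[float, float] = FARRED_BAND,
) -> float:
    """Red to far-red photon flux ratio (dimensionless).

    Defaults to the 655-665 nm / 725-735 nm convention.  Scale-invariant in
    the overall flux level.

    Raises
    ------
    ZeroDivisionError
        If the far-red band carries no photons.
    """
    red = integrate_band(spectrum, *red_band).value
    farred = integrate_band(spectrum, *farred_band).value
    if farred == 0.0:
        raise ZeroDivisionError("far-red band integral is zero; R:FR undefined")
    return red / farred


def ppfd_to_dli(ppfd: float, photoperiod_h: float) -> float:
    """Instantaneous PPFD (umol m-2 s-1) to daily light integral (mol m-2 d-1).

    Assumes the flux is held for ``photoperiod_h`` hours, as under a lamp
    on a fixed timer: ``ppfd * photoperiod_h * 3600 * 1e-6``.
    """
    if ppfd < 0:
        raise ValueError("ppfd must be non-negative")
    if not 0 <= photoperiod_h <= 24:
        raise ValueError("photoperiod must be within 0-24 h")
    return ppfd * photoperiod_h * 3600.0 * 1e-6


def dli_to_ppfd(dli: float, photoperiod_h: float) -> float:
    """Inverse of :func:`ppfd_to_dli` for a positive photoperiod."""
    if dli < 0:
        raise ValueError("dli must be non-negative")
    if not 0 < photoperiod_h <= 24:
        raise ValueError("photoperiod must be within (0, 24] h")
    return dli / (photoperiod_h * 3600.0 * 1e-6)


def dli_to_energy(dli: float) -> float:
    """Daily light integral (mol m-2 d-1) to daily energy (MJ m-2 d-1)."""
    if dli < 0:
        raise ValueError("dli must be non-negative")
    return dli * ENERGY_PER_MOL_PAR


def energy_to_dli(energy_mj: float) -> float:
    """Inverse of :func:`dli_to_energy`."""
    if energy_mj < 0:
        raise ValueError("energy must be non-negative")
    return energy_mj / ENERGY_PER_MOL_PAR


def transmission_factor(inside_series, outside_series) -> float:
    """Greenhouse light transmission from paired daily PPFD series.

    Arithmetic mean over days of the inside/outside ratio.  For a physical
    greenhouse the result lies in (0, 1].
    """
    inside = np.asarray(inside_series, dtype=float)
    outside = np.asarray(outside_series, dtype=float)
    if inside.shape != outside.shape or inside.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    if np.any(outside <= 0):
        raise ZeroDivisionError("outside PPFD must be positive every day")
    if np.any(inside < 0):
        raise ValueError("inside PPFD must be non-negative")
    return float(np.mean(inside / outside))


def sl_nl_ratio(supplemental_sum: float, natural_sum: float) -> float:
    """Ratio of supplemental to natural light received over a period.

    Both arguments are cumulated light sums (mol m-2 or MJ m-2, same unit).
    An SL/NL above 1 means the lamps delivered more light than the sun did
    inside the greenhouse — the regime where supplemental light drives most
    of the growth response.
    """
    if natural_sum <= 0:
        raise ValueError("natural light sum must be positive")
    if supplemental_sum < 0:
        raise ValueError("supplemental light sum must be non-negative")
    return supplemental_sum / natural_sum


def read_environment_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a daily-environment table.

    Expected columns: ``day, mean_temp_C, natural_dli_700, natural_dli_800,
    photoperiod_h``; one row per day since treatment start.
    """
    df = pd.read_csv(path)
    missing = set(ENVIRONMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"environment CSV {path} missing columns: {sorted(missing)}"
        )
    df = df[ENVIRONMENT_COLUMNS].copy()
    if (df["natural_dli_700"] < 0).any():
        raise ValueError("natural_dli_700 must be non-negative")
    if (df["natural_dli_800"] < df["natural_dli_700"] - 1e-12).any():
        raise ValueError("natural_dli_800 must be >= natural_dli_700")
    if ((df["photoperiod_h"] < 0) | (df["photoperiod_h"] > 24)).any():
        raise ValueError("photoperiod_h must be within 0-24 h")
    return df


def write_environment_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[ENVIRONMENT_COLUMNS].to_csv(path, index=False)
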