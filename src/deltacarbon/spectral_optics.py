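"""Hyperspectral underwater light model.

Downwelling shortwave irradiance is restricted to its UV-visible fraction
(factor 0.43), distributed across wavelength bands by a normalized black-body
(Planck, 5778 K) spectrum, attenuated through the water column with a
semi-analytical diffuse attenuation coefficient

    kd(lambda) = (1 + m0 * theta_s) * a_t + m1 * (1 - m2 * exp(-m3 * a_t)) * b_b

and propagated layer by layer with Beer-Lambert exponentials.  Total
absorption a_t is the sum of pure water plus mass-specific contributions from
three chromophoric DOC classes, phytoplankton chlorophyll, and suspended
particulate matter (SPM = ISS + LPOC + RPOC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralGrid",
    "IOPLibrary",
    "IrradianceProfile",
    "build_surface_spectrum",
    "total_absorption",
    "kd_spectrum",
    "propagate",
    "photon_flux",
    "solar_zenith_default",
    "KD_COEFFICIENTS",
    "UV_VIS_FRACTION",
]

# Planck constants and unit bridge for mol-photon conversion
_H = 6.62607015e-34     # J s
_C = 2.99792458e8       # m s-1
_NA = 6.02214076e23     # mol-1
_K_B = 1.380649e-23     # J K-1
_T_SUN = 5778.0         # K, solar black-body temperature

#: fraction of broadband shortwave in the 285-700 nm UV-visible window
UV_VIS_FRACTION = 0.43

#: semi-analytical kd coefficients (m0, m1, m2, m3)
KD_COEFFICIENTS = (0.005, 4.18, 0.52, 10.8)

#: default solar zenith angle (degrees) when forcing provides none
solar_zenith_default = 30.0

# Pure-water absorption (m-1): compact table spanning 285-700 nm with the
# characteristic UV rise, clear-water minimum near 420 nm, and red rise.
_WATER_A_TABLE = np.array([
    (285, 0.0390), (290, 0.0340), (300, 0.0141), (310, 0.0105),
    (320, 0.0084), (330, 0.0068), (340, 0.0056), (350, 0.0046),
    (360, 0.0036), (370, 0.0029), (380, 0.0023), (390, 0.0020),
    (400, 0.0046), (410, 0.0047), (420, 0.0045), (430, 0.0050),
    (440, 0.0064), (450, 0.0092), (460, 0.0098), (470, 0.0106),
    (480, 0.0127), (490, 0.0150), (500, 0.0204), (510, 0.0325),
    (520, 0.0409), (530, 0.0434), (540, 0.0474), (550, 0.0565),
    (560, 0.0619), (570, 0.0695), (580, 0.0896), (590, 0.1351),
    (600, 0.2224), (610, 0.2644), (620, 0.2755), (630, 0.2916),
    (640, 0.3108), (650, 0.3400), (660, 0.4100), (670, 0.4390),
    (680, 0.4650), (690, 0.5160), (700, 0.6240),
])

# Pure-water backscatter bb_w at 500 nm (m-1) with lambda^-4.32 dependence
_BB_W_500 = 0.00144
_BB_W_EXP = -4.32


@dataclass(frozen=True)
class SpectralGrid:
    """Ascending wavelength axis (nm) with a uniform band width (nm)."""

    wavelengths: np.ndarray
    band_width: float = 5.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength axis must be a 1-d array with >= 2 bands")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(wl <= 0) or self.band_width <= 0:
            raise ValueError("wavelengths and band width must be positive")

    @classmethod
    def default(cls) -> "SpectralGrid":
        """285-700 nm inclusive at 5 nm spacing (84 bands)."""
        return cls(wavelengths=np.arange(285.0, 700.1, 5.0), band_width=5.0)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def par_mask(self) -> np.ndarray:
        """Boolean mask of the photosynthetically active 400-700 nm window."""
        wl = self.wavelengths
        return (wl >= 400.0) & (wl <= 700.0)

    def index_nearest(self, wavelength: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - wavelength)))


def water_absorption(grid: SpectralGrid) -> np.ndarray:
    """Pure-water absorption (m-1) interpolated onto ``grid``."""
    return np.interp(grid.wavelengths, _WATER_A_TABLE[:, 0], _WATER_A_TABLE[:, 1])


def water_backscatter(grid: SpectralGrid) -> np.ndarray:
    """Pure-water backscatter (m-1), power-law in wavelength."""
    return _BB_W_500 * (grid.wavelengths / 500.0) ** _BB_W_EXP


def _exponential_spectrum(grid: SpectralGrid, a_ref: float, slope: float,
                          ref_wavelength: float = 300.0) -> np.ndarray:
    return a_ref * np.exp(-slope * (grid.wavelengths - ref_wavelength))


def _phytoplankton_spectrum(grid: SpectralGrid, peak: float = 0.035) -> np.ndarray:
    """Chlorophyll-specific absorption (m2 mg chl-1): blue + red Gaussian peaks."""
    wl = grid.wavelengths
    blue = np.exp(-0.5 * ((wl - 440.0) / 35.0) ** 2)
    red = 0.55 * np.exp(-0.5 * ((wl - 675.0) / 12.0) ** 2)
    uv = 0.35 * np.exp(-0.5 * ((wl - 330.0) / 40.0) ** 2)
    return peak * (blue + red + uv)


@dataclass(frozen=True)
class IOPLibrary:
    """Mass-specific inherent optical properties on a shared grid.

    Units: ``a_w``/``bb_w`` m-1; CDOC spectra m2 (g C)-1; ``a_star_phi``
    m2 (mg chl)-1; SPM spectra m2 g-1.
    """

    grid: SpectralGrid
    a_w: np.ndarray
    a_star_cdoc_w: np.ndarray
    a_star_cdoc_ss: np.ndarray
    a_star_cdoc_m: np.ndarray
    a_star_phi: np.ndarray
    a_star_spm: np.ndarray
    bb_w: np.ndarray
    bb_star_spm: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n_bands
        for name in ("a_w", "a_star_cdoc_w", "a_star_cdoc_ss", "a_star_cdoc_m",
                     "a_star_phi", "a_star_spm", "bb_w", "bb_star_spm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"IOP spectrum {name!r} is not on the shared grid "
                                 f"({arr.shape} vs {n} bands)")
            if np.any(arr < 0):
                raise ValueError(f"IOP spectrum {name!r} has negative values")

    @classmethod
    def default(cls, grid: SpectralGrid | None = None) -> "IOPLibrary":
        """Exponential CDOC spectra with seasonal slopes and riverine a300/DOC.

        Slopes: 0.018 nm-1 (winter riverine), 0.016 (spring/summer riverine),
        0.022 (marine); reference magnitudes at 300 nm sit in the riverine
        2-4 m2 (g C)-1 range.
        """
        grid = grid or SpectralGrid.default()
        return cls(
            grid=grid,
            a_w=water_absorption(grid),
            a_star_cdoc_w=_exponential_spectrum(grid, 3.5, 0.018),
            a_star_cdoc_ss=_exponential_spectrum(grid, 2.5, 0.016),
            a_star_cdoc_m=_exponential_spectrum(grid, 0.8, 0.022),
            a_star_phi=_phytoplankton_spectrum(grid),
            a_star_spm=_exponential_spectrum(grid, 0.05, 0.011, ref_wavelength=440.0),
            bb_w=water_backscatter(grid),
            bb_star_spm=np.full(grid.n_bands, 0.01),
        )

    def cdoc_spectra(self) -> dict[str, np.ndarray]:
        return {
            "cdoc_w": self.a_star_cdoc_w,
            "cdoc_ss": self.a_star_cdoc_ss,
            "cdoc_m": self.a_star_cdoc_m,
        }

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "wavelength_nm": self.grid.wavelengths,
            "a_w": self.a_w,
            "a_star_cdoc_w": self.a_star_cdoc_w,
            "a_star_cdoc_ss": self.a_star_cdoc_ss,
            "a_star_cdoc_m": self.a_star_cdoc_m,
            "a_star_phi": self.a_star_phi,
            "a_star_spm": self.a_star_spm,
            "bb_w": self.bb_w,
            "bb_star_spm": self.bb_star_spm,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IOPLibrary":
        df = pd.read_csv(path)
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        width = float(np.median(np.diff(wl))) if wl.size > 1 else 5.0
        grid = SpectralGrid(wavelengths=wl, band_width=width)
        return cls(grid=grid, a_w=df["a_w"].to_numpy(float),
                   a_star_cdoc_w=df["a_star_cdoc_w"].to_numpy(float),
                   a_star_cdoc_ss=df["a_star_cdoc_ss"].to_numpy(float),
                   a_star_cdoc_m=df["a_star_cdoc_m"].to_numpy(float),
                   a_star_phi=df["a_star_phi"].to_numpy(float),
                   a_star_spm=df["a_star_spm"].to_numpy(float),
                   bb_w=df["bb_w"].to_numpy(float),
                   bb_star_spm=df["bb_star_spm"].to_numpy(float))


@dataclass
class IrradianceProfile:
    """Downwelling irradiance through a layered column.

    ``ed`` holds interface values (n_layers + 1 rows, surface first,
    W m-2 nm-1 per band); ``ed_mid`` mid-layer values used for rate
    calculations; ``par_by_layer`` the mid-layer 400-700 nm integral
    (W m-2); ``kd_par`` the per-layer PAR attenuation (m-1).
    """

    grid: SpectralGrid
    ed: np.ndarray
    ed_mid: np.ndarray
    kd: np.ndarray
    par_by_layer: np.ndarray
    kd_par: np.ndarray


def planck_weights(grid: SpectralGrid) -> np.ndarray:
    """Normalized black-body (5778 K) band weights on ``grid`` (sum = 1)."""
    lam = grid.wavelengths * 1e-9
    # spectral radiance shape; normalization removes all constant prefactors
    b = lam ** -5 / np.expm1(_H * _C / (lam * _K_B * _T_SUN))
    return b / b.sum()


def build_surface_spectrum(shortwave: float, grid: SpectralGrid) -> np.ndarray:
    """Distribute broadband shortwave (W m-2) over the UV-visible grid.

    Returns per-band irradiance (W m-2 nm-1) whose integral
    (sum x band width) equals ``UV_VIS_FRACTION * shortwave``.
    """
    if shortwave < 0:
        raise ValueError("shortwave irradiance must be nonnegative")
    weights = planck_weights(grid)
    total = UV_VIS_FRACTION * shortwave
    return total * weights / grid.band_width


def total_absorption(concentrations: dict[str, float | np.ndarray],
                     iops: IOPLibrary) -> np.ndarray:
    """Total absorption a_t(lambda) = a_w + sum of constituent contributions.

    ``concentrations`` carries g m-3 entries for ``cdoc_w``, ``cdoc_ss``,
    ``cdoc_m``, ``spm`` and mg m-3 ``chl``.  Scalar entries give a 1-d
    spectrum; array entries broadcast against the trailing band axis.
    """
    def _conc(key: str):
        v = concentrations.get(key, 0.0)
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 0):
            raise ValueError(f"concentration {key!r} must be nonnegative")
        return arr[..., None] if arr.ndim else arr

    a_t = (iops.a_w
           + iops.a_star_cdoc_w * _conc("cdoc_w")
           + iops.a_star_cdoc_ss * _conc("cdoc_ss")
           + iops.a_star_cdoc_m * _conc("cdoc_m")
           + iops.a_star_phi * _conc("chl")
           + iops.a_star_spm * _conc("spm"))
    return a_t


def total_backscatter(spm, iops: IOPLibrary) -> np.ndarray:
    """b_b(lambda) = bb_w + bb*_SPM x [SPM]."""
    arr = np.asarray(spm, dtype=float)
    if arr.ndim:
        arr = arr[..., None]
    return iops.bb_w + iops.bb_star_spm * arr


def kd_spectrum(a_t: np.ndarray, b_b: np.ndarray,
                solar_zenith: float = solar_zenith_default,
                coefficients: tuple[float, float, float, float] = KD_COEFFICIENTS,
                ) -> np.ndarray:
    """Semi-analytical diffuse attenuation coefficient (m-1) per band."""
    if not 0.0 <= solar_zenith < 90.0:
        raise ValueError("solar zenith must be in [0, 90) degrees for a "
                         "downwelling light path")
    a_t = np.asarray(a_t, dtype=float)
    b_b = np.asarray(b_b, dtype=float)
    if np.any(b_b < 0):
        raise ValueError("backscatter must be nonnegative")
    m0, m1, m2, m3 = coefficients
    return (1.0 + m0 * solar_zenith) * a_t + m1 * (1.0 - m2 * np.exp(-m3 * a_t)) * b_b


def propagate(ed_surface: np.ndarray, kd: np.ndarray,
              layer_thicknesses: np.ndarray, grid: SpectralGrid,
              ) -> IrradianceProfile:
    """Beer-Lambert propagation through layers.

    ``kd`` has shape (n_layers, n_bands); ``ed_surface`` (n_bands,).
    Mid-layer irradiance (half-thickness attenuation within each layer) is
    what rate calculations consume.
    """
    dz = np.asarray(layer_thicknesses, dtype=float)
    if np.any(dz <= 0):
        raise ValueError("layer thicknesses must be positive")
    kd = np.atleast_2d(np.asarray(kd, dtype=float))
    n_layers = dz.size
    if kd.shape[0] != n_layers:
        raise ValueError("kd and layer thicknesses disagree on layer count")

    ed = np.empty((n_layers + 1, kd.shape[1]))
    ed[0] = ed_surface
    trans = np.exp(-kd * dz[:, None])
    for j in range(n_layers):
        ed[j + 1] = ed[j] * trans[j]
    ed_mid = ed[:-1] * np.exp(-0.5 * kd * dz[:, None])

    mask = grid.par_mask()
    bw = grid.band_width
    par_mid = ed_mid[:, mask].sum(axis=1) * bw
    par_if = ed[:, mask].sum(axis=1) * bw
    with np.errstate(divide="ignore", invalid="ignore"):
        kd_par = np.where(par_if[:-1] > 0,
                          -np.log(np.maximum(par_if[1:], 1e-300) /
                                  np.maximum(par_if[:-1], 1e-300)) / dz,
                          0.0)
    return IrradianceProfile(grid=grid, ed=ed, ed_mid=ed_mid, kd=kd,
                             par_by_layer=par_mid, kd_par=kd_par)


def photon_flux(ed_band, wavelength_nm, band_width: float):
    """Convert band irradiance (W m-2 nm-1) to mol photons m-2 s-1.

    Photon energy at wavelength lambda is h*c/lambda, so the molar photon
    flux is ed * band_width * lambda / (h c N_A), linear in ed and
    proportional to lambda.
    """
    ed = np.asarray(ed_band, dtype=float)
    if np.any(ed < 0):
        raise ValueError("irradiance must be nonnegative")
    lam_m = np.asarray(wavelength_nm, dtype=float) * 1e-9
    return ed * band_width * lam_m / (_H * _C * _NA)
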