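"""Photodegradation of chromophoric DOC.

Photons absorbed in a layer are apportioned to each absorbing constituent by
its share of total absorption, band by band.  An apparent quantum yield
(AQY, mol C transformed per mol photons absorbed, decaying exponentially
with wavelength) converts photon absorption by each chromophoric DOC class
into a carbon mass loss, which a transfer matrix distributes among marine
CDOC (photobleaching toward more biolabile material), non-chromophoric
refractory DOC, and a small direct photomineralization sink to CO2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral_optics import IrradianceProfile, SpectralGrid, photon_flux

__all__ = [
    "AQYSpectrum",
    "PhotoTransferMatrix",
    "absorbed_photons_by_class",
    "photo_transform",
    "CARBON_MOLAR_MASS",
    "PHOTO_SOURCES",
]

CARBON_MOLAR_MASS = 12.011  # g C mol-1

#: chromophoric classes that lose mass photochemically
PHOTO_SOURCES = ("cdoc_w", "cdoc_ss", "cdoc_m")
#: destinations of photodegraded mass, per source row
PHOTO_TARGETS = ("cdoc_m", "ncdoc3", "dic")


@dataclass(frozen=True)
class AQYSpectrum:
    """Apparent quantum yield per chromophoric DOC class.

    AQY_c(lambda) = scale * phi0_c * exp(-slope * (lambda - 290)), in
    mol C (mol photons)-1.  ``scale`` is the scenario switch: 0 disables
    photodegradation, 2 doubles it.
    """

    phi0: dict[str, float] = field(default_factory=lambda: {
        "cdoc_w": 5e-5, "cdoc_ss": 5e-5, "cdoc_m": 5e-6})
    slope: float = 0.02          # nm-1
    scale: float = 1.0
    ref_wavelength: float = 290.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.phi0.values()) or self.scale < 0:
            raise ValueError("AQY magnitudes must be nonnegative")
        if self.slope < 0:
            raise ValueError("AQY spectral slope must be nonnegative")

    def evaluate(self, cls: str, wavelengths: np.ndarray) -> np.ndarray:
        """AQY spectrum for one class on a wavelength axis (nm)."""
        return (self.scale * self.phi0[cls]
                * np.exp(-self.slope * (np.asarray(wavelengths, float)
                                        - self.ref_wavelength)))


@dataclass(frozen=True)
class PhotoTransferMatrix:
    """Row-stochastic routing of photodegraded mass per source class.

    Rows (sources) map to fractions sent to marine CDOC, refractory
    non-chromophoric DOC, and the dissolved-inorganic-carbon (CO2) sink.
    Direct photomineralization is kept far smaller than photobleaching.
    """

    rows: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "cdoc_w": (0.30, 0.69, 0.01),
        "cdoc_ss": (0.30, 0.69, 0.01),
        "cdoc_m": (0.00, 0.99, 0.01),
    })

    def __post_init__(self) -> None:
        for src, row in self.rows.items():
            if len(row) != 3 or any(f < 0 for f in row):
                raise ValueError(f"invalid transfer row for {src!r}")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"transfer matrix row {src!r} does not sum to 1 "
                                 f"(got {sum(row)})")

    def fraction(self, source: str, target: str) -> float:
        return self.rows[source][PHOTO_TARGETS.index(target)]


def absorbed_photons_by_class(profile: IrradianceProfile, a_t: np.ndarray,
                              a_class: np.ndarray, layer: int,
                              layer_thickness: float) -> float:
    """Photons absorbed by one constituent in one layer (mol m-3 s-1).

    Per band, the photon flux lost between the layer's top and bottom
    interfaces is attributed to the constituent in proportion to its share
    of total absorption a_class / a_t; bands where a_t = 0 (transparent
    limit) absorb nothing.
    """
    a_t = np.asarray(a_t, dtype=float)
    a_class = np.asarray(a_class, dtype=float)
    if np.any(a_class > a_t + 1e-12):
        raise ValueError("constituent absorption exceeds total absorption")
    wl = profile.grid.wavelengths
    bw = profile.grid.band_width
    top = photon_flux(profile.ed[layer], wl, bw)
    bottom = photon_flux(profile.ed[layer + 1], wl, bw)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(a_t > 0, a_class / np.where(a_t > 0, a_t, 1.0), 0.0)
    return float(((top - bottom) * share).sum() / layer_thickness)


def photo_transform(concentrations: dict[str, float],
                    photons_by_class: dict[str, np.ndarray],
                    wavelengths: np.ndarray,
                    aqy: AQYSpectrum,
                    matrix: PhotoTransferMatrix,
                    dt_seconds: float) -> tuple[dict[str, float], float]:
    """One explicit photochemistry step for a single layer.

    ``photons_by_class`` holds per-band absorbed photon rates
    (mol m-3 s-1) for each chromophoric class.  Returns (tendencies in
    g C m-3 over the step, CO2 mass to the DIC ledger in g C m-3); losses
    are clipped so no class is driven below zero.
    """
    tendencies = {k: 0.0 for k in ("cdoc_w", "cdoc_ss", "cdoc_m", "ncdoc3")}
    dic = 0.0
    for src in PHOTO_SOURCES:
        photons = np.asarray(photons_by_class.get(src, 0.0), dtype=float)
        if np.any(photons < 0):
            raise ValueError("photon absorption must be nonnegative")
        rate = float((aqy.evaluate(src, wavelengths) * photons).sum()) \
            * CARBON_MOLAR_MASS                       # g C m-3 s-1
        loss = rate * dt_seconds
        available = concentrations.get(src, 0.0) + tendencies.get(src, 0.0)
        loss = min(loss, max(available, 0.0))
        if loss <= 0.0:
            continue
        tendencies[src] -= loss
        tendencies["cdoc_m"] += matrix.fraction(src, "cdoc_m") * loss
        tendencies["ncdoc3"] += matrix.fraction(src, "ncdoc3") * loss
        dic += matrix.fraction(src, "dic") * loss
    return tendencies, dic
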