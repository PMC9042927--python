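"""Tissue optical properties and closed-form optics.

The packaged table ``data/tissue_optical_properties.csv`` carries the
absorption coefficient, scattering coefficient and anisotropy factor of
marmoset skull, gray matter and white matter at the six tested LED
wavelengths.  Note a known notation wrinkle in the sources these values
trace to: the skull power law below is written for a "reduced" coefficient
yet reproduces the table's scattering column, which is used as the plain
``mu_s`` with ``g = 0.92`` applied separately; the table is treated as
authoritative (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: refractive indices (skull from bone literature, brain from standard MC
#: tissue settings); ambient is air
N_SKULL = 1.56
N_BRAIN = 1.37
N_AIR = 1.0

#: default layer thicknesses (mm): thin marmoset skull over a 10 mm cube
THICKNESS_SKULL_MM = 0.5
THICKNESS_GRAY_MM = 1.3
THICKNESS_WHITE_MM = 8.2
CUBE_MM = 10.0


def load_optical_properties() -> pd.DataFrame:
    """The packaged tissue table: columns wavelength_nm, tissue
    (skull/gray/white), mu_a_mm, mu_s_mm, g."""
    with resources.files("wfmap.data").joinpath(
            "tissue_optical_properties.csv").open() as fh:
        return pd.read_csv(fh)


def skull_mus_prime(wavelength_nm: float) -> float:
    """Skull scattering power law, 1533.01 * lambda^-0.65 (mm^-1).

    Evaluates the published wavelength fit for skull scattering; the
    packaged table's skull mu_s column equals this expression at every
    tested wavelength (the "prime" in the name records how the fit is
    labeled in the source literature, not an extra (1-g) factor here).
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 1533.01 * wavelength_nm ** -0.65


def reduced_scattering(mu_s: float, g: float) -> float:
    """mu_s' = mu_s * (1 - g), the inverse transport mean free path."""
    return mu_s * (1.0 - g)


def mean_free_path(mu_s: float) -> float:
    """Scattering mean free path, 1/mu_s (mm)."""
    if mu_s <= 0:
        raise ValueError("mu_s must be positive")
    return 1.0 / mu_s


def depolarization_length(mu_s_prime: float) -> float:
    """Characteristic travel distance for full depolarization of linearly
    polarized light, 1/mu_s' (mm)."""
    if mu_s_prime <= 0:
        raise ValueError("mu_s' must be positive")
    return 1.0 / mu_s_prime


def brain_absorption(extinction_hbo_cm_M: float, extinction_hbr_cm_M: float,
                     blood_volume_fraction: float = 0.03,
                     hemoglobin_mM: float = 2.0,
                     hbr_fraction: float = 0.25) -> float:
    """Blood-based brain absorption coefficient (mm^-1, natural log).

    Assumes the dominant brain absorber is blood at the given volume
    fraction, with total hemoglobin ``hemoglobin_mM`` split
    ``hbr_fraction`` HbR / ``1 - hbr_fraction`` HbO.  Extinction inputs are
    molar (base-10) extinction coefficients in cm^-1/M, the unit of the
    standard hemoglobin tabulations; the ln(10) factor and the cm -> mm
    conversion are applied here.
    """
    if min(extinction_hbo_cm_M, extinction_hbr_cm_M, blood_volume_fraction,
           hemoglobin_mM) < 0 or not 0 <= hbr_fraction <= 1:
        raise ValueError("inputs must be non-negative (hbr_fraction in [0,1])")
    eps = hbr_fraction * extinction_hbr_cm_M + (1 - hbr_fraction) * extinction_hbo_cm_M
    conc_M = hemoglobin_mM * 1e-3
    mu_a_cm = np.log(10.0) * eps * conc_M  # base-10 extinction -> natural log
    return blood_volume_fraction * mu_a_cm / 10.0  # cm^-1 -> mm^-1


def defocus_tolerance(blur_diameter_mm: float, refractive_index: float = 1.0,
                      numerical_aperture: float = 0.03) -> float:
    """Depth h >= D*n/(2*NA) a target must sit from the focal plane before
    its lateral blur exceeds diameter D (mm)."""
    if numerical_aperture <= 0:
        raise ValueError("NA must be positive")
    return blur_diameter_mm * refractive_index / (2.0 * numerical_aperture)


# ---------------------------------------------------------------------------
# layered medium for photon transport


@dataclass
class OpticalLayer:
    name: str
    thickness_mm: float
    mu_a: float  # mm^-1
    mu_s: float  # mm^-1
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("coefficients must be non-negative")
        if not -1 < self.g < 1:
            raise ValueError("anisotropy g must be in (-1, 1)")


@dataclass
class MediumStack:
    """Ordered layers top to bottom filling a finite cube (lateral extent x
    lateral extent x summed thickness), ambient air above."""

    layers: list[OpticalLayer]
    lateral_extent_mm: float = CUBE_MM
    n_ambient: float = N_AIR

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("need at least one layer")
        depth = sum(l.thickness_mm for l in self.layers)
        if abs(depth - self.lateral_extent_mm) > 1e-9:
            raise ValueError(
                f"layer thicknesses sum to {depth} mm, expected the "
                f"{self.lateral_extent_mm} mm cube depth"
            )

    @property
    def boundaries_mm(self) -> np.ndarray:
        """z of layer interfaces, starting at the 0 (top) surface."""
        return np.concatenate([[0.0], np.cumsum([l.thickness_mm for l in self.layers])])

    def mu_a_vector(self) -> np.ndarray:
        return np.array([l.mu_a for l in self.layers])


def head_stack(wavelength_nm: float = 530.0,
               skull_mm: float = THICKNESS_SKULL_MM,
               gray_mm: float = THICKNESS_GRAY_MM,
               white_mm: float | None = None) -> MediumStack:
    """The default three-layer model: skull / gray matter / white matter
    with the packaged coefficients at the given wavelength, white matter
    padding the cube to 10 mm."""
    table = load_optical_properties()
    sel = table[table.wavelength_nm == wavelength_nm]
    if sel.empty:
        raise ValueError(f"no tabulated properties at {wavelength_nm} nm")
    row = {r.tissue: r for r in sel.itertuples()}
    if white_mm is None:
        white_mm = CUBE_MM - skull_mm - gray_mm
    layers = [
        OpticalLayer("skull", skull_mm, row["skull"].mu_a_mm, row["skull"].mu_s_mm,
                     row["skull"].g, N_SKULL),
        OpticalLayer("gray", gray_mm, row["gray"].mu_a_mm, row["gray"].mu_s_mm,
                     row["gray"].g, N_BRAIN),
        OpticalLayer("white", white_mm, row["white"].mu_a_mm, row["white"].mu_s_mm,
                     row["white"].g, N_BRAIN),
    ]
    return MediumStack(layers)
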