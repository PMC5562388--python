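"""Semi-infinite-medium diffusion model and the optical-loss (OL) scale.

Continuous-wave light launched at the tissue surface and detected at a
source-detector separation ``rho`` is modeled with the steady-state diffusion
approximation for a homogeneous semi-infinite medium.  The spatially resolved
diffuse reflectance R(rho) (mm^-2) uses the standard two-source construction:
an isotropic point source buried one transport mean free path below the
surface plus a negative image source mirrored about the extrapolated boundary,
whose position follows from the internal-reflection parameter A of the
refractive-index mismatch (Fresnel, n = 1.4 by default).

The optical loss is the dimensionless attenuation scale used to compare
channels across media:

    OL(rho) = 1 / (R(rho) * A_aperture),

with a standardized circular detection aperture of 8 mm diameter.  On the
silicone calibration phantom, OL of 1e4 / 1e6 / 1e7 corresponds to separations
of roughly 25 / 45 / 55 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "OpticalProperties",
    "OpticalLossModel",
    "diffuse_reflectance",
    "optical_loss",
    "sds_for_optical_loss",
    "mua_from_chromophores",
    "model_dpf",
    "load_optical_properties",
    "phantom_properties",
]

LN10 = math.log(10.0)
#: decadic mM^-1 cm^-1  ->  muM^-1 mm^-1  (1/1000 for mM->muM, 1/10 for cm->mm)
MM_CM_TO_UM_MM = 1e-4


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a homogeneous medium.

    mua : absorption coefficient, mm^-1 (> 0)
    musp : reduced scattering coefficient, mm^-1 (> 0)
    n_tissue : refractive index (>= 1), used for the boundary condition
    """

    mua: float
    musp: float
    n_tissue: float = 1.4

    def __post_init__(self) -> None:
        if self.mua <= 0:
            raise ValueError("mua must be positive")
        if self.musp <= 0:
            raise ValueError("musp must be positive")
        if self.n_tissue < 1:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class OpticalLossModel:
    """Detection-aperture convention for the optical-loss scale.

    ``aperture_diameter`` is the diameter (mm) of the standardized circular
    detection aperture (8 mm per the IEC 80601-2-71 convention).
    """

    aperture_diameter: float = 8.0

    def __post_init__(self) -> None:
        if self.aperture_diameter <= 0:
            raise ValueError("aperture diameter must be positive")

    @property
    def aperture_area(self) -> float:
        """Aperture area in mm^2."""
        return math.pi * (self.aperture_diameter / 2.0) ** 2


def _boundary_A(n: float) -> float:
    # Groenhuis polynomial fit for the effective internal reflection
    # coefficient r_d of a tissue/air boundary, A = (1 + r_d) / (1 - r_d).
    r_d = -1.440 * n**-2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


def diffuse_reflectance(rho, props: OpticalProperties):
    """Steady-state spatially resolved diffuse reflectance R(rho), mm^-2.

    Two-source (real + image about the extrapolated boundary) solution of the
    diffusion equation for a homogeneous semi-infinite medium.  ``rho`` may be
    a scalar or array of separations in mm; all entries must be positive.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr <= 0):
        raise ValueError("source-detector separation must be positive")
    mutp = props.mua + props.musp  # transport attenuation coefficient
    z0 = 1.0 / mutp  # depth of the isotropic source
    D = 1.0 / (3.0 * mutp)
    mueff = math.sqrt(3.0 * props.mua * mutp)
    zb = 2.0 * _boundary_A(props.n_tissue) * D  # extrapolated-boundary offset
    r1 = np.sqrt(z0**2 + rho_arr**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho_arr**2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    out = (term1 + term2) / (4.0 * math.pi)
    return out if out.ndim else float(out)


def optical_loss(
    rho, props: OpticalProperties, model: OpticalLossModel | None = None
):
    """Dimensionless optical loss OL = 1 / (R(rho) * aperture area)."""
    model = model or OpticalLossModel()
    return 1.0 / (diffuse_reflectance(rho, props) * model.aperture_area)


def sds_for_optical_loss(
    target_ol: float,
    props: OpticalProperties,
    model: OpticalLossModel | None = None,
    bracket: tuple[float, float] = (0.5, 200.0),
    tol_mm: float = 0.01,
) -> float:
    """Separation (mm) at which the optical loss reaches ``target_ol``.

    Root of ``optical_loss(rho) = target_ol`` by bracketing search on
    log10(OL), to a tolerance of 0.01 mm.  Raises if the target is outside
    the range spanned by the bracket (e.g. below the minimum achievable OL).
    """
    model = model or OpticalLossModel()
    lo, hi = bracket

    def f(r: float) -> float:
        return math.log10(optical_loss(r, props, model)) - math.log10(target_ol)

    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target OL {target_ol:g} not bracketed by rho in [{lo}, {hi}] mm"
        )
    return float(brentq(f, lo, hi, xtol=tol_mm))


def mua_from_chromophores(
    baseline_mua: float,
    delta_conc_um: dict[str, float] | "np.ndarray",
    extinction_mM_cm: dict[str, float] | "np.ndarray",
):
    """Absorption coefficient (mm^-1) after chromophore concentration changes.

    mua = baseline + ln(10) * sum_C eps_C * dC, with decadic extinction
    coefficients in mM^-1 cm^-1 and concentration changes in muM (internally
    converted to muM^-1 mm^-1).  Keys of the two mappings must match; array
    inputs are paired positionally and concentration entries may be time
    series.  Raises if the result would be non-positive (unphysical).
    """
    if isinstance(delta_conc_um, dict) != isinstance(extinction_mM_cm, dict):
        raise TypeError("delta_conc and extinction must both be dicts or both arrays")
    if isinstance(delta_conc_um, dict):
        if set(delta_conc_um) != set(extinction_mM_cm):
            raise ValueError("chromophore keys of concentrations and extinctions differ")
        keys = sorted(delta_conc_um)
        dc = np.stack([np.asarray(delta_conc_um[k], dtype=float) for k in keys])
        eps = np.array([extinction_mM_cm[k] for k in keys], dtype=float)
    else:
        dc = np.atleast_2d(np.asarray(delta_conc_um, dtype=float))
        eps = np.asarray(extinction_mM_cm, dtype=float)
        if dc.shape[0] != eps.shape[0]:
            raise ValueError("one extinction coefficient per chromophore required")
    delta = LN10 * np.tensordot(eps * MM_CM_TO_UM_MM, dc, axes=(0, 0))
    mua = baseline_mua + delta
    if np.any(mua <= 0):
        raise ValueError("resulting absorption coefficient is non-positive")
    return mua if np.ndim(mua) else float(mua)


def model_dpf(rho: float, props: OpticalProperties, d_mua: float = 1e-6) -> float:
    """Differential pathlength factor implied by the diffusion model.

    DPF = (dA/dmua) / rho with A = -ln R(rho): the mean partial pathlength per
    unit geometric separation, evaluated by central difference at the baseline
    absorption.  Useful for making a simulated recording and its MBLL
    inversion mutually consistent.
    """
    lo = OpticalProperties(props.mua - d_mua, props.musp, props.n_tissue)
    hi = OpticalProperties(props.mua + d_mua, props.musp, props.n_tissue)
    dA = -(math.log(diffuse_reflectance(rho, hi)) - math.log(diffuse_reflectance(rho, lo)))
    return dA / (2.0 * d_mua) / rho


def load_optical_properties() -> pd.DataFrame:
    """Packaged optical-property table (medium, wavelength, mua, musp)."""
    with resources.files("nirstwin.data").joinpath("optical_properties.csv").open() as fh:
        return pd.read_csv(fh)


def phantom_properties(wavelength_nm: float = 850.0) -> OpticalProperties:
    """Silicone-phantom optical properties at the tabulated column nearest
    ``wavelength_nm`` (680 or 850 nm)."""
    tab = load_optical_properties()
    tab = tab[tab.medium == "silicone_phantom"]
    row = tab.iloc[(tab.wavelength_nm - wavelength_nm).abs().argmin()]
    return OpticalProperties(mua=row.mua_mm, musp=row.musp_mm)
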