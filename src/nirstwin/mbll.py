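"""Modified Beer-Lambert law (MBLL) chromophore reconstruction.

Attenuation changes at the four LED wavelengths are inverted for
concentration changes of two (O2Hb, HHb) or three (plus the oxCCO
oxidized-minus-reduced difference) chromophores:

    dC = (1/L) * pinv(ln10 * E) @ [dA(lambda_i) / DPF(lambda_i)]_i

where E holds decadic extinction coefficients (converted internally to
muM^-1 mm^-1), DPF is the differential pathlength factor per wavelength, L
the geometric source-detector distance in mm, and

    dA(lambda, t) = -ln[(I(lambda, t) - b(t)) / (I(lambda, t0) - b(t0))]

after backlight (ambient) subtraction.  With four wavelengths the extinction
matrix is tall, so the inversion is the Moore-Penrose pseudoinverse, i.e. the
least-squares solution (for full column rank E this equals (E'E)^-1 E').
Wavelength subsets support the two- and three-wavelength comparisons used for
reconstruction-variance analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .light_transport import LN10, MM_CM_TO_UM_MM, OpticalProperties, model_dpf
from .instrument import MEASURED_WAVELENGTHS_NM, NOMINAL_WAVELENGTHS_NM

__all__ = [
    "ExtinctionSystem",
    "AttenuationSeries",
    "delta_attenuation",
    "pseudoinverse",
    "reconstruct",
    "subset_reconstruct",
    "load_extinction_table",
]

CHROMOPHORE_NAMES = ("o2hb", "hhb", "oxcco")


def load_extinction_table() -> pd.DataFrame:
    """Packaged extinction/DPF table at the measured LED wavelengths."""
    with resources.files("nirstwin.data").joinpath("extinction_dpf.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class ExtinctionSystem:
    """Everything the MBLL inversion needs for one channel.

    wavelengths : nm, the measured LED peaks (default 774/817/865/892);
    extinction : (n_wl, 3) decadic coefficients, mM^-1 cm^-1, columns ordered
    (O2Hb, HHb, oxCCO-difference); dpf : DPF per wavelength; pathlength : mm.
    """

    wavelengths: tuple[float, ...]
    extinction: np.ndarray
    dpf: np.ndarray
    pathlength: float

    def __post_init__(self) -> None:
        E = np.asarray(self.extinction, dtype=float)
        d = np.asarray(self.dpf, dtype=float)
        object.__setattr__(self, "extinction", E)
        object.__setattr__(self, "dpf", d)
        if E.shape != (len(self.wavelengths), 3):
            raise ValueError("extinction must be (n_wavelengths, 3)")
        if d.shape != (len(self.wavelengths),):
            raise ValueError("one DPF per wavelength required")
        if np.any(d <= 0):
            raise ValueError("DPF values must be positive")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be positive")
        if np.linalg.matrix_rank(E) < min(E.shape):
            raise ValueError("extinction matrix must have full column rank")

    @classmethod
    def default(cls, pathlength_mm: float, dpf_scale: float = 1.0) -> "ExtinctionSystem":
        """System built from the packaged tables; ``dpf_scale`` rescales the
        tabulated DPF values (configurable normalization)."""
        tab = load_extinction_table()
        return cls(
            wavelengths=tuple(tab.wavelength_nm.astype(float)),
            extinction=tab[
                ["eps_o2hb_mM_cm", "eps_hhb_mM_cm", "eps_oxcco_diff_mM_cm"]
            ].to_numpy(),
            dpf=dpf_scale * tab.dpf.to_numpy(),
            pathlength=pathlength_mm,
        )

    @classmethod
    def for_medium(
        cls, pathlength_mm: float, props: OpticalProperties
    ) -> "ExtinctionSystem":
        """System whose DPF is derived from the diffusion model of ``props``
        at the channel separation (self-consistent with simulated media)."""
        tab = load_extinction_table()
        dpf = model_dpf(pathlength_mm, props)
        return cls(
            wavelengths=tuple(tab.wavelength_nm.astype(float)),
            extinction=tab[
                ["eps_o2hb_mM_cm", "eps_hhb_mM_cm", "eps_oxcco_diff_mM_cm"]
            ].to_numpy(),
            dpf=np.full(len(tab), dpf),
            pathlength=pathlength_mm,
        )

    def weighted_matrix(self, n_chromophores: int = 3, rows=None) -> np.ndarray:
        """ln-based extinction matrix in muM^-1 mm^-1, first ``n`` columns,
        optionally restricted to the wavelength rows in ``rows``."""
        E = LN10 * MM_CM_TO_UM_MM * self.extinction[:, :n_chromophores]
        return E if rows is None else E[rows]

    def wavelength_indices(self, wavelengths_nm) -> list[int]:
        """Map requested wavelengths to table rows; nominal LED values
        (770/810/855/885) are accepted as aliases of the measured peaks."""
        idx = []
        for w in wavelengths_nm:
            if w in NOMINAL_WAVELENGTHS_NM:
                w = MEASURED_WAVELENGTHS_NM[NOMINAL_WAVELENGTHS_NM.index(w)]
            if w == 850.0:  # common shorthand for the 855-nm (measured 865) LED
                w = 865.0
            diffs = [abs(w - wl) for wl in self.wavelengths]
            j = int(np.argmin(diffs))
            if diffs[j] > 15.0:
                raise ValueError(f"no LED wavelength near {w} nm")
            idx.append(j)
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate wavelengths in subset")
        return idx


@dataclass
class AttenuationSeries:
    """Optical-density changes dA per wavelength (dimensionless, natural log).

    ``delta_a`` has shape (n_wavelengths, n_samples); ``mode`` records
    whether samples are referenced to a fixed baseline or to the previous
    sample (the two are related by a telescoping cumulative sum).
    """

    wavelengths: tuple[float, ...]
    delta_a: np.ndarray
    mode: str = "baseline"

    def __post_init__(self) -> None:
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if self.delta_a.ndim != 2 or self.delta_a.shape[0] != len(self.wavelengths):
            raise ValueError("delta_a must be (n_wavelengths, n_samples)")
        if self.mode not in ("baseline", "previous"):
            raise ValueError("mode must be 'baseline' or 'previous'")
        if not np.all(np.isfinite(self.delta_a)):
            raise ValueError("attenuation series contains non-finite values")

    def to_baseline(self) -> "AttenuationSeries":
        """Convert previous-sample increments to baseline-referenced dA by
        the telescoping cumulative sum (identity if already baseline mode)."""
        if self.mode == "baseline":
            return self
        return AttenuationSeries(
            self.wavelengths, np.cumsum(self.delta_a, axis=1), "baseline"
        )


def delta_attenuation(
    intensity: np.ndarray,
    backlight: np.ndarray | float = 0.0,
    wavelengths: tuple[float, ...] = MEASURED_WAVELENGTHS_NM,
    mode: str = "baseline",
    baseline_index: int = 0,
) -> AttenuationSeries:
    """Attenuation change from raw per-wavelength intensities.

    The backlight (ambient) series is subtracted from every wavelength slot
    first; then dA = -ln(I_corr(t) / I_corr(ref)) with the reference either a
    fixed baseline sample or the previous sample.  Raises (naming wavelength
    and sample) if any corrected intensity is non-positive.
    """
    I = np.atleast_2d(np.asarray(intensity, dtype=float))
    b = np.asarray(backlight, dtype=float)
    corr = I - b
    if np.any(corr <= 0):
        wl_i, s_i = np.argwhere(corr <= 0)[0]
        raise ValueError(
            f"non-positive backlight-corrected intensity at wavelength index "
            f"{wl_i} ({wavelengths[wl_i]} nm), sample {s_i}"
        )
    if mode == "baseline":
        ref = corr[:, [baseline_index]]
        dA = -np.log(corr / ref)
    elif mode == "previous":
        ratio = corr[:, 1:] / corr[:, :-1]
        dA = np.concatenate([np.zeros((corr.shape[0], 1)), -np.log(ratio)], axis=1)
    else:
        raise ValueError("mode must be 'baseline' or 'previous'")
    return AttenuationSeries(tuple(wavelengths[: I.shape[0]]), dA, mode)


def pseudoinverse(matrix: np.ndarray, cond_limit: float = 1e8) -> np.ndarray:
    """SVD-based Moore-Penrose pseudoinverse with a rank guard.

    For a tall full-column-rank matrix this equals the normal-equations left
    inverse (E'E)^-1 E' and satisfies pinv(E) @ E = I.  Raises with the
    condition number if the matrix is (numerically) rank deficient.
    """
    M = np.asarray(matrix, dtype=float)
    s = np.linalg.svd(M, compute_uv=False)
    if s[-1] == 0 or s[0] / s[-1] > cond_limit:
        cond = math.inf if s[-1] == 0 else s[0] / s[-1]
        raise np.linalg.LinAlgError(
            f"rank-deficient matrix: condition number {cond:.3g}"
        )
    return np.linalg.pinv(M)


def reconstruct(
    da: AttenuationSeries, system: ExtinctionSystem, n_chromophores: int = 3
) -> np.ndarray:
    """Chromophore concentration changes (muM) from attenuation changes.

    Each wavelength's dA is divided by its DPF, the stack is multiplied by
    the pseudoinverse of the (ln-based, unit-converted) extinction matrix and
    by 1/L.  Returns (n_chromophores, n_samples) ordered (O2Hb, HHb[, oxCCO]).
    """
    if n_chromophores not in (2, 3):
        raise ValueError("n_chromophores must be 2 or 3")
    if len(da.wavelengths) != len(system.wavelengths):
        raise ValueError(
            f"attenuation has {len(da.wavelengths)} wavelengths, "
            f"system expects {len(system.wavelengths)}"
        )
    y = da.to_baseline().delta_a / system.dpf[:, None]
    E = system.weighted_matrix(n_chromophores)
    return pseudoinverse(E) @ y / system.pathlength


def subset_reconstruct(
    da: AttenuationSeries,
    system: ExtinctionSystem,
    wavelength_subset,
    n_chromophores: int = 2,
) -> np.ndarray:
    """Reconstruction restricted to a wavelength subset.

    A square subset is solved exactly, a larger one by least squares.  The
    subset may use nominal LED wavelengths (e.g. 770 and 850 nm) as aliases
    for the measured peaks.
    """
    rows = system.wavelength_indices(wavelength_subset)
    if len(rows) < n_chromophores:
        raise ValueError("subset smaller than the number of chromophores")
    y = da.to_baseline().delta_a[rows] / system.dpf[rows, None]
    E = system.weighted_matrix(n_chromophores, rows=rows)
    return pseudoinverse(E) @ y / system.pathlength
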