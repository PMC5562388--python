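"""Instrument-characterization metrics.

Reproduces the bench-characterization procedures: raw-intensity SNR
(20*log10(mean/sd)), relative drift slope over a 1-min window, noise
equivalent power from dark noise via the SiPM characteristics, dynamic
optical range (20 dB per decade), and the reconstruction-variance ratios
that quantify the benefit of three- and four-wavelength MBLL over the
classic two-wavelength inversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import (
    AnalogChain,
    ELEMENTARY_CHARGE_C,
    RawRecording,
    SipmModel,
    photon_energy_j,
)
from .mbll import AttenuationSeries, ExtinctionSystem, delta_attenuation, subset_reconstruct

__all__ = [
    "QualityReport",
    "snr_db",
    "drift_slope",
    "nep",
    "dynamic_range_db",
    "variance_ratio",
    "quality_report",
]

#: wavelength subsets (nominal nm) compared against the 770/850 two-wavelength
#: baseline in the variance-ratio analysis
DEFAULT_SUBSETS = {
    "2wl": (770.0, 850.0),
    "3wl": (770.0, 810.0, 850.0),
    "4wl": (770.0, 810.0, 850.0, 885.0),
}


def snr_db(series: np.ndarray) -> float:
    """Raw-signal SNR: 20*log10(mean / sd).

    A constant series (sd = 0) returns +inf with a warning; a zero or
    negative mean raises (SNR of an intensity requires a positive level).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    m = x.mean()
    if m <= 0:
        raise ValueError("SNR undefined for non-positive mean intensity")
    s = x.std(ddof=0)
    if s == 0:
        warnings.warn("zero-variance series: SNR is unbounded")
        return math.inf
    return 20.0 * math.log10(m / s)


def drift_slope(
    series: np.ndarray,
    fs: float,
    window_start_s: float = 600.0,
    window_len_s: float = 60.0,
) -> float:
    """Relative drift slope (permil/s) from a linear fit.

    Least-squares line over the ``window_len_s`` window starting at
    ``window_start_s`` (the bench procedure uses a 1-min window 10 min after
    start); the slope is normalized by the window-mean intensity and
    reported in parts-per-thousand per second.
    """
    x = np.asarray(series, dtype=float)
    i0 = int(round(window_start_s * fs))
    i1 = i0 + int(round(window_len_s * fs))
    if i0 < 0 or i1 > x.size or i1 - i0 < 2:
        raise ValueError("drift window outside the recording")
    seg = x[i0:i1]
    t = np.arange(i1 - i0) / fs
    slope = np.polyfit(t, seg, 1)[0]
    return 1000.0 * slope / seg.mean()


def nep(
    dark_noise_sd_v: float,
    wavelength_nm: float,
    chain: AnalogChain | None = None,
    sipm: SipmModel | None = None,
    gain: float | None = None,
) -> float:
    """Noise equivalent power (W): optical power at which SNR = 0 dB.

    The dark-noise voltage sd is referred back to a photocurrent through the
    TIA gain, then converted to optical power with the SiPM characteristics:
    NEP = (sd / |G_TIA|) * E_photon / (G * PDE * e).
    """
    if dark_noise_sd_v <= 0:
        raise ValueError("dark-noise sd must be positive")
    chain = chain or AnalogChain()
    sipm = sipm or SipmModel()
    g = sipm.gain_max if gain is None else gain
    if g <= 0:
        raise ValueError("NEP undefined below breakdown (gain 0)")
    noise_current = dark_noise_sd_v / chain.tia_gain_v_per_a
    return (
        noise_current
        * photon_energy_j(wavelength_nm)
        / (g * sipm.pde_at(wavelength_nm) * ELEMENTARY_CHARGE_C)
    )


def dynamic_range_db(p_max_w: float, nep_w: float) -> float:
    """Dynamic optical range 20*log10(p_max / NEP); 20 dB per decade."""
    if not p_max_w > nep_w > 0:
        raise ValueError("need p_max > NEP > 0")
    return 20.0 * math.log10(p_max_w / nep_w)


def _detrend_linear(seg: np.ndarray) -> np.ndarray:
    t = np.arange(seg.shape[-1], dtype=float)
    coef = np.polyfit(t, seg.T, 1)
    fit = np.outer(coef[0], t) + coef[1][:, None] if seg.ndim > 1 else coef[0] * t + coef[1]
    return seg - fit


def variance_ratio(
    recording: RawRecording,
    system: ExtinctionSystem,
    channel_label: str | None = None,
    subsets: dict[str, tuple[float, ...]] | None = None,
    segment_len: int = 400,
    n_segments: int = 11,
) -> dict[str, dict[str, float]]:
    """Reconstruction-variance ratios relative to the 770/850-nm inversion.

    Splits the recording into ``n_segments`` steady-state segments of
    ``segment_len`` samples, linearly detrends each, reconstructs O2Hb and
    HHb per wavelength subset, and averages var(subset)/var(2wl) across
    segments.  Returns {subset: {"o2hb": ratio, "hhb": ratio}}.
    """
    subsets = subsets or DEFAULT_SUBSETS
    if "2wl" not in subsets:
        raise ValueError("subsets must include the '2wl' reference")
    if len(subsets) < 2:
        raise ValueError("need at least one subset besides the reference")
    i_ch = 0 if channel_label is None else recording.channel_index(channel_label)
    n_t = recording.intensity.shape[-1]
    if n_segments * segment_len > n_t:
        raise ValueError(
            f"recording too short: need {n_segments}*{segment_len} samples, have {n_t}"
        )
    da = delta_attenuation(
        recording.intensity[i_ch],
        recording.backlight[i_ch],
        wavelengths=recording.wavelengths,
    )
    ratios: dict[str, list[np.ndarray]] = {k: [] for k in subsets if k != "2wl"}
    for s in range(n_segments):
        sl = slice(s * segment_len, (s + 1) * segment_len)
        seg = AttenuationSeries(da.wavelengths, da.delta_a[:, sl])
        conc = {
            k: _detrend_linear(subset_reconstruct(seg, system, wl, n_chromophores=2))
            for k, wl in subsets.items()
        }
        v2 = conc["2wl"].var(axis=1)
        if np.any(v2 == 0):
            raise ValueError("degenerate (noiseless) segment: 2-wavelength variance is 0")
        for k in ratios:
            ratios[k].append(conc[k].var(axis=1) / v2)
    out: dict[str, dict[str, float]] = {}
    for k, vals in ratios.items():
        mean = np.mean(vals, axis=0)
        out[k] = {"o2hb": float(mean[0]), "hhb": float(mean[1])}
    return out


@dataclass
class QualityReport:
    """Bench-characterization summary for a recording/configuration."""

    snr_db: dict[str, dict[str, float]]  # channel label -> wavelength -> dB
    drift_slope_permil_s: dict[str, float]
    nep_w: dict[str, float]  # wavelength -> W
    dynamic_range_db: dict[str, float]
    variance_ratios: dict[str, dict[str, float]] | None = None

    def to_dict(self) -> dict:
        return {
            "snr_db": self.snr_db,
            "drift_slope_permil_s": self.drift_slope_permil_s,
            "nep_w": self.nep_w,
            "dynamic_range_db": self.dynamic_range_db,
            "variance_ratios": self.variance_ratios,
        }

    def table(self) -> str:
        lines = ["Technical performance", "=" * 42]
        for ch, per_wl in self.snr_db.items():
            vals = ", ".join(f"{wl}: {v:.1f} dB" for wl, v in per_wl.items())
            lines.append(f"SNR [{ch}]        {vals}")
        for ch, v in self.drift_slope_permil_s.items():
            lines.append(f"Drift [{ch}]      {v:+.3f} permil/s")
        nepline = ", ".join(f"{float(w):.0f} nm: {v*1e12:.2f} pW" for w, v in self.nep_w.items())
        lines.append(f"NEP               {nepline}")
        drline = ", ".join(f"{float(w):.0f} nm: {v:.1f} dB" for w, v in self.dynamic_range_db.items())
        lines.append(f"Dynamic range     {drline}")
        if self.variance_ratios:
            for k, d in self.variance_ratios.items():
                lines.append(
                    f"Var ratio {k}/2wl  O2Hb: {d['o2hb']:.3f}, HHb: {d['hhb']:.3f}"
                )
        return "\n".join(lines)


def quality_report(
    recording: RawRecording,
    dark_noise_sd_v: float = 1.5e-3,
    p_max_w: float = 1e-3,
    drift_window_start_s: float | None = None,
    system: ExtinctionSystem | None = None,
    chain: AnalogChain | None = None,
    sipm: SipmModel | None = None,
) -> QualityReport:
    """Assemble the characterization metrics for a recording."""
    chain = chain or AnalogChain()
    sipm = sipm or SipmModel()
    snr: dict[str, dict[str, float]] = {}
    drifts: dict[str, float] = {}
    for i, ch in enumerate(recording.channels):
        snr[ch.label] = {
            f"{wl:.0f}nm": snr_db(recording.intensity[i, j])
            for j, wl in enumerate(recording.wavelengths)
        }
        if drift_window_start_s is not None:
            drifts[ch.label] = drift_slope(
                recording.intensity[i, 0], recording.fs, drift_window_start_s
            )
    neps = {
        f"{wl:.0f}": nep(dark_noise_sd_v, wl, chain, sipm)
        for wl in recording.wavelengths
    }
    dr = {k: dynamic_range_db(p_max_w, v) for k, v in neps.items()}
    ratios = None
    if system is not None:
        try:
            ratios = variance_ratio(recording, system)
        except ValueError:
            ratios = None
    return QualityReport(snr, drifts, neps, dr, ratios)
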