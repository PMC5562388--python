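"""Digital twin of the measurement electronics.

Models the path from optical power at the detector to the recorded,
multiplexed raw samples: SiPM photon detection with fired-cell saturation and
overvoltage-dependent gain, transimpedance amplification, 16-bit ADC
quantization over a 0-3 V range at 100 kHz, on-board 64-sample plateau
averaging per 1.2-ms slot, a software photocurrent safety limit (1.5 mA)
that deactivates only the offending channel, multiplicative sensor warm-up
drift, and a noise model (shot + electronic floor) that can be calibrated to
a target short-channel SNR.

The default recording path assumes the detector operates in its linear
regime, as the instrument arranges by adjusting LED currents and SiPM
overvoltage for leveled detector intensities; the fired-cell saturation law
is exposed by :func:`sipm_response` for characterizing the departure from
linearity at short separations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instrument import (
    Channel,
    CycleTiming,
    MEASURED_WAVELENGTHS_NM,
    OptodeNetwork,
    enumerate_channels,
)
from .light_transport import OpticalProperties, diffuse_reflectance
from .mbll import ExtinctionSystem
from .physiology import ChromophoreTimecourse, compose_layers

__all__ = [
    "PLANCK_J_S",
    "SPEED_OF_LIGHT_M_S",
    "ELEMENTARY_CHARGE_C",
    "SipmModel",
    "AnalogChain",
    "DriftConfig",
    "NoiseConfig",
    "RawRecording",
    "sipm_gain",
    "sipm_response",
    "safety_limit",
    "slot_average",
    "drift_model",
    "simulate_recording",
]

PLANCK_J_S = 6.62607015e-34
SPEED_OF_LIGHT_M_S = 2.99792458e8
ELEMENTARY_CHARGE_C = 1.602176634e-19


def photon_energy_j(wavelength_nm: float) -> float:
    return PLANCK_J_S * SPEED_OF_LIGHT_M_S / (wavelength_nm * 1e-9)


@dataclass(frozen=True)
class SipmModel:
    """Silicon-photomultiplier detector model.

    3600 Geiger-mode cells, internal gain 8.2e6 at the 33-V maximum bias and
    1.4e6 at 28 V, zero below breakdown (gain linear in overvoltage through
    the two anchor points); photon detection efficiencies per LED wavelength
    13/9/6/4 %.  ``recovery_window_s`` is the per-cell dead/recovery window
    governing the fired-cell saturation law.
    """

    n_cells: int = 3600
    gain_max: float = 8.2e6
    bias_max_v: float = 33.0
    gain_ref: float = 1.4e6
    bias_ref_v: float = 28.0
    bias_min_v: float = 24.0
    pde: tuple[float, ...] = (0.13, 0.09, 0.06, 0.04)
    pde_wavelengths_nm: tuple[float, ...] = MEASURED_WAVELENGTHS_NM
    photocurrent_limit_a: float = 1.5e-3
    active_area_mm2: float = 9.0
    recovery_window_s: float = 1e-7

    @property
    def gain_slope_per_v(self) -> float:
        return (self.gain_max - self.gain_ref) / (self.bias_max_v - self.bias_ref_v)

    @property
    def breakdown_voltage_v(self) -> float:
        """Bias at which the linear gain fit crosses zero (~26.97 V)."""
        return self.bias_ref_v - self.gain_ref / self.gain_slope_per_v

    def pde_at(self, wavelength_nm: float) -> float:
        diffs = [abs(wavelength_nm - w) for w in self.pde_wavelengths_nm]
        j = int(np.argmin(diffs))
        if diffs[j] > 30.0:
            raise ValueError(f"no PDE tabulated near {wavelength_nm} nm")
        return self.pde[j]


@dataclass(frozen=True)
class AnalogChain:
    """Transimpedance amplifier + anti-aliasing filter + ADC.

    TIA gain magnitude 1000 V/A (inverting; the filter stage restores a
    positive signal), 15.8-kHz low-pass, 16-bit ADC over 0-3 V at 100 kHz.
    """

    tia_gain_v_per_a: float = 1000.0
    lpf_cutoff_hz: float = 15.8e3
    adc_bits: int = 16
    adc_fullscale_v: float = 3.0
    adc_rate_hz: float = 100e3

    @property
    def lsb_v(self) -> float:
        return self.adc_fullscale_v / 2**self.adc_bits

    @property
    def sample_window_s(self) -> float:
        return 1.0 / self.adc_rate_hz

    def voltage(self, photocurrent_a) -> np.ndarray:
        """TIA output voltage, clipped to the ADC range."""
        v = np.asarray(photocurrent_a, dtype=float) * self.tia_gain_v_per_a
        return np.clip(v, 0.0, self.adc_fullscale_v)

    def quantize(self, voltage_v) -> np.ndarray:
        """Round to the ADC grid (LSB = fullscale / 2^bits), clipped."""
        v = np.clip(np.asarray(voltage_v, dtype=float), 0.0, self.adc_fullscale_v)
        return np.round(v / self.lsb_v) * self.lsb_v


def sipm_gain(bias_v: float, model: SipmModel | None = None) -> float:
    """SiPM internal gain at a bias voltage.

    Zero at or below breakdown (the 24-V parking bias turns the sensor off);
    linear in overvoltage above breakdown, passing through the measured
    anchor points (28 V, 1.4e6) and (33 V, 8.2e6).
    """
    model = model or SipmModel()
    if not model.bias_min_v <= bias_v <= model.bias_max_v:
        raise ValueError(
            f"bias {bias_v} V outside [{model.bias_min_v}, {model.bias_max_v}] V"
        )
    vbr = model.breakdown_voltage_v
    if bias_v <= vbr:
        return 0.0
    return model.gain_slope_per_v * (bias_v - vbr)


def sipm_response(
    incident_power_w,
    wavelength_nm: float,
    bias_v: float,
    model: SipmModel | None = None,
) -> np.ndarray:
    """SiPM photocurrent (A) for incident optical power.

    The photon arrival rate P*lambda/(h*c) is thinned by the PDE; the mean
    number of photons per cell-recovery window fires
    ``N_cells * (1 - exp(-n / N_cells))`` cells (saturation as the fired-cell
    count approaches the cell count), and each fired cell contributes one
    avalanche of ``gain * e`` charge.  Linear in P at low power, asymptotic
    to the cell-count ceiling at high power.
    """
    model = model or SipmModel()
    P = np.asarray(incident_power_w, dtype=float)
    if np.any(P < 0):
        raise ValueError("incident power cannot be negative")
    gain = sipm_gain(bias_v, model)
    rate = P / photon_energy_j(wavelength_nm) * model.pde_at(wavelength_nm)
    n_per_window = rate * model.recovery_window_s
    fired = model.n_cells * (1.0 - np.exp(-n_per_window / model.n_cells))
    detected_rate = fired / model.recovery_window_s
    out = detected_rate * gain * ELEMENTARY_CHARGE_C
    return out if out.ndim else float(out)


def safety_limit(
    photocurrent_a: np.ndarray, limit_a: float = 1.5e-3
) -> np.ndarray:
    """Per-sample channel-active mask for the software overcurrent shutdown.

    From the first sample whose photocurrent exceeds the limit, the channel
    is deactivated (mask False onward).  Other channels are unaffected by
    construction — the mask is computed per channel.
    """
    series = np.asarray(photocurrent_a, dtype=float)
    active = np.ones(series.shape, dtype=bool)
    over = np.nonzero(series > limit_a)[0]
    if over.size:
        active[over[0]:] = False
    return active


def slot_average(
    subsamples: np.ndarray,
    timing: CycleTiming | None = None,
) -> float:
    """On-board moving-average value for one 1.2-ms slot.

    Averages the 64 ADC subsamples of the plateau region, which starts
    0.3 ms (30 samples at 100 kHz) after the LED is powered.  Raises if the
    slot does not contain 64 plateau samples.
    """
    t = timing or CycleTiming()
    x = np.asarray(subsamples, dtype=float)
    start = int(round(t.adc_rate_khz * t.plateau_delay_ms))
    if x.size < start + t.avg_window_samples:
        raise ValueError(
            f"slot holds {x.size} samples; need {start + t.avg_window_samples} "
            f"({t.avg_window_samples} plateau samples after {start} settling samples)"
        )
    return float(x[start : start + t.avg_window_samples].mean())


@dataclass(frozen=True)
class DriftConfig:
    """Multiplicative sensor warm-up drift (PDE temperature dependence).

    The sensitivity settles exponentially; the local relative slope of the
    default curve is -0.3 permil/s at t = 60 s and -0.1 permil/s at
    t = 600 s (anchor values configurable).
    """

    slope_60s_per_s: float = 3e-4
    slope_600s_per_s: float = 1e-4
    t_early_s: float = 60.0
    t_late_s: float = 600.0
    enabled: bool = True

    @property
    def tau_s(self) -> float:
        return (self.t_late_s - self.t_early_s) / math.log(
            self.slope_60s_per_s / self.slope_600s_per_s
        )

    @property
    def amplitude_per_s(self) -> float:
        return self.slope_60s_per_s * math.exp(self.t_early_s / self.tau_s)

    def local_relative_slope(self, t_s) -> np.ndarray:
        """d(ln factor)/dt — negative (sensitivity decays while warming up)."""
        t = np.asarray(t_s, dtype=float)
        if not self.enabled:
            return np.zeros_like(t)
        return -self.amplitude_per_s * np.exp(-t / self.tau_s)


def drift_model(t_s, config: DriftConfig | None = None) -> np.ndarray:
    """Multiplicative drift factor over time (1 at t = 0; disabled -> 1)."""
    config = config or DriftConfig()
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if not config.enabled:
        out = np.ones_like(t)
    else:
        a, tau = config.amplitude_per_s, config.tau_s
        out = np.exp(-a * tau * (1.0 - np.exp(-t / tau)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise model: Poisson-limited shot noise on the detected
    photoelectron rate plus a constant electronic floor (V, per ADC
    subsample, before the 64-sample average)."""

    electronic_sd_v: float = 1.5e-3
    include_shot: bool = True
    enabled: bool = True

    @staticmethod
    def shot_sd_v(
        voltage_v, gain: float, chain: AnalogChain, model: SipmModel
    ) -> np.ndarray:
        """Shot-noise sd (V, per subsample) at a given signal voltage.

        The photoelectron count in one ADC sample window is
        n = I * tau / (G * e); its Poisson fluctuation gives a relative sd
        of 1/sqrt(n).
        """
        v = np.asarray(voltage_v, dtype=float)
        if gain <= 0:
            raise ValueError("shot noise undefined below breakdown (gain 0)")
        n_pe = (
            v
            / chain.tia_gain_v_per_a
            * chain.sample_window_s
            / (gain * ELEMENTARY_CHARGE_C)
        )
        out = np.where(n_pe > 0, v / np.sqrt(np.maximum(n_pe, 1e-300)), 0.0)
        return out

    @classmethod
    def calibrated(
        cls,
        target_snr_db: float = 64.0,
        signal_v: float = 1.0,
        bias_v: float = 28.0,
        chain: AnalogChain | None = None,
        model: SipmModel | None = None,
        navg: int = 64,
    ) -> "NoiseConfig":
        """Electronic floor set so a channel at ``signal_v`` measures the
        target SNR (20*log10(mean/sd)) after the on-board 64-sample average.

        Raises if shot noise alone already exceeds the target.
        """
        chain = chain or AnalogChain()
        model = model or SipmModel()
        gain = sipm_gain(bias_v, model)
        total_sub_sd = signal_v * 10 ** (-target_snr_db / 20.0) * math.sqrt(navg)
        shot = float(cls.shot_sd_v(signal_v, gain, chain, model))
        if shot >= total_sub_sd:
            raise ValueError(
                f"shot noise ({shot:.3g} V) alone exceeds the {target_snr_db}-dB "
                "budget; lower the gain or target"
            )
        return cls(electronic_sd_v=math.sqrt(total_sub_sd**2 - shot**2))


@dataclass
class RawRecording:
    """Multiplexed raw recording: per channel x wavelength slot-averaged
    intensities (V), the backlight slot, timestamps, and channel metadata.

    ``active`` marks samples before any software safety shutdown of the
    channel.
    """

    channels: list[Channel]
    wavelengths: tuple[float, ...]
    time: np.ndarray
    intensity: np.ndarray  # (n_channels, n_wavelengths, n_samples), V
    backlight: np.ndarray  # (n_channels, n_samples), V
    active: np.ndarray  # (n_channels, n_samples), bool
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_ch, n_wl, n_t = self.intensity.shape
        if n_ch != len(self.channels) or n_wl != len(self.wavelengths):
            raise ValueError("intensity shape inconsistent with metadata")
        if self.backlight.shape != (n_ch, n_t) or self.active.shape != (n_ch, n_t):
            raise ValueError("backlight/active shape inconsistent with intensity")
        if len(self.time) != n_t:
            raise ValueError("time axis inconsistent with intensity")

    def channel_index(self, label: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.label == label:
                return i
        raise KeyError(f"no channel {label!r}")

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.time}
        for i, ch in enumerate(self.channels):
            for j, wl in enumerate(self.wavelengths):
                cols[f"{ch.label}_{wl:.0f}nm"] = self.intensity[i, j]
            cols[f"{ch.label}_backlight"] = self.backlight[i]
        return pd.DataFrame(cols)


def _baseline_voltages(
    channels: list[Channel],
    wavelengths: tuple[float, ...],
    target_voltage_v: float,
    leveled: bool,
    medium: OpticalProperties | None,
    reference_sds_mm: float,
) -> np.ndarray:
    """(n_ch, n_wl) baseline slot voltages.

    Leveled mode emulates the per-channel LED-current/overvoltage adjustment
    (every channel sits at the target voltage); fixed-settings mode scales
    the target by the diffuse-reflectance ratio to the reference separation.
    """
    n_ch, n_wl = len(channels), len(wavelengths)
    v0 = np.full((n_ch, n_wl), float(target_voltage_v))
    if not leveled:
        if medium is None:
            raise ValueError("fixed-settings mode requires medium optical properties")
        r_ref = diffuse_reflectance(reference_sds_mm, medium)
        for i, ch in enumerate(channels):
            v0[i, :] *= diffuse_reflectance(ch.sds, medium) / r_ref
    return v0


def simulate_recording(
    network: OptodeNetwork,
    extracerebral: ChromophoreTimecourse,
    cerebral: ChromophoreTimecourse | None = None,
    *,
    systems: dict[str, ExtinctionSystem] | None = None,
    noise: NoiseConfig | None = None,
    drift: DriftConfig | None = None,
    seed: int = 0,
    backlight_v: float = 0.05,
    target_voltage_v: float = 1.0,
    leveled: bool = True,
    medium: OpticalProperties | None = None,
    cerebral_weight: float = 1.0,
    sipm: SipmModel | None = None,
    chain: AnalogChain | None = None,
) -> RawRecording:
    """Simulate a full multiplexed raw recording for every channel.

    Per cycle each channel records one backlight slot (ambient offset) and
    four wavelength slots.  The slot voltage is the channel's baseline level
    attenuated by the MBLL forward model of its composed chromophore series,
    multiplied by the warm-up drift, offset by the backlight, perturbed by
    shot + electronic noise on each of the 64 ADC subsamples, quantized to
    the 16-bit grid and plateau-averaged.  The software safety limit
    deactivates a channel from the first over-current sample without
    touching the others.  Deterministic under a fixed seed.

    ``systems`` maps channel labels to the ExtinctionSystem used for the
    forward attenuation (default: the packaged system at each channel's
    SDS); pass the same systems to the reconstruction for a consistent
    forward/inverse pair.
    """
    sipm = sipm or SipmModel()
    chain = chain or AnalogChain()
    noise = noise if noise is not None else NoiseConfig(enabled=False)
    drift = drift or DriftConfig(enabled=False)
    rng = np.random.default_rng(seed)

    channels = enumerate_channels(network)
    if cerebral is None:
        cerebral = ChromophoreTimecourse.zeros(
            len(extracerebral.time) / extracerebral.fs, extracerebral.fs, "cerebral"
        )
    t = extracerebral.time
    n_t = len(t)
    fs = extracerebral.fs
    if systems is None:
        systems = {
            ch.label: ExtinctionSystem.default(pathlength_mm=ch.sds) for ch in channels
        }
    for ch in channels:
        if ch.label not in systems:
            raise ValueError(f"no extinction system for channel {ch.label}")

    wavelengths = tuple(next(iter(systems.values())).wavelengths)
    n_wl = len(wavelengths)
    v0 = _baseline_voltages(
        channels, wavelengths, target_voltage_v, leveled, medium,
        network.intra_module_sds,
    )
    drift_t = drift_model(t, drift)
    navg = CycleTiming().avg_window_samples

    intensity = np.empty((len(channels), n_wl, n_t))
    backlight = np.empty((len(channels), n_t))
    active = np.ones((len(channels), n_t), dtype=bool)

    for i, ch in enumerate(channels):
        system = systems[ch.label]
        tc = compose_layers(extracerebral, cerebral, ch, cerebral_weight)
        # forward MBLL attenuation: dA = ln10 * eps * dC * DPF * L per wavelength
        dA = (system.weighted_matrix(3) @ tc.as_matrix()) * (
            system.dpf[:, None] * system.pathlength
        )
        bias = network.module(ch.detector_module).sipm_overvoltage
        gain = sipm_gain(bias, sipm)

        def measure_slot(v_clean: np.ndarray) -> np.ndarray:
            """64 noisy quantized subsamples -> plateau average, vectorized."""
            if not noise.enabled:
                return chain.quantize(v_clean)
            sd = np.full_like(v_clean, noise.electronic_sd_v)
            if noise.include_shot:
                sd = np.sqrt(sd**2 + NoiseConfig.shot_sd_v(v_clean, gain, chain, sipm) ** 2)
            sub = v_clean[:, None] + sd[:, None] * rng.standard_normal((v_clean.size, navg))
            return chain.quantize(sub).mean(axis=1)

        bl_clean = backlight_v * drift_t
        backlight[i] = measure_slot(bl_clean)
        for j in range(n_wl):
            v_clean = v0[i, j] * np.exp(-dA[j]) * drift_t + bl_clean
            intensity[i, j] = measure_slot(v_clean)
            active[i] &= safety_limit(
                intensity[i, j] / chain.tia_gain_v_per_a, sipm.photocurrent_limit_a
            )

    return RawRecording(
        channels=channels,
        wavelengths=wavelengths,
        time=t,
        intensity=intensity,
        backlight=backlight,
        active=active,
        fs=fs,
        meta={"seed": seed, "leveled": leveled, "backlight_v": backlight_v,
              "target_voltage_v": target_voltage_v},
    )
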