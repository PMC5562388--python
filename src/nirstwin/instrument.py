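"""Optode-network data model and instrument scheduling arithmetic.

The instrument is a network of N identical hexagonal modules, each carrying
four time-multiplexed LEDs and one silicon-photomultiplier (SiPM) detector.
During a measurement cycle one module acts as source while every module
(including the source itself) reads out its detector, so N modules yield
N x N optical channels: N short-separation (SS) channels, where source and
detector sit on the same printed circuit board 7.5 mm apart, and N*(N-1)
long-separation (LS) channels between distinct modules.

The scheduling arithmetic in this module is exact and deterministic: the
measurement cycle is 6.6 ms of light acquisition (five 1.2-ms slots:
backlight + four wavelengths), 1.2 ms of on-board averaging, and 0.6 ms of
bus communication per module read out.  The achievable per-channel sampling
frequency for NS source and ND detector modules is
``100 Hz / (NS * (1 + 0.06 * ND))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "NOMINAL_WAVELENGTHS_NM",
    "MEASURED_WAVELENGTHS_NM",
    "OptodeModule",
    "OptodeNetwork",
    "Channel",
    "CycleTiming",
    "enumerate_channels",
    "sampling_frequency",
    "cycle_duration",
    "adc_samples_per_window",
    "effective_sampling_rate",
]

#: Nominal LED peak wavelengths (nm) as selected for chromophore separability.
NOMINAL_WAVELENGTHS_NM: tuple[float, ...] = (770.0, 810.0, 855.0, 885.0)
#: Spectrometer-measured LED peak wavelengths (nm) used for extinction lookup.
MEASURED_WAVELENGTHS_NM: tuple[float, ...] = (774.0, 817.0, 865.0, 892.0)

LED_CURRENT_RANGE_MA = (1.0, 90.0)
SIPM_BIAS_RANGE_V = (24.0, 33.0)

#: Intra-module source-detector separation (mm): LED-to-SiPM distance on the PCB.
DEFAULT_INTRA_MODULE_SDS_MM = 7.5


@dataclass(frozen=True)
class OptodeModule:
    """One hexagonal optode module: four LEDs plus one SiPM detector.

    Parameters
    ----------
    id : int
        Unique module identifier (doubles as the I2C-style address).
    position : tuple of float
        2-D head-surface coordinate in mm.
    led_wavelengths : sequence of float
        Four nominal LED wavelengths, nm.
    led_measured_wavelengths : sequence of float
        Four measured LED peak wavelengths, nm.
    led_currents : sequence of float
        Four LED forward currents, mA; each within [1, 90].
    sipm_overvoltage : float
        SiPM bias-voltage setting, V; within [24, 33].
    """

    id: int
    position: tuple[float, float]
    led_wavelengths: tuple[float, ...] = NOMINAL_WAVELENGTHS_NM
    led_measured_wavelengths: tuple[float, ...] = MEASURED_WAVELENGTHS_NM
    led_currents: tuple[float, ...] = (30.0, 60.0, 30.0, 90.0)
    sipm_overvoltage: float = 28.0

    def __post_init__(self) -> None:
        if len(self.led_wavelengths) != 4:
            raise ValueError("a module carries exactly 4 LED wavelengths")
        if len(self.led_measured_wavelengths) != 4:
            raise ValueError("a module carries exactly 4 measured wavelengths")
        if len(self.led_currents) != 4:
            raise ValueError("a module carries exactly 4 LED currents")
        lo, hi = LED_CURRENT_RANGE_MA
        for i_f in self.led_currents:
            if not lo <= i_f <= hi:
                raise ValueError(
                    f"LED forward current {i_f} mA outside [{lo}, {hi}] mA"
                )
        lo, hi = SIPM_BIAS_RANGE_V
        if not lo <= self.sipm_overvoltage <= hi:
            raise ValueError(
                f"SiPM bias {self.sipm_overvoltage} V outside [{lo}, {hi}] V"
            )


@dataclass(frozen=True)
class OptodeNetwork:
    """A set of optode modules placed on the head surface."""

    modules: tuple[OptodeModule, ...]
    intra_module_sds: float = DEFAULT_INTRA_MODULE_SDS_MM

    def __post_init__(self) -> None:
        if len(self.modules) < 1:
            raise ValueError("a network needs at least one module")
        ids = [m.id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValueError("module ids must be unique")
        if self.intra_module_sds <= 0:
            raise ValueError("intra-module SDS must be positive")

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module(self, module_id: int) -> OptodeModule:
        for m in self.modules:
            if m.id == module_id:
                return m
        raise KeyError(f"no module with id {module_id}")

    @classmethod
    def from_positions(
        cls,
        positions: Sequence[tuple[float, float]],
        intra_module_sds: float = DEFAULT_INTRA_MODULE_SDS_MM,
        **module_kwargs,
    ) -> "OptodeNetwork":
        """Build a network of identical modules at the given 2-D positions."""
        mods = tuple(
            OptodeModule(id=i, position=tuple(p), **module_kwargs)
            for i, p in enumerate(positions)
        )
        return cls(modules=mods, intra_module_sds=intra_module_sds)


@dataclass(frozen=True)
class Channel:
    """One source-detector pair.

    ``kind`` is ``"SS"`` iff source and detector are the same module (the
    7.5-mm on-board separation); every cross-module pair is ``"LS"`` with the
    Euclidean inter-module distance as its SDS.
    """

    source_module: int
    detector_module: int
    sds: float
    kind: str  # "SS" | "LS"

    def __post_init__(self) -> None:
        if self.kind not in ("SS", "LS"):
            raise ValueError("channel kind must be 'SS' or 'LS'")
        if (self.source_module == self.detector_module) != (self.kind == "SS"):
            raise ValueError("kind 'SS' iff source and detector module coincide")
        if self.sds < 0:
            raise ValueError("SDS must be non-negative")

    @property
    def label(self) -> str:
        return f"S{self.source_module}D{self.detector_module}"


@dataclass(frozen=True)
class CycleTiming:
    """Timing constants of one measurement cycle (all in ms unless noted).

    The 6.6-ms acquisition window holds five 1.2-ms slots (backlight + four
    wavelengths) plus margin; the ADC free-runs at 100 kHz and the on-board
    moving average uses 64 samples from the slot plateau reached 0.3 ms after
    the LED is powered.
    """

    acquisition_ms: float = 6.6
    processing_ms: float = 1.2
    comm_ms_per_module: float = 0.6
    slot_ms: float = 1.2
    adc_rate_khz: float = 100.0
    avg_window_samples: int = 64
    plateau_delay_ms: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "acquisition_ms",
            "processing_ms",
            "comm_ms_per_module",
            "slot_ms",
            "adc_rate_khz",
            "plateau_delay_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.avg_window_samples < 1:
            raise ValueError("avg_window_samples must be >= 1")
        # five slots (backlight + 4 wavelengths) must fit the acquisition window
        if 5 * self.slot_ms > self.acquisition_ms + 1e-9:
            raise ValueError("acquisition window shorter than 5 slots")


def enumerate_channels(network: OptodeNetwork) -> list[Channel]:
    """List all N^2 channels of a network.

    Every module in turn acts as source while every module (the source
    included) reads out its detector, so N modules give exactly N*N channels:
    N SS self-pairs at the intra-module separation and N*(N-1) LS pairs at
    the Euclidean inter-module distance.
    """
    channels: list[Channel] = []
    for src in network.modules:
        for det in network.modules:
            if src.id == det.id:
                channels.append(
                    Channel(src.id, det.id, network.intra_module_sds, "SS")
                )
            else:
                d = math.dist(src.position, det.position)
                channels.append(Channel(src.id, det.id, d, "LS"))
    return channels


def sampling_frequency(n_sources: int, n_detectors: int) -> float:
    """Per-channel sampling frequency (Hz) for NS sources and ND detectors.

    Evaluates ``100 Hz / (NS * (1 + 0.06 * ND))``: the 100-Hz cycle budget is
    shared across the NS source turns, and every detector module read out adds
    0.6 ms (= 6% of the 10-ms budget) of communication time.
    """
    if n_sources < 1:
        raise ValueError("need at least one source module")
    if n_detectors < 0:
        raise ValueError("detector count cannot be negative")
    return 100.0 / (n_sources * (1.0 + 0.06 * n_detectors))


def cycle_duration(n_modules_read: int, timing: CycleTiming | None = None) -> float:
    """Duration of one measurement cycle in ms.

    Acquisition (6.6 ms) + on-board processing (1.2 ms) + 0.6 ms communication
    per module read out.
    """
    if n_modules_read < 1:
        raise ValueError("at least one module must be read out")
    t = timing or CycleTiming()
    return t.acquisition_ms + t.processing_ms + n_modules_read * t.comm_ms_per_module


def adc_samples_per_window(adc_rate_khz: float, window_ms: float) -> int:
    """Number of ADC samples acquired in a window (rate in kHz, window in ms)."""
    if adc_rate_khz <= 0:
        raise ValueError("ADC rate must be positive")
    if window_ms < 0:
        raise ValueError("window length cannot be negative")
    return math.floor(adc_rate_khz * window_ms)


def effective_sampling_rate(
    network: OptodeNetwork, timing: CycleTiming | None = None
) -> dict[str, float]:
    """Achievable per-channel sampling rate for a network configuration.

    The shared-bus formula and the <10-ms cycle budget are independent
    constraints; the achievable rate is the minimum of the two.  Returns all
    three components (Hz).
    """
    n = network.n_modules
    f_formula = sampling_frequency(n, n)
    f_cycle = 1000.0 / (cycle_duration(n, timing) * n)
    return {
        "formula_hz": f_formula,
        "cycle_bound_hz": f_cycle,
        "effective_hz": min(f_formula, f_cycle),
    }
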