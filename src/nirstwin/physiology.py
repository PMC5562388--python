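"""Ground-truth chromophore time courses for the evaluation protocols.

Generates layered physiology in muM for the three chromophores tracked by the
instrument — oxyhemoglobin (O2Hb), deoxyhemoglobin (HHb), and the
oxidized-minus-reduced cytochrome-c-oxidase difference (oxCCO):

* extracerebral systemic oscillations (Mayer waves ~0.1 Hz, respiration
  ~0.25 Hz, cardiac ~1 Hz) seen by short- and long-separation channels alike;
* a cerebral hemodynamic response to a block-design motor task (canonical
  double-gamma kernel convolved with the task boxcar), seen by
  long-separation channels only;
* an arm arterial-occlusion trajectory (venous rise, arterial desaturation
  ramp, post-release hyperemia) for muscle measurements.

Short-separation channels contain only the extracerebral layer; long
channels add the cerebral layer scaled by a partial-pathlength weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .instrument import Channel

__all__ = [
    "ChromophoreTimecourse",
    "OscillationComponent",
    "RestSpec",
    "MotorBlockSpec",
    "OcclusionSpec",
    "systemic_oscillations",
    "motor_task_response",
    "occlusion_timecourse",
    "compose_layers",
    "canonical_hrf",
]

CHROMOPHORES = ("o2hb", "hhb", "oxcco")


@dataclass
class ChromophoreTimecourse:
    """Equal-length chromophore concentration-change series on a uniform grid.

    time : s; delta_o2hb / delta_hhb / delta_oxcco : muM;
    layer : 'extracerebral' | 'cerebral' | 'muscle' | 'composite'.
    """

    time: np.ndarray
    delta_o2hb: np.ndarray
    delta_hhb: np.ndarray
    delta_oxcco: np.ndarray
    layer: str = "composite"

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("delta_o2hb", "delta_hhb", "delta_oxcco"):
            if len(getattr(self, name)) != n:
                raise ValueError("all chromophore series must match the time grid")
        if n >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time grid must be uniform")

    @property
    def fs(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    def as_matrix(self) -> np.ndarray:
        """(3, T) array ordered (O2Hb, HHb, oxCCO)."""
        return np.vstack([self.delta_o2hb, self.delta_hhb, self.delta_oxcco])

    @classmethod
    def from_matrix(cls, time: np.ndarray, mat: np.ndarray, layer: str = "composite"):
        return cls(time, mat[0].copy(), mat[1].copy(), mat[2].copy(), layer)

    @classmethod
    def zeros(cls, duration_s: float, fs: float, layer: str = "composite"):
        t = np.arange(int(round(duration_s * fs))) / fs
        z = np.zeros_like(t)
        return cls(t, z.copy(), z.copy(), z.copy(), layer)


@dataclass(frozen=True)
class OscillationComponent:
    """One sinusoidal systemic component: frequency (Hz), O2Hb amplitude (muM),
    HHb amplitude (muM), and fractional frequency jitter (seeded)."""

    freq_hz: float
    amp_o2hb_um: float
    amp_hhb_um: float
    freq_jitter: float = 0.02


# Default systemic mix: Mayer waves dominate O2Hb, HHb follows attenuated
# (amplitudes in muM chosen to qualitatively match resting-state recordings).
DEFAULT_OSCILLATIONS = (
    OscillationComponent(0.1, 0.40, 0.10),   # Mayer waves
    OscillationComponent(0.25, 0.20, 0.05),  # respiration
    OscillationComponent(1.0, 0.20, 0.05),   # cardiac
)


@dataclass(frozen=True)
class RestSpec:
    """Resting-state protocol: systemic oscillations only."""

    duration_s: float = 300.0
    oscillations: tuple[OscillationComponent, ...] = DEFAULT_OSCILLATIONS

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class MotorBlockSpec:
    """Block-design motor task: 20-s task / 20-s rest, 10 repetitions.

    ``amp_o2hb_um`` is the peak cerebral O2Hb response (muM); HHb responds
    with the opposite sign at ``hhb_ratio`` times the O2Hb amplitude; oxCCO
    stays flat during the task.
    """

    task_s: float = 20.0
    rest_s: float = 20.0
    repetitions: int = 10
    lead_in_s: float = 10.0
    amp_o2hb_um: float = 0.5
    hhb_ratio: float = -0.3
    oscillations: tuple[OscillationComponent, ...] = DEFAULT_OSCILLATIONS

    def __post_init__(self) -> None:
        if self.task_s <= 0 or self.rest_s <= 0:
            raise ValueError("task and rest durations must be positive")
        if self.repetitions < 1:
            raise ValueError("at least one repetition required")

    @property
    def duration_s(self) -> float:
        return self.lead_in_s + self.repetitions * (self.task_s + self.rest_s)

    @property
    def onsets_s(self) -> np.ndarray:
        return self.lead_in_s + (self.task_s + self.rest_s) * np.arange(self.repetitions)


@dataclass(frozen=True)
class OcclusionSpec:
    """Arm arterial occlusion: 120-s cuff + 180-s rest, three repetitions
    (onsets 120, 420, 720 s; total 1020 s).

    During the cuff a brief venous phase raises both hemoglobins, then the
    arterial phase ramps O2Hb down and HHb up; release produces a hyperemic
    O2Hb overshoot / HHb undershoot with exponential recovery.  oxCCO shows a
    small upward trend during occlusion (|oxCCO| / |HHb| = ``occ_oxcco_ratio``)
    and a release peak at ``release_oxcco_ratio`` of the HHb excursion.
    """

    onsets_s: tuple[float, ...] = (120.0, 420.0, 720.0)
    cuff_s: float = 120.0
    total_s: float = 1020.0
    venous_s: float = 10.0
    venous_rise_um: float = 1.5
    o2hb_drop_um: float = -15.0
    hhb_rise_um: float = 15.0
    overshoot_o2hb_um: float = 10.0
    undershoot_hhb_um: float = -5.0
    refill_tau_s: float = 4.0
    hyperemia_peak_s: float = 8.0
    recovery_tau_s: float = 25.0
    occ_oxcco_ratio: float = 0.08
    release_oxcco_ratio: float = 0.2

    def __post_init__(self) -> None:
        if self.cuff_s <= 0 or self.total_s <= 0:
            raise ValueError("durations must be positive")
        onsets = sorted(self.onsets_s)
        for a, b in zip(onsets, onsets[1:]):
            if a + self.cuff_s > b:
                raise ValueError("cuff intervals overlap")
        if onsets and onsets[-1] + self.cuff_s > self.total_s:
            raise ValueError("cuff interval exceeds recording duration")


def _max_freq(oscillations) -> float:
    return max((o.freq_hz for o in oscillations), default=0.0)


def systemic_oscillations(
    spec: RestSpec | MotorBlockSpec,
    duration_s: float | None = None,
    fs: float = 25.0,
    seed: int = 0,
) -> ChromophoreTimecourse:
    """Extracerebral systemic physiology as a sum of jittered sinusoids.

    Each component gets a seeded random phase and a small relative frequency
    perturbation; O2Hb carries the full amplitudes, HHb the attenuated ones,
    oxCCO stays flat.  Raises if ``fs`` undersamples the fastest component.
    """
    oscillations = spec.oscillations
    if duration_s is None:
        duration_s = spec.duration_s
    fmax = _max_freq(oscillations)
    if fs < 2.0 * fmax:
        raise ValueError(
            f"fs = {fs} Hz undersamples the {fmax}-Hz component (need >= {2*fmax} Hz)"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    o2hb = np.zeros_like(t)
    hhb = np.zeros_like(t)
    for comp in oscillations:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        f = comp.freq_hz * (1.0 + comp.freq_jitter * rng.standard_normal())
        lag = rng.uniform(0.0, 0.5)  # HHb slightly lags O2Hb
        o2hb += comp.amp_o2hb_um * np.sin(2.0 * np.pi * f * t + phase)
        hhb += comp.amp_hhb_um * np.sin(2.0 * np.pi * f * t + phase - lag)
    return ChromophoreTimecourse(t, o2hb, hhb, np.zeros_like(t), "extracerebral")


def canonical_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                  undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel, unit peak."""
    h = _gamma_dist.pdf(t, peak_s) - undershoot_ratio * _gamma_dist.pdf(t, undershoot_s)
    return h / h.max()


def motor_task_response(
    spec: MotorBlockSpec, duration_s: float | None = None, fs: float = 25.0
) -> ChromophoreTimecourse:
    """Cerebral hemodynamic response to the block design (deterministic).

    The task boxcar is convolved with the canonical double-gamma kernel and
    normalized to unit peak, so ``amp_o2hb_um`` is the realized O2Hb peak;
    HHb mirrors it scaled by ``hhb_ratio`` (negative); oxCCO is zero.
    """
    if duration_s is None:
        duration_s = spec.duration_s
    if spec.onsets_s[-1] + spec.task_s > duration_s:
        raise ValueError("block design does not fit the requested duration")
    t = np.arange(int(round(duration_s * fs))) / fs
    box = np.zeros_like(t)
    for onset in spec.onsets_s:
        box[(t >= onset) & (t < onset + spec.task_s)] = 1.0
    kernel = canonical_hrf(np.arange(0.0, 30.0, 1.0 / fs))
    resp = np.convolve(box, kernel)[: len(t)]
    peak = resp.max()
    if peak > 0:
        resp /= peak
    o2hb = spec.amp_o2hb_um * resp
    hhb = spec.hhb_ratio * spec.amp_o2hb_um * resp
    return ChromophoreTimecourse(t, o2hb, hhb, np.zeros_like(t), "cerebral")


def _alpha_pulse(t_rel: np.ndarray, peak_s: float, tau_s: float) -> np.ndarray:
    """Smooth pulse rising to 1 at ``peak_s`` then decaying with ``tau_s``."""
    x = np.clip(t_rel, 0.0, None)
    rise = 1.0 - np.exp(-x / (peak_s / 3.0))
    decay = np.exp(-np.clip(x - peak_s, 0.0, None) / tau_s)
    pulse = rise * decay
    m = pulse.max()
    return pulse / m if m > 0 else pulse


def occlusion_timecourse(spec: OcclusionSpec, fs: float = 25.0) -> ChromophoreTimecourse:
    """Piecewise muscle trajectory for the arterial-occlusion protocol."""
    t = np.arange(int(round(spec.total_s * fs))) / fs
    o2hb = np.zeros_like(t)
    hhb = np.zeros_like(t)
    oxcco = np.zeros_like(t)
    for onset in sorted(spec.onsets_s):
        rel = t - onset
        cuff = (rel >= 0) & (rel < spec.cuff_s)
        venous = cuff & (rel < spec.venous_s)
        arterial = cuff & (rel >= spec.venous_s)
        # venous phase: both hemoglobins rise together
        o2hb[venous] += spec.venous_rise_um * rel[venous] / spec.venous_s
        hhb[venous] += spec.venous_rise_um * rel[venous] / spec.venous_s
        # arterial phase: linear desaturation ramps from the venous level
        frac = (rel[arterial] - spec.venous_s) / (spec.cuff_s - spec.venous_s)
        o2hb[arterial] += spec.venous_rise_um + frac * (spec.o2hb_drop_um - spec.venous_rise_um)
        hhb[arterial] += spec.venous_rise_um + frac * (spec.hhb_rise_um - spec.venous_rise_um)
        # oxCCO: small upward trend bounded by occ_oxcco_ratio * |HHb change|
        oxcco[cuff] += (
            spec.occ_oxcco_ratio * abs(spec.hhb_rise_um) * np.clip(rel[cuff], 0, spec.cuff_s) / spec.cuff_s
        )
        # release: rapid refill back toward baseline plus a hyperemic
        # overshoot/undershoot pulse with slower exponential recovery
        post = rel >= spec.cuff_s
        tr = rel[post] - spec.cuff_s
        pulse = _alpha_pulse(tr, spec.hyperemia_peak_s, spec.recovery_tau_s)
        refill = np.exp(-tr / spec.refill_tau_s)
        o2hb[post] += spec.o2hb_drop_um * refill + spec.overshoot_o2hb_um * pulse
        hhb[post] += spec.hhb_rise_um * refill + spec.undershoot_hhb_um * pulse
        # pulse amplitude chosen so the realized oxCCO release peak sits at
        # release_oxcco_ratio * |HHb excursion| on top of the decaying trend
        occ_level = spec.occ_oxcco_ratio * abs(spec.hhb_rise_um)
        peak_target = spec.release_oxcco_ratio * abs(spec.hhb_rise_um)
        pulse_amp = peak_target - occ_level * np.exp(-spec.hyperemia_peak_s / spec.recovery_tau_s)
        oxcco[post] += occ_level * np.exp(-tr / spec.recovery_tau_s) + pulse_amp * pulse
    return ChromophoreTimecourse(t, o2hb, hhb, oxcco, "muscle")


def compose_layers(
    extracerebral: ChromophoreTimecourse,
    cerebral: ChromophoreTimecourse,
    channel: Channel,
    cerebral_weight: float = 1.0,
) -> ChromophoreTimecourse:
    """Effective chromophore series seen by a channel.

    SS channels sample only the extracerebral layer; LS channels add the
    cerebral layer scaled by a partial-pathlength weight (default 1.0).
    """
    if len(extracerebral.time) != len(cerebral.time) or not np.allclose(
        extracerebral.time, cerebral.time
    ):
        raise ValueError("extracerebral and cerebral time grids differ")
    if channel.kind == "SS":
        mat = extracerebral.as_matrix().copy()
    else:
        mat = extracerebral.as_matrix() + cerebral_weight * cerebral.as_matrix()
    return ChromophoreTimecourse.from_matrix(extracerebral.time, mat, "composite")
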