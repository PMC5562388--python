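"""Post-reconstruction processing for the in-vivo analyses.

Zero-phase Chebyshev-II filtering of concentration time courses, sliding
window short-channel regression (scaled subtraction of the short-separation
signal from the long-separation signal, per chromophore), and trial-wise
block averaging with standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "FilterSpec",
    "EpochSet",
    "design_filter",
    "zero_phase_filter",
    "short_channel_regression",
    "block_average",
]


@dataclass(frozen=True)
class FilterSpec:
    """Chebyshev-II filter specification.

    ``edges_hz`` are the passband edges (one for lowpass, two for bandpass);
    the Chebyshev-II stopband edges are placed ``stop_edge_factor`` (default
    one octave) outside the passband.  ``order`` is the design order passed
    to the IIR designer; ``stopband_db`` the stopband attenuation.  The
    defaults mirror the instrument's analyses: a third-order 1-Hz lowpass
    for occlusion recordings and a fourth-order 0.01-0.5-Hz bandpass for the
    motor task, both applied forward-backward (zero phase).
    """

    kind: str  # "lowpass" | "bandpass"
    order: int
    edges_hz: tuple[float, ...]
    stopband_db: float = 40.0
    zero_phase: bool = True
    stop_edge_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise ValueError("kind must be 'lowpass' or 'bandpass'")
        n_edges = 1 if self.kind == "lowpass" else 2
        if len(self.edges_hz) != n_edges:
            raise ValueError(f"{self.kind} needs {n_edges} band edge(s)")
        if any(e <= 0 for e in self.edges_hz):
            raise ValueError("band edges must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    @classmethod
    def occlusion_lowpass(cls) -> "FilterSpec":
        return cls(kind="lowpass", order=3, edges_hz=(1.0,))

    @classmethod
    def motor_bandpass(cls) -> "FilterSpec":
        return cls(kind="bandpass", order=4, edges_hz=(0.01, 0.5))


def design_filter(spec: FilterSpec, fs: float):
    """Second-order sections for the specified Chebyshev-II filter."""
    nyq = fs / 2.0
    if spec.kind == "lowpass":
        ws = spec.edges_hz[0] * spec.stop_edge_factor
        if ws >= nyq:
            raise ValueError(f"stopband edge {ws} Hz at or above Nyquist ({nyq} Hz)")
        wn = ws
        btype = "lowpass"
    else:
        lo, hi = spec.edges_hz
        ws_lo = lo / spec.stop_edge_factor
        ws_hi = hi * spec.stop_edge_factor
        if ws_hi >= nyq:
            raise ValueError(f"stopband edge {ws_hi} Hz at or above Nyquist ({nyq} Hz)")
        wn = (ws_lo, ws_hi)
        btype = "bandpass"
    return _signal.cheby2(
        spec.order, spec.stopband_db, wn, btype=btype, fs=fs, output="sos"
    )


def zero_phase_filter(series: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply the filter forward-backward (zero net phase, squared magnitude).

    ``series`` filters along its last axis; it must exceed the filtfilt
    padding requirement.
    """
    sos = design_filter(spec, fs)
    x = np.asarray(series, dtype=float)
    if spec.zero_phase:
        return _signal.sosfiltfilt(sos, x, axis=-1)
    return _signal.sosfilt(sos, x, axis=-1)


def _rolling_alpha(
    short: np.ndarray, long: np.ndarray, window: int
) -> np.ndarray:
    """Per-sample projection coefficient of long onto short over a centered
    sliding window (mean-centered least squares); windows shrink at the
    record edges."""
    s = pd.Series(short)
    l = pd.Series(long)
    minp = max(2, window // 2)
    ms = s.rolling(window, center=True, min_periods=minp).mean()
    ml = l.rolling(window, center=True, min_periods=minp).mean()
    cov = (s * l).rolling(window, center=True, min_periods=minp).mean() - ms * ml
    var = (s * s).rolling(window, center=True, min_periods=minp).mean() - ms**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (cov / var).to_numpy()
    bad = ~np.isfinite(alpha) | (var.to_numpy() <= 1e-300)
    if bad.any():
        warnings.warn("zero-variance short-channel window: scaling set to 0")
        alpha[bad] = 0.0
    return alpha


def short_channel_regression(
    long: np.ndarray,
    short: np.ndarray,
    fs: float,
    window_s: float = 120.0,
    return_alpha: bool = False,
):
    """Remove the scaled short-separation signal from the long-separation one.

    For each chromophore row and each 120-s sliding window, the scaling
    factor is the least-squares projection coefficient
    alpha = <SS, LS> / <SS, SS> on mean-centered windowed data; the corrected
    series is LS - alpha*SS assembled with per-sample alpha.  Rows are
    processed independently (separate factors for O2Hb and HHb).
    """
    L = np.atleast_2d(np.asarray(long, dtype=float))
    S = np.atleast_2d(np.asarray(short, dtype=float))
    if L.shape != S.shape:
        raise ValueError("long and short series must be aligned and equal shape")
    window = int(round(window_s * fs))
    if window > L.shape[1]:
        raise ValueError("regression window longer than the recording")
    out = np.empty_like(L)
    alphas = np.empty_like(L)
    for r in range(L.shape[0]):
        a = _rolling_alpha(S[r], L[r], window)
        alphas[r] = a
        out[r] = L[r] - a * S[r]
    if np.asarray(long).ndim == 1:
        out, alphas = out[0], alphas[0]
    return (out, alphas) if return_alpha else out


@dataclass
class EpochSet:
    """Trial epochs cut around event onsets.

    ``epochs``: (n_trials, ..., n_timepoints) with the leading trial axis;
    ``t_rel``: time relative to onset (s); ``mean`` / ``sem``: per-timepoint
    across-trial mean and standard error.
    """

    epochs: np.ndarray
    t_rel: np.ndarray
    event_times: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.epochs.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        if self.n_trials < 2:
            warnings.warn("standard error undefined for a single trial; reporting 0")
            return np.zeros_like(self.epochs[0])
        return self.epochs.std(axis=0, ddof=1) / np.sqrt(self.n_trials)


def block_average(
    series: np.ndarray,
    event_times_s,
    fs: float,
    window_s: tuple[float, float] = (-2.0, 40.0),
    baseline_s: tuple[float, float] | None = (-2.0, 0.0),
) -> EpochSet:
    """Cut trials around onsets and average them.

    Epochs span ``window_s`` relative to each onset (default -2 s to +40 s,
    covering the 20-s task and 20-s rest); each epoch is shifted so the mean
    of its ``baseline_s`` (pre-onset) interval is zero.  Events whose window
    exceeds the recording are dropped; raises if none remain.
    """
    x = np.asarray(series, dtype=float)
    n_t = x.shape[-1]
    i_lo = int(round(window_s[0] * fs))
    i_hi = int(round(window_s[1] * fs))
    t_rel = np.arange(i_lo, i_hi) / fs
    epochs = []
    kept = []
    for onset in np.atleast_1d(np.asarray(event_times_s, dtype=float)):
        i0 = int(round(onset * fs)) + i_lo
        i1 = int(round(onset * fs)) + i_hi
        if i0 < 0 or i1 > n_t:
            continue
        ep = x[..., i0:i1].copy()
        if baseline_s is not None:
            b0 = int(round((onset + baseline_s[0]) * fs))
            b1 = int(round((onset + baseline_s[1]) * fs))
            base = x[..., b0:b1].mean(axis=-1, keepdims=True)
            ep -= base
        epochs.append(ep)
        kept.append(onset)
    if not epochs:
        raise ValueError("no complete epoch fits the recording")
    return EpochSet(
        epochs=np.stack(epochs), t_rel=t_rel, event_times=np.asarray(kept)
    )
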