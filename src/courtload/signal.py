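"""Raw triaxial acceleration -> filtered net-force intensity series.

The processing chain mirrors accelerometry-based time-motion analysis in
court sports: each axis of a 100 Hz trace is band-pass filtered (0.1-15 Hz
Butterworth, zero-phase), the per-sample resultant magnitude is multiplied
by body mass to give net force in newtons, and the force is averaged over
fixed epochs.  The session intensity metric AvF_NET is the mean epoch
force; session volume is the impulse AvF_NET x duration (kN.s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal as sps

G_TO_MS2 = 9.81  # standard gravity, m/s^2 per g


@dataclass
class AccelTrace:
    """Uniformly sampled triaxial acceleration for one player-session.

    ``samples`` is an (n, 3) array in units of g.
    """

    player_id: str
    session_id: str
    sample_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class ForceSeries:
    """Epoch-averaged net force (newtons) for one player-session."""

    player_id: str
    session_id: str
    epoch_length: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.values.size and self.values.min() < 0:
            raise ValueError("force values must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length


def design_bandpass(sample_rate: float, low: float = 0.1, high: float = 15.0,
                    order: int = 4) -> np.ndarray:
    """Second-order sections for the band-pass Butterworth filter.

    ``order`` is the overall filter order (poles); the underlying low-pass
    prototype has order // 2 poles, which `scipy.signal.butter` expands to
    ``order`` for a band-pass design.
    """
    nyq = sample_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"cutoffs must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got low={low}, high={high}"
        )
    if order < 2 or order % 2:
        raise ValueError("order must be an even integer >= 2")
    return _cached_design(sample_rate, low, high, order)


@lru_cache(maxsize=32)
def _cached_design(sample_rate: float, low: float, high: float,
                   order: int) -> np.ndarray:
    return sps.butter(order // 2, [low, high], btype="bandpass",
                      fs=sample_rate, output="sos")


def bandpass_gain(freq_hz, sample_rate: float, low: float = 0.1,
                  high: float = 15.0, order: int = 4,
                  zero_phase: bool = True) -> np.ndarray:
    """Magnitude response of the implemented filter at ``freq_hz``.

    Zero-phase (forward-backward) application squares the single-pass
    magnitude.  Used by the synthetic generator to pre-compensate carrier
    amplitudes so planted intensities survive filtering exactly.
    """
    sos = design_bandpass(sample_rate, low, high, order)
    w = 2 * np.pi * np.atleast_1d(np.asarray(freq_hz, float)) / sample_rate
    _, h = sps.sosfreqz(sos, worN=w)
    mag = np.abs(h)
    if zero_phase:
        mag = mag ** 2
    return mag if np.ndim(freq_hz) else float(mag[0])


def bandpass_filter(trace: AccelTrace, low: float = 0.1, high: float = 15.0,
                    order: int = 4) -> AccelTrace:
    """Zero-phase band-pass filter each axis of a trace.

    DC (gravity) lies below the 0.1 Hz edge and is removed; the 0.1-15 Hz
    movement band passes with unit gain.  Forward-backward application
    preserves event timing so epoch band assignment is not phase-shifted.
    """
    if trace.sample_rate <= 2 * high:
        raise ValueError(
            f"sample_rate {trace.sample_rate} Hz must exceed twice the upper "
            f"cutoff {high} Hz (Nyquist)"
        )
    if trace.n_samples <= 3 * order:
        raise ValueError("trace too short to filter")
    sos = design_bandpass(trace.sample_rate, low, high, order)
    filtered = sps.sosfiltfilt(sos, trace.samples, axis=0)
    return replace(trace, samples=np.ascontiguousarray(filtered))


def resultant_acceleration(trace: AccelTrace) -> np.ndarray:
    """Per-sample Euclidean magnitude sqrt(ax^2+ay^2+az^2), in g."""
    return np.linalg.norm(trace.samples, axis=1)


def compute_force_series(magnitude_g: np.ndarray, body_mass_kg: float,
                         sample_rate: float, epoch_length: float = 1.0, *,
                         player_id: str = "", session_id: str = "") -> ForceSeries:
    """Convert an acceleration-magnitude series to epoch-mean net force.

    Force per sample is magnitude (g) x 9.81 m/s^2 x mass (kg), in newtons;
    each epoch value is the mean force over the epoch.  A trailing partial
    epoch is dropped (at most one epoch of the trace).
    """
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    magnitude_g = np.asarray(magnitude_g, dtype=float)
    force = magnitude_g * G_TO_MS2 * body_mass_kg
    per_epoch = int(round(epoch_length * sample_rate))
    if per_epoch < 1:
        raise ValueError("epoch shorter than one sample")
    n_epochs = force.size // per_epoch
    if n_epochs == 0:
        raise ValueError("trace shorter than one epoch")
    epochs = force[: n_epochs * per_epoch].reshape(n_epochs, per_epoch).mean(axis=1)
    return ForceSeries(player_id=player_id, session_id=session_id,
                       epoch_length=epoch_length, values=epochs)


def session_intensity(force: ForceSeries) -> float:
    """AvF_NET: mean net force over all epochs (newtons)."""
    if force.n_epochs == 0:
        raise ValueError("empty force series")
    return float(force.values.mean())


def session_impulse(force: ForceSeries, duration_s: float | None = None) -> float:
    """Impulse = AvF_NET x duration, in kN.s.

    ``duration_s`` defaults to the monitored duration of the series.
    """
    if duration_s is None:
        duration_s = force.duration_s
    return session_intensity(force) * duration_s / 1000.0


def analog_bandpass_magnitude(freq_hz, low: float = 0.1, high: float = 15.0,
                              order: int = 4) -> np.ndarray:
    """Closed-form Butterworth band-pass magnitude |H(j2πf)|.

    For the low-pass-to-band-pass transformed Butterworth of overall order
    2N (prototype order N = order/2):

        |H|^2 = 1 / (1 + ((w^2 - w0^2) / (w B))^(2N))

    with w0^2 = w_low w_high and B = w_high - w_low.  Serves as the
    independent frequency-response oracle for the digital implementation
    (evaluated at bilinear-prewarped frequencies by the caller).
    """
    n = order // 2
    w = 2 * np.pi * np.asarray(freq_hz, dtype=float)
    wl, wh = 2 * np.pi * low, 2 * np.pi * high
    with np.errstate(divide="ignore"):
        x = (w ** 2 - wl * wh) / (w * (wh - wl))
    return 1.0 / np.sqrt(1.0 + x ** (2 * n))
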