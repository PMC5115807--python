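"""Photocurrent trace containers and feature extraction.

Whole-cell photocurrents of light-driven Na+ pumps show a stereotyped shape:
a fast rise to a peak current on light onset, partial inactivation to a
steady-state plateau, and decay back to baseline at light offset.  The two
summary amplitudes are expressed as current densities (pA/pF, i.e. divided
by the whole-cell capacitance so that cells of different size are
comparable): ``i_p`` the peak density, ``i_ss`` the steady-state density at
the end of the light pulse, and the inactivation ratio ``(i_p - i_ss)/i_p``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "PhotocurrentTrace",
    "TraceFeatures",
    "baseline_subtract",
    "extract_features",
]


@dataclass(frozen=True)
class PhotocurrentTrace:
    """A sampled whole-cell photocurrent recording.

    Parameters
    ----------
    time : ndarray
        Uniform, strictly increasing sample times in seconds.
    current : ndarray
        Membrane current in pA; outward pump current is positive.
    capacitance : float
        Whole-cell capacitance in pF (> 0), used to normalize to densities.
    light_on, light_off : float
        Illumination epoch in seconds, contained in the record.
    irradiance : float
        Light power density in mW/mm^2.
    wavelength_band : tuple
        Nominal illumination band in nm (center or (lo, hi)).
    holding_potential : float
        Command potential in mV.
    """

    time: np.ndarray
    current: np.ndarray
    capacitance: float
    light_on: float
    light_off: float
    irradiance: float = float("nan")
    wavelength_band: tuple = (534.0, 600.0)
    holding_potential: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if t.ndim != 1 or t.shape != i.shape:
            raise ValueError("time and current must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("trace must contain at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if not (t[0] <= self.light_on < self.light_off <= t[-1]):
            raise ValueError("light epoch must lie within the record")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "current", i)

    @property
    def sample_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class TraceFeatures:
    """Summary amplitudes of a photocurrent: densities in pA/pF."""

    i_p: float
    i_ss: float
    inactivation_ratio: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if np.isnan(self.inactivation_ratio):
            ratio = 0.0 if self.i_p == 0 else (self.i_p - self.i_ss) / self.i_p
            object.__setattr__(self, "inactivation_ratio", ratio)


def baseline_subtract(
    trace: PhotocurrentTrace, baseline_window: float = 0.05
) -> PhotocurrentTrace:
    """Subtract the mean pre-light current from the whole trace.

    The baseline is the mean over the ``baseline_window`` seconds immediately
    preceding light onset; metadata is preserved.
    """
    if baseline_window <= 0:
        raise ValueError("baseline_window must be positive")
    start = trace.light_on - baseline_window
    if start < trace.time[0] - 1e-12:
        raise ValueError("baseline window extends before the start of the record")
    mask = (trace.time >= start) & (trace.time < trace.light_on)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    offset = float(trace.current[mask].mean())
    return replace(trace, current=trace.current - offset)


def _lowpass(current: np.ndarray, sample_rate: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass; identity when already band-limited."""
    nyq = sample_rate / 2.0
    if cutoff_hz >= nyq or current.size < 15:
        return current
    sos = signal.butter(4, cutoff_hz / nyq, output="sos")
    return signal.sosfiltfilt(sos, current)


def extract_features(
    trace: PhotocurrentTrace,
    steady_window: float = 0.05,
    peak_filter_hz: float | None = 1000.0,
) -> TraceFeatures:
    """Extract peak and steady-state current densities from a light pulse.

    ``i_p`` is the maximum in-epoch current (on a low-pass filtered copy, to
    reject single-sample noise peaks) divided by capacitance.  ``i_ss`` is
    the mean current over the final ``steady_window`` seconds before light
    offset, divided by capacitance.  The inactivation ratio is
    ``(i_p - i_ss)/i_p`` (0 when ``i_p`` is 0).  The trace is expected to be
    baseline-subtracted (see :func:`baseline_subtract`).

    A slightly negative steady-state estimate (noise around zero) is clamped
    to 0 with a warning so that the ratio stays within [0, 1].
    """
    if trace.capacitance <= 0:
        raise ValueError("capacitance must be positive")
    epoch_len = trace.light_off - trace.light_on
    if steady_window <= 0 or steady_window > epoch_len:
        raise ValueError("steady_window must be positive and fit inside the light epoch")

    in_light = (trace.time >= trace.light_on) & (trace.time <= trace.light_off)
    if not in_light.any():
        raise ValueError("light epoch contains no samples")

    current = trace.current
    if peak_filter_hz is not None:
        current = _lowpass(current, trace.sample_rate, peak_filter_hz)

    i_p = float(current[in_light].max()) / trace.capacitance

    steady_mask = (trace.time >= trace.light_off - steady_window) & in_light
    i_ss = float(trace.current[steady_mask].mean()) / trace.capacitance
    if i_ss < 0:
        warnings.warn(
            "negative steady-state estimate clamped to 0 (noise around baseline)",
            stacklevel=2,
        )
        i_ss = 0.0
    # Noise can also push the terminal-window mean a hair above the filtered peak.
    i_ss = min(i_ss, i_p) if i_p > 0 else i_ss

    ratio = 0.0 if i_p == 0 else (i_p - i_ss) / i_p
    return TraceFeatures(i_p=i_p, i_ss=i_ss, inactivation_ratio=ratio)
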