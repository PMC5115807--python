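"""Optogenetic silencing analysis of current-clamp recordings.

A neuron expressing a light-driven Na+ pump fires repetitively under square
current injection; during illumination the pump hyperpolarizes the membrane
and suppresses firing, often followed by a transient rebound after light
offset.  The analysis chain is: detect spikes by threshold crossing, bin
them into 1-s time zones across repeated sweeps, compare matched 'Light' and
'Dark' protocols by the ratio of firing in the before/during/after windows,
and test zone-wise differences with exact rank tests (see
:mod:`nartools.stats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import RankTestResult, exact_rank_tests  # noqa: F401  (re-export)

__all__ = [
    "VoltageTrace",
    "SpikeRaster",
    "ZoneStats",
    "detect_spikes",
    "zone_rates",
    "light_dark_ratios",
    "exact_rank_tests",
    "DEFAULT_WINDOWS",
    "ALT_WINDOWS",
]

# Ratio windows in seconds: before / during / after irradiation. The
# alternative set treats light onset as falling in the 2-s zone instead.
DEFAULT_WINDOWS = {"before": (0.0, 1.0), "during": (1.0, 11.0), "after": (11.0, 12.0)}
ALT_WINDOWS = {"before": (0.0, 1.0), "during": (2.0, 11.0), "after": (11.0, 12.0)}


@dataclass(frozen=True)
class VoltageTrace:
    """One current-clamp sweep (membrane potential vs time)."""

    time: np.ndarray
    potential: np.ndarray  # mV, junction-potential corrected
    injection_epoch: tuple[float, float]
    light_epoch: tuple[float, float] | None = None
    sweep_id: str = ""
    neuron_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.potential, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("time and potential must be 1-D of equal length")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform and increasing")
        for epoch in (self.injection_epoch, self.light_epoch):
            if epoch is not None and not (t[0] <= epoch[0] < epoch[1] <= t[-1]):
                raise ValueError("epochs must lie within the record")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "potential", v)


@dataclass(frozen=True)
class SpikeRaster:
    """Spike times per sweep, sweep order preserved."""

    spike_times: list  # list of 1-D arrays, seconds

    def __post_init__(self) -> None:
        clean = []
        for times in self.spike_times:
            times = np.asarray(times, dtype=float)
            if times.size > 1 and np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing within a sweep")
            clean.append(times)
        object.__setattr__(self, "spike_times", clean)

    @property
    def n_sweeps(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class ZoneStats:
    """Per-sweep spike counts in uniform 1-s time zones."""

    zone_edges: np.ndarray  # length n_zones + 1
    counts: np.ndarray  # (n_sweeps, n_zones)
    protocol: str = ""  # "Dark" or "Light"
    n_outside: int = 0  # spikes falling outside the analysis window
    rate: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.zone_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        width = edges[1] - edges[0]
        object.__setattr__(self, "zone_edges", edges)
        object.__setattr__(self, "counts", counts)
        # mean count across sweeps per zone, in spikes/s
        object.__setattr__(self, "rate", counts.mean(axis=0) / width)


def detect_spikes(
    trace: VoltageTrace, threshold: float = -10.0, refractory: float = 0.002
) -> np.ndarray:
    """Times of upward threshold crossings separated by >= ``refractory``.

    The default -10 mV threshold sits well above synaptic noise and well
    below the action-potential overshoot, so crossing times are insensitive
    to its exact value.
    """
    v = trace.potential
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite samples in potential trace")
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = trace.time[crossings]
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def zone_rates(raster: SpikeRaster, zone_edges) -> ZoneStats:
    """Bin each sweep's spikes into uniform 1-s zones.

    Returns per-sweep per-zone counts; ``rate`` is the mean count across
    sweeps (spikes/s for 1-s zones).  Spikes outside the window are counted
    in no zone and reported via ``n_outside``.
    """
    edges = np.asarray(zone_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least one zone")
    widths = np.diff(edges)
    if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
        raise ValueError("zone edges must be uniform and increasing")
    counts = np.zeros((raster.n_sweeps, edges.size - 1))
    n_outside = 0
    for i, times in enumerate(raster.spike_times):
        counts[i], _ = np.histogram(times, bins=edges)
        n_outside += int(((times < edges[0]) | (times >= edges[-1])).sum())
    return ZoneStats(zone_edges=edges, counts=counts, n_outside=n_outside)


def light_dark_ratios(
    light: ZoneStats, dark: ZoneStats, windows: dict[str, tuple[float, float]] | None = None
) -> dict[str, float]:
    """Light/Dark firing ratios over named time windows.

    ``ratio = (summed Light-protocol spikes in window) / (summed Dark-protocol
    spikes in window)``; NaN (flagged) when the dark denominator is zero.
    Default windows: before 0-1 s, during 1-11 s, after 11-12 s.
    """
    if windows is None:
        windows = DEFAULT_WINDOWS
    if light.zone_edges.shape != dark.zone_edges.shape or not np.allclose(
        light.zone_edges, dark.zone_edges
    ):
        raise ValueError("Light and Dark protocols must share the zone grid")
    edges = light.zone_edges
    ratios: dict[str, float] = {}
    for name, (lo, hi) in windows.items():
        mask = (edges[:-1] >= lo - 1e-9) & (edges[1:] <= hi + 1e-9)
        if not mask.any():
            raise ValueError(f"window {name!r} covers no zones")
        num = float(light.counts[:, mask].sum())
        den = float(dark.counts[:, mask].sum())
        ratios[name] = num / den if den > 0 else float("nan")
    return ratios
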