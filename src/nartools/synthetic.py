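"""Seedable generators for every input the analysis pipeline consumes.

Each generator emulates one class of raw data from a Na+-pump rhodopsin
characterization study: whole-cell photocurrent traces, irradiance-response
point sets, normalized current-voltage series, two-channel confocal soma
images, current-clamp silencing sweeps, E. coli suspension pH traces, and
parent apoprotein sequences for chimera construction.  All generators are
pure functions of their parameters and seed: identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chimera import IANAR_BOUNDARIES, KR2_BOUNDARIES
from .dose_response import DoseResponse, michaelis_menten, suppressed_michaelis_menten
from .silencing import SpikeRaster, VoltageTrace
from .targeting import TwoChannelImage
from .traces import PhotocurrentTrace
from .transport import CONDITIONS, PhTrace
from .voltage_spectrum import IVSeries

__all__ = [
    "TraceGenParams",
    "ImageGenParams",
    "SilencingGenParams",
    "gen_photocurrent_trace",
    "gen_dose_response",
    "gen_iv_series",
    "gen_soma_image",
    "gen_silencing_experiment",
    "gen_ph_trace",
    "gen_parent_sequences",
]


# ---------------------------------------------------------------------------
# photocurrent traces


@dataclass(frozen=True)
class TraceGenParams:
    """Generating parameters for a pump photocurrent trace.

    ``peak_amplitude`` and the steady level ``steady_fraction *
    peak_amplitude`` are current densities in pA/pF (outward positive).
    Default kinetics (tau_act 5 ms, tau_inact 100 ms, tau_deact 10 ms at
    10 kHz sampling) reproduce the stereotyped fast-rise / partial-
    inactivation / fast-deactivation shape of pump photocurrents.
    """

    peak_amplitude: float = 4.26  # pA/pF
    steady_fraction: float = 0.225
    tau_act: float = 0.005  # s
    tau_inact: float = 0.100  # s
    tau_deact: float = 0.010  # s
    capacitance: float = 20.0  # pF
    light_on: float = 0.2  # s
    light_off: float = 1.2  # s (1-s pulse)
    duration: float = 1.5  # s
    sample_rate: float = 10_000.0  # Hz
    irradiance: float = 99.0  # mW/mm^2
    noise_sd: float = 0.0  # pA/pF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0 or not 0 <= self.steady_fraction <= 1:
            raise ValueError("peak_amplitude >= 0 and steady_fraction in [0,1] required")
        if min(self.tau_act, self.tau_inact, self.tau_deact) <= 0:
            raise ValueError("time constants must be positive")
        if self.sample_rate <= 0 or self.capacitance <= 0:
            raise ValueError("sample_rate and capacitance must be positive")
        if not 0 <= self.light_on < self.light_off <= self.duration:
            raise ValueError("need 0 <= light_on < light_off <= duration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_photocurrent_trace(params: TraceGenParams) -> PhotocurrentTrace:
    """Generate a noisy outward pump photocurrent.

    During light: saturating rise with ``tau_act`` to the peak density, then
    exponential relaxation with ``tau_inact`` toward the steady level
    (inactivation is gated to start once activation is complete, so the
    attained peak matches ``peak_amplitude`` up to the residual activation
    shortfall of < 0.1%).  After light: exponential deactivation with
    ``tau_deact``.  Gaussian noise of sd ``noise_sd`` (pA/pF) is added and
    the trace is stored in pA (density times capacitance).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.sample_rate)) + 1
    time = np.arange(n) / p.sample_rate
    density = np.zeros(n)

    steady = p.steady_fraction * p.peak_amplitude
    in_light = (time >= p.light_on) & (time <= p.light_off)
    t_rel = time[in_light] - p.light_on
    rise = 1.0 - np.exp(-t_rel / p.tau_act)
    inact_start = 7.0 * p.tau_act  # activation ~complete; peak attained here
    decay = np.exp(-np.clip(t_rel - inact_start, 0.0, None) / p.tau_inact)
    density[in_light] = (steady + (p.peak_amplitude - steady) * decay) * rise

    after = time > p.light_off
    level_at_off = density[in_light][-1] if in_light.any() else 0.0
    density[after] = level_at_off * np.exp(-(time[after] - p.light_off) / p.tau_deact)

    if p.noise_sd > 0:
        density = density + rng.normal(0.0, p.noise_sd, size=n)

    return PhotocurrentTrace(
        time=time,
        current=density * p.capacitance,
        capacitance=p.capacitance,
        light_on=p.light_on,
        light_off=p.light_off,
        irradiance=p.irradiance,
    )


# ---------------------------------------------------------------------------
# dose-response sets

#: Irradiance grid (mW/mm^2) used in the characterization protocol, up to the
#: maximal deliverable power density of 99 mW/mm^2.
DEFAULT_IRRADIANCES = (1.0, 3.0, 6.0, 12.0, 25.0, 50.0, 99.0)


def gen_dose_response(
    imax: float,
    kd: float,
    irradiances=DEFAULT_IRRADIANCES,
    noise_cv: float = 0.0,
    suppression: tuple[float, float, float] | None = None,
    n_cells: int = 1,
    seed: int = 0,
) -> list[DoseResponse]:
    """Per-cell irradiance-response points from a saturating hyperbola.

    ``response(x) = imax*x/(x+kd)`` minus, when ``suppression=(amp,
    threshold, kd2)`` is given, ``amp*(x-threshold)/((x-threshold)+kd2)`` for
    ``x > threshold``.  Noise is multiplicative Gaussian with coefficient of
    variation ``noise_cv``.
    """
    x = np.asarray(irradiances, dtype=float)
    if x.size == 0:
        raise ValueError("irradiance list must not be empty")
    if np.any(x <= 0) or kd <= 0:
        raise ValueError("irradiances and kd must be positive")
    if suppression is None:
        y_true = michaelis_menten(x, imax, kd)
    else:
        amp, threshold, kd2 = suppression
        y_true = suppressed_michaelis_menten(x, imax, kd, amp, kd2, threshold=threshold)
    rng = np.random.default_rng(seed)
    cells = []
    for c in range(n_cells):
        y = y_true * (1.0 + noise_cv * rng.standard_normal(x.size)) if noise_cv > 0 else y_true.copy()
        cells.append(DoseResponse(irradiance=x, response=y, cell_id=f"cell{c:03d}"))
    return cells


# ---------------------------------------------------------------------------
# current-voltage series

DEFAULT_VOLTAGES = (-80.0, -60.0, -40.0, -20.0, 0.0)


def gen_iv_series(
    slope_neg: float,
    voltages=DEFAULT_VOLTAGES,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IVSeries:
    """Normalized I-V points ``1 + slope_neg * V`` plus Gaussian noise.

    ``slope_neg`` is in 1/mV (e.g. 7.33e-3 for a slope reported as 7.33 in
    10^-3 mV^-1 units).  The value at 0 mV is fixed at 1 before noise; the
    returned series is unnormalized when noise is present (re-normalize with
    :func:`nartools.voltage_spectrum.normalize_iv` before slope estimation).
    """
    v = np.asarray(voltages, dtype=float)
    if not np.any(v == 0.0):
        raise ValueError("voltage grid must include 0 mV")
    current = 1.0 + slope_neg * v
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, size=v.size)
        return IVSeries(voltage=v, current=current, normalized=False)
    return IVSeries(voltage=v, current=current, normalized=True)


# ---------------------------------------------------------------------------
# confocal soma images


@dataclass(frozen=True)
class ImageGenParams:
    """Generating parameters for a two-channel soma image.

    The marker (WGA role) channel is a membrane ring of radius
    ``membrane_radius`` with a Gaussian radial cross-section of FWHM
    ``membrane_width``.  The reporter (eYFP role) channel is either the
    co-localized ring (``membrane`` mode), interior aggregates
    (``intracellular`` mode), or a ``mix_fraction``-weighted blend
    (``mixed``).  The default 0.133 um pixel pitch makes a 3-pixel lag span
    ~0.4 um.
    """

    image_size: int = 96  # pixels (square)
    pixel_pitch: float = 0.133  # um/pixel
    membrane_radius: float = 5.0  # um
    membrane_width: float = 0.8  # um FWHM
    targeting_mode: str = "membrane"  # membrane | intracellular | mixed
    channel_gains: tuple[float, float] = (1.0, 1.0)  # (reporter, marker)
    mix_fraction: float = 0.5  # membrane share in mixed mode
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.targeting_mode not in ("membrane", "intracellular", "mixed"):
            raise ValueError("targeting_mode must be membrane, intracellular or mixed")
        if self.pixel_pitch <= 0 or self.membrane_radius <= 0 or self.membrane_width <= 0:
            raise ValueError("geometry parameters must be positive")
        sigma = self.membrane_width / 2.355
        extent_px = (self.membrane_radius + 3.0 * sigma) / self.pixel_pitch
        if extent_px >= self.image_size / 2.0:
            raise ValueError("membrane ring (with its skirt) exceeds the frame")
        if any(g < 0 for g in self.channel_gains) or self.noise_sd < 0:
            raise ValueError("gains and noise_sd must be non-negative")


def gen_soma_image(params: ImageGenParams) -> TwoChannelImage:
    """Generate a two-channel soma image with a known targeting phenotype."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.image_size
    center = (n - 1) / 2.0
    rows, cols = np.indices((n, n))
    dist_um = np.hypot(rows - center, cols - center) * p.pixel_pitch
    sigma = p.membrane_width / 2.355

    ring = np.exp(-((dist_um - p.membrane_radius) ** 2) / (2.0 * sigma**2))

    def interior_blobs() -> np.ndarray:
        # one central aggregate (guarantees signal on both centroid axes)
        # plus two random ones well inside the membrane
        blobs = np.exp(-(dist_um**2) / (2.0 * (1.5 * sigma * 2) ** 2))
        for _ in range(2):
            r = rng.uniform(0.0, 0.5 * p.membrane_radius)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            br = center + (r / p.pixel_pitch) * np.sin(theta)
            bc = center + (r / p.pixel_pitch) * np.cos(theta)
            d2 = (rows - br) ** 2 + (cols - bc) ** 2
            blobs = blobs + np.exp(-d2 * p.pixel_pitch**2 / (2.0 * (2.0 * sigma) ** 2))
        return blobs / blobs.max()

    if p.targeting_mode == "membrane":
        reporter = ring.copy()
    elif p.targeting_mode == "intracellular":
        reporter = interior_blobs()
    else:
        reporter = p.mix_fraction * ring + (1.0 - p.mix_fraction) * interior_blobs()

    g_rep, g_mark = p.channel_gains
    reporter = g_rep * reporter
    marker = g_mark * ring
    if p.noise_sd > 0:
        reporter = reporter + rng.normal(0.0, p.noise_sd, size=reporter.shape)
        marker = marker + rng.normal(0.0, p.noise_sd, size=marker.shape)
    reporter = np.clip(reporter, 0.0, None)
    marker = np.clip(marker, 0.0, None)

    return TwoChannelImage(
        reporter=reporter, marker=marker, pixel_pitch=p.pixel_pitch,
        centroid=(center, center),
    )


# ---------------------------------------------------------------------------
# current-clamp silencing experiments


@dataclass(frozen=True)
class SilencingGenParams:
    """Generating parameters for a repeated-sweep silencing experiment.

    Spikes are drawn as an inhomogeneous Poisson process confined to the
    current-injection epoch: ``baseline_rate`` ordinarily, ``silenced_rate``
    during the light epoch, ``rebound_rate`` for 1 s after light offset.
    Each spike is rendered as a stereotyped 2-ms triangular waveform of
    +80 mV on a membrane-potential baseline that is depolarized during
    injection and hyperpolarized by ``hyperpolarization`` during light.
    Defaults follow a 10-s illumination inside a 12-s injection.
    """

    sweep_count: int = 10
    duration: float = 13.0  # s
    injection_epoch: tuple[float, float] = (0.0, 12.0)
    light_epoch: tuple[float, float] | None = (1.0, 11.0)
    baseline_rate: float = 10.0  # spikes/s
    silenced_rate: float = 0.5
    rebound_rate: float = 20.0
    rebound_duration: float = 1.0  # s
    rmp: float = -65.0  # mV
    injection_depolarization: float = 10.0  # mV
    hyperpolarization: float = 15.0  # mV during light
    sample_rate: float = 5_000.0  # Hz
    noise_sd: float = 0.5  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweep_count < 1:
            raise ValueError("sweep_count must be >= 1")
        if min(self.baseline_rate, self.silenced_rate, self.rebound_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not all(np.isfinite([self.baseline_rate, self.silenced_rate, self.rebound_rate])):
            raise ValueError("rates must be finite")
        lo, hi = self.injection_epoch
        if not 0 <= lo < hi <= self.duration:
            raise ValueError("injection epoch must lie within the sweep")
        if self.light_epoch is not None:
            lo, hi = self.light_epoch
            if not 0 <= lo < hi <= self.duration:
                raise ValueError("light epoch must lie within the sweep")


SPIKE_HALF_WIDTH = 0.001  # s; 2-ms triangular event
SPIKE_HEIGHT = 80.0  # mV above local baseline
MIN_ISI = 0.005  # s; enforced separation between generated spikes


def _rate_segments(p: SilencingGenParams) -> list[tuple[float, float, float]]:
    """(start, stop, rate) pieces of the firing-rate profile."""
    inj_lo, inj_hi = p.injection_epoch
    if p.light_epoch is None:
        return [(inj_lo, inj_hi, p.baseline_rate)]
    lt_lo, lt_hi = p.light_epoch
    reb_hi = min(lt_hi + p.rebound_duration, inj_hi)
    segs = [
        (inj_lo, lt_lo, p.baseline_rate),
        (lt_lo, lt_hi, p.silenced_rate),
        (lt_hi, reb_hi, p.rebound_rate),
        (reb_hi, inj_hi, p.baseline_rate),
    ]
    return [(a, b, r) for a, b, r in segs if b > a]


def gen_silencing_experiment(
    params: SilencingGenParams,
) -> tuple[list[VoltageTrace], SpikeRaster]:
    """Generate current-clamp sweeps plus the ground-truth spike raster."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.sample_rate)) + 1
    time = np.arange(n) / p.sample_rate

    inj_mask = (time >= p.injection_epoch[0]) & (time < p.injection_epoch[1])
    light_mask = (
        (time >= p.light_epoch[0]) & (time < p.light_epoch[1])
        if p.light_epoch is not None
        else np.zeros(n, dtype=bool)
    )

    traces: list[VoltageTrace] = []
    raster: list[np.ndarray] = []
    for sweep in range(p.sweep_count):
        spikes: list[float] = []
        for a, b, rate in _rate_segments(p):
            count = rng.poisson(rate * (b - a))
            spikes.extend(rng.uniform(a, b, size=count))
        spikes = np.sort(np.asarray(spikes))
        kept: list[float] = []
        for t in spikes:
            if not kept or t - kept[-1] >= MIN_ISI:
                kept.append(float(t))
        spike_times = np.asarray(kept)

        v = np.full(n, p.rmp)
        v[inj_mask] += p.injection_depolarization
        v[light_mask] -= p.hyperpolarization
        for t0 in spike_times:
            # triangular waveform: linear rise over 1 ms, linear fall over 1 ms
            lo = max(int((t0 - SPIKE_HALF_WIDTH) * p.sample_rate), 0)
            hi = min(int((t0 + SPIKE_HALF_WIDTH) * p.sample_rate) + 1, n)
            seg_t = time[lo:hi]
            shape = np.clip(1.0 - np.abs(seg_t - t0) / SPIKE_HALF_WIDTH, 0.0, None)
            v[lo:hi] += SPIKE_HEIGHT * shape
        if p.noise_sd > 0:
            v = v + rng.normal(0.0, p.noise_sd, size=n)

        traces.append(
            VoltageTrace(
                time=time, potential=v,
                injection_epoch=p.injection_epoch, light_epoch=p.light_epoch,
                sweep_id=f"sweep{sweep:02d}",
            )
        )
        raster.append(spike_times)

    return traces, SpikeRaster(spike_times=raster)


# ---------------------------------------------------------------------------
# pH assay traces

# illumination-epoch drifts in pH/min: (no-CCCP slope, CCCP multiplier)
_PH_SLOPES = {
    "NaCl": (0.040, 2.0),  # alkalinization, enhanced by uncoupler
    "Na2SO4": (0.040, 2.0),  # anion-independent
    "KCl": (-0.030, 0.2),  # acidification, diminished by uncoupler
}


def gen_ph_trace(
    condition: str,
    cccp: bool = False,
    seed: int = 0,
    duration: float = 300.0,
    light_epoch: tuple[float, float] = (60.0, 240.0),
    sample_rate: float = 1.0,
    noise_sd: float = 0.002,
    start_ph: float = 7.0,
) -> PhTrace:
    """Monotone suspension-pH drift during illumination, plus noise.

    Upward drift for NaCl/Na2SO4 (steeper with CCCP), downward for KCl
    (flattened toward zero with CCCP); flat before light, value held after.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    slope_per_min, cccp_mult = _PH_SLOPES[condition]
    slope = slope_per_min * (cccp_mult if cccp else 1.0) / 60.0  # pH/s

    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate)) + 1
    time = np.arange(n) / sample_rate
    lo, hi = light_epoch
    drift = slope * np.clip(time - lo, 0.0, hi - lo)
    ph = start_ph + drift
    if noise_sd > 0:
        ph = ph + rng.normal(0.0, noise_sd, size=n)
    return PhTrace(time=time, ph=ph, light_epoch=light_epoch, condition=condition, cccp=cccp)


# ---------------------------------------------------------------------------
# parent sequences for chimera construction

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def gen_parent_sequences(seed: int = 0) -> tuple[SeqRecord, SeqRecord]:
    """Synthetic stand-ins for the two parent apoprotein sequences.

    Returns a 279-residue IaNaR-like record and a 280-residue KR2-like
    record whose TMD3 segments are identical (so the junction-2 and
    junction-3 chimeras coincide, as for the real parents).  Residues are
    otherwise random; these are synthetic sequences for pipeline testing,
    not the deposited accessions.
    """
    rng = np.random.default_rng(seed)
    kr2 = rng.choice(_AA, size=280)
    kr2[0], ia_start = "M", "M"
    ia = rng.choice(_AA, size=279)
    ia[0] = ia_start
    # share TMD3 exactly: IaNaR 101..127 (1-based) == KR2 102..128
    k_lo = KR2_BOUNDARIES.resumption_start(2) - 1  # 0-based 101
    k_hi = KR2_BOUNDARIES.resumption_start(3) - 1  # 0-based 128 (exclusive)
    i_lo = IANAR_BOUNDARIES.resumption_start(2) - 1  # 0-based 100
    ia[i_lo : i_lo + (k_hi - k_lo)] = kr2[k_lo:k_hi]
    ia_rec = SeqRecord(Seq("".join(ia)), id="IaNaR_synthetic",
                       description="synthetic 279-aa IaNaR-like parent")
    kr2_rec = SeqRecord(Seq("".join(kr2)), id="KR2_synthetic",
                        description="synthetic 280-aa KR2-like parent")
    return ia_rec, kr2_rec
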