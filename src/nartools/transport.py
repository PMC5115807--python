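"""Ion-transport classification from E. coli suspension pH assays.

An outward cation pump expressed in E. coli hyperpolarizes the cell on
illumination; the suspension pH then rises through secondary H+ uptake into
the cells.  The protonophore CCCP dissipates the membrane potential and
amplifies this secondary flux.  A primary outward H+ pump instead acidifies
the suspension, and CCCP short-circuits (diminishes) that primary signal.
The condition panel therefore separates the two mechanisms:

* NaCl / Na2SO4 (Na+ available): pH rises, enhanced by CCCP  -> the pump
  moves a cation other than H+ (Na+); anion identity is irrelevant.
* KCl (no Na+): pH falls, diminished by CCCP -> the pump falls back to
  pumping H+ when only larger cations are present.

The residual physiological relevance of the H+ mode is bounded by the flux
ratio: intracellular Na+ activity exceeds H+ activity by a large factor, so
even a much larger H+ rate constant yields a small fractional H+ flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PhTrace",
    "TransportCall",
    "FluxRatioBound",
    "ph_slope",
    "classify_transport",
    "flux_ratio_bound",
]

CONDITIONS = ("NaCl", "Na2SO4", "KCl")


@dataclass(frozen=True)
class PhTrace:
    """A suspension pH recording with an illumination epoch."""

    time: np.ndarray  # s
    ph: np.ndarray
    light_epoch: tuple[float, float]
    condition: str
    cccp: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.ph, dtype=float)
        if t.ndim != 1 or t.shape != p.shape:
            raise ValueError("time and ph must be 1-D of equal length")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        lo, hi = self.light_epoch
        if not (t[0] <= lo < hi <= t[-1]):
            raise ValueError("light epoch must lie within the record")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "ph", p)


@dataclass(frozen=True)
class SlopeCall:
    slope: float  # pH/min, baseline-corrected
    sign: int  # -1, 0, +1 after dead-band


@dataclass(frozen=True)
class TransportCall:
    signs: dict  # (condition, cccp) -> sign
    verdict: str  # sodium_pump | proton_pump | inconclusive
    rationale: str


@dataclass(frozen=True)
class FluxRatioBound:
    activity_ratio: float
    rate_constant_ratio_range: tuple[float, float]
    bound_range_percent: tuple[float, float]


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(sps.linregress(t, y).slope)


def ph_slope(trace: PhTrace, dead_band: float = 0.005, min_samples: int = 30) -> SlopeCall:
    """Baseline-corrected pH slope over the illumination epoch, in pH/min.

    The slope is estimated by least squares over the central 80% of the
    illumination epoch (avoiding onset/offset transients) and corrected by
    subtracting the pre-light baseline slope.  The sign call uses a dead-band
    (default 0.005 pH/min) below which the slope is reported as zero.
    """
    lo, hi = trace.light_epoch
    span = hi - lo
    core_lo, core_hi = lo + 0.1 * span, hi - 0.1 * span
    core = (trace.time >= core_lo) & (trace.time <= core_hi)
    if core.sum() < min_samples:
        raise ValueError("too few samples in the illumination epoch")
    slope = _ols_slope(trace.time[core], trace.ph[core]) * 60.0

    pre = trace.time < lo
    if pre.sum() >= 3:
        slope -= _ols_slope(trace.time[pre], trace.ph[pre]) * 60.0

    sign = 0 if abs(slope) <= dead_band else (1 if slope > 0 else -1)
    return SlopeCall(slope=slope, sign=sign)


def _cccp_enhances(base: float, with_cccp: float, rel_change: float = 0.25) -> bool:
    """Same-sign slope grew by >= 25% under CCCP."""
    if base == 0:
        return False
    return np.sign(with_cccp) == np.sign(base) and (
        abs(with_cccp) >= (1 + rel_change) * abs(base)
    )


def _cccp_diminishes(base: float, with_cccp: float, rel_change: float = 0.25) -> bool:
    """Slope shrank toward zero by >= 25% (or flipped past it) under CCCP."""
    if base == 0:
        return False
    return abs(with_cccp) <= (1 - rel_change) * abs(base) or (
        np.sign(with_cccp) != np.sign(base)
    )


def classify_transport(slopes: dict) -> TransportCall:
    """Classify pump selectivity from per-condition pH slopes.

    ``slopes`` maps ``(condition, cccp_flag)`` to :class:`SlopeCall` (or a
    bare slope in pH/min).  NaCl and KCl, each with and without CCCP, are
    required; Na2SO4 (no CCCP needed) optionally confirms anion independence.

    Verdict ``sodium_pump``: suspension alkalinizes in NaCl (secondary H+
    uptake, enhanced by CCCP) and acidifies in KCl (primary H+ pumping,
    diminished by CCCP).  ``proton_pump``: acidification in NaCl that CCCP
    diminishes.  Anything else: ``inconclusive``.
    """
    def get(cond: str, cccp: bool) -> float:
        key = (cond, cccp)
        if key not in slopes:
            raise ValueError(f"missing required condition {key}")
        val = slopes[key]
        return val.slope if isinstance(val, SlopeCall) else float(val)

    nacl, nacl_c = get("NaCl", False), get("NaCl", True)
    kcl, kcl_c = get("KCl", False), get("KCl", True)
    signs = {k: int(np.sign(v.slope if isinstance(v, SlopeCall) else v)) for k, v in slopes.items()}

    anion_note = ""
    if ("Na2SO4", False) in slopes:
        na2so4 = slopes[("Na2SO4", False)]
        na2so4 = na2so4.slope if isinstance(na2so4, SlopeCall) else float(na2so4)
        if np.sign(na2so4) == np.sign(nacl):
            anion_note = " Na2SO4 matches NaCl: anion-independent."
        else:
            anion_note = " Na2SO4 disagrees with NaCl: anion dependence unexplained."

    if nacl > 0 and _cccp_enhances(nacl, nacl_c) and kcl < 0 and _cccp_diminishes(kcl, kcl_c):
        return TransportCall(
            signs=signs, verdict="sodium_pump",
            rationale=(
                "Alkalinization with Na+ present (CCCP-enhanced secondary H+ uptake) "
                "and acidification without Na+ (CCCP-diminished primary H+ pumping)."
                + anion_note
            ),
        )
    if nacl < 0 and _cccp_diminishes(nacl, nacl_c):
        return TransportCall(
            signs=signs, verdict="proton_pump",
            rationale=(
                "Acidification with Na+ present, diminished by CCCP: primary outward "
                "H+ pumping regardless of cation." + anion_note
            ),
        )
    return TransportCall(
        signs=signs, verdict="inconclusive",
        rationale="Slope pattern matches neither pump signature." + anion_note,
    )


def flux_ratio_bound(
    activity_ratio: float, rate_constant_ratio_range: tuple[float, float]
) -> FluxRatioBound:
    """Upper bound on the H+/Na+ flux fraction, as a percent interval.

    With intracellular Na+ activity exceeding H+ activity by
    ``activity_ratio`` and the H+ uptake rate constant exceeding the Na+ one
    by a factor in ``rate_constant_ratio_range``, the H+ flux fraction is at
    most ``rate_constant_ratio / activity_ratio`` (elementwise on the range).
    """
    lo, hi = rate_constant_ratio_range
    if activity_ratio <= 0 or lo <= 0 or hi <= 0:
        raise ValueError("activity and rate-constant ratios must be positive")
    if lo > hi:
        lo, hi = hi, lo
    return FluxRatioBound(
        activity_ratio=activity_ratio,
        rate_constant_ratio_range=(lo, hi),
        bound_range_percent=(100.0 * lo / activity_ratio, 100.0 * hi / activity_ratio),
    )
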