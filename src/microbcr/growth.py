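"""Diauxic batch-growth kinetics: phase segmentation, rates and yields.

A Crabtree-positive yeast batch on glucose grows in two phases: a fast
glucose phase during which ethanol accumulates, then — after glucose is
exhausted, visible as a sharp drop in off-gas CO₂ — a slower phase on the
accumulated ethanol.  This module segments a multi-channel cultivation
record into those phases, fits the specific growth rate µ of each by
log-linear regression of biomass versus time, and computes yield
coefficients Y_X/S = ΔBDW/ΔS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

from microbcr.errors import InsufficientDataError

__all__ = [
    "CultivationRecord",
    "GrowthPhaseResult",
    "PhaseFit",
    "specific_growth_rate",
    "detect_diauxic_shift",
    "yield_coefficient",
    "summarize_cultivation",
]


@dataclass
class CultivationRecord:
    """Multi-channel cultivation time series.

    Channels may be absent (``None``) or contain NaN for missing samples.
    ``bdw`` is the biomass concentration (bio dry weight, g L⁻¹); off-gas
    channels are % (v/v).
    """

    timestamps_h: np.ndarray
    bdw: np.ndarray
    ph: np.ndarray | None = None
    dot: np.ndarray | None = None
    co2_offgas: np.ndarray | None = None
    o2_offgas: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        self.bdw = np.asarray(self.bdw, dtype=float)
        if len(self.timestamps_h) != len(self.bdw):
            raise ValueError("timestamps and bdw must have equal length")
        if len(self.timestamps_h) > 1 and not np.all(np.diff(self.timestamps_h) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for name in ("ph", "dot", "co2_offgas", "o2_offgas"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if len(ch) != len(self.timestamps_h):
                    raise ValueError(f"channel {name} length mismatch")
                setattr(self, name, ch)


@dataclass(frozen=True)
class PhaseFit:
    """One growth phase: window and fitted specific growth rate."""

    t_start_h: float
    t_end_h: float
    mu_per_h: float
    mu_stderr: float


@dataclass(frozen=True)
class GrowthPhaseResult:
    """Assembled diauxic-batch summary."""

    lag_end_h: float
    phase1: PhaseFit | None
    phase2: PhaseFit | None
    glucose_depletion_time_h: float | None
    y1: float | None          # g_BDW (produced) per g glucose
    y_total: float | None     # max BDW per g glucose
    x_max: float


def specific_growth_rate(
    record: CultivationRecord, window: tuple[float, float]
) -> tuple[float, float]:
    """Specific growth rate µ (h⁻¹) over a time window, with standard error.

    Least-squares slope of ln(BDW) versus time.  Non-positive biomass
    samples inside the window are excluded with a warning; fewer than three
    usable samples is an error.
    """
    t_lo, t_hi = window
    t = record.timestamps_h
    x = record.bdw
    sel = (t >= t_lo) & (t <= t_hi) & np.isfinite(x)
    n_nonpos = int(np.sum(sel & (x <= 0)))
    if n_nonpos:
        warnings.warn(
            f"{n_nonpos} non-positive BDW samples excluded from rate fit",
            stacklevel=2,
        )
    sel &= x > 0
    if sel.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 positive BDW samples in window {window}, got {int(sel.sum())}"
        )
    fit = stats.linregress(t[sel], np.log(x[sel]))
    return float(fit.slope), float(fit.stderr)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window clipped at ends)."""
    if width <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def detect_diauxic_shift(
    record: CultivationRecord,
    smooth_window: int = 5,
    min_drop_fraction: float = 0.2,
) -> float | None:
    """Glucose-depletion time from the off-gas CO₂ drop, or None.

    The end of fermentative (glucose) metabolism shows as a sharp fall in
    off-gas CO₂.  The channel is smoothed with a centered moving average and
    the time of the steepest negative derivative after the CO₂ peak is
    returned.  A trace whose post-peak drop is smaller than
    ``min_drop_fraction`` of its dynamic range (e.g. a monotone or
    single-phase trace) yields ``None`` (no shift detected).  The result is
    invariant to affine rescaling of the CO₂ channel.
    """
    if record.co2_offgas is None:
        raise ValueError("co2_offgas channel required for shift detection")
    co2 = _moving_average(record.co2_offgas, smooth_window)
    t = record.timestamps_h
    rng_span = co2.max() - co2.min()
    if rng_span <= 0:
        return None
    i_peak = int(np.argmax(co2))
    post = co2[i_peak:]
    if post.size < 3 or (post.max() - post.min()) < min_drop_fraction * rng_span:
        return None
    deriv = np.gradient(co2, t)
    deriv[:i_peak] = 0.0  # only the fall after the fermentation peak counts
    i_shift = int(np.argmin(deriv))
    if deriv[i_shift] >= 0:
        return None
    return float(t[i_shift])


def yield_coefficient(
    delta_bdw: float, delta_substrate: float, ndigits: int | None = None
) -> float:
    """Biomass-per-substrate yield Y_X/S = ΔBDW / ΔS (g g⁻¹).

    ``ndigits`` applies half-away-from-zero reporting rounding
    (e.g. 12.1/20 = 0.605 → 0.61 at two decimals).
    """
    if delta_substrate <= 0:
        raise ValueError("substrate consumption must be > 0")
    y = delta_bdw / delta_substrate
    if ndigits is None:
        return y
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(y)).quantize(q, rounding=ROUND_HALF_UP))


def _detect_lag_end(record: CultivationRecord, rel_rise: float = 0.05) -> float:
    """First time biomass has risen ``rel_rise`` above its initial level."""
    x0 = record.bdw[0]
    above = np.flatnonzero(record.bdw > x0 * (1 + rel_rise))
    if above.size == 0:
        return float(record.timestamps_h[0])
    i = max(int(above[0]) - 1, 0)
    return float(record.timestamps_h[i])


def summarize_cultivation(
    record: CultivationRecord,
    s0: float,
    trim_fraction: float = 0.10,
    smooth_window: int = 5,
    phase1_window: tuple[float, float] | None = None,
    phase2_window: tuple[float, float] | None = None,
) -> GrowthPhaseResult:
    """Full diauxic-batch summary: phases, rates and yields against ``s0``.

    Chains CO₂-based shift detection, per-phase log-linear rate fits (phase
    windows trimmed by ``trim_fraction`` of their duration at each end to
    avoid transition bias) and yield coefficients: the glucose-phase yield
    uses the biomass *produced* up to depletion, the total yield the maximum
    biomass reached — both over the initial glucose ``s0``.  Manual phase
    windows override the detected ones.  A record with no detectable shift
    (or truncated before it) reports phase 2 as absent.
    """
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    t = record.timestamps_h
    x = record.bdw
    x0 = float(x[0])
    x_max = float(np.nanmax(x))
    lag_end = _detect_lag_end(record)

    t_shift = (
        detect_diauxic_shift(record, smooth_window=smooth_window)
        if record.co2_offgas is not None
        else None
    )

    def _trim(lo: float, hi: float) -> tuple[float, float]:
        margin = trim_fraction * (hi - lo)
        return lo + margin, hi - margin

    phase1 = None
    y1 = None
    if phase1_window is None:
        hi = t_shift if t_shift is not None else float(t[-1])
        phase1_window = _trim(lag_end, hi)
    try:
        mu1, se1 = specific_growth_rate(record, phase1_window)
        phase1 = PhaseFit(phase1_window[0], phase1_window[1], mu1, se1)
    except InsufficientDataError:
        pass

    if t_shift is not None:
        x_dep = float(np.interp(t_shift, t, x))
        y1 = yield_coefficient(x_dep - x0, s0)

    phase2 = None
    if t_shift is not None:
        if phase2_window is None:
            # stationary begins where biomass saturates near its maximum
            after = t > t_shift
            sat = np.flatnonzero(after & (x >= 0.99 * x_max))
            t_stat = float(t[sat[0]]) if sat.size else float(t[-1])
            phase2_window = _trim(t_shift, t_stat)
        try:
            mu2, se2 = specific_growth_rate(record, phase2_window)
            phase2 = PhaseFit(phase2_window[0], phase2_window[1], mu2, se2)
        except InsufficientDataError:
            pass

    y_total = yield_coefficient(x_max, s0) if t_shift is not None else None
    return GrowthPhaseResult(
        lag_end_h=lag_end,
        phase1=phase1,
        phase2=phase2,
        glucose_depletion_time_h=t_shift,
        y1=y1,
        y_total=y_total,
        x_max=x_max,
    )
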