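"""Dynamic gassing-out estimation of the volumetric oxygen transfer
coefficient kLa.

The liquid is deoxygenated with nitrogen, the gas is switched to air at
t = 0, and the dissolved oxygen tension (DOT) relaxes as

    c(t) = c* − (c* − c0) · exp(−kLa·t).

Rearranged, ln((c* − c0)/(c* − c(t))) is linear in t with slope kLa, so the
estimator is an ordinary least-squares fit of that log-deficit against time
(free intercept, slope reported) over the early part of the rise — by
default samples up to 40 % of saturation, where the signal is far from the
sensor's saturation plateau.  Estimates are reported in h⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from microbcr.errors import InsufficientDataError

__all__ = [
    "DOTSeries",
    "KLaEstimate",
    "estimate_kla",
    "two_point_oxygen_calibration",
]


@dataclass
class DOTSeries:
    """Dissolved oxygen tension trace, % air saturation.

    ``c_star`` (saturation) and ``c0`` (level at the gas switch) may be left
    unset; the estimator then takes c* from the trailing plateau and c0 from
    the first sample.
    """

    timestamps_s: np.ndarray
    dot: np.ndarray
    c_star: float | None = None
    c0: float | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.dot = np.asarray(self.dot, dtype=float)
        if len(self.timestamps_s) != len(self.dot):
            raise ValueError("timestamps and dot must have equal length")
        if len(self.timestamps_s) > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.c_star is not None and self.c0 is not None and self.c0 >= self.c_star:
            raise ValueError("c0 must be below c_star")


@dataclass(frozen=True)
class KLaEstimate:
    """Fitted volumetric oxygen transfer coefficient."""

    kla_per_h: float
    n_points_used: int
    fit_r2: float
    window_s: tuple[float, float]


def estimate_kla(
    series: DOTSeries,
    upper_fraction: float = 0.40,
    switch_time_s: float = 0.0,
    plateau_frames: int = 10,
    method: str = "log_linear",
) -> KLaEstimate:
    """Fit kLa from a gassing-out DOT trace.

    Parameters
    ----------
    upper_fraction
        Upper end of the fitting window as a fraction of saturation; samples
        with DOT above ``upper_fraction · c*`` are excluded, as is anything
        at or above c* itself.
    switch_time_s
        Time of the N₂ → air switch; samples before it are ignored and c0
        defaults to the first sample at/after it.
    plateau_frames
        Number of trailing samples averaged for the c* default.
    method
        ``"log_linear"`` (default): OLS slope of the log oxygen deficit
        versus time.  ``"pointwise"``: evaluate the closed-form rate at each
        usable sample and average — a cruder single-point variant kept for
        comparison.
    """
    t = series.timestamps_s
    c = series.dot
    after = t >= switch_time_s
    t, c = t[after], c[after]
    if len(t) < 2:
        raise InsufficientDataError("fewer than 2 samples after the gas switch")

    c_star = series.c_star if series.c_star is not None else float(
        c[-max(plateau_frames, 1):].mean()
    )
    c0 = series.c0 if series.c0 is not None else float(c[0])
    if c0 >= c_star:
        raise InsufficientDataError("no oxygen rise: c0 >= c*")

    usable = (c >= c0) & (c <= upper_fraction * c_star) & (c < c_star)
    tw, cw = t[usable], c[usable]
    if len(tw) < 2:
        raise InsufficientDataError(
            f"fewer than 2 usable samples below {upper_fraction:.0%} of saturation"
        )

    y = np.log((c_star - c0) / (c_star - cw))
    if method == "log_linear":
        fit = stats.linregress(tw, y)
        kla_s = fit.slope
        r2 = fit.rvalue**2
    elif method == "pointwise":
        rel = tw - tw[0]
        pos = rel > 0
        if not np.any(pos):
            raise InsufficientDataError("pointwise method needs t > 0 samples")
        kla_s = float(np.mean((y[pos] - y[0]) / rel[pos]))
        r2 = float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")

    if kla_s <= 0:
        raise InsufficientDataError("non-positive fitted slope: no oxygen uptake")
    return KLaEstimate(
        kla_per_h=kla_s * 3600.0,
        n_points_used=int(len(tw)),
        fit_r2=float(r2),
        window_s=(float(tw[0]), float(tw[-1])),
    )


def two_point_oxygen_calibration(
    signal_0pct: float, signal_100pct: float
) -> Callable[[float], float]:
    """Linear sensor calibration from the two anchor readings.

    The optical sensor is read at deoxygenated (N₂-flushed, 0 %) and
    air-saturated (100 %) conditions; raw readings map linearly (with
    extrapolation) between the anchors.
    """
    if signal_0pct == signal_100pct:
        raise ValueError("calibration anchors must differ")
    span = signal_100pct - signal_0pct

    def to_percent(signal):
        return (np.asarray(signal, dtype=float) - signal_0pct) / span * 100.0

    return to_percent
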