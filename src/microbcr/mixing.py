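"""Colorimetric mixing-time analysis.

After injecting an absorbing tracer, the spatial mean grey level of a region
of interest relaxes toward its homogeneous value.  The pipeline is:

1. per-frame ROI mean grey value  I_grey(t) = (1/n_pixel) Σ I_grey,i ;
2. two-point normalization between an initial reference (pre-injection) and
   a final reference (fully mixed) window,
   I_norm(t) = (I_grey(t) − I_grey(t₀)) / (I_grey(t_f) − I_grey(t₀)) ;
3. the mixing time t_M = t* − t₀, with t* the time where 95 % homogeneity
   (|I_norm| ≥ 0.95) is reached.

The normalization is direction-agnostic (darkening or brightening tracer)
and invariant to affine grey-level transforms of the whole sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from microbcr.errors import HomogeneityNotReachedError, NoTracerDetectedError
from microbcr.frames import FrameSequence

__all__ = ["MixingTrace", "roi_mean_grey", "normalize_trace", "mixing_time",
           "detect_injection_frame"]


@dataclass
class MixingTrace:
    """Raw and normalized ROI grey-value signal.

    ``t0`` is the reference time the mixing time is measured from (by default
    the first frame); ``tf`` the time of the final reference frame.  By
    construction the normalized signal is 0 over the initial window and 1
    over the final window.
    """

    timestamps: np.ndarray
    i_grey: np.ndarray
    i_normalized: np.ndarray
    t0: float
    tf: float
    t_mix: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")


def roi_mean_grey(seq: FrameSequence) -> np.ndarray:
    """Per-frame arithmetic mean grey value over the ROI."""
    r0, r1, c0, c1 = seq.roi
    if r0 >= r1 or c0 >= c1:
        raise ValueError("empty ROI")
    return seq.frames[:, r0:r1, c0:c1].mean(axis=(1, 2))


def detect_injection_frame(i_grey: np.ndarray) -> int:
    """Index of the largest single-frame grey-level change (tracer arrival)."""
    if len(i_grey) < 2:
        return 0
    return int(np.argmax(np.abs(np.diff(np.asarray(i_grey, dtype=float))))) + 1


def normalize_trace(
    timestamps: np.ndarray,
    i_grey: np.ndarray,
    t0_frames: int = 10,
    tf_frames: int = 10,
    t0_frame: int = 0,
    min_contrast: float = 5.0,
) -> MixingTrace:
    """Two-point normalization of an ROI grey trace.

    The initial reference level is the mean of the ``t0_frames`` frames
    ending at ``t0_frame`` (i.e. pre-injection frames when ``t0_frame`` is
    the injection index; the leading frames when it is 0); the final level is
    the mean of the last ``tf_frames`` frames.  ``min_contrast`` (grey
    levels) guards against dividing by a vanishing reference difference when
    no tracer reached the ROI.
    """
    t = np.asarray(timestamps, dtype=float)
    g = np.asarray(i_grey, dtype=float)
    if len(t) != len(g):
        raise ValueError("timestamps and grey trace must have equal length")
    n0 = max(int(t0_frames), 1)
    nf = max(int(tf_frames), 1)
    if len(g) <= n0 + nf:
        raise ValueError("trace shorter than the two reference windows")
    lo = max(t0_frame - n0 + 1, 0)
    i0 = g[lo : t0_frame + 1].mean() if t0_frame > 0 else g[:n0].mean()
    i_f = g[-nf:].mean()
    if abs(i_f - i0) < min_contrast:
        raise NoTracerDetectedError(
            f"reference contrast {abs(i_f - i0):.2f} below floor {min_contrast}"
        )
    norm = (g - i0) / (i_f - i0)
    return MixingTrace(
        timestamps=t, i_grey=g, i_normalized=norm, t0=float(t[t0_frame]),
        tf=float(t[-1]),
    )


def mixing_time(
    trace: MixingTrace, threshold: float = 0.95, hold: str = "sustained"
) -> float:
    """Mixing time t_M = t* − t₀ at the given homogeneity threshold.

    ``hold="first_crossing"`` takes the earliest sample with
    I_norm ≥ threshold; ``"sustained"`` (default) requires the threshold to
    hold for every later sample as well, which is robust to grey-level
    fluctuations from bubbles crossing the ROI.  Raises
    :class:`HomogeneityNotReachedError` if the threshold is never met.
    """
    if hold not in ("first_crossing", "sustained"):
        raise ValueError(f"unknown hold rule {hold!r}")
    ok = trace.i_normalized >= threshold
    if hold == "sustained":
        ok = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise HomogeneityNotReachedError(
            f"normalized trace never reaches {threshold:.2f}"
        )
    t_star = trace.timestamps[idx[0]]
    t_m = float(t_star - trace.t0)
    trace.t_mix = t_m
    return t_m
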