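"""Seeded generators for every input modality the pipeline consumes.

A micro bubble column's instrumentation produces four kinds of raw data:
bubbly greyscale frames (static imaging), tracer-mixing videos, dissolved
oxygen tension (DOT) traces from gassing-out experiments, and multi-channel
cultivation time series.  Each generator here emulates one of those
modalities, attaches the exact ground truth it was built from, and is
bit-reproducible under a fixed seed — so every downstream estimator can be
tested as a recovery problem without hardware.

The diauxic cultivation generator is a deliberate stand-in model:  a
piecewise-exponential batch (lag → glucose phase at µ₁ → ethanol phase at µ₂
→ stationary) with a hard substrate switch and fixed molar stoichiometry
(1 mol ethanol and 2.16 mol CO₂ formed per mol glucose consumed under the
Crabtree effect).  It reproduces the qualitative features of a monitored
S. cerevisiae batch — not the physiology.  The sensor channels (pH, DOT,
off-gas) are phenomenological shapes that exist to exercise phase detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from microbcr.bubbles import equivalent_sphere_diameter
from microbcr.frames import FrameSequence
from microbcr.growth import CultivationRecord
from microbcr.oxygen import DOTSeries

__all__ = [
    "SyntheticConfig",
    "DiauxicModelParams",
    "make_bubble_frames",
    "make_mixing_video",
    "make_dot_curve",
    "make_cultivation_record",
]

# molar masses, g mol⁻¹
_M_GLUCOSE = 180.16
_M_ETHANOL = 46.07
_M_CO2 = 44.01

_LN20 = math.log(20.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Shared generator knobs.

    ``noise_sd`` is interpreted in the output channel's own units: grey
    levels for images, % air saturation for DOT, g L⁻¹ (biomass) for
    cultivation records.  ``pixel_scale_mm`` and ``image_shape`` only matter
    for the camera emulators.
    """

    seed: int = 0
    fps: float = 50.0
    pixel_scale_mm: float = 0.02
    image_shape: tuple[int, int] = (128, 128)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.pixel_scale_mm <= 0:
            raise ValueError("pixel_scale_mm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# Defaults below encode a published cultivation timeline: lag 0.5 h, glucose
# (20 g L⁻¹) exhausted at 5.3 h having produced 6.3 g L⁻¹ biomass at
# µ₁ = 0.403 h⁻¹, ethanol phase at µ₂ = 0.147 h⁻¹ ending at 12.1 g L⁻¹.
# X0 follows from requiring depletion at 5.3 h; Y2 from the 12.1 g L⁻¹ peak.
_X0_DEFAULT = 6.3 / math.expm1(0.403 * (5.3 - 0.5))  # ≈ 1.064 g L⁻¹
_EMAX_DEFAULT = 20.0 / _M_GLUCOSE * 1.0 * _M_ETHANOL  # ≈ 5.11 g L⁻¹
_Y2_DEFAULT = (12.1 - (_X0_DEFAULT + 6.3)) / _EMAX_DEFAULT  # ≈ 0.926


@dataclass(frozen=True)
class DiauxicModelParams:
    """Parameters of the piecewise-exponential diauxic batch stand-in.

    Attributes
    ----------
    X0 : g L⁻¹
        Inoculum biomass (bio dry weight).
    S0 : g L⁻¹
        Initial glucose.
    mu1, mu2 : h⁻¹
        Specific growth rates on glucose and on ethanol; ``mu2 < mu1`` for a
        diauxic profile.
    Y1 : g_BDW g_glucose⁻¹
        Biomass yield on glucose.
    Y2 : g_BDW g_ethanol⁻¹
        Biomass yield on ethanol (phase 2).
    lag : h
        Lag-phase duration (biomass constant).
    etoh_per_glucose, co2_per_glucose : mol mol⁻¹
        Fermentation stoichiometry during the glucose phase.
    """

    X0: float = _X0_DEFAULT
    S0: float = 20.0
    mu1: float = 0.403
    mu2: float = 0.147
    Y1: float = 6.3 / 20.0
    Y2: float = _Y2_DEFAULT
    lag: float = 0.5
    etoh_per_glucose: float = 1.0
    co2_per_glucose: float = 2.16

    def __post_init__(self) -> None:
        for name in (
            "X0", "S0", "mu1", "mu2", "Y1", "Y2", "lag",
            "etoh_per_glucose", "co2_per_glucose",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.X0 <= 0:
            raise ValueError("X0 must be > 0")

    @property
    def glucose_depletion_time(self) -> float:
        """Time (h) at which glucose reaches zero."""
        return self.lag + math.log1p(self.Y1 * self.S0 / self.X0) / self.mu1

    @property
    def ethanol_max(self) -> float:
        """Ethanol concentration (g L⁻¹) at glucose depletion."""
        return self.S0 / _M_GLUCOSE * self.etoh_per_glucose * _M_ETHANOL

    @property
    def ethanol_depletion_time(self) -> float:
        """Time (h) at which ethanol reaches zero (start of stationary)."""
        x_dep = self.X0 + self.Y1 * self.S0
        if self.mu2 == 0 or self.Y2 == 0 or self.ethanol_max == 0:
            return math.inf
        return (
            self.glucose_depletion_time
            + math.log1p(self.Y2 * self.ethanol_max / x_dep) / self.mu2
        )


# --------------------------------------------------------------------------
# bubbly frames


def _render_ellipses(
    shape: tuple[int, int],
    bubbles_px: list[tuple[float, float, float, float, float]],
    bg: float,
    fg: float,
    supersample: int = 4,
) -> np.ndarray:
    """Render dark ellipses with sub-pixel edge coverage (area-averaged)."""
    img = np.full(shape, bg, dtype=float)
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    for r0, c0, a, b, theta in bubbles_px:
        rmin = max(int(math.floor(r0 - a - 1)), 0)
        rmax = min(int(math.ceil(r0 + a + 1)) + 1, shape[0])
        cmin = max(int(math.floor(c0 - a - 1)), 0)
        cmax = min(int(math.ceil(c0 + a + 1)) + 1, shape[1])
        if rmin >= rmax or cmin >= cmax:
            continue
        rr = np.arange(rmin, rmax)[:, None, None, None] + offs[None, None, :, None]
        cc = np.arange(cmin, cmax)[None, :, None, None] + offs[None, None, None, :]
        dy = rr - r0
        dx = cc - c0
        u = (dx * math.cos(theta) + dy * math.sin(theta)) / a
        v = (-dx * math.sin(theta) + dy * math.cos(theta)) / b
        cover = (u * u + v * v <= 1.0).mean(axis=(2, 3))
        patch = img[rmin:rmax, cmin:cmax]
        patch -= (bg - fg) * cover
    return img


def make_bubble_frames(
    cfg: SyntheticConfig,
    bubbles: list[tuple[tuple[float, float], float, float, float]],
    n_frames: int = 1,
    clip_mode: str = "raise",
    background_grey: float = 220.0,
    bubble_grey: float = 30.0,
) -> FrameSequence:
    """Render dark elliptical bubbles on a bright background.

    Parameters
    ----------
    bubbles
        One entry per bubble: ``((center_row_mm, center_col_mm), d_major_mm,
        d_minor_mm, orientation_rad)``.  The orientation is the angle of the
        major axis from the image column (horizontal) axis.  The same bubbles
        are rendered in every frame.
    n_frames
        Number of (identical apart from noise) frames to emit.
    clip_mode
        ``"raise"`` refuses bubbles that do not fit inside the image;
        ``"clip"`` renders them truncated at the border.

    Returns
    -------
    FrameSequence
        With ``ground_truth["bubbles"]`` listing each bubble's axes and its
        equivalent spherical diameter d_SB = ∛(d_major² · d_minor).
    """
    rows, cols = cfg.image_shape
    scale = cfg.pixel_scale_mm
    px: list[tuple[float, float, float, float, float]] = []
    truth = []
    for (cr_mm, cc_mm), dmaj, dmin, theta in bubbles:
        if not (dmaj > 0 and dmin > 0):
            raise ValueError("bubble axes must be > 0")
        if dmin > dmaj:
            dmaj, dmin = dmin, dmaj
        a = dmaj / 2 / scale
        b = dmin / 2 / scale
        r0 = cr_mm / scale
        c0 = cc_mm / scale
        inside = (a <= r0 <= rows - a) and (a <= c0 <= cols - a)
        if not inside and clip_mode == "raise":
            raise ValueError(
                f"bubble at ({cr_mm}, {cc_mm}) mm with d_major {dmaj} mm "
                f"does not fit in a {rows}x{cols} frame at {scale} mm/px"
            )
        px.append((r0, c0, a, b, theta))
        truth.append(
            {
                "center_row_px": r0,
                "center_col_px": c0,
                "d_major_mm": dmaj,
                "d_minor_mm": dmin,
                "orientation_rad": theta,
                "d_sb_mm": equivalent_sphere_diameter(dmaj, dmin),
            }
        )

    base = _render_ellipses((rows, cols), px, background_grey, bubble_grey)
    rng = cfg.rng()
    frames = np.empty((n_frames, rows, cols), dtype=np.uint8)
    for i in range(n_frames):
        img = base
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=base.shape)
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    timestamps = np.arange(n_frames) / cfg.fps
    return FrameSequence(
        frames=frames,
        timestamps=timestamps,
        fps=cfg.fps,
        pixel_scale_mm=scale,
        ground_truth={"bubbles": truth},
    )


# --------------------------------------------------------------------------
# tracer-mixing video


def make_mixing_video(
    cfg: SyntheticConfig,
    tau: float,
    t_inject: float,
    duration: float,
    mode: str = "exponential",
    i_initial: float = 230.0,
    i_final: float = 30.0,
) -> FrameSequence:
    """Emulate a colorimetric mixing experiment video.

    The spatial mean grey level of every frame follows either a first-order
    relaxation toward homogeneity after tracer injection,

        I(t) = I_f + (I_0 − I_f) · exp(−(t − t_inject)/τ)   for t ≥ t_inject,

    or an instantaneous step at ``t_inject``.  With the initial reference
    taken at the start of the recording, the true 95 %-homogeneity time is
    ``t_inject + τ·ln 20`` (exponential) or ``t_inject`` (step); it is stored
    in ``ground_truth["t_mix_s"]``.

    Frames are 8-bit; a fixed stratified sub-level dither pattern is baked in
    so that the ROI *mean* resolves grey levels well below the quantization
    step, as a real camera's spatial shading does.
    """
    if duration <= t_inject:
        raise ValueError("duration must exceed t_inject")
    if mode == "exponential":
        if tau <= 0:
            raise ValueError("tau must be > 0 in exponential mode")
        t_mix = t_inject + tau * _LN20
    elif mode == "step":
        t_mix = t_inject
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows, cols = cfg.image_shape
    n_frames = int(round(duration * cfg.fps)) + 1
    timestamps = np.arange(n_frames) / cfg.fps

    level = np.full(n_frames, i_initial, dtype=float)
    after = timestamps >= t_inject
    if mode == "exponential":
        level[after] = i_final + (i_initial - i_final) * np.exp(
            -(timestamps[after] - t_inject) / tau
        )
    else:
        level[after] = i_final

    rng = cfg.rng()
    n_px = rows * cols
    # stratified dither: floor(I + d) averages back to I across the frame
    dither = rng.permutation((np.arange(n_px) + 0.5) / n_px).reshape(rows, cols)

    frames = np.empty((n_frames, rows, cols), dtype=np.uint8)
    for i, lvl in enumerate(level):
        img = np.floor(lvl + dither)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    return FrameSequence(
        frames=frames,
        timestamps=timestamps,
        fps=cfg.fps,
        pixel_scale_mm=cfg.pixel_scale_mm,
        ground_truth={
            "t_mix_s": t_mix,
            "t_inject_s": t_inject,
            "tau_s": tau if mode == "exponential" else 0.0,
            "mode": mode,
        },
    )


# --------------------------------------------------------------------------
# gassing-out DOT curve


def make_dot_curve(
    cfg: SyntheticConfig,
    kla_per_h: float,
    c_star: float = 100.0,
    c0: float = 0.0,
    duration_s: float = 60.0,
    sampling_dt_s: float = 1.0,
) -> DOTSeries:
    """First-order re-oxygenation curve after a N₂ → air gas switch.

    c(t) = c* − (c* − c0)·exp(−kLa·t), with optional additive Gaussian noise
    of sd ``cfg.noise_sd`` (% air saturation).  The generating kLa (h⁻¹) is
    attached as ground truth.
    """
    if kla_per_h <= 0:
        raise ValueError("kla must be > 0")
    if c0 >= c_star:
        raise ValueError("c0 must be below c_star")
    if sampling_dt_s <= 0:
        raise ValueError("sampling_dt must be > 0")
    kla_s = kla_per_h / 3600.0
    t = np.arange(0.0, duration_s + 0.5 * sampling_dt_s, sampling_dt_s)
    dot = c_star - (c_star - c0) * np.exp(-kla_s * t)
    if cfg.noise_sd > 0:
        dot = dot + cfg.rng().normal(0.0, cfg.noise_sd, size=t.shape)
    return DOTSeries(
        timestamps_s=t,
        dot=dot,
        c_star=c_star,
        c0=c0,
        ground_truth={"kla_per_h": kla_per_h},
    )


# --------------------------------------------------------------------------
# diauxic cultivation record


def make_cultivation_record(
    params: DiauxicModelParams,
    cfg: SyntheticConfig,
    duration_h: float = 14.0,
    sampling_dt_h: float = 1.0 / 60.0,
    bdw_noise: str = "gaussian",
    o2_phase2: str = "flat",
) -> CultivationRecord:
    """Integrate the diauxic batch stand-in and emit all monitored channels.

    Phases (hard switches, closed-form within each):

    * lag (``t < lag``): X = X0, S = S0.
    * glucose phase: dX/dt = µ₁X, dS/dt = −(1/Y₁)dX/dt; ethanol and
      cumulative CO₂ follow the molar stoichiometry per glucose consumed.
    * ethanol phase (from glucose depletion): dX/dt = µ₂X,
      dE/dt = −(1/Y₂)dX/dt, until E = 0.
    * stationary: X constant.

    Channels: ``bdw`` = X; ``ph`` falls with glucose consumed (organic-acid
    proxy), is flat in phase 2 and creeps up in stationary; ``dot`` falls
    during both growth phases and recovers in stationary; ``co2_offgas`` is
    proportional to the instantaneous CO₂ evolution rate (large in phase 1,
    small in phase 2 — its drop at glucose depletion is the diauxic-shift
    marker); ``o2_offgas`` mirrors CO₂ during phase 1.  ``o2_phase2`` selects
    whether O₂ also dips during ethanol growth (``"decrease"``) or stays flat
    (``"flat"``, the default, matching what the monitored batch showed).

    ``bdw_noise``: ``"gaussian"`` adds sd ``cfg.noise_sd`` g L⁻¹;
    ``"lognormal"`` multiplies by exp(N(0, cfg.noise_sd)) (scattered-light
    like).  Sensor channels get scaled-down Gaussian noise.
    """
    if sampling_dt_h <= 0:
        raise ValueError("sampling_dt must be > 0")
    if bdw_noise not in ("gaussian", "lognormal"):
        raise ValueError(f"unknown bdw_noise {bdw_noise!r}")
    if o2_phase2 not in ("flat", "decrease"):
        raise ValueError(f"unknown o2_phase2 {o2_phase2!r}")

    p = params
    t = np.arange(0.0, duration_h + 0.5 * sampling_dt_h, sampling_dt_h)
    t_dep = p.glucose_depletion_time
    t_eth = p.ethanol_depletion_time
    x_dep = p.X0 + p.Y1 * p.S0
    e_max = p.ethanol_max
    x_max = x_dep + p.Y2 * e_max

    X = np.full_like(t, p.X0)
    S = np.full_like(t, p.S0)
    E = np.zeros_like(t)
    r_co2_1 = np.zeros_like(t)  # phase-1 CO2 evolution rate, g L⁻¹ h⁻¹
    r_co2_2 = np.zeros_like(t)

    m1 = (t >= p.lag) & (t < t_dep)
    X[m1] = p.X0 * np.exp(p.mu1 * (t[m1] - p.lag))
    S[m1] = p.S0 - (X[m1] - p.X0) / p.Y1
    consumed = (p.S0 - S[m1]) / _M_GLUCOSE
    E[m1] = consumed * p.etoh_per_glucose * _M_ETHANOL
    r_co2_1[m1] = (p.mu1 * X[m1] / p.Y1) / _M_GLUCOSE * p.co2_per_glucose * _M_CO2

    m2 = (t >= t_dep) & (t < t_eth)
    X[m2] = x_dep * np.exp(p.mu2 * (t[m2] - t_dep))
    S[m2] = 0.0
    E[m2] = np.maximum(e_max - (X[m2] - x_dep) / p.Y2, 0.0)
    # ethanol oxidation releases far less CO2 per biomass than fermentation
    r_co2_2[m2] = 0.2 * p.mu2 * X[m2]

    m3 = t >= t_eth
    X[m3] = x_max
    S[m3] = 0.0
    E[m3] = 0.0

    r_co2 = r_co2_1 + r_co2_2
    peak = r_co2_1.max() if r_co2_1.max() > 0 else 1.0
    co2 = 0.04 + 3.0 * r_co2 / peak  # % v/v, ambient baseline, ~3 % at peak
    co2_p1 = 0.04 + 3.0 * r_co2_1 / peak

    o2_src = co2 if o2_phase2 == "decrease" else co2_p1
    o2 = 20.95 - (o2_src - 0.04)

    dot = 100.0 - 90.0 * (X - p.X0) / max(x_max - p.X0, 1e-12)
    if np.any(m3) and t_eth < math.inf:
        dot[m3] = dot[m3] + (100.0 - dot[m3]) * (1 - np.exp(-(t[m3] - t_eth) / 0.5))

    ph = np.full_like(t, 4.5)
    grow = t >= p.lag
    ph[grow] = 4.5 - 0.5 * (p.S0 - S[grow]) / max(p.S0, 1e-12)
    if np.any(m3) and t_eth < math.inf:
        ph[m3] = ph[m3] + 0.2 * (1 - np.exp(-(t[m3] - t_eth) / 2.0))

    bdw = X.copy()
    if cfg.noise_sd > 0:
        rng = cfg.rng()
        if bdw_noise == "gaussian":
            bdw = bdw + rng.normal(0.0, cfg.noise_sd, size=t.shape)
        else:
            bdw = bdw * np.exp(rng.normal(0.0, cfg.noise_sd, size=t.shape))
        ph = ph + rng.normal(0.0, 0.02 * cfg.noise_sd, size=t.shape)
        dot = dot + rng.normal(0.0, 1.0 * cfg.noise_sd, size=t.shape)
        co2 = co2 + rng.normal(0.0, 0.05 * cfg.noise_sd, size=t.shape)
        o2 = o2 + rng.normal(0.0, 0.05 * cfg.noise_sd, size=t.shape)

    truth = {
        "mu1": p.mu1,
        "mu2": p.mu2,
        "lag_end": p.lag,
        "glucose_depletion_time": t_dep,
        "ethanol_depletion_time": t_eth,
        "x_max": x_max,
        "y1": (x_dep - p.X0) / p.S0,
        "y_total": x_max / p.S0,
        "glucose": S,
        "ethanol": E,
    }
    return CultivationRecord(
        timestamps_h=t,
        bdw=bdw,
        ph=ph,
        dot=dot,
        co2_offgas=co2,
        o2_offgas=o2,
        ground_truth=truth,
    )
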