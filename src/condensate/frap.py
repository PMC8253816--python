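"""FRAP analysis: recovery traces, exponential fits, diffusion, kymographs.

A photobleached region of a liquid-like condensate refills by exchange of
molecules with the surrounding pool. The normalized intensity is modelled as

    I(t) = i0 + (P - i0) * (1 - exp(-t / tau)),   t >= 0,

with ``t = 0`` at the bleach frame, ``i0`` the immediate post-bleach level,
``P`` the plateau (mobile fraction, in % of the pre-bleach mean) and ``tau``
the recovery time constant. The diffusion coefficient is estimated to order
of magnitude as ``D ~ L^2 / tau`` where ``L`` is the bleached-spot diameter.

Normalization is "simple": each trace is divided by its own pre-bleach mean
(after background subtraction). No acquisition-photofading correction is
applied; the per-frame background term is the hook for adding one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .exceptions import FitError, GeometryError, NormalizationError
from .io_formats import CircleRoi, LineRoi, TimelapseStack

__all__ = [
    "RecoveryTrace",
    "FrapFit",
    "Kymograph",
    "exponential_recovery",
    "extract_recovery_trace",
    "fit_recovery",
    "estimate_diffusion",
    "compute_kymograph",
]


def exponential_recovery(
    t: np.ndarray | float, tau_s: float, plateau_pct: float, i0_pct: float
) -> np.ndarray | float:
    """Closed-form single-exponential recovery, in % of pre-bleach."""
    t = np.asarray(t, dtype=float)
    return i0_pct + (plateau_pct - i0_pct) * (1.0 - np.exp(-t / tau_s))


@dataclass(frozen=True)
class RecoveryTrace:
    """Normalized intensity vs time; ``t = 0`` at the bleach frame."""

    times_s: np.ndarray
    intensity_pct: np.ndarray
    roi_label: str = ""
    region: str = "inside"  # "inside" | "outside"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.intensity_pct, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "intensity_pct", y)

    @property
    def post_bleach(self) -> tuple[np.ndarray, np.ndarray]:
        sel = self.times_s >= 0
        return self.times_s[sel], self.intensity_pct[sel]


@dataclass(frozen=True)
class FrapFit:
    """Fitted recovery parameters and goodness of fit."""

    tau_s: float
    plateau_pct: float
    i0_pct: float
    rss: float
    n_points: int


@dataclass(frozen=True)
class Kymograph:
    """Position-vs-time intensity matrix sampled along a line.

    Rows are positions (one per integer pixel step along the line, i.e.
    ``floor(length_px) + 1`` rows), columns are frames.
    """

    data: np.ndarray
    position_spacing_um: float
    frame_interval_s: float

    @property
    def n_positions(self) -> int:
        return self.data.shape[0]


def extract_recovery_trace(
    stack: TimelapseStack,
    roi: CircleRoi,
    bleach_frame: int,
    background_roi: CircleRoi,
    *,
    region: str = "inside",
    channel: int = 0,
    outer_scale: float = 2.0,
) -> RecoveryTrace:
    """Per-frame mean in the bleach ROI, background-subtracted and normalized.

    ``region="inside"`` measures within the circle; ``region="outside"``
    measures the annulus between the circle and ``outer_scale`` times its
    diameter (the unbleached part of the condensate). The per-frame background
    mean (from ``background_roi``, disjoint from the measurement region) is
    subtracted, then the trace is divided by its pre-bleach average and
    scaled to percent.
    """
    if region not in ("inside", "outside"):
        raise ValueError(f"region must be 'inside' or 'outside', got {region!r}")
    if not 0 < bleach_frame <= stack.n_frames - 1:
        raise ValueError("need at least one pre-bleach and one post-bleach frame")
    shape = (stack.meta.height_px, stack.meta.width_px)
    px = stack.meta.pixel_size_um
    inner = roi.mask(shape, px)
    if region == "inside":
        measure = inner
    else:
        outer = CircleRoi(roi.center_px, roi.diameter_um * outer_scale).mask(shape, px)
        measure = outer & ~inner
    bg_mask = background_roi.mask(shape, px)
    if np.any(measure & bg_mask):
        raise GeometryError("background ROI overlaps the measurement region")
    if not measure.any() or not bg_mask.any():
        raise GeometryError("measurement or background ROI rasterizes to zero pixels")

    frames = stack.data[:, channel]
    signal = frames[:, measure].mean(axis=1) - frames[:, bg_mask].mean(axis=1)
    pre = signal[:bleach_frame].mean()
    if pre <= 0:
        raise NormalizationError(
            f"pre-bleach background-subtracted mean is {pre:.3g}; cannot normalize"
        )
    pct = signal / pre * 100.0
    times = stack.times_s(origin_frame=bleach_frame)
    return RecoveryTrace(times, pct, roi_label=roi.label, region=region)


def fit_recovery(trace: RecoveryTrace, *, max_iter: int = 1000) -> FrapFit:
    """Least-squares fit of the single-exponential recovery model.

    Only ``t >= 0`` points are used (pre-bleach points serve normalization).
    Initialization: ``i0`` = first post-bleach value, ``P`` = mean of the last
    three points, ``tau`` = time to half of (P - i0). A trace that does not
    recover (plateau estimate at or below i0) or never converges raises
    :class:`FitError`.
    """
    t, y = trace.post_bleach
    if len(t) < 3:
        raise FitError(f"need >= 3 post-bleach points, got {len(t)}")
    i0_init = float(y[0])
    p_init = float(np.mean(y[-3:]))
    if p_init <= i0_init:
        raise FitError(
            "post-bleach trace does not recover "
            f"(plateau estimate {p_init:.3g} <= initial {i0_init:.3g}); "
            "tau is unidentifiable"
        )
    half = i0_init + 0.5 * (p_init - i0_init)
    above = np.nonzero(y >= half)[0]
    tau_init = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1]) / 3.0
    tau_init = max(tau_init, float(t[1] - t[0]) / 10.0)

    def model(tt, i0, p, tau):
        return i0 + (p - i0) * (1.0 - np.exp(-tt / tau))

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=[i0_init, p_init, tau_init],
            method="lm",
            maxfev=max_iter * 5,
            ftol=1e-12,
            xtol=1e-12,
        )
    except RuntimeError as exc:
        raise FitError(f"recovery fit did not converge: {exc}") from exc
    i0, p, tau = map(float, popt)
    if tau <= 0 or not np.isfinite(tau):
        raise FitError(f"recovery fit returned non-physical tau = {tau:.3g} s")
    rss = float(np.sum((y - model(t, i0, p, tau)) ** 2))
    return FrapFit(tau_s=tau, plateau_pct=p, i0_pct=i0, rss=rss, n_points=len(t))


def estimate_diffusion(fit: FrapFit | float, bleach_diameter_um: float) -> float:
    """Order-of-magnitude diffusion estimate ``D ~ L^2 / tau`` (um^2/s).

    ``L`` is the diameter of the bleached region. This is a scaling estimate,
    not a reaction-diffusion model fit; expect order-of-magnitude accuracy.
    """
    tau = fit.tau_s if isinstance(fit, FrapFit) else float(fit)
    if bleach_diameter_um <= 0:
        raise ValueError("bleach_diameter_um must be > 0")
    if tau <= 0:
        raise ValueError("tau_s must be > 0")
    return bleach_diameter_um**2 / tau


def compute_kymograph(
    stack: TimelapseStack, line: LineRoi, *, channel: int = 0
) -> Kymograph:
    """Sample intensity along a line at unit-pixel steps, one column per frame.

    Bilinear interpolation along the line; averaged over ``width_px`` parallel
    lines offset perpendicularly (offsets clamped at the frame border). A line
    of ``n`` integer pixel steps yields ``n + 1`` position rows.
    """
    h, w = stack.meta.height_px, stack.meta.width_px
    for name, (x, y) in (("p0", line.p0_px), ("p1", line.p1_px)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise GeometryError(
                f"line endpoint {name}=({x}, {y}) lies outside the {w}x{h} frame"
            )
    n_steps = int(np.floor(line.length_px))
    n_pos = n_steps + 1
    ux = (line.p1_px[0] - line.p0_px[0]) / line.length_px
    uy = (line.p1_px[1] - line.p0_px[1]) / line.length_px
    s = np.arange(n_pos, dtype=float)
    xs = line.p0_px[0] + s * ux
    ys = line.p0_px[1] + s * uy
    # perpendicular unit vector for width averaging
    px_, py_ = -uy, ux
    offsets = np.arange(line.width_px, dtype=float) - (line.width_px - 1) / 2.0

    out = np.empty((n_pos, stack.n_frames), dtype=float)
    frames = stack.data[:, channel]
    for k in range(stack.n_frames):
        acc = np.zeros(n_pos)
        for off in offsets:
            coords = np.vstack([ys + off * py_, xs + off * px_])
            acc += ndimage.map_coordinates(frames[k], coords, order=1, mode="nearest")
        out[:, k] = acc / len(offsets)
    return Kymograph(
        data=out,
        position_spacing_um=stack.meta.pixel_size_um,
        frame_interval_s=stack.meta.frame_interval_s,
    )
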