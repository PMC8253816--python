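"""Fusion shape relaxation and the size scaling of its timescale.

When two liquid droplets coalesce, surface tension relaxes the merged shape
back to a sphere. The projected aspect ratio decays as

    AR(t) = 1 + (ar0 - 1) * exp(-t / tau_f),

and for liquids the relaxation time grows linearly with droplet size,
``tau_f ~ K * d`` — the slope ``K`` (s/um) is the inverse capillary velocity
(viscosity over surface tension). This module measures AR(t) per event from
second central moments of the half-max region, fits the exponential per
event, and fits the linear size scaling across events by ordinary least
squares with a free intercept (so users can test whether it vanishes).
The merged droplet's equivalent diameter is the size variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .detection import EventRecord, Track
from .exceptions import FitError
from .io_formats import TimelapseStack

__all__ = [
    "AspectRatioSeries",
    "RelaxationFit",
    "ScalingFit",
    "measure_aspect_ratio_series",
    "fit_relaxation",
    "fit_size_scaling",
]


@dataclass(frozen=True)
class AspectRatioSeries:
    """Aspect ratio vs time from contact (t = 0) for one fusion event."""

    event_id: str
    times_s: np.ndarray
    ar_values: np.ndarray
    final_diameter_um: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.ar_values, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and AR values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 1):
            raise ValueError("aspect ratios must be >= 1")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "ar_values", y)


@dataclass(frozen=True)
class RelaxationFit:
    tau_f_s: float
    ar0: float
    rss: float


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of relaxation time against merged-droplet diameter."""

    slope_K_s_per_um: float
    intercept_s: float
    stderr_slope: float
    n_events: int
    r2: float


def _halfmax_region(img: np.ndarray, center_xy: tuple[float, float], search_px: float):
    """Regionprops of the half-max component nearest ``center_xy``, or None."""
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    near = (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= search_px**2
    if not near.any():
        return None
    background = float(np.median(img))
    peak = float(img[near].max())
    if peak <= background:
        return None
    level = background + 0.5 * (peak - background)
    labels = sk_label(img >= level)
    cand = labels[near & (img >= level)]
    cand = cand[cand > 0]
    if cand.size == 0:
        return None
    lab = int(np.bincount(cand).argmax())
    for props in regionprops((labels == lab).astype(int)):
        return props
    return None  # pragma: no cover


def measure_aspect_ratio_series(
    stack: TimelapseStack,
    event: EventRecord,
    *,
    tracks: Sequence[Track] | None = None,
    center_px: tuple[float, float] | None = None,
    channel: int = 0,
    search_radius_um: float = 3.0,
) -> AspectRatioSeries:
    """Measure AR = major/minor axis of the merged region after contact.

    The merged region is re-segmented per frame at the half-max contour
    around the event location (taken from the child track if ``tracks`` is
    given, else from ``center_px``, else the brightest pixel of the contact
    frame). Frames where the region is lost are recorded as gaps and the
    series continues.
    """
    if event.kind != "fusion":
        raise ValueError("aspect-ratio series is defined for fusion events")
    contact = event.frame
    if stack.n_frames - contact < 3:
        raise ValueError("need >= 3 post-contact frames")
    px = stack.meta.pixel_size_um
    if tracks is not None:
        child = next(
            (tr for tr in tracks if tr.track_id == event.child_track_ids[0]), None
        )
        det = child.at(contact) if child is not None else None
        if det is None:
            raise ValueError("child track has no detection at the contact frame")
        center = det.centroid_px
    elif center_px is not None:
        center = center_px
    else:
        img0 = stack.data[contact, channel]
        iy, ix = np.unravel_index(np.argmax(img0), img0.shape)
        center = (float(ix), float(iy))

    search_px = search_radius_um / px
    times, ars = [], []
    last_area_px = None
    for f in range(contact, stack.n_frames):
        props = _halfmax_region(stack.data[f, channel], center, search_px)
        if props is None or props.axis_minor_length <= 0:
            continue  # gap: region lost in this frame
        times.append((f - contact) * stack.meta.frame_interval_s)
        ars.append(props.axis_major_length / props.axis_minor_length)
        cy, cx = props.centroid
        center = (float(cx), float(cy))
        last_area_px = props.area
    if len(times) < 3:
        raise FitError("merged region found in fewer than 3 post-contact frames")
    final_d = float(np.sqrt(4.0 * last_area_px / np.pi) * px)
    event_id = f"fusion_f{contact}_" + "-".join(map(str, event.parent_track_ids))
    return AspectRatioSeries(
        event_id=event_id,
        times_s=np.asarray(times),
        ar_values=np.asarray(ars),
        final_diameter_um=final_d,
    )


def fit_relaxation(series: AspectRatioSeries, *, max_iter: int = 1000) -> RelaxationFit:
    """Least-squares fit of ``AR(t) = 1 + (ar0 - 1) exp(-t / tau_f)``.

    Initialization: ``ar0`` = first value, ``tau_f`` = time to half-decay of
    (AR - 1). A series flat at AR ~ 1 is unidentifiable and raises
    :class:`FitError`.
    """
    t = series.times_s
    y = series.ar_values
    if len(t) < 3:
        raise FitError("need >= 3 points to fit the relaxation")
    ar0_init = float(y[0])
    if ar0_init - 1.0 < 0.02 or float(np.max(y)) - 1.0 < 0.02:
        raise FitError("series is flat at AR ~ 1; relaxation time unidentifiable")
    half = 1.0 + 0.5 * (ar0_init - 1.0)
    below = np.nonzero(y <= half)[0]
    tau_init = float(t[below[0]]) if below.size and t[below[0]] > 0 else float(t[-1]) / 3.0

    def model(tt, ar0, tau):
        return 1.0 + (ar0 - 1.0) * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=[ar0_init, tau_init],
            method="lm",
            maxfev=max_iter * 5,
            ftol=1e-12,
            xtol=1e-12,
        )
    except RuntimeError as exc:
        raise FitError(f"relaxation fit did not converge: {exc}") from exc
    ar0, tau = map(float, popt)
    if tau <= 0 or ar0 <= 1 or not np.isfinite(tau):
        raise FitError(f"non-physical relaxation fit (ar0={ar0:.3g}, tau={tau:.3g})")
    rss = float(np.sum((y - model(t, ar0, tau)) ** 2))
    return RelaxationFit(tau_f_s=tau, ar0=ar0, rss=rss)


def fit_size_scaling(
    events: Sequence[tuple[float, float]] | np.ndarray,
) -> ScalingFit:
    """OLS of relaxation time on merged-droplet diameter, free intercept.

    ``events`` is a sequence of ``(tau_f_s, final_diameter_um)`` pairs; at
    least 3 events spanning a >= 2-fold diameter range are required. Returns
    the slope ``K`` (s/um), its OLS standard error, and r^2.
    """
    arr = np.asarray(events, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("events must be (tau_f_s, final_diameter_um) pairs")
    if arr.shape[0] < 3:
        raise ValueError(f"need >= 3 events for the size scaling, got {arr.shape[0]}")
    tau, d = arr[:, 0], arr[:, 1]
    if np.ptp(d) == 0:
        raise ValueError("zero diameter variance; scaling slope undefined")
    if d.max() / d.min() < 2.0:
        raise ValueError("events must span at least a 2-fold diameter range")
    res = stats.linregress(d, tau)
    return ScalingFit(
        slope_K_s_per_um=float(res.slope),
        intercept_s=float(res.intercept),
        stderr_slope=float(res.stderr),
        n_events=arr.shape[0],
        r2=float(res.rvalue**2),
    )
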