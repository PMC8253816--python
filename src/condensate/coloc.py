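"""Two-channel line-profile colocalization and perturbation response.

Colocalization is operationalized from line scans across condensates: the
Pearson correlation between the two channels over the condensate span plus
the partner channel's enrichment over its diffuse nuclear baseline. The
baseline excludes nucleoli (regions below the 10th intensity percentile of
the smoothed nucleus) and the condensates themselves.

Perturbation (hexanediol-style dispersal/washout) is quantified per
condensate from its contrast time series: dispersal time is the first
post-treatment crossing below ``contrast_threshold``, recovery a re-crossing
within ``window_s`` after washout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError
from .io_formats import LineRoi, TimelapseStack

__all__ = [
    "LineProfile",
    "ColocSummary",
    "PerturbationResult",
    "extract_line_profile",
    "profile_colocalization",
    "measure_contrast_series",
    "perturbation_response",
]


@dataclass(frozen=True)
class LineProfile:
    """Per-channel bilinear intensity samples along a line, plus baselines."""

    positions_um: np.ndarray
    intensities: np.ndarray  # (n_channels, n_positions)
    nuclear_baseline: np.ndarray  # per channel
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.intensities.shape[1] != len(self.positions_um):
            raise ValueError("positions and intensity rows must align")
        if self.intensities.shape[0] != len(self.nuclear_baseline):
            raise ValueError("one baseline per channel is required")
        if np.any(np.asarray(self.nuclear_baseline) <= 0):
            raise ValueError("nuclear baselines must be > 0")


@dataclass(frozen=True)
class ColocSummary:
    pearson_r: float
    enrichment: tuple[float, ...]  # per channel, over the condensate span
    coloc_call: bool
    degenerate: bool = False  # zero-variance channel over the span


@dataclass(frozen=True)
class PerturbationResult:
    dispersal_times_s: tuple[float | None, ...]
    recovered: tuple[bool, ...]
    recovered_fraction: float  # nan when no track dispersed
    n_dispersed: int

    @property
    def defined(self) -> bool:
        return self.n_dispersed > 0


def _sample_line(img: np.ndarray, line: LineRoi) -> np.ndarray:
    n_pos = int(np.floor(line.length_px)) + 1
    ux = (line.p1_px[0] - line.p0_px[0]) / line.length_px
    uy = (line.p1_px[1] - line.p0_px[1]) / line.length_px
    s = np.arange(n_pos, dtype=float)
    xs = line.p0_px[0] + s * ux
    ys = line.p0_px[1] + s * uy
    px_, py_ = -uy, ux
    offsets = np.arange(line.width_px, dtype=float) - (line.width_px - 1) / 2.0
    acc = np.zeros(n_pos)
    for off in offsets:
        coords = np.vstack([ys + off * py_, xs + off * px_])
        acc += ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    return acc / len(offsets)


def extract_line_profile(
    stack: TimelapseStack,
    line: LineRoi,
    nucleus_mask: np.ndarray,
    *,
    frame: int = 0,
    channels: Sequence[int] | None = None,
    nucleolus_percentile: float = 10.0,
    condensate_factor: float = 1.5,
    primary_channel: int = 0,
) -> LineProfile:
    """Sample a line profile across condensates with per-channel baselines.

    The per-channel nuclear baseline is the mean within ``nucleus_mask``
    after removing nucleoli (pixels below the ``nucleolus_percentile`` of the
    smoothed channel within the nucleus) and condensates (pixels brighter
    than ``condensate_factor`` times the provisional nuclear median). The
    line must cross at least one condensate in the primary channel.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    if channels is None:
        channels = range(stack.n_channels)
    channels = list(channels)
    h, w = stack.meta.height_px, stack.meta.width_px
    for name, (x, y) in (("p0", line.p0_px), ("p1", line.p1_px)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise GeometryError(f"line endpoint {name} lies outside the frame")

    profiles, baselines = [], []
    for c in channels:
        img = stack.data[frame, c]
        smooth = ndimage.gaussian_filter(img, 2.0)
        lo = np.percentile(smooth[nucleus_mask], nucleolus_percentile)
        nucleolus = smooth < lo
        provisional = float(np.median(img[nucleus_mask & ~nucleolus]))
        condensates = img > condensate_factor * provisional
        sel = nucleus_mask & ~nucleolus & ~condensates
        if not sel.any():
            sel = nucleus_mask & ~nucleolus
        baselines.append(float(img[sel].mean()))
        profiles.append(_sample_line(img, line))
    profiles = np.asarray(profiles)
    baselines = np.asarray(baselines)

    primary_idx = channels.index(primary_channel) if primary_channel in channels else 0
    if profiles[primary_idx].max() <= condensate_factor * baselines[primary_idx]:
        raise ValueError(
            "line does not cross any condensate in the primary channel "
            f"(max {profiles[primary_idx].max():.3g} vs baseline "
            f"{baselines[primary_idx]:.3g})"
        )
    positions = np.arange(profiles.shape[1], dtype=float) * stack.meta.pixel_size_um
    names = tuple(stack.meta.channel_names[c] for c in channels)
    return LineProfile(
        positions_um=positions,
        intensities=profiles,
        nuclear_baseline=baselines,
        channel_names=names,
    )


def profile_colocalization(
    profile: LineProfile,
    condensate_span: tuple[int, int],
    *,
    r_min: float = 0.5,
    enrichment_min: float = 1.5,
    primary: int = 0,
    partner: int = 1,
) -> ColocSummary:
    """Pearson r and per-channel enrichment over one condensate span.

    ``condensate_span`` is a half-open index interval into the profile.
    The call is positive when ``r >= r_min`` and the partner channel is
    enriched at least ``enrichment_min`` over its nuclear baseline. A
    zero-variance channel makes r undefined: the call is False and flagged.
    """
    lo, hi = condensate_span
    n = profile.intensities.shape[1]
    if not (0 <= lo < hi <= n):
        raise ValueError(f"span [{lo}, {hi}) outside profile of length {n}")
    seg = profile.intensities[:, lo:hi]
    enrichment = tuple(
        float(seg[c].mean() / profile.nuclear_baseline[c])
        for c in range(seg.shape[0])
    )
    a, b = seg[primary], seg[partner]
    if np.std(a) == 0 or np.std(b) == 0:
        return ColocSummary(
            pearson_r=float("nan"),
            enrichment=enrichment,
            coloc_call=False,
            degenerate=True,
        )
    r = float(np.corrcoef(a, b)[0, 1])
    call = (r >= r_min) and (enrichment[partner] >= enrichment_min)
    return ColocSummary(pearson_r=r, enrichment=enrichment, coloc_call=call)


def measure_contrast_series(
    stack: TimelapseStack,
    centers_px: Sequence[tuple[float, float]],
    radius_um: float,
    *,
    channel: int = 0,
    nucleus_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Contrast (droplet mean / nuclear baseline) per droplet per frame.

    The baseline at each frame is the median within the nucleus mask (whole
    frame when None) after excluding 1.5x-dilated droplet disks.
    """
    h, w = stack.meta.height_px, stack.meta.width_px
    px = stack.meta.pixel_size_um
    r = radius_um / px
    yy, xx = np.mgrid[0:h, 0:w]
    disks = [
        (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2 for cx, cy in centers_px
    ]
    exclude = np.zeros((h, w), dtype=bool)
    for cx, cy in centers_px:
        exclude |= (xx - cx) ** 2 + (yy - cy) ** 2 <= (1.5 * r) ** 2
    base_sel = (
        np.asarray(nucleus_mask, dtype=bool) if nucleus_mask is not None else np.ones((h, w), bool)
    ) & ~exclude
    if not base_sel.any():
        raise ValueError("no pixels left for the nuclear baseline")
    out = np.empty((len(centers_px), stack.n_frames), dtype=float)
    for k in range(stack.n_frames):
        img = stack.data[k, channel]
        baseline = float(np.median(img[base_sel]))
        if baseline <= 0:
            raise ValueError(f"non-positive nuclear baseline at frame {k}")
        for i, disk in enumerate(disks):
            out[i, k] = float(img[disk].mean()) / baseline
    return out


def perturbation_response(
    contrast: np.ndarray,
    frame_interval_s: float,
    treat_frame: int,
    washout_frame: int,
    *,
    contrast_threshold: float = 1.2,
    window_s: float = 10.0,
) -> PerturbationResult:
    """Score dispersal and recovery per condensate from contrast series.

    ``contrast`` is (n_tracks, n_frames). Dispersal time is measured from
    ``treat_frame``; recovery requires the contrast to re-cross the threshold
    within ``window_s`` after ``washout_frame``. The recovered fraction is
    over dispersed tracks only and is NaN (flagged) when none dispersed.
    """
    if contrast_threshold <= 1.0:
        raise ValueError(
            "contrast_threshold must be > 1 (contrast 1 means no condensate)"
        )
    if washout_frame <= treat_frame:
        raise ValueError("washout_frame must be after treat_frame")
    contrast = np.atleast_2d(np.asarray(contrast, dtype=float))
    n_tracks, n_frames = contrast.shape
    window_frames = int(np.floor(window_s / frame_interval_s))
    if washout_frame + 1 > n_frames:
        raise ValueError("series must cover treatment and washout")

    dispersal: list[float | None] = []
    recovered: list[bool] = []
    for series in contrast:
        post = np.nonzero(series[treat_frame:] < contrast_threshold)[0]
        if post.size == 0:
            dispersal.append(None)
            recovered.append(False)
            continue
        dispersal.append(float(post[0] * frame_interval_s))
        stop = min(n_frames, washout_frame + window_frames + 1)
        rec = series[washout_frame:stop]
        # a genuine re-cross: below threshold at some point in the window,
        # then at or above it afterwards
        below = np.nonzero(rec < contrast_threshold)[0]
        recovered.append(
            bool(below.size and np.any(rec[below[0]:] >= contrast_threshold))
        )
    n_disp = sum(d is not None for d in dispersal)
    n_rec = sum(r for d, r in zip(dispersal, recovered) if d is not None)
    frac = n_rec / n_disp if n_disp else float("nan")
    return PerturbationResult(
        dispersal_times_s=tuple(dispersal),
        recovered=tuple(recovered),
        recovered_fraction=frac,
        n_dispersed=n_disp,
    )
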