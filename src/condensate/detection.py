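"""Condensate segmentation, frame-to-frame linking, and event calling.

Segmentation: Laplacian-of-Gaussian blob seeds, grown to the half-max contour
around each seed; the nuclear background is the median intensity of the
nucleus mask (Otsu on a heavily smoothed copy) outside detected blobs.

Linking: greedy nearest-neighbour, closest pair first, each detection used at
most once, links beyond ``gate_um`` rejected. Ties are broken by track id and
then by detection centroid, so the result is invariant to input ordering.

Events: a fusion is called at frame ``t`` when the terminating parent
track(s) at ``t - 1`` lie within ``proximity_um`` of a child present at ``t``
whose area matches the summed parent areas within ``area_tolerance``;
a fission is the time mirror. Because greedy linking lets the merged blob
continue one parent's track, both the two-parents-end/child-starts and the
one-parent-ends/child-continues signatures are recognized.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .io_formats import TimelapseStack

__all__ = [
    "Condensate",
    "Track",
    "EventRecord",
    "segment_frame",
    "segment_stack",
    "link_tracks",
    "detect_events",
]


@dataclass(frozen=True)
class Condensate:
    """One segmented condensate in one frame."""

    frame: int
    centroid_px: tuple[float, float]  # (x, y)
    area_px: int
    equivalent_diameter_um: float
    mean_intensity: float
    contrast: float


@dataclass
class Track:
    """A condensate followed over frames (strictly increasing)."""

    track_id: int
    condensates: list[Condensate] = field(default_factory=list)

    @property
    def first_frame(self) -> int:
        return self.condensates[0].frame

    @property
    def last_frame(self) -> int:
        return self.condensates[-1].frame

    def at(self, frame: int) -> Condensate | None:
        for c in self.condensates:
            if c.frame == frame:
                return c
        return None

    def __len__(self) -> int:
        return len(self.condensates)


@dataclass(frozen=True)
class EventRecord:
    """A detected fusion (2 parents, 1 child) or fission (1 parent, 2 children)."""

    kind: str  # "fusion" | "fission"
    frame: int
    parent_track_ids: tuple[int, ...]
    child_track_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind == "fusion" and (len(self.parent_track_ids), len(self.child_track_ids)) != (2, 1):
            raise ValueError("fusion needs 2 parents and 1 child")
        if self.kind == "fission" and (len(self.parent_track_ids), len(self.child_track_ids)) != (1, 2):
            raise ValueError("fission needs 1 parent and 2 children")
        if self.kind not in ("fusion", "fission"):
            raise ValueError(f"unknown event kind {self.kind!r}")


def _nuclear_background(img: np.ndarray, blob_mask: np.ndarray) -> float:
    """Median of the nucleus mask outside detected blobs, with fallbacks."""
    smooth = ndimage.gaussian_filter(img, max(img.shape) / 8.0)
    nucleus = np.ones_like(img, dtype=bool)
    if smooth.max() - smooth.min() > 1e-12:
        try:
            nucleus = smooth > threshold_otsu(smooth)
        except ValueError:  # pragma: no cover - degenerate histogram
            pass
        frac = nucleus.mean()
        if frac < 0.01 or frac > 0.99:
            nucleus = np.ones_like(img, dtype=bool)
    sel = nucleus & ~blob_mask
    if not sel.any():
        sel = ~blob_mask
    if not sel.any():  # pragma: no cover - blobs covering the whole frame
        sel = np.ones_like(img, dtype=bool)
    return float(np.median(img[sel]))


def segment_frame(
    image: np.ndarray,
    pixel_size_um: float,
    *,
    frame: int = 0,
    sigma_range: tuple[float, float] = (1.0, 4.0),
    num_sigma: int = 5,
    contrast_min: float = 1.5,
    min_area_px: int = 4,
    blob_threshold: float = 0.05,
) -> list[Condensate]:
    """Segment disk-like condensates in a single-channel 2-D image.

    Returns an empty list (not an error) when the image carries no contrast.
    Centroids are intensity-weighted (above background) and sub-pixel.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_frame expects a single-channel 2-D image")
    span = img.max() - img.min()
    if span <= 0:
        return []
    norm = (img - img.min()) / span
    blobs = blob_log(
        norm,
        min_sigma=sigma_range[0],
        max_sigma=sigma_range[1],
        num_sigma=num_sigma,
        threshold=blob_threshold,
    )
    if len(blobs) == 0:
        return []

    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    blob_mask = np.zeros_like(img, dtype=bool)
    for by, bx, bs in blobs:
        r = 2.0 * bs * np.sqrt(2)
        blob_mask |= (xx - bx) ** 2 + (yy - by) ** 2 <= r**2
    background = _nuclear_background(img, blob_mask)

    found: dict[int, Condensate] = {}
    for by, bx, bs in blobs:
        r_seed = max(bs * np.sqrt(2), 2.0)
        local = (xx - bx) ** 2 + (yy - by) ** 2 <= r_seed**2
        peak = img[local].max()
        if peak <= background:
            continue
        level = background + 0.5 * (peak - background)
        labels = sk_label(img >= level)
        seed_labels = labels[local & (img >= level)]
        seed_labels = seed_labels[seed_labels > 0]
        if seed_labels.size == 0:
            continue
        lab = int(np.bincount(seed_labels).argmax())
        if lab in found:
            continue
        region = labels == lab
        area = int(region.sum())
        if area < min_area_px:
            continue
        mean_int = float(img[region].mean())
        contrast = mean_int / background if background > 0 else np.inf
        if contrast < contrast_min:
            continue
        weights = img[region] - background
        cx = float(np.average(xx[region], weights=weights))
        cy = float(np.average(yy[region], weights=weights))
        found[lab] = Condensate(
            frame=frame,
            centroid_px=(cx, cy),
            area_px=area,
            equivalent_diameter_um=float(np.sqrt(4.0 * area / np.pi) * pixel_size_um),
            mean_intensity=mean_int,
            contrast=float(contrast),
        )
    return sorted(found.values(), key=lambda c: c.centroid_px)


def segment_stack(stack: TimelapseStack, *, channel: int = 0, **params) -> list[Condensate]:
    """Segment every frame of one channel; returns a flat detection list."""
    out: list[Condensate] = []
    for k in range(stack.n_frames):
        out.extend(
            segment_frame(stack.data[k, channel], stack.meta.pixel_size_um, frame=k, **params)
        )
    return out


def link_tracks(
    detections: list[Condensate],
    gate_um: float,
    pixel_size_um: float,
    *,
    max_gap: int = 1,
) -> list[Track]:
    """Greedy nearest-neighbour linking of per-frame detections into tracks.

    Candidate links between active track ends and new detections are taken
    closest-distance-first; each side is used once; links beyond ``gate_um``
    are rejected and unlinked detections start new tracks. ``max_gap`` is the
    largest allowed frame difference along a track (1 = consecutive frames).
    """
    if gate_um <= 0 or max_gap < 1:
        raise ValueError("gate_um must be > 0 and max_gap >= 1")
    by_frame: dict[int, list[Condensate]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)
    tracks: list[Track] = []
    active: list[Track] = []
    for f in sorted(by_frame):
        dets = sorted(by_frame[f], key=lambda c: c.centroid_px)
        active = [tr for tr in active if f - tr.last_frame <= max_gap]
        candidates = []
        for tr in active:
            end = tr.condensates[-1]
            for j, det in enumerate(dets):
                d_um = (
                    np.hypot(
                        det.centroid_px[0] - end.centroid_px[0],
                        det.centroid_px[1] - end.centroid_px[1],
                    )
                    * pixel_size_um
                )
                if d_um <= gate_um:
                    candidates.append((d_um, tr.track_id, det.centroid_px, tr, j))
        taken_tracks: set[int] = set()
        taken_dets: set[int] = set()
        for d_um, tid, _c, tr, j in sorted(candidates, key=lambda c: c[:3]):
            if tid in taken_tracks or j in taken_dets:
                continue
            tr.condensates.append(dets[j])
            taken_tracks.add(tid)
            taken_dets.add(j)
        for j, det in enumerate(dets):
            if j not in taken_dets:
                tr = Track(track_id=len(tracks), condensates=[det])
                tracks.append(tr)
                active.append(tr)
    return tracks


def _dist_um(a: Condensate, b: Condensate, pixel_size_um: float) -> float:
    return float(
        np.hypot(a.centroid_px[0] - b.centroid_px[0], a.centroid_px[1] - b.centroid_px[1])
        * pixel_size_um
    )


def detect_events(
    tracks: list[Track],
    proximity_um: float,
    pixel_size_um: float,
    *,
    area_tolerance: float = 0.25,
) -> list[EventRecord]:
    """Call fusion and fission events from linked tracks.

    Each track participates in at most one event per frame. The conservation
    check requires the child area within ``area_tolerance`` of the summed
    parent areas (mirrored for fissions).
    """
    if not tracks:
        return []
    frames = sorted({c.frame for tr in tracks for c in tr.condensates})
    events: list[EventRecord] = []

    def area_ok(child: float, parents: float) -> bool:
        return abs(child - parents) <= area_tolerance * parents

    for t in frames[1:]:
        used: set[int] = set()
        ended = sorted(
            (tr for tr in tracks if tr.last_frame == t - 1), key=lambda tr: tr.track_id
        )
        started = sorted(
            (tr for tr in tracks if tr.first_frame == t), key=lambda tr: tr.track_id
        )
        present = sorted(
            (tr for tr in tracks if tr.at(t) is not None), key=lambda tr: tr.track_id
        )
        # --- fusions -------------------------------------------------------
        for tr in present:
            if tr.track_id in used:
                continue
            c_t = tr.at(t)
            near = [
                e
                for e in ended
                if e.track_id != tr.track_id
                and e.track_id not in used
                and _dist_um(e.condensates[-1], c_t, pixel_size_um) <= proximity_um
            ]
            c_prev = tr.at(t - 1)
            if c_prev is not None:
                # merged blob continued this track; one partner ended
                best = None
                for e in near:
                    total = c_prev.area_px + e.condensates[-1].area_px
                    if area_ok(c_t.area_px, total):
                        miss = abs(c_t.area_px - total)
                        if best is None or miss < best[0]:
                            best = (miss, e)
                if best is not None:
                    e = best[1]
                    events.append(
                        EventRecord(
                            kind="fusion",
                            frame=t,
                            parent_track_ids=tuple(sorted((e.track_id, tr.track_id))),
                            child_track_ids=(tr.track_id,),
                        )
                    )
                    used.update((e.track_id, tr.track_id))
            elif tr.first_frame == t:
                best = None
                for e1, e2 in itertools.combinations(near, 2):
                    total = e1.condensates[-1].area_px + e2.condensates[-1].area_px
                    if area_ok(c_t.area_px, total):
                        miss = abs(c_t.area_px - total)
                        if best is None or miss < best[0]:
                            best = (miss, e1, e2)
                if best is not None:
                    _, e1, e2 = best
                    events.append(
                        EventRecord(
                            kind="fusion",
                            frame=t,
                            parent_track_ids=tuple(sorted((e1.track_id, e2.track_id))),
                            child_track_ids=(tr.track_id,),
                        )
                    )
                    used.update((e1.track_id, e2.track_id, tr.track_id))
        # --- fissions (time mirror) ---------------------------------------
        for tr in tracks:
            if tr.track_id in used or tr.at(t - 1) is None:
                continue
            c_prev = tr.at(t - 1)
            near_started = [
                s
                for s in started
                if s.track_id != tr.track_id
                and s.track_id not in used
                and _dist_um(s.condensates[0], c_prev, pixel_size_um) <= proximity_um
            ]
            c_t = tr.at(t)
            if c_t is not None:
                best = None
                for s in near_started:
                    total = c_t.area_px + s.condensates[0].area_px
                    if area_ok(total, c_prev.area_px):
                        miss = abs(total - c_prev.area_px)
                        if best is None or miss < best[0]:
                            best = (miss, s)
                if best is not None:
                    s = best[1]
                    events.append(
                        EventRecord(
                            kind="fission",
                            frame=t,
                            parent_track_ids=(tr.track_id,),
                            child_track_ids=tuple(sorted((tr.track_id, s.track_id))),
                        )
                    )
                    used.update((tr.track_id, s.track_id))
            elif tr.last_frame == t - 1:
                best = None
                for s1, s2 in itertools.combinations(near_started, 2):
                    total = s1.condensates[0].area_px + s2.condensates[0].area_px
                    if area_ok(total, c_prev.area_px):
                        miss = abs(total - c_prev.area_px)
                        if best is None or miss < best[0]:
                            best = (miss, s1, s2)
                if best is not None:
                    _, s1, s2 = best
                    events.append(
                        EventRecord(
                            kind="fission",
                            frame=t,
                            parent_track_ids=(tr.track_id,),
                            child_track_ids=tuple(sorted((s1.track_id, s2.track_id))),
                        )
                    )
                    used.update((tr.track_id, s1.track_id, s2.track_id))
    return events
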