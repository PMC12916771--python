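"""Leukocyte motion analysis.

Detection is threshold + connected components with a size filter; linking is
greedy mutual-nearest-neighbor under a per-frame displacement gate, with a
centroid-extrapolation fallback that re-assigns identities across short
detection gaps ("ghost" repair). Amoeboid cells get a hybrid mode that
matches by footprint overlap first and falls back to centroids. Still-image
leukocyte counting follows a blur-subtract-median-find-maxima recipe with a
prominence criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from ._morph import drop_small
from .stack import FrameStack

__all__ = [
    "Detection",
    "CellTrack",
    "RoseHistogram",
    "detect_cells",
    "link_nn",
    "ghost_reassign",
    "link_hybrid",
    "filter_and_summarize",
    "count_spots",
]


@dataclass
class Detection:
    frame: int
    centroid_um: tuple[float, float]  # (y, x)
    area_px: float
    polygon_px: np.ndarray | None = None  # (N, 2) outline vertices, (row, col)
    pixel_idx: frozenset = frozenset()  # raveled pixel indices, for IoU

    def iou(self, other: "Detection") -> float:
        if not self.pixel_idx or not other.pixel_idx:
            return 0.0
        inter = len(self.pixel_idx & other.pixel_idx)
        union = len(self.pixel_idx | other.pixel_idx)
        return inter / union if union else 0.0


@dataclass
class CellTrack:
    track_id: int
    detections: list[Detection] = field(default_factory=list)
    ghost_repaired: bool = False
    contact_flagged: bool = False

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    @property
    def centroids(self) -> np.ndarray:
        return np.asarray([d.centroid_um for d in self.detections])

    @property
    def net_displacement(self) -> float:
        """|last centroid - first centroid| in µm."""
        if len(self.detections) < 2:
            return 0.0
        c = self.centroids
        return float(np.hypot(*(c[-1] - c[0])))

    def step_vectors(self) -> np.ndarray:
        return np.diff(self.centroids, axis=0)

    def last_velocity(self) -> np.ndarray:
        """Displacement per frame over the last step (µm/frame)."""
        if len(self.detections) < 2:
            return np.zeros(2)
        d0, d1 = self.detections[-2], self.detections[-1]
        gap = d1.frame - d0.frame
        return (np.asarray(d1.centroid_um) - np.asarray(d0.centroid_um)) / max(gap, 1)


@dataclass
class RoseHistogram:
    bin_edges: np.ndarray  # radians, length n_bins + 1
    counts: np.ndarray

    @property
    def n_steps(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_cells(
    stack: FrameStack,
    channel: int | str = 1,
    min_size: int = 20,
    threshold: float | None = None,
) -> list[list[Detection]]:
    """Per-frame cell detections: Otsu (or fixed) threshold, components, size filter."""
    c = stack.channel_index(channel)
    pix = stack.pixels[:, c]
    if stack.has_z:
        pix = pix.max(axis=1)
    out: list[list[Detection]] = []
    width = stack.frame_shape[1]
    for k, frame in enumerate(pix):
        if threshold is None:
            if np.ptp(frame) == 0:
                out.append([])
                continue
            thr = filters.threshold_otsu(frame)
        else:
            thr = threshold
        mask = frame > thr
        mask = drop_small(mask, min_size)
        labels = measure.label(mask)
        dets = []
        for p in measure.regionprops(labels):
            contours = measure.find_contours(labels == p.label, 0.5)
            poly = max(contours, key=len) if contours else None
            rows, cols = np.nonzero(labels == p.label)
            dets.append(
                Detection(
                    frame=k,
                    centroid_um=(
                        p.centroid[0] * stack.pixel_size,
                        p.centroid[1] * stack.pixel_size,
                    ),
                    area_px=float(p.area),
                    polygon_px=poly,
                    pixel_idx=frozenset((rows * width + cols).tolist()),
                )
            )
        out.append(dets)
    return out


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _greedy_mutual_matches(cost: np.ndarray, gate: float) -> list[tuple[int, int]]:
    """Repeatedly take the global minimum of the cost matrix under the gate."""
    if cost.size == 0:
        return []
    cost = cost.astype(float).copy()
    matches = []
    while np.isfinite(cost).any():
        i, j = np.unravel_index(np.argmin(cost), cost.shape)
        if cost[i, j] > gate:
            break
        matches.append((int(i), int(j)))
        cost[i, :] = np.inf
        cost[:, j] = np.inf
    return matches


def link_nn(
    detections: list[list[Detection]], max_dist: float
) -> list[CellTrack]:
    """Frame-to-frame greedy mutual-nearest-neighbor linking (gate in µm/frame)."""
    if len(detections) < 2:
        raise ValueError("linking needs >= 2 frames")
    tracks: list[CellTrack] = []
    active: list[CellTrack] = []
    next_id = 0

    def start(det: Detection) -> CellTrack:
        nonlocal next_id
        tr = CellTrack(track_id=next_id, detections=[det])
        next_id += 1
        tracks.append(tr)
        return tr

    for det in detections[0]:
        active.append(start(det))

    for k in range(1, len(detections)):
        dets = detections[k]
        if active and dets:
            prev_pts = np.asarray([tr.detections[-1].centroid_um for tr in active])
            cur_pts = np.asarray([d.centroid_um for d in dets])
            cost = np.hypot(
                prev_pts[:, None, 0] - cur_pts[None, :, 0],
                prev_pts[:, None, 1] - cur_pts[None, :, 1],
            )
            matches = _greedy_mutual_matches(cost, max_dist)
        else:
            matches = []
        matched_tracks, matched_dets = set(), set()
        for i, j in matches:
            active[i].detections.append(dets[j])
            matched_tracks.add(i)
            matched_dets.add(j)
        new_active = [tr for i, tr in enumerate(active) if i in matched_tracks]
        for j, det in enumerate(dets):
            if j not in matched_dets:
                new_active.append(start(det))
        active = new_active
    return tracks


def ghost_reassign(
    tracks: list[CellTrack],
    max_dist: float,
    gap_max: int = 2,
    radius_factor: float = 1.5,
) -> list[CellTrack]:
    """Merge a track ending at frame f with one starting at f+g (g <= gap_max).

    The candidate start centroid must lie within ``radius_factor * max_dist``
    of the ended track's position extrapolated at its last velocity. Ties:
    smallest extrapolated distance, then lower track_id. Merged tracks keep
    the earlier identity and are flagged ``ghost_repaired``.
    """
    tracks = sorted(tracks, key=lambda tr: tr.track_id)
    merged_away: set[int] = set()
    gate = radius_factor * max_dist

    changed = True
    while changed:
        changed = False
        for tr in tracks:
            if tr.track_id in merged_away:
                continue
            end_frame = tr.detections[-1].frame
            end_pos = np.asarray(tr.detections[-1].centroid_um)
            vel = tr.last_velocity()
            best: tuple[float, int, CellTrack] | None = None
            for cand in tracks:
                if cand.track_id == tr.track_id or cand.track_id in merged_away:
                    continue
                gap = cand.detections[0].frame - end_frame
                if not 1 <= gap <= gap_max:
                    continue
                predicted = end_pos + vel * gap
                dist = float(np.hypot(*(np.asarray(cand.detections[0].centroid_um) - predicted)))
                if dist <= gate:
                    key = (dist, cand.track_id)
                    if best is None or key < (best[0], best[1]):
                        best = (dist, cand.track_id, cand)
            if best is not None:
                _, _, cand = best
                tr.detections.extend(cand.detections)
                tr.ghost_repaired = True
                merged_away.add(cand.track_id)
                changed = True
    return [tr for tr in tracks if tr.track_id not in merged_away]


def link_hybrid(
    detections: list[list[Detection]],
    max_dist: float,
    iou_min: float = 0.3,
    gap_max: int = 2,
    radius_factor: float = 1.5,
) -> list[CellTrack]:
    """Polygon-overlap-first linking for amoeboid cells.

    Frame-to-frame matches are made by footprint IoU >= ``iou_min``
    (inclusive); leftovers fall back to centroid nearest-neighbor under
    ``max_dist``; ghost repair runs afterwards.
    """
    if len(detections) < 2:
        raise ValueError("linking needs >= 2 frames")
    tracks: list[CellTrack] = []
    active: list[CellTrack] = []
    next_id = 0

    def start(det: Detection) -> CellTrack:
        nonlocal next_id
        tr = CellTrack(track_id=next_id, detections=[det])
        next_id += 1
        tracks.append(tr)
        return tr

    for det in detections[0]:
        active.append(start(det))

    for k in range(1, len(detections)):
        dets = detections[k]
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        if active and dets:
            # primary: IoU (maximize => minimize negative IoU, gate at -iou_min)
            iou = np.asarray(
                [[tr.detections[-1].iou(d) for d in dets] for tr in active]
            )
            iou_matches = _greedy_mutual_matches(
                np.where(iou >= iou_min, -iou, np.inf), gate=-iou_min
            )
            for i, j in iou_matches:
                active[i].detections.append(dets[j])
                matched_tracks.add(i)
                matched_dets.add(j)
            # fallback: centroid NN on the residual
            rem_i = [i for i in range(len(active)) if i not in matched_tracks]
            rem_j = [j for j in range(len(dets)) if j not in matched_dets]
            if rem_i and rem_j:
                prev_pts = np.asarray(
                    [active[i].detections[-1].centroid_um for i in rem_i]
                )
                cur_pts = np.asarray([dets[j].centroid_um for j in rem_j])
                cost = np.hypot(
                    prev_pts[:, None, 0] - cur_pts[None, :, 0],
                    prev_pts[:, None, 1] - cur_pts[None, :, 1],
                )
                for a, b in _greedy_mutual_matches(cost, max_dist):
                    active[rem_i[a]].detections.append(dets[rem_j[b]])
                    matched_tracks.add(rem_i[a])
                    matched_dets.add(rem_j[b])
        new_active = [tr for i, tr in enumerate(active) if i in matched_tracks]
        for j, det in enumerate(dets):
            if j not in matched_dets:
                new_active.append(start(det))
        active = new_active

    return ghost_reassign(tracks, max_dist, gap_max=gap_max, radius_factor=radius_factor)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _shared_fraction(a: CellTrack, b: CellTrack) -> float:
    keys_a = {(d.frame, d.centroid_um) for d in a.detections}
    keys_b = {(d.frame, d.centroid_um) for d in b.detections}
    if not keys_a or not keys_b:
        return 0.0
    return len(keys_a & keys_b) / min(len(keys_a), len(keys_b))


def filter_and_summarize(
    tracks: list[CellTrack],
    wound_direction: tuple[float, float] = (0.0, 1.0),
    n_bins: int = 12,
    duplicate_overlap: float = 0.5,
):
    """Drop redundant fragments, summarize per-track motion, build a rose plot.

    Tracks sharing more than ``duplicate_overlap`` of their detections
    collapse onto the longer one. Step angles are measured relative to the
    supplied wound direction (0 rad = toward the wound).

    Returns ``(summaries: DataFrame, rose: RoseHistogram, kept_tracks)``.
    """
    import pandas as pd

    if not tracks:
        raise ValueError("no tracks to summarize")
    kept: list[CellTrack] = []
    for tr in sorted(tracks, key=len, reverse=True):
        if any(_shared_fraction(tr, other) > duplicate_overlap for other in kept):
            continue
        kept.append(tr)
    kept.sort(key=lambda tr: tr.track_id)

    ref = np.asarray(wound_direction, dtype=float)
    ref_angle = np.arctan2(ref[0], ref[1])  # (y, x) convention

    rows = []
    all_angles: list[float] = []
    for tr in kept:
        steps = tr.step_vectors()
        angles = np.arctan2(steps[:, 0], steps[:, 1]) - ref_angle if len(steps) else np.empty(0)
        angles = np.mod(angles + np.pi, 2 * np.pi) - np.pi
        all_angles.extend(angles.tolist())
        rows.append(
            {
                "track_id": tr.track_id,
                "n_detections": len(tr),
                "net_displacement_um": tr.net_displacement,
                "ghost_repaired": tr.ghost_repaired,
                "contact_flagged": tr.contact_flagged,
            }
        )
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(all_angles, bins=edges)
    return pd.DataFrame(rows), RoseHistogram(bin_edges=edges, counts=counts), kept


# ---------------------------------------------------------------------------
# still-image spot counting
# ---------------------------------------------------------------------------

def count_spots(
    image: np.ndarray,
    sigma: float = 50.0,
    median_radius: int = 5,
    prominence: float = 1950.0,
) -> tuple[int, np.ndarray]:
    """Count bright spots in a still image.

    Pipeline: subtract a Gaussian-blurred copy (background estimate), median
    filter, then keep strict local maxima standing out by at least
    ``prominence`` (h-maxima). The prominence value is on the 16-bit scale;
    rescale it proportionally for other bit depths.

    Returns ``(count, coordinates)`` with coordinates as (row, col) floats.
    """
    img = np.asarray(image, dtype=float)
    background = ndimage.gaussian_filter(img, sigma=sigma)
    subtracted = img - background
    filtered = ndimage.median_filter(subtracted, footprint=morphology.disk(median_radius))
    if np.ptp(filtered) == 0:
        return 0, np.empty((0, 2))
    # h-maxima: regional maxima whose height above the surrounding saddle
    # is at least `prominence`
    shifted = filtered - filtered.min()
    peaks_mask = morphology.h_maxima(shifted, h=prominence)
    labels = measure.label(peaks_mask)
    coords = np.asarray(
        [p.centroid for p in measure.regionprops(labels)], dtype=float
    ).reshape(-1, 2)
    return int(labels.max()), coords
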