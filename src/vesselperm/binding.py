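"""Nuclear-envelope reporter translocation quantification.

The read-out is the ratio of reporter intensity at the nuclear rim to the
nucleoplasm interior. Nuclei are segmented per frame (Gaussian smoothing,
rolling-ball background subtraction, Otsu, marker-based watershed), tracked
by nearest-centroid linking, converted to per-nucleus binding curves
normalized to their first timepoint, and the propagation speed of the
translocation wave is recovered by regressing per-nucleus onset times on
distance from the wound origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt
from scipy import ndimage
from skimage import feature, filters, measure, restoration, segmentation

from ._morph import binary_erode, drop_small
from .leakage import ROISpec
from .stack import FrameStack

__all__ = [
    "NucleusTrack",
    "BindingCurve",
    "WaveFit",
    "segment_nuclei",
    "rim_nucleoplasm_ratio",
    "track_nuclei",
    "binding_curve",
    "line_profile",
    "detect_onset",
    "estimate_wave_speed",
]

#: nuclei closer to the wound than this show constitutive binding and are
#: excluded from wave fitting (µm)
MIN_WAVE_DISTANCE_UM = 30.0


@dataclass
class NucleusTrack:
    nucleus_id: int
    frames: list[int] = field(default_factory=list)
    times: list[float] = field(default_factory=list)  # s
    centroids_um: list[tuple[float, float]] = field(default_factory=list)
    areas_px: list[float] = field(default_factory=list)
    rim_means: list[float] = field(default_factory=list)
    nucleoplasm_means: list[float] = field(default_factory=list)
    ratios: list[float] = field(default_factory=list)
    continuous: bool = True

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class BindingCurve:
    times: np.ndarray  # s
    normalized_ratio: np.ndarray  # ratio(t)/ratio(t0)
    peak: float
    peak_time: float


@dataclass
class WaveFit:
    speed: float | None  # µm/s; None when undefined
    intercept: float | None  # s
    r_squared: float | None
    n_nuclei: int
    distances: np.ndarray
    onsets: np.ndarray
    diagnostic: str = ""


# ---------------------------------------------------------------------------
# segmentation and per-nucleus measurement
# ---------------------------------------------------------------------------

def _segment_frame(
    image: np.ndarray,
    sigma: float,
    rolling_ball_radius: float,
    min_size: int,
    marker_min_distance: int,
) -> np.ndarray:
    smoothed = filters.gaussian(image.astype(float), sigma=sigma, preserve_range=True)
    if rolling_ball_radius > 0:
        smoothed = smoothed - restoration.rolling_ball(
            smoothed, radius=rolling_ball_radius
        )
    if np.ptp(smoothed) == 0:
        return np.zeros(image.shape, dtype=np.int32)
    mask = smoothed > filters.threshold_otsu(smoothed)
    mask = drop_small(mask, min_size)
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32)
    distance = ndimage.distance_transform_edt(mask)
    peaks = feature.peak_local_max(
        distance, min_distance=marker_min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    if markers.max() == 0:
        return measure.label(mask).astype(np.int32)
    labels = segmentation.watershed(-distance, markers, mask=mask)
    labels = drop_small(labels, min_size)
    return labels.astype(np.int32)


def segment_nuclei(
    stack: FrameStack,
    reporter_channel: int | str = 1,
    sigma: float = 2.0,
    rolling_ball_radius: float = 50.0,
    min_size: int = 30,
    marker_min_distance: int = 7,
) -> list[np.ndarray]:
    """Per-frame nucleus label masks from the reporter channel.

    For 3-D stacks the middle z-slice is used per frame. An empty labeling
    is returned with a warning, not an error.
    """
    c = stack.channel_index(reporter_channel)
    pix = stack.pixels[:, c]
    if stack.has_z:
        pix = pix[:, pix.shape[1] // 2]
    masks = [
        _segment_frame(frame, sigma, rolling_ball_radius, min_size, marker_min_distance)
        for frame in pix
    ]
    if all(m.max() == 0 for m in masks):
        warnings.warn("no nuclei found in any frame", stacklevel=2)
    return masks


def rim_nucleoplasm_ratio(
    label_mask: np.ndarray,
    reporter_image: np.ndarray,
    nucleus_id: int,
    r_rim: int = 2,
    r_core: int = 3,
) -> tuple[float, float, float]:
    """(rim_mean, nucleoplasm_mean, ratio) for one labeled nucleus.

    Rim: ring between the mask boundary and the mask eroded by ``r_rim`` px.
    Nucleoplasm: the mask eroded by ``r_core`` px. Nuclei whose interior
    vanishes after erosion raise ValueError (caller drops them).
    """
    mask = label_mask == nucleus_id
    if not mask.any():
        raise ValueError(f"nucleus {nucleus_id} not present in mask")
    rim_interior = binary_erode(mask, r_rim)
    core = binary_erode(mask, r_core)
    rim = mask & ~rim_interior
    if not core.any() or not rim.any():
        raise ValueError(f"nucleus {nucleus_id} too small for rim/core geometry")
    rim_mean = float(reporter_image[rim].mean())
    core_mean = float(reporter_image[core].mean())
    if core_mean <= 0:
        raise ValueError("nucleoplasm mean must be positive")
    return rim_mean, core_mean, rim_mean / core_mean


def track_nuclei(
    label_masks: list[np.ndarray],
    reporter_images: list[np.ndarray] | np.ndarray,
    pixel_size: float,
    frame_interval: float,
    max_displacement_um: float = 10.0,
    r_rim: int = 2,
    r_core: int = 3,
) -> list[NucleusTrack]:
    """Nearest-centroid linking of segmented nuclei across frames.

    Tracks not spanning every frame are flagged ``continuous=False`` (the
    population-curve stage excludes them). Unlinkable objects simply start
    new (discontinuous) tracks.
    """
    n_frames = len(label_masks)
    if n_frames < 2:
        raise ValueError("tracking needs at least 2 frames")

    per_frame: list[list[dict]] = []
    for k in range(n_frames):
        props = measure.regionprops(label_masks[k])
        objs = []
        for p in props:
            try:
                rim, core, ratio = rim_nucleoplasm_ratio(
                    label_masks[k], np.asarray(reporter_images[k]), p.label, r_rim, r_core
                )
            except ValueError:
                continue  # dropped: too small for the geometry
            objs.append(
                {
                    "centroid_um": (p.centroid[0] * pixel_size, p.centroid[1] * pixel_size),
                    "area": float(p.area),
                    "rim": rim,
                    "core": core,
                    "ratio": ratio,
                }
            )
        per_frame.append(objs)

    tracks: list[NucleusTrack] = []
    active: dict[int, NucleusTrack] = {}  # track id -> track (present in prev frame)
    next_id = 0

    def start(obj: dict, k: int) -> None:
        nonlocal next_id
        tr = NucleusTrack(nucleus_id=next_id)
        _append(tr, obj, k)
        active[next_id] = tr
        tracks.append(tr)
        next_id += 1

    def _append(tr: NucleusTrack, obj: dict, k: int) -> None:
        tr.frames.append(k)
        tr.times.append(k * frame_interval)
        tr.centroids_um.append(obj["centroid_um"])
        tr.areas_px.append(obj["area"])
        tr.rim_means.append(obj["rim"])
        tr.nucleoplasm_means.append(obj["core"])
        tr.ratios.append(obj["ratio"])

    for obj in per_frame[0]:
        start(obj, 0)

    for k in range(1, n_frames):
        objs = per_frame[k]
        prev = list(active.items())
        matches = _mutual_nearest(
            [tr.centroids_um[-1] for _, tr in prev],
            [o["centroid_um"] for o in objs],
            max_displacement_um,
        )
        new_active: dict[int, NucleusTrack] = {}
        matched_objs = set()
        for i, j in matches:
            tid, tr = prev[i]
            _append(tr, objs[j], k)
            new_active[tid] = tr
            matched_objs.add(j)
        for j, obj in enumerate(objs):
            if j not in matched_objs:
                start(obj, k)
                # freshly started mid-movie tracks live in `active` via start();
                # collect them into the new active set
        for tid, tr in list(active.items()):
            if tid not in new_active and tr.frames and tr.frames[-1] == k:
                new_active[tid] = tr
        active = new_active

    for tr in tracks:
        tr.continuous = len(tr.frames) == n_frames
    return tracks


def _mutual_nearest(
    points_a: list[tuple[float, float]],
    points_b: list[tuple[float, float]],
    max_dist: float,
) -> list[tuple[int, int]]:
    """Greedy mutual-nearest-neighbor matching under a distance gate."""
    if not points_a or not points_b:
        return []
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
    matches = []
    d = d.copy()
    while True:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > max_dist or not np.isfinite(d[i, j]):
            break
        matches.append((int(i), int(j)))
        d[i, :] = np.inf
        d[:, j] = np.inf
        if np.isinf(d).all():
            break
    return matches


# ---------------------------------------------------------------------------
# binding curves and wave speed
# ---------------------------------------------------------------------------

def binding_curve(
    track_or_ratio,
    times: np.ndarray | None = None,
    smooth_window: int | None = None,
) -> BindingCurve:
    """Ratio trace normalized to its first timepoint, with peak statistics.

    Accepts a continuous :class:`NucleusTrack` or a raw ratio array plus
    times. Optional median smoothing (edge-preserving); off by default since
    a window-3 median erases single-frame peaks.
    """
    if isinstance(track_or_ratio, NucleusTrack):
        track = track_or_ratio
        if not track.continuous:
            raise ValueError("binding_curve requires a continuous track")
        ratio = np.asarray(track.ratios, dtype=float)
        times = np.asarray(track.times, dtype=float)
    else:
        ratio = np.asarray(track_or_ratio, dtype=float)
        if times is None:
            raise ValueError("times required when passing a raw ratio array")
        times = np.asarray(times, dtype=float)
    if ratio[0] <= 0:
        raise ValueError("initial ratio must be positive for normalization")
    norm = ratio / ratio[0]
    if smooth_window is not None:
        if smooth_window % 2 == 0:
            raise ValueError("median window must be odd")
        norm = medfilt(norm, kernel_size=smooth_window)
    k = int(np.argmax(norm))
    return BindingCurve(
        times=times, normalized_ratio=norm, peak=float(norm[k]), peak_time=float(times[k])
    )


def line_profile(
    image: np.ndarray, line: ROISpec, pixel_size: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear-interpolated intensity profile along a line ROI.

    Returns (positions µm, intensities) sampled at unit-pixel steps.
    """
    if line.kind != "line":
        raise ValueError("line_profile takes a line ROI")
    line.check_bounds(image.shape)
    y0, x0, y1, x1 = line.coordinates
    values = measure.profile_line(
        np.asarray(image, dtype=float), (y0, x0), (y1, x1), linewidth=1, order=1,
        mode="reflect",
    )
    positions = np.arange(len(values)) * pixel_size
    return positions, values


def detect_onset(curve: BindingCurve, min_amplitude: float = 0.05) -> float | None:
    """Half-rise onset: first crossing of ``1 + 0.5 * (peak - 1)``.

    The crossing is located with linear interpolation between frames; None
    if the curve never rises by more than ``min_amplitude``.
    """
    if curve.peak - 1.0 <= min_amplitude:
        return None
    threshold = 1.0 + 0.5 * (curve.peak - 1.0)
    above = curve.normalized_ratio >= threshold
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    k = int(idx[0])
    if k == 0:
        return float(curve.times[0])
    t0, t1 = curve.times[k - 1], curve.times[k]
    v0, v1 = curve.normalized_ratio[k - 1], curve.normalized_ratio[k]
    if v1 == v0:
        return float(t1)
    frac = (threshold - v0) / (v1 - v0)
    return float(t0 + frac * (t1 - t0))


def estimate_wave_speed(
    curves: list[BindingCurve],
    distances: np.ndarray,
    min_distance_um: float = MIN_WAVE_DISTANCE_UM,
    min_amplitude: float = 0.05,
) -> WaveFit:
    """Fit per-nucleus onset times against wound distance: onset = a + d / v.

    Nuclei closer than ``min_distance_um`` (constitutive binding) or without
    a detected onset are excluded. Requires >= 3 usable nuclei; a
    non-positive slope yields an undefined speed with a diagnostic.
    """
    distances = np.asarray(distances, dtype=float)
    if len(curves) != len(distances):
        raise ValueError("curves and distances length mismatch")
    d_list, t_list = [], []
    for curve, d in zip(curves, distances):
        if d < min_distance_um:
            continue
        onset = detect_onset(curve, min_amplitude=min_amplitude)
        if onset is not None:
            d_list.append(d)
            t_list.append(onset)
    d_arr = np.asarray(d_list)
    t_arr = np.asarray(t_list)
    if len(d_arr) < 3:
        raise ValueError(f"wave fit needs >= 3 nuclei with onsets, got {len(d_arr)}")

    slope, intercept = np.polyfit(d_arr, t_arr, 1)
    predicted = intercept + slope * d_arr
    ss_res = float(np.sum((t_arr - predicted) ** 2))
    ss_tot = float(np.sum((t_arr - t_arr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    # speed only when the slope is significantly positive: > 2 standard
    # errors, and the implied onset spread across the field is non-degenerate
    d_span = float(d_arr.max() - d_arr.min())
    if len(d_arr) > 2 and d_span > 0:
        se = np.sqrt(
            (ss_res / (len(d_arr) - 2)) / float(np.sum((d_arr - d_arr.mean()) ** 2))
        )
    else:
        se = np.inf
    significant = slope > 2 * se and slope * d_span > 1e-9
    if slope <= 0 or not significant:
        return WaveFit(
            speed=None,
            intercept=float(intercept),
            r_squared=r2,
            n_nuclei=len(d_arr),
            distances=d_arr,
            onsets=t_arr,
            diagnostic="non-positive onset-vs-distance slope; no propagating wave",
        )
    return WaveFit(
        speed=float(1.0 / slope),
        intercept=float(intercept),
        r_squared=r2,
        n_nuclei=len(d_arr),
        distances=d_arr,
        onsets=t_arr,
    )
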