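"""Seeded synthetic time-lapse generator with analytic ground truth.

Scenes are described by :class:`SceneSpec` and rendered into two-channel
stacks: channel 0 carries the vascular tracer (vessel band, perivascular and
wound leakage), channel 1 the reporter (nuclei with a rim-gain pulse, moving
cell blobs). All latent quantities needed by parameter-recovery tests are
computed in closed form from the spec, never from rendered pixels.

The leakage kinetics are a saturating exponential
``A * (1 - exp(-(t - t_switch)/tau))`` after the solution switch — the true
functional form is unknown; this choice is monotone-rise-then-plateau and
analytically integrable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .stack import FrameStack

__all__ = [
    "VesselBand",
    "LeakRegion",
    "NucleusSpec",
    "CellPath",
    "NoiseSpec",
    "SceneSpec",
    "GroundTruth",
    "make_scene",
    "blockade_pair",
    "render_movie",
    "render_spot_still",
    "binding_curves_from_scene",
    "amplitude_for_excess_auc",
    "saturating_rise",
]

PRESETS = (
    "hypo_wound",
    "iso_wound",
    "no_wound",
    "blockade_pair",
    "translocation_wave",
    "tracking_field",
    "spot_still",
)


def _plainify(obj):
    """Recursively convert numpy scalars/arrays to plain Python for YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def saturating_rise(t, t_switch: float, tau: float):
    """``1 - exp(-(t - t_switch)/tau)`` for t >= t_switch, else 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= t_switch, -np.expm1(-(t - t_switch) / tau), 0.0)
    return out if out.ndim else float(out)


def _rise_integral(t_switch: float, tau: float, t_end: float) -> float:
    """Closed-form integral of :func:`saturating_rise` over [t_switch, t_end]."""
    span = max(t_end - t_switch, 0.0)
    return span - tau * (1.0 - np.exp(-span / tau))


@dataclass
class VesselBand:
    """Horizontal bright band standing in for the caudal vessel."""

    y_center: float  # px
    width_px: float
    intensity: float
    dilation_amplitude: float = 0.0  # fractional widening at plateau
    dilation_tau: float = 120.0  # s

    def width_at(self, t, t_switch: float):
        return self.width_px * (
            1.0 + self.dilation_amplitude * saturating_rise(t, t_switch, self.dilation_tau)
        )


@dataclass
class LeakRegion:
    """Rectangle whose mean intensity rises after the switch."""

    top: int
    left: int
    height: int
    width: int
    baseline: float
    amplitude: float
    tau: float = 300.0  # s

    @property
    def rect(self) -> tuple[int, int, int, int]:
        return (self.top, self.left, self.height, self.width)

    def mean_excess_at(self, t, t_switch: float):
        return self.amplitude * saturating_rise(t, t_switch, self.tau)


@dataclass
class NucleusSpec:
    centroid_um: tuple[float, float]  # (y, x)
    radius_px: float = 8.0
    rim_gain: float = 2.0
    pulse_onset: float = 0.0  # s, absolute time
    pulse_duration: float = 10.0  # s
    rise_time: float = 2.0  # s
    rim_width_px: float = 2.0
    intensity: float = 100.0

    def pulse_at(self, t):
        """Trapezoidal pulse envelope in [0, 1]."""
        t = np.asarray(t, dtype=float)
        up = np.clip((t - self.pulse_onset) / max(self.rise_time, 1e-9), 0.0, 1.0)
        down = np.clip(
            (self.pulse_onset + self.pulse_duration + self.rise_time - t)
            / max(self.rise_time, 1e-9),
            0.0,
            1.0,
        )
        out = np.minimum(up, down)
        return out if out.ndim else float(out)


@dataclass
class CellPath:
    """Blob moving at constant speed through waypoints (µm)."""

    waypoints_um: list[tuple[float, float]]
    speed: float  # µm/s
    radius_px: float = 5.0
    intensity: float = 150.0

    def position_at(self, t: float) -> tuple[float, float]:
        pts = np.asarray(self.waypoints_um, dtype=float)
        if len(pts) == 1:
            return tuple(pts[0])
        seg = np.diff(pts, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        s = np.clip(self.speed * t, 0.0, cum[-1])
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg) - 1)
        frac = 0.0 if seg_len[i] == 0 else (s - cum[i]) / seg_len[i]
        p = pts[i] + frac * seg[i]
        return (float(p[0]), float(p[1]))


@dataclass
class NoiseSpec:
    photon_scale: float = 0.0  # photons per intensity unit; 0 disables shot noise
    read_noise_sd: float = 0.0
    background_offset: float = 10.0


@dataclass
class SceneSpec:
    """Full description of a synthetic acquisition."""

    image_shape: tuple[int, int] = (128, 128)
    n_frames: int = 121
    frame_interval: float = 30.0  # s
    pixel_size: float = 0.65  # µm/px
    switch_frame: int = 10
    vessel: VesselBand | None = None
    wound_region: LeakRegion | None = None
    perivascular_region: LeakRegion | None = None
    nuclei: list[NucleusSpec] = field(default_factory=list)
    front_speed: float | None = None  # µm/s
    wound_origin_um: tuple[float, float] = (0.0, 0.0)
    cells: list[CellPath] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    drift_px: np.ndarray | None = None  # (n_frames, 2) of (dy, dx)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.front_speed is not None:
            self._apply_front_speed()
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        h, w = self.image_shape
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0 <= self.switch_frame < self.n_frames:
            raise ValueError("switch_frame must satisfy 0 <= switch_frame < n_frames")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")
        for region in (self.wound_region, self.perivascular_region):
            if region is None:
                continue
            if region.amplitude < 0 or region.baseline < 0:
                raise ValueError("region amplitudes must be >= 0")
            if (
                region.top < 0
                or region.left < 0
                or region.top + region.height > h
                or region.left + region.width > w
            ):
                raise ValueError(f"region {region.rect} outside image {self.image_shape}")
        if self.vessel is not None:
            if self.vessel.intensity < 0:
                raise ValueError("vessel intensity must be >= 0")
            max_w = self.vessel.width_px * (1 + max(self.vessel.dilation_amplitude, 0))
            if self.vessel.y_center - max_w / 2 < 0 or self.vessel.y_center + max_w / 2 > h:
                raise ValueError("vessel band (incl. dilation) outside image")
        if self.drift_px is not None:
            self.drift_px = np.asarray(self.drift_px, dtype=float)
            if self.drift_px.shape != (self.n_frames, 2):
                raise ValueError("drift_px must have shape (n_frames, 2)")
        if self.front_speed is not None and self.front_speed <= 0:
            raise ValueError("front_speed must be > 0")

    def _apply_front_speed(self) -> None:
        t_switch = self.switch_time
        origin = np.asarray(self.wound_origin_um, dtype=float)
        for nuc in self.nuclei:
            d = float(np.hypot(*(np.asarray(nuc.centroid_um) - origin)))
            nuc.pulse_onset = t_switch + d / self.front_speed

    # -- derived quantities -------------------------------------------------
    @property
    def switch_time(self) -> float:
        return self.switch_frame * self.frame_interval

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def nucleus_distances(self) -> np.ndarray:
        origin = np.asarray(self.wound_origin_um, dtype=float)
        if not self.nuclei:
            return np.empty(0)
        pts = np.asarray([n.centroid_um for n in self.nuclei], dtype=float)
        return np.hypot(pts[:, 0] - origin[0], pts[:, 1] - origin[1])

    # -- config round-trip --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.drift_px is not None:
            d["drift_px"] = self.drift_px.tolist()
        return _plainify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        if d.get("vessel") is not None:
            d["vessel"] = VesselBand(**d["vessel"])
        for key in ("wound_region", "perivascular_region"):
            if d.get(key) is not None:
                d[key] = LeakRegion(**d[key])
        d["nuclei"] = [
            NucleusSpec(**{**n, "centroid_um": tuple(n["centroid_um"])})
            for n in d.get("nuclei", [])
        ]
        d["cells"] = [
            CellPath(**{**c, "waypoints_um": [tuple(p) for p in c["waypoints_um"]]})
            for c in d.get("cells", [])
        ]
        if d.get("noise") is not None:
            d["noise"] = NoiseSpec(**d["noise"])
        d["image_shape"] = tuple(d["image_shape"])
        d["wound_origin_um"] = tuple(d["wound_origin_um"])
        if d.get("drift_px") is not None:
            d["drift_px"] = np.asarray(d["drift_px"], dtype=float)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SceneSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Latent scene parameters, computed analytically from the SceneSpec."""

    excess_auc_vessel: float = 0.0  # arb·s above the no-leakage baseline
    ib_end_true: float = 1.0
    max_dilation_true: float = 1.0
    front_speed_true: float | None = None
    nucleus_onsets: list[float] = field(default_factory=list)  # s
    nucleus_distances: list[float] = field(default_factory=list)  # µm
    cell_paths_um: np.ndarray | None = None  # (n_cells, n_frames, 2)
    spot_count: int = 0
    spot_coords: list[tuple[float, float]] = field(default_factory=list)
    sub_threshold_count: int = 0
    drift_px: np.ndarray | None = None

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("cell_paths_um", "drift_px"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def amplitude_for_excess_auc(
    target_auc: float,
    baseline: float,
    t_switch: float,
    tau: float,
    t_end: float,
) -> float:
    """Leak amplitude whose *normalized* excess AUC over [0, t_end] equals target.

    The normalized excess trace is ``(A / baseline) * rise(t)``; its analytic
    integral is ``(A / baseline) * integral(rise)``, so invert for A.
    """
    shape = _rise_integral(t_switch, tau, t_end)
    if shape <= 0:
        raise ValueError("no post-switch window to accumulate leakage")
    return baseline * target_auc / shape


def _scene_ground_truth(scene: SceneSpec) -> GroundTruth:
    gt = GroundTruth()
    t_end = scene.duration
    if scene.perivascular_region is not None and scene.perivascular_region.amplitude > 0:
        reg = scene.perivascular_region
        gt.excess_auc_vessel = (
            reg.amplitude / reg.baseline * _rise_integral(scene.switch_time, reg.tau, t_end)
        )
    if scene.wound_region is not None and scene.wound_region.baseline > 0:
        reg = scene.wound_region
        gt.ib_end_true = 1.0 + reg.amplitude / reg.baseline * saturating_rise(
            t_end, scene.switch_time, reg.tau
        )
    if scene.vessel is not None:
        gt.max_dilation_true = float(
            scene.vessel.width_at(t_end, scene.switch_time) / scene.vessel.width_px
        )
    gt.front_speed_true = scene.front_speed
    gt.nucleus_onsets = [n.pulse_onset for n in scene.nuclei]
    gt.nucleus_distances = list(scene.nucleus_distances())
    if scene.cells:
        paths = np.empty((len(scene.cells), scene.n_frames, 2))
        for i, cell in enumerate(scene.cells):
            for k, t in enumerate(scene.times):
                paths[i, k] = cell.position_at(float(t))
        gt.cell_paths_um = paths
    gt.drift_px = None if scene.drift_px is None else scene.drift_px.copy()
    return gt


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _default_geometry(image_shape: tuple[int, int]) -> dict:
    """Vessel band, perivascular/wound/background rectangles scaled to the frame."""
    h, w = image_shape
    yc = h * 0.42
    band_w = max(8.0, h * 0.12)
    periv = dict(
        top=int(h * 0.62), left=int(w * 0.12), height=int(h * 0.22), width=int(w * 0.62)
    )
    wound = dict(top=int(h * 0.12), left=int(w * 0.78), height=int(h * 0.3), width=int(w * 0.16))
    return {"y_center": yc, "width_px": band_w, "periv": periv, "wound": wound}


def make_scene(preset: str, **overrides) -> SceneSpec:
    """Build a validated :class:`SceneSpec` from a named preset.

    Scene-level overrides (``n_frames``, ``seed``, ``noise`` ...) are passed
    through; preset-level knobs are ``excess_auc`` (hypo/iso/blockade arms),
    ``wound_excess``, ``dilation_amplitude``, ``front_speed``, ``n_nuclei``,
    ``n_cells``.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")

    scene_kwargs = {
        "image_shape": (128, 128),
        "n_frames": 121,
        "frame_interval": 30.0,
        "pixel_size": 0.65,
        "switch_frame": 10,
        "seed": 0,
    }
    preset_knobs = {
        "excess_auc": None,
        "wound_excess": None,
        "dilation_amplitude": None,
        "front_speed": None,
        "n_nuclei": 6,
        "n_cells": 4,
        "tau": 300.0,
    }
    for key, val in overrides.items():
        if key in preset_knobs:
            preset_knobs[key] = val
        else:
            scene_kwargs[key] = val

    if preset == "translocation_wave":
        # laser-wound acquisitions are faster and shorter than the dextran ones
        if "n_frames" not in overrides:
            scene_kwargs["n_frames"] = 60
        if "frame_interval" not in overrides:
            scene_kwargs["frame_interval"] = 2.5
        if "switch_frame" not in overrides:
            scene_kwargs["switch_frame"] = 4

    if "switch_frame" not in overrides and scene_kwargs["switch_frame"] >= scene_kwargs[
        "n_frames"
    ]:
        scene_kwargs["switch_frame"] = scene_kwargs["n_frames"] // 2

    shape = tuple(scene_kwargs["image_shape"])
    geom = _default_geometry(shape)
    t_switch = scene_kwargs["switch_frame"] * scene_kwargs["frame_interval"]
    t_end = (scene_kwargs["n_frames"] - 1) * scene_kwargs["frame_interval"]
    tau = preset_knobs["tau"]

    def leak_region(which: str, baseline: float, excess_auc: float | None, end_excess: float):
        """Excess parameterized either by target AUC (periv) or end-value (wound)."""
        geo = geom[which]
        if excess_auc is not None and excess_auc > 0:
            amp = amplitude_for_excess_auc(excess_auc, baseline, t_switch, tau, t_end)
        elif end_excess > 0:
            amp = baseline * end_excess / saturating_rise(t_end, t_switch, tau)
        else:
            amp = 0.0
        return LeakRegion(baseline=baseline, amplitude=amp, tau=tau, **geo)

    vessel = VesselBand(
        y_center=geom["y_center"], width_px=geom["width_px"], intensity=200.0
    )
    periv = leak_region("periv", 50.0, None, 0.0)
    wound = leak_region("wound", 40.0, None, 0.0)
    nuclei: list[NucleusSpec] = []
    cells: list[CellPath] = []
    front_speed = preset_knobs["front_speed"]

    if preset in ("hypo_wound", "blockade_pair"):
        auc = preset_knobs["excess_auc"] if preset_knobs["excess_auc"] is not None else 25.0
        periv = leak_region("periv", 50.0, auc, 0.0)
        wound = leak_region(
            "wound", 40.0, None,
            preset_knobs["wound_excess"] if preset_knobs["wound_excess"] is not None else 0.8,
        )
        vessel.dilation_amplitude = (
            preset_knobs["dilation_amplitude"]
            if preset_knobs["dilation_amplitude"] is not None
            else 0.4
        )
    elif preset == "iso_wound":
        auc = preset_knobs["excess_auc"] if preset_knobs["excess_auc"] is not None else 3.0
        periv = leak_region("periv", 50.0, auc, 0.0)
        wound = leak_region(
            "wound", 40.0, None,
            preset_knobs["wound_excess"] if preset_knobs["wound_excess"] is not None else 0.1,
        )
        vessel.dilation_amplitude = (
            preset_knobs["dilation_amplitude"]
            if preset_knobs["dilation_amplitude"] is not None
            else 0.05
        )
    elif preset == "no_wound":
        pass  # zero amplitudes everywhere
    elif preset == "translocation_wave":
        if front_speed is None:
            front_speed = 50.0
        n = preset_knobs["n_nuclei"]
        rng = np.random.default_rng(scene_kwargs.get("seed", 0))
        h_um = shape[0] * scene_kwargs["pixel_size"]
        w_um = shape[1] * scene_kwargs["pixel_size"]
        # rise time spans >= 2 frame intervals so half-rise onsets interpolate
        # exactly on the linear ramp
        rise = 2.0 * scene_kwargs["frame_interval"]
        for i in range(n):
            y = float(rng.uniform(0.2, 0.8) * h_um)
            x = float(rng.uniform(0.2, 0.8) * w_um)
            nuclei.append(NucleusSpec(centroid_um=(y, x), rise_time=rise))
        vessel = None
        periv = wound = None
    elif preset == "tracking_field":
        n = preset_knobs["n_cells"]
        h_um = shape[0] * scene_kwargs["pixel_size"]
        w_um = shape[1] * scene_kwargs["pixel_size"]
        rng = np.random.default_rng(scene_kwargs.get("seed", 0))
        # separate y lanes so blobs never merge into one component
        lanes = np.linspace(0.15, 0.85, max(n, 2))[:n] * h_um
        for i in range(n):
            start = (float(lanes[i]), float(rng.uniform(0.1, 0.3) * w_um))
            end = (start[0], float(0.85 * w_um))
            cells.append(CellPath(waypoints_um=[start, end], speed=0.1))
        vessel = None
        periv = wound = None
    elif preset == "spot_still":
        scene_kwargs["n_frames"] = overrides.get("n_frames", 1)
        scene_kwargs["switch_frame"] = 0
        vessel = None
        periv = wound = None

    # explicit component overrides win over preset-built ones
    vessel = scene_kwargs.pop("vessel", vessel)
    periv = scene_kwargs.pop("perivascular_region", periv)
    wound = scene_kwargs.pop("wound_region", wound)
    nuclei = scene_kwargs.pop("nuclei", nuclei)
    cells = scene_kwargs.pop("cells", cells)
    return SceneSpec(
        vessel=vessel,
        wound_region=wound,
        perivascular_region=periv,
        nuclei=nuclei,
        cells=cells,
        front_speed=front_speed,
        **scene_kwargs,
    )


def blockade_pair(
    control_auc: float = 25.0, treated_auc: float = 3.0, **overrides
) -> tuple[SceneSpec, SceneSpec]:
    """Matched control/treated scenes differing only in leak amplitude."""
    control = make_scene("blockade_pair", excess_auc=control_auc, **overrides)
    treated = make_scene("blockade_pair", excess_auc=treated_auc, **overrides)
    return control, treated


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _disk_coverage(shape, cy, cx, radius):
    """Anti-aliased disk: coverage in [0, 1] with a 1-px soft edge."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r = np.hypot(yy - cy, xx - cx)
    return np.clip(radius - r + 0.5, 0.0, 1.0)


def analytic_frame(scene: SceneSpec, t: float) -> np.ndarray:
    """Noise-free (C, Y, X) frame of the scene model at time t seconds."""
    h, w = scene.image_shape
    base = scene.noise.background_offset
    tracer = np.full((h, w), base, dtype=float)
    reporter = np.full((h, w), base, dtype=float)

    if scene.vessel is not None:
        width = scene.vessel.width_at(t, scene.switch_time)
        yy = np.arange(h, dtype=float)[:, None]
        cover = np.clip(width / 2 - np.abs(yy - scene.vessel.y_center) + 0.5, 0.0, 1.0)
        tracer += scene.vessel.intensity * cover

    for reg in (scene.perivascular_region, scene.wound_region):
        if reg is None:
            continue
        sl = (slice(reg.top, reg.top + reg.height), slice(reg.left, reg.left + reg.width))
        tracer[sl] += reg.baseline + reg.mean_excess_at(t, scene.switch_time)

    for nuc in scene.nuclei:
        cy = nuc.centroid_um[0] / scene.pixel_size
        cx = nuc.centroid_um[1] / scene.pixel_size
        disk = _disk_coverage((h, w), cy, cx, nuc.radius_px)
        inner = _disk_coverage((h, w), cy, cx, nuc.radius_px - nuc.rim_width_px)
        rim = disk - inner
        gain = 1.0 + (nuc.rim_gain - 1.0) * nuc.pulse_at(t)
        reporter += nuc.intensity * (inner + gain * rim)

    for cell in scene.cells:
        cy_um, cx_um = cell.position_at(t)
        reporter += cell.intensity * _disk_coverage(
            (h, w), cy_um / scene.pixel_size, cx_um / scene.pixel_size, cell.radius_px
        )

    return np.stack([tracer, reporter])


def render_movie(scene: SceneSpec) -> tuple[FrameStack, GroundTruth]:
    """Render the scene into a 2-channel stack plus its analytic ground truth.

    Deterministic given ``scene.seed``; with zero noise and drift the pixels
    equal the analytic model exactly.
    """
    from scipy import ndimage

    rng = np.random.default_rng(scene.seed)
    frames = np.empty((scene.n_frames, 2, *scene.image_shape), dtype=float)
    for k, t in enumerate(scene.times):
        img = analytic_frame(scene, float(t))
        if scene.noise.photon_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * scene.noise.photon_scale) / (
                scene.noise.photon_scale
            )
        if scene.noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, scene.noise.read_noise_sd, size=img.shape)
        if scene.drift_px is not None:
            dy, dx = scene.drift_px[k]
            if dy or dx:
                img = np.stack(
                    [ndimage.shift(c, (dy, dx), order=1, mode="nearest") for c in img]
                )
        frames[k] = img

    stack = FrameStack(
        pixels=frames,
        pixel_size=scene.pixel_size,
        frame_interval=scene.frame_interval,
        channel_names=["tracer", "reporter"],
    )
    return stack, _scene_ground_truth(scene)


def render_spot_still(
    n_spots: int,
    spacing: float = 28.0,
    seed: int = 0,
    image_shape: tuple[int, int] = (256, 256),
    prominence: float = 1950.0,
    margin: float = 2.0,
    n_sub: int = 0,
    sub_margin: float = 0.5,
    sigma_px: float = 6.0,
    background: float = 100.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Still image with Gaussian spots on a jittered grid plus ground truth.

    ``n_spots`` spots have peak amplitude ``margin * prominence`` above
    background (countable); ``n_sub`` extra spots sit at ``sub_margin *
    prominence`` (below the counting threshold when ``sub_margin < 1``).
    """
    total = n_spots + n_sub
    h, w = image_shape
    pad = spacing / 2 + 4 * sigma_px
    cols = max(1, int((w - 2 * pad) // spacing) + 1)
    rows = max(1, int((h - 2 * pad) // spacing) + 1)
    if total > rows * cols:
        raise ValueError(
            f"cannot place {total} spots at spacing {spacing} in a {image_shape} frame"
        )
    rng = np.random.default_rng(seed)
    slots = [(pad + r * spacing, pad + c * spacing) for r in range(rows) for c in range(cols)]
    idx = rng.choice(len(slots), size=total, replace=False)
    jitter = rng.uniform(-2.0, 2.0, size=(total, 2))

    img = np.full(image_shape, background, dtype=float)
    yy, xx = np.mgrid[:h, :w]
    coords: list[tuple[float, float]] = []
    for i, j in enumerate(idx):
        cy, cx = slots[j][0] + jitter[i, 0], slots[j][1] + jitter[i, 1]
        amp = margin * prominence if i < n_spots else sub_margin * prominence
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2))
        coords.append((float(cy), float(cx)))

    gt = GroundTruth(
        spot_count=n_spots,
        spot_coords=coords[:n_spots],
        sub_threshold_count=n_sub,
    )
    return img, gt


def binding_curves_from_scene(
    scene: SceneSpec,
    onset_jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic per-nucleus rim:core ratio curves for the scene's pulse law.

    Returns ``(times, ratios, distances)`` with ``ratios`` of shape
    ``(n_nuclei, n_frames)``. Optional Gaussian jitter is added to each
    nucleus onset before sampling (the wave-speed Monte-Carlo input).
    """
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    times = scene.times.astype(float)
    ratios = np.empty((len(scene.nuclei), scene.n_frames))
    for i, nuc in enumerate(scene.nuclei):
        onset = nuc.pulse_onset + (
            rng.normal(0.0, onset_jitter_sd) if onset_jitter_sd > 0 else 0.0
        )
        shifted = dataclasses.replace(nuc, pulse_onset=onset)
        ratios[i] = 1.0 + (nuc.rim_gain - 1.0) * shifted.pulse_at(times)
    return times, ratios, scene.nucleus_distances()
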