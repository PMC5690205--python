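"""Synthetic cine-CT studies of the moving-wire fiducial frame.

Renders axial CT frames of a thorax-like phantom sitting inside a body
frame whose add-on device carries two copper wires, one on each side of
the patient.  As the surrogate (central piece) moves vertically with the
breathing waveform, the wire cross-sections seen in a slice at
longitudinal coordinate Z move vertically with the lever-ratio-scaled
displacement.  The renderer knows the ground truth, so the studies it
produces calibrate and validate the measurement pipeline end to end.

Acquisition defaults emulate a 10-slice scanner running a cine protocol:
slabs of 8 x 3 mm slices, 0.5 s exposure, ~0.8 s between frames, 16 s per
slab, FOV 500 mm on a 768 x 768 matrix (0.651 mm pixels).

Image coordinates follow the usual screen convention: origin at the
upper-left corner, x to the right, y downward toward the patient table.
Exhale (minimum anterior displacement) therefore corresponds to the
*maximal* image-y of the wires.  The centre of pixel (row i, col j) sits
at physical (x, y) = ((j + 0.5) s, (i + 0.5) s) with s the pixel spacing,
so ``px = mm / s - 0.5`` converts a physical coordinate to the pixel-index
scale used for centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .geometry import FrameGeometry, lever_ratio
from .motion import MotionWaveform, evaluate_waveform

__all__ = [
    "AcquisitionConfig",
    "SceneConfig",
    "TargetConfig",
    "CineFrame",
    "CineStudy",
    "render_frame",
    "simulate_cine_study",
    "DEFAULT_ACQUISITION",
    "DEFAULT_SCENE",
]

# Fixed intensity scale (HU).  Copper saturates clinical HU scales; any
# value far above soft tissue works, fixed here for reproducibility.
HU_BACKGROUND = -1000.0
HU_BODY = 40.0
HU_LUNG = -700.0
HU_WIRE = 3000.0
HU_TARGET = 40.0


@dataclass(frozen=True)
class AcquisitionConfig:
    """Cine acquisition parameters.

    ``pixel_spacing_mm`` is derived (fov/matrix); ``frames_per_slice`` is
    ``floor(cine_duration / frame_interval)``.
    """

    n_slabs: int = 4
    slices_per_slab: int = 8
    slice_thickness_mm: float = 3.0
    frame_interval_s: float = 0.8
    exposure_s: float = 0.5
    cine_duration_s: float = 16.0
    fov_mm: float = 500.0
    matrix: int = 768
    noise_sd_hu: float = 20.0
    inter_slab_gap_s: float = 0.0
    timing_jitter_s: float = 0.0
    motion_blur: bool = False
    blur_subsamples: int = 5

    def __post_init__(self) -> None:
        if self.matrix < 16:
            raise ValueError("matrix too small")
        if self.frame_interval_s <= 0 or self.cine_duration_s <= 0:
            raise ValueError("timing parameters must be positive")
        if self.timing_jitter_s < 0 or self.timing_jitter_s >= self.frame_interval_s / 2:
            raise ValueError("timing_jitter_s must be in [0, frame_interval/2)")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")

    @property
    def pixel_spacing_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def frames_per_slice(self) -> int:
        return int(math.floor(self.cine_duration_s / self.frame_interval_s))

    @classmethod
    def from_config(cls, cfg: dict) -> "AcquisitionConfig":
        return cls(**cfg)

    def to_config(self) -> dict:
        return {
            "n_slabs": self.n_slabs,
            "slices_per_slab": self.slices_per_slab,
            "slice_thickness_mm": self.slice_thickness_mm,
            "frame_interval_s": self.frame_interval_s,
            "exposure_s": self.exposure_s,
            "cine_duration_s": self.cine_duration_s,
            "fov_mm": self.fov_mm,
            "matrix": self.matrix,
            "noise_sd_hu": self.noise_sd_hu,
            "inter_slab_gap_s": self.inter_slab_gap_s,
            "timing_jitter_s": self.timing_jitter_s,
            "motion_blur": self.motion_blur,
            "blur_subsamples": self.blur_subsamples,
        }


DEFAULT_ACQUISITION = AcquisitionConfig()


@dataclass(frozen=True)
class TargetConfig:
    """Optional spherical target inside the lung, with independent motion.

    Only used for end-to-end phase-sorting demonstrations — the signal
    pipeline never looks at the target.
    """

    diameter_mm: float = 30.0
    center_mm: tuple = (175.0, 240.0)  # (x, y) in image mm
    z_mm: float = 0.0  # longitudinal centre (same system as slice z)
    waveform_y: Optional[MotionWaveform] = None  # AP (image y) motion
    waveform_z: Optional[MotionWaveform] = None  # longitudinal motion


@dataclass(frozen=True)
class SceneConfig:
    """Static layout of the rendered axial scene (all in image mm)."""

    wire_x_mm: tuple = (70.0, 430.0)
    wire_baseline_y_mm: float = 380.0
    wire_diameter_mm: float = 2.0
    body_center_mm: tuple = (250.0, 250.0)
    body_semiaxes_mm: tuple = (160.0, 110.0)
    lung_offsets_mm: tuple = (-75.0, 75.0)  # lateral lung centres vs body centre
    lung_center_y_mm: float = 240.0
    lung_semiaxes_mm: tuple = (55.0, 70.0)
    target: Optional[TargetConfig] = None

    @classmethod
    def for_geometry(cls, g: FrameGeometry, fov_mm: float = 500.0, **kw) -> "SceneConfig":
        """Place the wires symmetrically about the image midline at the
        lateral separation the frame geometry prescribes."""
        half = g.wire_sep_x_mm / 2.0
        return cls(wire_x_mm=(fov_mm / 2 - half, fov_mm / 2 + half), **kw)


DEFAULT_SCENE = SceneConfig()


@dataclass
class CineFrame:
    """One axial cine image plus its acquisition metadata."""

    frame_id: int
    slab: int
    slice_idx: int
    slice_z_mm: float
    time_s: float
    pixel_spacing_mm: float
    pixels: np.ndarray  # int16, HU
    true_centers_px: Optional[tuple] = None  # ((xl, yl), (xr, yr))
    true_displacement_mm: Optional[float] = None  # central-piece ground truth

    @property
    def slice_key(self) -> tuple:
        return (self.slab, self.slice_idx)


@dataclass
class CineStudy:
    """An ordered collection of cine frames grouped by slab and slice."""

    frames: list
    geometry: FrameGeometry
    acquisition: AcquisitionConfig
    scene: SceneConfig = DEFAULT_SCENE
    ground_truth: Optional[MotionWaveform] = None

    def slice_keys(self) -> list:
        seen: dict = {}
        for f in self.frames:
            seen.setdefault(f.slice_key, None)
        return list(seen)

    def frames_for_slice(self, slice_key: tuple) -> list:
        frames = sorted(
            (f for f in self.frames if f.slice_key == tuple(slice_key)),
            key=lambda f: f.time_s,
        )
        times = [f.time_s for f in frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"acquisition times not strictly increasing in slice {slice_key}")
        return frames

    def slice_z(self, slice_key: tuple) -> float:
        for f in self.frames:
            if f.slice_key == tuple(slice_key):
                return f.slice_z_mm
        raise KeyError(f"no such slice: {slice_key}")

    def most_distal_slice(self) -> tuple:
        """The slice farthest from the central piece (smallest lever ratio).

        Measuring well there implies the easier, closer slices also work.
        """
        return max(
            self.slice_keys(),
            key=lambda k: abs(self.slice_z(k) - self.geometry.z0_mm),
        )

    def frame_by_id(self, frame_id: int) -> CineFrame:
        for f in self.frames:
            if f.frame_id == frame_id:
                return f
        raise KeyError(f"no frame with id {frame_id}")


# ---------------------------------------------------------------------------
# rendering

_SUPERSAMPLE = 16


def _disc_coverage_patch(cx_px: float, cy_px: float, r_px: float, shape: tuple):
    """Area-coverage fractions of a disc over the pixels of its bounding
    box, estimated on a 16x16 subpixel grid (coverage error < 1/256 per
    pixel, centroid error far below 0.1 px for wire-sized discs).

    Returns ``(row0, col0, patch)`` with patch values in [0, 1].
    """
    r0 = max(int(math.floor(cy_px - r_px)) - 1, 0)
    r1 = min(int(math.ceil(cy_px + r_px)) + 2, shape[0])
    c0 = max(int(math.floor(cx_px - r_px)) - 1, 0)
    c1 = min(int(math.ceil(cx_px + r_px)) + 2, shape[1])
    n = _SUPERSAMPLE
    sub = (np.arange(n) + 0.5) / n - 0.5
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    yy = rows[:, None] + sub[None, :]  # (nr, n) subpixel y offsets
    xx = cols[:, None] + sub[None, :]
    dy2 = (yy - cy_px) ** 2
    dx2 = (xx - cx_px) ** 2
    inside = (dy2[:, None, :, None] + dx2[None, :, None, :]) <= r_px**2
    patch = inside.mean(axis=(2, 3))
    return r0, c0, patch


@lru_cache(maxsize=8)
def _scene_template(matrix: int, fov_mm: float, scene: SceneConfig) -> np.ndarray:
    """Static body/lung background in HU (float32), cached per scene."""
    s = fov_mm / matrix
    coords = (np.arange(matrix) + 0.5) * s
    xx, yy = np.meshgrid(coords, coords)
    img = np.full((matrix, matrix), HU_BACKGROUND, dtype=np.float32)
    bx, by = scene.body_center_mm
    ax, ay = scene.body_semiaxes_mm
    body = ((xx - bx) / ax) ** 2 + ((yy - by) / ay) ** 2 <= 1.0
    img[body] = HU_BODY
    lax, lay = scene.lung_semiaxes_mm
    for off in scene.lung_offsets_mm:
        lung = ((xx - (bx + off)) / lax) ** 2 + ((yy - scene.lung_center_y_mm) / lay) ** 2 <= 1.0
        img[lung] = HU_LUNG
    return img


def _blend_disc(img: np.ndarray, cx_px: float, cy_px: float, r_px: float, value: float) -> None:
    r0, c0, patch = _disc_coverage_patch(cx_px, cy_px, r_px, img.shape)
    view = img[r0 : r0 + patch.shape[0], c0 : c0 + patch.shape[1]]
    view *= 1.0 - patch
    view += patch * value


def render_frame(
    wire_y_left_mm: float,
    wire_y_right_mm: float,
    wire_x_mm: Sequence[float],
    cfg: AcquisitionConfig,
    rng: Optional[np.random.Generator] = None,
    scene: SceneConfig = DEFAULT_SCENE,
    target_xy_mm: Optional[tuple] = None,
    target_radius_mm: float = 0.0,
) -> np.ndarray:
    """Render one axial frame with the wires at the given vertical positions.

    Positions are physical image coordinates in mm (origin upper-left,
    y toward the table).  The two wire cross-sections are anti-aliased
    2 mm discs at HU_WIRE; additive Gaussian noise of ``cfg.noise_sd_hu``
    is applied when ``rng`` is given and the noise sd is positive.
    Returns an int16 HU array.  Discs touching the image border are
    rejected.
    """
    s = cfg.pixel_spacing_mm
    r_px = (scene.wire_diameter_mm / 2.0) / s
    img = _scene_template(cfg.matrix, cfg.fov_mm, scene).copy()

    for x_mm, y_mm in zip(wire_x_mm, (wire_y_left_mm, wire_y_right_mm)):
        cx = x_mm / s - 0.5
        cy = y_mm / s - 0.5
        if (
            cx - r_px < 0.5
            or cy - r_px < 0.5
            or cx + r_px > cfg.matrix - 1.5
            or cy + r_px > cfg.matrix - 1.5
        ):
            raise ValueError(
                f"wire disc at ({x_mm:g}, {y_mm:g}) mm overlaps the image border"
            )
        _blend_disc(img, cx, cy, r_px, HU_WIRE)

    if target_xy_mm is not None and target_radius_mm > 0:
        _blend_disc(
            img,
            target_xy_mm[0] / s - 0.5,
            target_xy_mm[1] / s - 0.5,
            target_radius_mm / s,
            HU_TARGET,
        )

    if rng is not None and cfg.noise_sd_hu > 0:
        img += rng.normal(0.0, cfg.noise_sd_hu, img.shape).astype(np.float32)
    return np.rint(np.clip(img, -32768, 32767)).astype(np.int16)


# ---------------------------------------------------------------------------
# study simulation


def default_slice_zs(g: FrameGeometry, cfg: AcquisitionConfig, most_distal_offset_mm: float = 200.0) -> list:
    """Contiguous slice positions for ``n_slabs`` slabs marching from the
    most distal evaluation plane toward the central piece."""
    z_start = g.z0_mm - most_distal_offset_mm
    n = cfg.n_slabs * cfg.slices_per_slab
    return [z_start + i * cfg.slice_thickness_mm for i in range(n)]


def simulate_cine_study(
    waveform: MotionWaveform,
    g: FrameGeometry,
    cfg: AcquisitionConfig,
    slice_zs: Sequence[float],
    scene: Optional[SceneConfig] = None,
    seed: Optional[int] = None,
    target: Optional[TargetConfig] = None,
) -> CineStudy:
    """Simulate a slab-sequential cine study with known ground truth.

    Slices are grouped into slabs of ``cfg.slices_per_slab`` in the given
    order; slab k is acquired during
    ``[k*(cine_duration + gap), ...]`` with ``frames_per_slice`` frames at
    ``frame_interval`` spacing, all slices of a slab sharing timestamps.
    The wire vertical displacement at a slice follows the lever-ratio
    projection of the waveform; image y *decreases* with anterior motion,
    so exhale frames show the wires at maximal image y.

    Identical ``seed`` (and inputs) reproduces the study bit for bit.
    """
    slice_zs = list(slice_zs)
    if not slice_zs:
        raise ValueError("slice_zs must be non-empty")
    if scene is None:
        scene = SceneConfig.for_geometry(g, fov_mm=cfg.fov_mm)
    for z in slice_zs:
        lever_ratio(g, z)  # validates position

    rng = np.random.default_rng(seed)
    s = cfg.pixel_spacing_mm
    if target is not None and scene.target is None:
        scene = replace(scene, target=target)
    tgt = scene.target

    frames: list = []
    frame_id = 0
    n_frames = cfg.frames_per_slice
    slab_span = cfg.cine_duration_s + cfg.inter_slab_gap_s
    n_slabs = math.ceil(len(slice_zs) / cfg.slices_per_slab)
    for slab in range(n_slabs):
        zs = slice_zs[slab * cfg.slices_per_slab : (slab + 1) * cfg.slices_per_slab]
        t0 = slab * slab_span
        for k in range(n_frames):
            t = t0 + k * cfg.frame_interval_s
            if cfg.timing_jitter_s > 0:
                t += rng.uniform(-cfg.timing_jitter_s, cfg.timing_jitter_s)
            if cfg.motion_blur:
                tt = t + np.linspace(0.0, cfg.exposure_s, cfg.blur_subsamples)
                disp = float(np.mean(evaluate_waveform(waveform, tt)))
            else:
                disp = float(evaluate_waveform(waveform, t))
            for slice_idx, z in enumerate(zs):
                ratio = lever_ratio(g, z)
                wire_y_mm = scene.wire_baseline_y_mm - ratio * disp
                tgt_xy = None
                tgt_r = 0.0
                if tgt is not None:
                    dz = z - (
                        tgt.z_mm
                        + (evaluate_waveform(tgt.waveform_z, t) if tgt.waveform_z else 0.0)
                    )
                    r_tgt = tgt.diameter_mm / 2.0
                    if abs(dz) < r_tgt:
                        tgt_r = math.sqrt(r_tgt**2 - dz**2)
                        ty = tgt.center_mm[1] - (
                            evaluate_waveform(tgt.waveform_y, t) if tgt.waveform_y else 0.0
                        )
                        tgt_xy = (tgt.center_mm[0], ty)
                pixels = render_frame(
                    wire_y_mm,
                    wire_y_mm,
                    scene.wire_x_mm,
                    cfg,
                    rng=rng,
                    scene=scene,
                    target_xy_mm=tgt_xy,
                    target_radius_mm=tgt_r,
                )
                centers = tuple(
                    (x / s - 0.5, wire_y_mm / s - 0.5) for x in scene.wire_x_mm
                )
                frames.append(
                    CineFrame(
                        frame_id=frame_id,
                        slab=slab,
                        slice_idx=slice_idx,
                        slice_z_mm=z,
                        time_s=t,
                        pixel_spacing_mm=s,
                        pixels=pixels,
                        true_centers_px=centers,
                        true_displacement_mm=disp,
                    )
                )
                frame_id += 1
    return CineStudy(
        frames=frames,
        geometry=g,
        acquisition=cfg,
        scene=scene,
        ground_truth=waveform,
    )
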