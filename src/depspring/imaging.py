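"""Particle detection and tracking from grayscale image stacks.

The processing chain mirrors classic bright-field particle tracking: a
per-pixel temporal median estimates the static background; frames are
background-subtracted and thresholded; connected components (8-connectivity,
minimum area) become detections with intensity-weighted centroids; detections
are linked frame-to-frame by greedy nearest-neighbour assignment within a
displacement limit.  A synthetic renderer (Gaussian blobs + noise) provides
ground-truth stacks for end-to-end testing.

Image coordinates: origin top-left, x right (columns), y down (rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

from .errors import ValidationError
from .trajectories import Trajectory

__all__ = [
    "ImageStack",
    "Detection",
    "Track",
    "median_background",
    "detect_particles",
    "link_tracks",
    "render_stack",
]


@dataclass(frozen=True)
class ImageStack:
    """Grayscale frames of uniform shape, with timing and scale metadata."""

    frames: np.ndarray = field(repr=False)
    frame_interval: float = 0.05
    pixel_size: float = 1e-6

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValidationError("frames must be a (T, H, W) array with T >= 1")
        if not np.all(np.isfinite(frames)) or np.any(frames < 0):
            raise ValidationError("intensities must be finite and non-negative")
        object.__setattr__(self, "frames", frames)
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValidationError("frame_interval and pixel_size must be > 0")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @classmethod
    def from_tiff(cls, path, frame_interval: float = 0.05, pixel_size: float = 1e-6) -> "ImageStack":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames=frames.astype(float), frame_interval=frame_interval, pixel_size=pixel_size)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32), photometric="minisblack")


@dataclass(frozen=True)
class Detection:
    """One detected blob: frame index, centroid (px) and area (px^2)."""

    frame: int
    x: float
    y: float
    area: float


def median_background(stack: ImageStack) -> np.ndarray:
    """Per-pixel temporal median frame; robust to sparse moving particles."""
    if len(stack) < 3:
        raise ValidationError("temporal median needs at least 3 frames")
    return np.median(stack.frames, axis=0)


def detect_particles(
    frame: np.ndarray,
    background: np.ndarray,
    threshold: float,
    min_area: int = 4,
    frame_index: int = 0,
) -> list[Detection]:
    """Threshold |frame - background| and report connected components.

    8-connected components with at least ``min_area`` pixels become
    detections; centroids are intensity-weighted by the absolute difference
    image for sub-pixel accuracy.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValidationError("frame and background shapes differ")
    diff = np.abs(frame - background)
    labels = measure.label(diff > threshold, connectivity=2)
    detections = []
    for region in measure.regionprops(labels, intensity_image=diff):
        if region.area < min_area:
            continue
        cy, cx = region.centroid_weighted
        detections.append(Detection(frame=frame_index, x=float(cx), y=float(cy), area=float(region.area)))
    return detections


@dataclass
class Track:
    """A linked sequence of detections (pixel coordinates)."""

    frames: list[int]
    x: list[float]
    y: list[float]

    def __len__(self) -> int:
        return len(self.frames)

    def to_trajectory(self, frame_interval: float, pixel_size: float, y_origin_px: float = 0.0) -> Trajectory:
        """Convert to metric units; ``y_origin_px`` maps the image y axis onto
        the electrode-centered device axis."""
        t = (np.asarray(self.frames, dtype=float) + 1.0) * frame_interval
        return Trajectory(
            t=t,
            y=(np.asarray(self.y) - y_origin_px) * pixel_size,
            x=np.asarray(self.x) * pixel_size,
            frame_interval=frame_interval,
        )


def link_tracks(detections: list[Detection], max_displacement: float) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Within each frame transition, candidate (track, detection) pairs closer
    than ``max_displacement`` are matched greedily by ascending distance;
    unmatched detections start new tracks, unmatched tracks end.
    """
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    if not by_frame:
        return []
    tracks: list[Track] = []
    active: list[Track] = []
    for frame in range(min(by_frame), max(by_frame) + 1):
        dets = by_frame.get(frame, [])
        pairs = []
        for ti, tr in enumerate(active):
            for di, d in enumerate(dets):
                dist = float(np.hypot(tr.x[-1] - d.x, tr.y[-1] - d.y))
                if dist <= max_displacement:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            d = dets[di]
            active[ti].frames.append(d.frame)
            active[ti].x.append(d.x)
            active[ti].y.append(d.y)
        survivors = [tr for ti, tr in enumerate(active) if ti in used_t]
        for di, d in enumerate(dets):
            if di not in used_d:
                tr = Track(frames=[d.frame], x=[d.x], y=[d.y])
                tracks.append(tr)
                survivors.append(tr)
        active = survivors
    return tracks


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for i, tr in enumerate(tracks):
        for f, x, y in zip(tr.frames, tr.x, tr.y):
            rows.append({"track": i, "frame": f, "x_px": x, "y_px": y})
    return pd.DataFrame(rows)


def render_stack(
    trajectories_px: list[np.ndarray],
    shape: tuple[int, int] = (64, 96),
    n_frames: int | None = None,
    amplitude: float = 100.0,
    sigma: float = 2.0,
    background_level: float = 50.0,
    noise_sd: float = 0.0,
    frame_interval: float = 0.05,
    pixel_size: float = 1e-6,
    seed: int | None = None,
) -> ImageStack:
    """Render moving Gaussian blobs on a constant background.

    ``trajectories_px``: one (n_frames, 2) array of (x, y) pixel positions per
    particle.  Gaussian noise of ``noise_sd`` is added per pixel (clipped at
    zero to keep intensities physical); reproducible via ``seed``.
    """
    trajectories_px = [np.asarray(p, dtype=float) for p in trajectories_px]
    if n_frames is None:
        if not trajectories_px:
            raise ValidationError("n_frames required when rendering an empty scene")
        n_frames = trajectories_px[0].shape[0]
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(seed)
    frames = np.full((n_frames, h, w), float(background_level))
    for path in trajectories_px:
        if path.shape != (n_frames, 2):
            raise ValidationError("each trajectory must be an (n_frames, 2) array of (x, y)")
        for k in range(n_frames):
            x0, y0 = path[k]
            frames[k] += amplitude * np.exp(
                -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2)
            )
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return ImageStack(
        frames=np.clip(frames, 0.0, None),
        frame_interval=frame_interval,
        pixel_size=pixel_size,
    )
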