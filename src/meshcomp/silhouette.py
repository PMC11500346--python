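"""Orthographic silhouettes: soft differentiable rendering, joint projection,
and silhouette extraction from DXA-style grayscale images.

Camera model is weak-perspective: 2D point = scale * (x, y) + (t_x, t_y),
depth (z) is dropped.  Image convention: x right, y down, origin top-left,
pixel centers at integer coordinates.  Masks carry a pixel spacing (m/px) so
camera scale has physical meaning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from ._raster import raster_backward, raster_forward
from .autodiff import Tensor

__all__ = [
    "CameraWP",
    "SilhouetteMask",
    "project_points",
    "project_points_t",
    "render_soft_silhouette",
    "render_soft_silhouette_t",
    "hard_rasterize",
    "extract_silhouette",
    "mask_iou",
]

log = logging.getLogger(__name__)


@dataclass
class CameraWP:
    """Weak-perspective camera: uniform scale (px/m) and 2D translation (px)."""

    scale: float
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("camera scale must be positive")
        self.translation = np.asarray(self.translation, dtype=np.float64)

    def as_array(self) -> np.ndarray:
        return np.array([self.scale, self.translation[0], self.translation[1]])

    @classmethod
    def from_array(cls, arr) -> "CameraWP":
        arr = np.asarray(arr, dtype=np.float64)
        return cls(scale=float(arr[0]), translation=arr[1:3].copy())


@dataclass
class SilhouetteMask:
    grid: np.ndarray  # (H, W) in [0, 1]; row 0 = top
    pixel_spacing: float = 1.0  # m/px

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.min() < -1e-9 or self.grid.max() > 1 + 1e-9:
            raise ValueError("mask values must lie in [0, 1]")

    @property
    def shape(self):
        return self.grid.shape

    def binary(self, threshold: float = 0.5) -> np.ndarray:
        return self.grid > threshold

    # -- PNG + JSON sidecar I/O --------------------------------------------
    def save(self, path) -> None:
        import imageio.v3 as iio

        path = Path(path)
        iio.imwrite(path, (np.clip(self.grid, 0, 1) * 255).astype(np.uint8))
        path.with_suffix(".json").write_text(
            json.dumps({"pixel_spacing_m": self.pixel_spacing})
        )

    @classmethod
    def load(cls, path) -> "SilhouetteMask":
        import imageio.v3 as iio

        path = Path(path)
        grid = np.asarray(iio.imread(path), dtype=np.float64) / 255.0
        spacing = 1.0
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            spacing = float(json.loads(sidecar.read_text()).get("pixel_spacing_m", 1.0))
        return cls(grid=grid, pixel_spacing=spacing)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def project_points_t(points3d: Tensor, cam: Tensor) -> Tensor:
    """(N, 3) points and camera tensor [s, t_x, t_y] -> (N, 2) pixels."""
    points3d, cam = ad.tensor(points3d), ad.tensor(cam)
    xy = ad.stack([points3d[:, 0], points3d[:, 1]], axis=1)
    return xy * cam[0] + ad.stack([cam[1], cam[2]])


def project_points(points3d, cam: CameraWP) -> np.ndarray:
    pts = np.asarray(points3d, dtype=np.float64)
    return pts[:, :2] * cam.scale + cam.translation


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _pad_for(sharpness: float) -> float:
    # sigmoid(-k * pad) < ~3e-4 beyond the padded bounding box
    return 8.0 / sharpness + 1.0


def render_soft_silhouette_t(
    projected: Tensor, faces: np.ndarray, size: tuple[int, int], sharpness: float,
    *, backface_cull: bool = True,
) -> Tensor:
    """Soft occupancy render of already-projected (N, 2) points; differentiable.

    For a closed mesh every silhouette pixel is covered by a front-facing
    face, so back-facing projected faces are skipped by default; pass
    ``backface_cull=False`` to aggregate over every face.
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    projected = ad.tensor(projected)
    h, w = size
    faces = np.ascontiguousarray(faces, dtype=np.int64)
    p2 = np.ascontiguousarray(projected.data)
    pad = _pad_for(sharpness)
    mask, q = raster_forward(p2, faces, h, w, float(sharpness), pad, backface_cull)

    def bwd(g):
        return (
            raster_backward(
                p2, faces, np.ascontiguousarray(g), q, float(sharpness), pad, backface_cull
            ),
        )

    return ad.custom_op((projected,), mask, bwd)


def render_soft_silhouette(
    mesh, cam: CameraWP, sharpness: float = 2.0, size: tuple[int, int] = (256, 256),
    pixel_spacing: float | None = None,
) -> SilhouetteMask:
    """Render a mesh silhouette under a weak-perspective camera.

    ``sharpness`` is in 1/px; the render tends to the hard rasterization as
    sharpness grows.
    """
    verts = mesh.vertices if hasattr(mesh, "vertices") else np.asarray(mesh[0])
    faces = mesh.faces if hasattr(mesh, "faces") else np.asarray(mesh[1])
    if len(faces) == 0:
        return SilhouetteMask(np.zeros(size), pixel_spacing or 1.0 / cam.scale)
    p2 = project_points(verts, cam)
    grid = render_soft_silhouette_t(
        ad.tensor(p2), faces, size, sharpness
    ).numpy()
    return SilhouetteMask(np.clip(grid, 0.0, 1.0), pixel_spacing or 1.0 / cam.scale)


def hard_rasterize(mesh, cam: CameraWP, size: tuple[int, int] = (256, 256)) -> SilhouetteMask:
    """Binary scanline rasterization (union of projected faces) via polygon fill."""
    from skimage.draw import polygon

    verts = mesh.vertices if hasattr(mesh, "vertices") else np.asarray(mesh[0])
    faces = mesh.faces if hasattr(mesh, "faces") else np.asarray(mesh[1])
    h, w = size
    grid = np.zeros((h, w), dtype=bool)
    p2 = project_points(verts, cam)
    for f in faces:
        rr, cc = polygon(p2[f, 1], p2[f, 0], shape=(h, w))
        grid[rr, cc] = True
    return SilhouetteMask(grid.astype(np.float64), 1.0 / cam.scale)


# ---------------------------------------------------------------------------
# extraction and comparison
# ---------------------------------------------------------------------------


def extract_silhouette(
    image: np.ndarray,
    threshold: float,
    *,
    keep_largest: bool = True,
    fill_holes: bool = True,
    pixel_spacing: float = 1.0,
) -> SilhouetteMask:
    """Threshold a DXA-style grayscale image into a clean binary silhouette.

    After thresholding, speckle is removed by keeping the largest connected
    component and interior holes are filled; both steps can be disabled.
    """
    from scipy.ndimage import binary_fill_holes
    from skimage.measure import label

    image = np.asarray(image, dtype=np.float64)
    mask = image > threshold
    if not mask.any():
        raise ValueError(f"empty mask: no pixel exceeds threshold {threshold}")
    if keep_largest:
        lab = label(mask, connectivity=2)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        mask = lab == int(np.argmax(counts))
    if fill_holes:
        mask = binary_fill_holes(mask)
    return SilhouetteMask(mask.astype(np.float64), pixel_spacing)


def mask_iou(a: SilhouetteMask, b: SilhouetteMask) -> float:
    """Intersection-over-union of two masks (soft masks binarized at 0.5)."""
    if a.shape != b.shape:
        raise ValueError(f"mask sizes differ: {a.shape} vs {b.shape}")
    ba, bb = a.binary(), b.binary()
    union = np.logical_or(ba, bb).sum()
    if union == 0:
        import warnings

        warnings.warn("both masks empty; IoU defined as 1", stacklevel=2)
        return 1.0
    return float(np.logical_and(ba, bb).sum() / union)
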