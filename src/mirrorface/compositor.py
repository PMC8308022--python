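"""Half-face mirror compositing.

The composited frame keeps the unaffected half of the image as captured
("natural" half) and replaces the affected half with the reflection of the
unaffected one across the face midline ("synthetic" half), with a linear
feathered blend across a narrow seam band centered on the axis.

Two replacement modes are provided:

``reflect_only`` (default)
    every affected-side pixel is sampled from the input at its Householder
    reflection across the axis (bilinear interpolation).
``mesh_warp``
    within the face mesh, a per-triangle affine warp maps the input onto
    the mirrored landmark geometry (piecewise-affine transform over the
    Delaunay mesh); outside the mesh the reflection sampling applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay

from .errors import AxisOutOfFrameError, ParameterError
from .landmarks import DetectionResult, LandmarkProvider, LandmarkSet, detect_landmarks
from .symmetry import SymmetryAxis, estimate_axis, mirrored_landmarks, reflect_point

__all__ = ["CompositeOptions", "CompositeFrame", "composite", "composite_stream",
           "electrode_occlusion_check"]

DEFAULT_SEAM_WIDTH = 11.0


@dataclass(frozen=True)
class CompositeOptions:
    warp_mode: str = "reflect_only"  # reflect_only | mesh_warp
    seam_width: float = DEFAULT_SEAM_WIDTH  # px, feather band across the axis
    face_only: bool = False  # restrict replacement to the landmark hull
    fill: str = "original"  # out-of-image reflected samples: original | edge

    def __post_init__(self) -> None:
        if self.warp_mode not in ("reflect_only", "mesh_warp"):
            raise ParameterError(f"unknown warp_mode {self.warp_mode!r}")
        if self.seam_width < 0:
            raise ParameterError("seam_width must be >= 0")


@dataclass
class CompositeFrame:
    """One composited output frame plus provenance."""

    image: np.ndarray
    axis: SymmetryAxis | None
    unaffected: str
    seam_width: float
    source_frame_index: int = 0
    face_found: bool = True
    warp_mode: str = "reflect_only"


def _unaffected_sign(unaffected: str) -> float:
    # signed_distance > 0 on the image-right side of an up-pointing axis
    if unaffected == "right":
        return 1.0
    if unaffected == "left":
        return -1.0
    raise ParameterError("unaffected must be 'left' or 'right' (image side)")


def _check_axis_in_frame(axis: SymmetryAxis, shape: tuple[int, int]) -> None:
    h, w = shape
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    s = axis.signed_distance(corners)
    if np.all(s > 0) or np.all(s < 0):
        raise AxisOutOfFrameError("symmetry axis does not intersect the image")


def _sample(channel: np.ndarray, coords_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear sample at (x, y) positions; returns (values, in_bounds mask)."""
    h, w = channel.shape
    x, y = coords_xy[..., 0], coords_xy[..., 1]
    inside = (x >= 0) & (x <= w - 1) & (y >= 0) & (y <= h - 1)
    vals = map_coordinates(channel.astype(np.float64), [y, x], order=1, mode="nearest")
    return vals, inside


def composite(
    image: np.ndarray,
    landmarks: LandmarkSet,
    axis: SymmetryAxis,
    unaffected: str,
    opts: CompositeOptions = CompositeOptions(),
    source_frame_index: int = 0,
) -> CompositeFrame:
    """Replace the affected half of ``image`` by the mirrored unaffected half.

    ``unaffected`` is the image side ("left"/"right") to keep.  Pixels more
    than ``seam_width/2`` into the unaffected side are returned untouched;
    affected-side pixels come from the reflected (or mesh-warped) sampling;
    a linear feather spans the seam band.  Deterministic: identical inputs
    produce bit-identical output.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        channels = [img]
    elif img.ndim == 3:
        channels = [img[..., c] for c in range(img.shape[2])]
    else:
        raise ParameterError("image must be 2-D grayscale or 3-D color")
    h, w = channels[0].shape
    _check_axis_in_frame(axis, (h, w))
    u = _unaffected_sign(unaffected)

    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    grid = np.stack([xs, ys], axis=-1)
    refl = reflect_point(grid.reshape(-1, 2), axis).reshape(h, w, 2)

    s = axis.signed_distance(grid.reshape(-1, 2)).reshape(h, w)
    if opts.seam_width > 0:
        alpha = np.clip(0.5 + (s * u) / opts.seam_width, 0.0, 1.0)
    else:
        alpha = (s * u >= 0).astype(float)

    mesh_maps = None
    if opts.warp_mode == "mesh_warp":
        mesh_maps = _mesh_warp_coords(landmarks, axis, unaffected, (h, w))

    replace_mask = None
    if opts.face_only:
        mirrored = mirrored_landmarks(landmarks, axis, unaffected)
        tri = Delaunay(mirrored.points)
        inside_hull = tri.find_simplex(grid.reshape(-1, 2)) >= 0
        replace_mask = inside_hull.reshape(h, w)

    out_channels = []
    for ch in channels:
        chf = ch.astype(np.float64)
        mirrored_vals, inside = _sample(ch, refl)
        if mesh_maps is not None:
            warp_xy, warp_valid = mesh_maps
            warp_vals, warp_in = _sample(ch, warp_xy)
            use = warp_valid & warp_in
            mirrored_vals = np.where(use, warp_vals, mirrored_vals)
            inside = inside | use
        if opts.fill == "original":
            mirrored_vals = np.where(inside, mirrored_vals, chf)
        a = alpha
        if replace_mask is not None:
            # outside the face hull nothing is replaced
            a = np.where(replace_mask, alpha, 1.0)
        out = a * chf + (1.0 - a) * mirrored_vals
        if np.issubdtype(ch.dtype, np.integer):
            info = np.iinfo(ch.dtype)
            out = np.clip(np.rint(out), info.min, info.max).astype(ch.dtype)
        else:
            out = out.astype(ch.dtype)
        out_channels.append(out)

    result = out_channels[0] if img.ndim == 2 else np.stack(out_channels, axis=-1)
    return CompositeFrame(
        image=result,
        axis=axis,
        unaffected=unaffected,
        seam_width=opts.seam_width,
        source_frame_index=source_frame_index,
        face_found=True,
        warp_mode=opts.warp_mode,
    )


def _mesh_warp_coords(
    landmarks: LandmarkSet, axis: SymmetryAxis, unaffected: str, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse piecewise-affine map for mesh_warp mode.

    Output geometry = mirrored landmarks; source geometry = input landmarks.
    Returns per-pixel input-space (x, y) coordinates and a validity mask
    (pixels inside the mirrored mesh hull).
    """
    from skimage.transform import PiecewiseAffineTransform

    mirrored = mirrored_landmarks(landmarks, axis, unaffected)
    # estimate the inverse directly: mirrored (output) -> original (input)
    if hasattr(PiecewiseAffineTransform, "from_estimate"):
        tform = PiecewiseAffineTransform.from_estimate(mirrored.points, landmarks.points)
        ok = bool(tform)
    else:  # scikit-image < 0.26
        tform = PiecewiseAffineTransform()
        ok = tform.estimate(mirrored.points, landmarks.points)
    h, w = shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    coords = np.stack([xs.ravel(), ys.ravel()], axis=-1)
    if not ok:
        return coords.reshape(h, w, 2), np.zeros((h, w), bool)
    mapped = tform(coords)
    valid = np.isfinite(mapped).all(axis=1)
    mapped = np.where(valid[:, None], mapped, coords)
    return mapped.reshape(h, w, 2), valid.reshape(h, w)


def composite_stream(
    frames: Iterable[np.ndarray],
    provider: LandmarkProvider | str,
    unaffected: str,
    opts: CompositeOptions = CompositeOptions(),
) -> Iterator[CompositeFrame]:
    """Detect -> estimate axis -> composite, frame by frame.

    Frames in which the provider finds no face pass through unmodified with
    ``face_found=False``.
    """
    for k, frame in enumerate(frames):
        det: DetectionResult = detect_landmarks(frame, provider)
        if not det.found:
            yield CompositeFrame(
                image=np.asarray(frame).copy(), axis=None, unaffected=unaffected,
                seam_width=opts.seam_width, source_frame_index=k, face_found=False,
                warp_mode=opts.warp_mode,
            )
            continue
        axis = estimate_axis(det.landmarks)
        yield composite(frame, det.landmarks, axis, unaffected, opts,
                        source_frame_index=k)


def electrode_occlusion_check(
    landmarks: LandmarkSet,
    axis: SymmetryAxis,
    regions: Iterable[tuple[float, float, float, float]],
    unaffected: str,
) -> list[dict]:
    """Report whether each region (x, y, w, h box, image coordinates) lies on
    the affected side — and is therefore hidden by the mirrored composite.

    ``hidden`` is "full" when the whole box is on the affected side,
    "partial" when the box straddles the axis, and "none" when it lies on
    the unaffected (visible) side.  Models the clinical caveat that an
    electrode reaching past the midline stays partially visible.
    """
    u = _unaffected_sign(unaffected)
    report = []
    for (x, y, bw, bh) in regions:
        corners = np.array([[x, y], [x + bw, y], [x, y + bh], [x + bw, y + bh]])
        s = axis.signed_distance(corners) * u
        if np.all(s < 0):
            hidden = "full"
        elif np.all(s > 0):
            hidden = "none"
        else:
            hidden = "partial"
        report.append({"region": (x, y, bw, bh), "hidden": hidden,
                       "hidden_bool": hidden == "full"})
    return report
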