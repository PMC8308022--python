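"""Parametric toy faces with known ground truth.

Generates 68-point landmark sets from a fixed bilaterally symmetric
template (proportions in units of the interocular distance, table below),
optionally tilted, translated and given a unilateral droop that emulates
the hallmark presentation of peripheral facial palsy: brow sagging, a
downturned mouth corner and a weakened lower eyelid on the affected side.
A matching raster face is rendered from smooth analytic primitives
(soft-edged ellipses and capsules), so the droop-0 face is symmetric about
its ground-truth axis to floating precision — the property the compositor
tests rely on.

Template proportions (face frame: x across, y down, origin between the
eyes, interocular distance = 1):

====================  =======================================
head outline          ellipse c=(0, 0.30), rx 1.15, ry 1.10 up / 1.30 down
eye centers           (-0.50, 0) and (+0.50, 0), half-width 0.21
brows                 y about -0.30, x 0.15 - 0.85
nose bridge           x = 0, y -0.05 - 0.50; alae at y about 0.65
mouth corners         (-0.42, 0.95) and (+0.42, 0.95)
chin (jaw midpoint)   (0, 1.60)
====================  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from . import schema68
from .errors import ParameterError
from .landmarks import DEFAULT_SCHEMA, FaceBox, LandmarkProvider, LandmarkSet, LandmarkSchema
from .symmetry import SymmetryAxis

__all__ = [
    "FaceParams",
    "generate_face",
    "generate_landmarks",
    "generate_sequence",
    "OracleProvider",
]

# ---------------------------------------------------------------------------
# the symmetric 68-point template (face frame, interocular = 1)
# ---------------------------------------------------------------------------

def _template_points() -> np.ndarray:
    pts = np.zeros((68, 2))
    # jaw 0-16 on an ellipse arc, chin at index 8
    i = np.arange(17)
    pts[0:17, 0] = -1.15 * np.cos(np.pi * i / 16)
    pts[0:17, 1] = 0.30 + 1.30 * np.sin(np.pi * i / 16)
    # brows 17-21 (left, outer->inner) and 22-26 (right, inner->outer)
    left_brow = np.array(
        [(-0.85, -0.28), (-0.68, -0.34), (-0.50, -0.36), (-0.32, -0.34), (-0.15, -0.30)]
    )
    pts[17:22] = left_brow
    pts[22:27] = left_brow[::-1] * [-1, 1]
    # nose bridge 27-30 and base 31-35
    pts[27:31] = [(0, -0.05), (0, 0.15), (0, 0.35), (0, 0.50)]
    pts[31:36] = [(-0.18, 0.62), (-0.09, 0.65), (0, 0.67), (0.09, 0.65), (0.18, 0.62)]
    # eyes 36-41 (left) / 42-47 (right)
    left_eye = np.array(
        [(-0.71, 0.0), (-0.57, -0.06), (-0.43, -0.06), (-0.29, 0.0),
         (-0.43, 0.06), (-0.57, 0.06)]
    )
    pts[36:42] = left_eye
    pts[42:48] = left_eye[[3, 2, 1, 0, 5, 4]] * [-1, 1]
    # outer mouth 48-59 (clockwise from left corner)
    pts[48:60] = [
        (-0.42, 0.95), (-0.25, 0.88), (-0.10, 0.84), (0.0, 0.85), (0.10, 0.84),
        (0.25, 0.88), (0.42, 0.95), (0.25, 1.03), (0.10, 1.07), (0.0, 1.08),
        (-0.10, 1.07), (-0.25, 1.03),
    ]
    # inner mouth 60-67
    pts[60:68] = [
        (-0.30, 0.95), (-0.12, 0.92), (0.0, 0.93), (0.12, 0.92), (0.30, 0.95),
        (0.12, 0.99), (0.0, 1.00), (-0.12, 0.99),
    ]
    return pts


_TEMPLATE = _template_points()

# droop weights: full effect on brow and mouth, half on the eye ring
_DROOP_WEIGHTS = np.zeros(68)
_DROOP_WEIGHTS[17:22] = 1.0   # left brow
_DROOP_WEIGHTS[22:27] = 1.0   # right brow
_DROOP_WEIGHTS[36:48] = 0.5   # eyes
_DROOP_WEIGHTS[48:68] = 1.0   # mouth
_DROOP_MAX = 0.3


@dataclass(frozen=True)
class FaceParams:
    """Parameters of one synthetic face; rendering is a pure function of
    these, so equal params (and seed) give bit-identical output."""

    image_size: tuple[int, int] = (640, 480)  # (width, height)
    center: tuple[float, float] | None = None  # defaults to image center
    interocular: float = 120.0  # px
    tilt_deg: float = 0.0
    droop_side: str = "none"  # image side: left | right | none
    droop_frac: float = 0.0   # fraction of interocular, 0-0.3
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        w, h = self.image_size
        # (w-1)/2 keeps the pixel grid symmetric about the midline
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def validate(self) -> None:
        if self.interocular <= 0:
            raise ParameterError("interocular must be positive")
        if not 0.0 <= self.droop_frac <= _DROOP_MAX:
            raise ParameterError(f"droop_frac must be in [0, {_DROOP_MAX}]")
        if self.droop_side not in ("left", "right", "none"):
            raise ParameterError("droop_side must be left, right or none")


def _face_frame_landmarks(params: FaceParams) -> np.ndarray:
    pts = _TEMPLATE.copy()
    if params.droop_side != "none" and params.droop_frac > 0:
        side_sign = -1.0 if params.droop_side == "left" else 1.0
        on_side = np.sign(pts[:, 0]) == side_sign
        pts[:, 1] += np.where(on_side, _DROOP_WEIGHTS * params.droop_frac, 0.0)
    return pts


def _rotation(tilt_deg: float) -> np.ndarray:
    t = np.radians(tilt_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def generate_landmarks(params: FaceParams) -> tuple[LandmarkSet, SymmetryAxis]:
    """Landmark set plus ground-truth axis, without rendering the raster.

    The ground-truth axis is the template midline (x = 0, pointing toward
    the forehead) carried through the same rotation/translation — i.e. the
    pre-droop axis, since droop displaces points along the face, not the
    midline itself.
    """
    params.validate()
    pts = _face_frame_landmarks(params)
    R = _rotation(params.tilt_deg)
    center = np.asarray(params.resolved_center())
    img_pts = center + params.interocular * (pts @ R.T)
    direction = R @ np.array([0.0, -1.0])
    axis = SymmetryAxis(tuple(center), (float(direction[0]), float(direction[1])))
    lms = LandmarkSet(DEFAULT_SCHEMA, img_pts, params.image_size)
    return lms, axis


# ---------------------------------------------------------------------------
# analytic raster rendering
# ---------------------------------------------------------------------------

_EDGE = 0.02  # soft-edge half width, face units


def _smoothstep(d: np.ndarray) -> np.ndarray:
    """1 inside (d<=-edge), 0 outside (d>=edge), smooth ramp between."""
    t = np.clip((_EDGE - d) / (2 * _EDGE), 0.0, 1.0)
    return t * t * (3 - 2 * t)


def _ellipse_alpha(qx, qy, cx, cy, rx, ry):
    d = np.hypot((qx - cx) / rx, (qy - cy) / ry) - 1.0
    return _smoothstep(d * min(rx, ry))


def _capsule_alpha(qx, qy, chain: np.ndarray, radius: float):
    """Soft union of capsules along a polyline."""
    alpha = np.zeros_like(qx)
    for (x0, y0), (x1, y1) in zip(chain[:-1], chain[1:]):
        vx, vy = x1 - x0, y1 - y0
        denom = vx * vx + vy * vy
        if denom == 0:
            t = np.zeros_like(qx)
        else:
            t = np.clip(((qx - x0) * vx + (qy - y0) * vy) / denom, 0.0, 1.0)
        d = np.hypot(qx - (x0 + t * vx), qy - (y0 + t * vy)) - radius
        alpha = np.maximum(alpha, _smoothstep(d))
    return alpha


def _render(params: FaceParams, face_pts: np.ndarray) -> np.ndarray:
    w, h = params.image_size
    center = np.asarray(params.resolved_center())
    R = _rotation(params.tilt_deg)
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    px, py = np.meshgrid(xs, ys)
    # pixel -> face frame
    rx_ = (px - center[0]) / params.interocular
    ry_ = (py - center[1]) / params.interocular
    qx = R[0, 0] * rx_ + R[1, 0] * ry_
    qy = R[0, 1] * rx_ + R[1, 1] * ry_

    img = np.full((h, w), 30.0)  # background

    def paint(alpha, value):
        nonlocal img
        img = img * (1 - alpha) + value * alpha

    # head: two half-ellipses sharing rx
    ry_head = np.where(qy >= 0.30, 1.30, 1.10)
    d_head = np.hypot((qx) / 1.15, (qy - 0.30) / ry_head) - 1.0
    paint(_smoothstep(d_head * 1.1), 200.0)

    # brows (capsules through the landmark chains)
    paint(_capsule_alpha(qx, qy, face_pts[17:22], 0.045), 80.0)
    paint(_capsule_alpha(qx, qy, face_pts[22:27], 0.045), 80.0)

    # eyes: sclera ellipse + pupil, geometry from the (possibly drooped) ring
    for ring in (face_pts[36:42], face_pts[42:48]):
        c = ring.mean(axis=0)
        erx = 0.5 * abs(ring[3, 0] - ring[0, 0])
        paint(_ellipse_alpha(qx, qy, c[0], c[1], erx, 0.085), 250.0)
        paint(_ellipse_alpha(qx, qy, c[0], c[1], 0.07, 0.07), 40.0)

    # nose: bridge capsule + base polyline
    paint(_capsule_alpha(qx, qy, face_pts[27:31], 0.05), 150.0)
    paint(_capsule_alpha(qx, qy, face_pts[31:36], 0.035), 150.0)

    # mouth: ellipse fitted to the (possibly drooped) outer ring
    ring = face_pts[48:60]
    c = ring.mean(axis=0)
    corner_vec = face_pts[54] - face_pts[48]
    half_w = 0.5 * np.hypot(*corner_vec)
    half_h = 0.5 * (face_pts[57, 1] - face_pts[51, 1])
    ang = np.arctan2(corner_vec[1], corner_vec[0])
    ca, sa = np.cos(ang), np.sin(ang)
    mx = ca * (qx - c[0]) + sa * (qy - c[1])
    my = -sa * (qx - c[0]) + ca * (qy - c[1])
    d_mouth = np.hypot(mx / half_w, my / max(half_h, 1e-6)) - 1.0
    paint(_smoothstep(d_mouth * min(half_w, half_h)), 100.0)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_face(params: FaceParams) -> tuple[np.ndarray, LandmarkSet, SymmetryAxis]:
    """Render one toy face.

    Returns ``(image, landmarks, ground_truth_axis)``; the image is a
    ``(height, width)`` uint8 array.
    """
    lms, axis = generate_landmarks(params)
    image = _render(params, _face_frame_landmarks(params))
    return image, lms, axis


def generate_sequence(
    params: FaceParams, n_frames: int, motion: tuple[float, float] = (0.0, 0.0)
) -> Iterator[tuple[np.ndarray, LandmarkSet, SymmetryAxis]]:
    """Frames of a face translating by ``motion`` px/frame, with per-frame
    ground truth."""
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    base_center = np.asarray(params.resolved_center())
    for k in range(n_frames):
        c = base_center + k * np.asarray(motion, float)
        yield generate_face(replace(params, center=(float(c[0]), float(c[1]))))


class OracleProvider:
    """Detector plug-in that returns pre-registered ground-truth landmarks.

    Reports no-face for (near-)blank images, mimicking a real detector's
    behaviour on empty frames; otherwise returns the stored landmarks and
    their bounding box.  Used to exercise the detection/compositing chain
    without an external model.
    """

    def __init__(self, landmarks: LandmarkSet | list[LandmarkSet]):
        self._frames = landmarks if isinstance(landmarks, list) else [landmarks]
        self._cursor = 0
        self.schema: LandmarkSchema = self._frames[0].schema

    def detect(self, image: np.ndarray):
        if image.size == 0 or float(np.ptp(image)) < 1.0:
            return None
        lms = self._frames[min(self._cursor, len(self._frames) - 1)]
        self._cursor += 1
        return FaceBox.from_points(lms.points, margin=2.0), lms.copy()


def interocular_distance(lms: LandmarkSet) -> float:
    """Distance between the two eye-ring centroids (68-point layout)."""
    left = lms.points[list(schema68.LEFT_EYE_68)].mean(axis=0)
    right = lms.points[list(schema68.RIGHT_EYE_68)].mean(axis=0)
    return float(np.hypot(*(right - left)))
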