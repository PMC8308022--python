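"""Bilateral symmetry axis of a face: estimation, reflection, side labels.

The face midline is modeled as an oriented line (anchor point + unit
direction, direction pointing from chin toward forehead).  It is estimated
by a total-least-squares line fit through the midpoints of all bilateral
landmark pairs together with the midline landmarks: for a bilaterally
symmetric point set every such constraint point lies exactly on the axis,
and under unilateral droop the midpoints move predominantly *along* the
axis, so the fit degrades gracefully.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InsufficientConstraintsError, SchemaMismatchError
from .landmarks import LandmarkSet

__all__ = [
    "SymmetryAxis",
    "estimate_axis",
    "reflect_point",
    "classify_sides",
    "mirrored_landmarks",
    "ON_AXIS_TOL_PX",
]

#: half-width of the "on-axis" band used by side classification, pixels
ON_AXIS_TOL_PX = 0.5


@dataclass(frozen=True)
class SymmetryAxis:
    """Oriented midline: a point on the line and a unit direction.

    By convention ``direction`` points "up" the face, from chin toward
    forehead; for an upright face in image coordinates (y down) that is
    approximately ``(0, -1)``.
    """

    anchor: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        norm = float(np.hypot(*d))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit length (got {norm})")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal (90 deg counter-clockwise from direction in x-right,
        y-down coordinates)."""
        dx, dy = self.direction
        return np.array([-dy, dx])

    def angle_from_vertical_deg(self) -> float:
        """Unsigned angle between the axis and the image vertical."""
        dx, dy = self.direction
        return float(np.degrees(np.arccos(min(1.0, abs(dy)))))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular signed distance of points from the axis line.

        The sign is the z-component of direction x (p - anchor): positive
        on one side, negative on the other.
        """
        p = np.atleast_2d(np.asarray(points, float))
        rel = p - np.asarray(self.anchor, float)
        dx, dy = self.direction
        return dx * rel[:, 1] - dy * rel[:, 0]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"anchor": list(self.anchor), "direction": list(self.direction)}
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SymmetryAxis":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(tuple(d["anchor"]), tuple(d["direction"]))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.hypot(*v)


def estimate_axis(lms: LandmarkSet) -> SymmetryAxis:
    """Estimate the face midline from a landmark set.

    Fits the total-least-squares line through the bilateral-pair midpoints
    and the midline landmarks (equal weights): anchor = centroid, direction
    = principal eigenvector of the 2x2 scatter matrix.  When the schema has
    no usable pairs or midline points, falls back to the principal axis of
    all landmarks.  The direction is oriented chin -> forehead using the
    schema's anatomical anchors.
    """
    schema = lms.schema
    pts = lms.points
    constraints = []
    for left, right in schema.bilateral_pairs:
        constraints.append(0.5 * (pts[left] + pts[right]))
    for idx in schema.midline_indices:
        constraints.append(pts[idx])
    constraints = np.asarray(constraints, float)
    if len(constraints) < 2:
        # PCA-of-all-points fallback
        constraints = pts
    if len(constraints) < 2:
        raise InsufficientConstraintsError(
            "need at least 2 bilateral pairs or midline points"
        )
    centroid = constraints.mean(axis=0)
    centered = constraints - centroid
    cov = centered.T @ centered
    # principal eigenvector of a symmetric 2x2 matrix
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, np.argmax(eigvals)]
    if np.allclose(cov, 0):
        raise InsufficientConstraintsError("constraint points are coincident")
    # orient chin -> forehead
    up = pts[schema.superior_index] - pts[schema.chin_index]
    if float(direction @ up) < 0:
        direction = -direction
    direction = _unit(direction)
    return SymmetryAxis(tuple(centroid), (float(direction[0]), float(direction[1])))


def reflect_point(p, axis: SymmetryAxis) -> np.ndarray:
    """Householder reflection of point(s) across the axis line.

    Accepts a single ``(x, y)`` or an ``(n, 2)`` array; returns the same
    shape.  The reflection is an involution: applying it twice returns the
    input (to floating precision).
    """
    arr = np.asarray(p, dtype=float)
    single = arr.ndim == 1
    pts = np.atleast_2d(arr)
    a = np.asarray(axis.anchor, float)
    d = np.asarray(axis.direction, float)
    rel = pts - a
    # v' = 2 (v.d) d - v  reflects across the line through a along d
    out = a + 2.0 * np.outer(rel @ d, d) - rel
    return out[0] if single else out


def classify_sides(
    lms: LandmarkSet | np.ndarray, axis: SymmetryAxis, tol: float = ON_AXIS_TOL_PX
) -> list[str]:
    """Label each point ``left-of-axis``, ``right-of-axis`` or ``on-axis``.

    "Left"/"right" are image sides for a face whose axis points up the
    image; labels are equivariant under rigid motions of face+axis.  Points
    within ``tol`` pixels of the line are on-axis (ties resolve on-axis).
    """
    pts = lms.points if isinstance(lms, LandmarkSet) else np.atleast_2d(lms)
    s = axis.signed_distance(pts)
    labels = []
    for v in s:
        if abs(v) <= tol:
            labels.append("on-axis")
        elif v > 0:
            labels.append("right-of-axis")
        else:
            labels.append("left-of-axis")
    return labels


def _image_side_of(label: str) -> str:
    return {"left-of-axis": "left", "right-of-axis": "right"}.get(label, "on")


def mirrored_landmarks(
    lms: LandmarkSet, axis: SymmetryAxis, unaffected: str
) -> LandmarkSet:
    """Replace affected-side points by the reflection of their partners.

    ``unaffected`` is the *image* side ("left" or "right") whose geometry is
    kept; every point on the other side is replaced by ``reflect_point`` of
    its bilateral partner.  Midline/on-axis points are kept.  The result is
    bilaterally symmetric about ``axis`` (up to the asymmetry of on-axis
    points themselves).
    """
    if unaffected not in ("left", "right"):
        raise ValueError("unaffected must be 'left' or 'right' (image side)")
    out = lms.points.copy()
    labels = classify_sides(lms, axis)
    for idx in range(len(lms)):
        side = _image_side_of(labels[idx])
        if side in ("on", unaffected):
            continue
        partner = lms.schema.partner(idx)
        if partner is None:
            # a midline-schema point displaced off axis: reflect it onto itself
            continue
        if _image_side_of(labels[partner]) == side:
            raise SchemaMismatchError(
                f"partner {partner} of affected point {idx} lies on the "
                "affected side too; cannot mirror"
            )
        out[idx] = reflect_point(lms.points[partner], axis)
    return LandmarkSet(lms.schema, out, lms.image_size)
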