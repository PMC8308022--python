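"""Facial landmark schemas, file I/O, the detector plug-in contract, and
triangular mesh construction.

Coordinate convention (used everywhere in the package): pixels, origin at
the top-left image corner, x rightward, y downward, 0-based indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
from scipy.spatial import Delaunay, QhullError

from . import schema68
from .errors import (
    DegenerateGeometryError,
    LandmarkParseError,
    ProviderError,
    SchemaMismatchError,
)

__all__ = [
    "LandmarkSchema",
    "LandmarkSet",
    "FaceBox",
    "TriangleMesh",
    "DetectionResult",
    "LandmarkProvider",
    "DEFAULT_SCHEMA",
    "load_landmarks",
    "save_landmarks",
    "detect_landmarks",
    "build_mesh",
    "register_provider",
    "get_provider",
]


@dataclass(frozen=True)
class LandmarkSchema:
    """Names and bilateral structure of a landmark layout.

    Every point index appears exactly once, either as a member of one
    bilateral pair or in ``midline_indices``.  ``chin_index`` and
    ``superior_index`` are midline anchors used to orient the face axis
    from chin toward forehead.
    """

    name: str
    point_names: tuple[str, ...]
    bilateral_pairs: tuple[tuple[int, int], ...]
    midline_indices: tuple[int, ...]
    chin_index: int
    superior_index: int

    def __post_init__(self) -> None:
        n = len(self.point_names)
        seen: set[int] = set()
        for left, right in self.bilateral_pairs:
            if left == right:
                raise SchemaMismatchError(f"pair ({left}, {right}) is degenerate")
            for idx in (left, right):
                if idx in seen:
                    raise SchemaMismatchError(f"index {idx} appears twice")
                seen.add(idx)
        for idx in self.midline_indices:
            if idx in seen:
                raise SchemaMismatchError(f"index {idx} appears twice")
            seen.add(idx)
        if seen != set(range(n)):
            raise SchemaMismatchError(
                f"pairs + midline must cover all {n} indices exactly once"
            )
        if self.chin_index not in self.midline_indices:
            raise SchemaMismatchError("chin_index must be a midline index")
        if self.superior_index not in self.midline_indices:
            raise SchemaMismatchError("superior_index must be a midline index")

    def __len__(self) -> int:
        return len(self.point_names)

    def index_of(self, label: str) -> int:
        try:
            return self.point_names.index(label)
        except ValueError:
            raise SchemaMismatchError(f"unknown point label {label!r}") from None

    def partner(self, index: int) -> int | None:
        """Bilateral partner of a point, or None for midline points."""
        for left, right in self.bilateral_pairs:
            if index == left:
                return right
            if index == right:
                return left
        return None


#: Default schema: the packaged 68-point layout.
DEFAULT_SCHEMA = LandmarkSchema(
    name="face68",
    point_names=schema68.POINT_NAMES_68,
    bilateral_pairs=schema68.BILATERAL_PAIRS_68,
    midline_indices=schema68.MIDLINE_INDICES_68,
    chin_index=schema68.CHIN_INDEX_68,
    superior_index=schema68.NOSE_BRIDGE_INDEX_68,
)


@dataclass
class LandmarkSet:
    """Named 2D feature points of one face, in pixel coordinates."""

    schema: LandmarkSchema
    points: np.ndarray  # (n, 2) float64
    image_size: tuple[int, int] | None = None  # (width, height)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.shape != (len(self.schema), 2):
            raise SchemaMismatchError(
                f"expected {len(self.schema)} points, got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise SchemaMismatchError("landmark coordinates must be finite")

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.schema, self.points.copy(), self.image_size)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned rectangle enclosing the detected face."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("face box must have positive extent")

    @classmethod
    def from_points(cls, points: np.ndarray, margin: float = 0.0) -> "FaceBox":
        pts = np.asarray(points, dtype=float)
        lo = pts.min(axis=0) - margin
        hi = pts.max(axis=0) + margin
        return cls(lo[0], lo[1], hi[0] - lo[0], hi[1] - lo[1])


@dataclass(frozen=True)
class TriangleMesh:
    """A triangulation of a landmark set, stored as vertex-index triples."""

    vertex_indices: tuple[tuple[int, int, int], ...]

    def __len__(self) -> int:
        return len(self.vertex_indices)


@dataclass
class DetectionResult:
    """Outcome of running a detector on one image.

    ``found`` is False when the provider reports no face; that is a normal
    result, not an error.
    """

    found: bool
    box: FaceBox | None = None
    landmarks: LandmarkSet | None = None


@runtime_checkable
class LandmarkProvider(Protocol):
    """Detector plug-in contract.

    ``detect`` returns ``(FaceBox, LandmarkSet)`` in image coordinates, or
    ``None`` when the image contains no face.  Implementations wrap external
    models (constrained local models, mediapipe, dlib, ...) or, for testing,
    return known ground-truth landmarks.
    """

    schema: LandmarkSchema

    def detect(self, image: np.ndarray) -> tuple[FaceBox, LandmarkSet] | None: ...


_PROVIDERS: dict[str, LandmarkProvider] = {}


def register_provider(name: str, provider: LandmarkProvider) -> None:
    _PROVIDERS[name] = provider


def get_provider(name: str) -> LandmarkProvider:
    try:
        return _PROVIDERS[name]
    except KeyError:
        raise ProviderError(
            f"no landmark provider registered under {name!r}; "
            f"available: {sorted(_PROVIDERS)}"
        ) from None


def detect_landmarks(
    image: np.ndarray, provider: LandmarkProvider | str
) -> DetectionResult:
    """Run a detector plug-in on one image.

    Returns a :class:`DetectionResult`; a no-face outcome is reported via
    ``found=False`` rather than an exception.
    """
    if isinstance(provider, str):
        provider = get_provider(provider)
    image = np.asarray(image)
    if image.size == 0:
        raise ProviderError("empty image")
    hit = provider.detect(image)
    if hit is None:
        return DetectionResult(found=False)
    box, lms = hit
    return DetectionResult(found=True, box=box, landmarks=lms)


# ---------------------------------------------------------------------------
# File I/O.  CSV dialect: header "label,x,y", one row per point.
# JSON dialect: {"schema": name, "points": [{"label":..,"x":..,"y":..}]}.
# ---------------------------------------------------------------------------

def save_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set as CSV or JSON (chosen by file extension)."""
    path = Path(path)
    rows = [
        (name, float(x), float(y))
        for name, (x, y) in zip(lms.schema.point_names, lms.points)
    ]
    if path.suffix.lower() == ".json":
        payload = {
            "schema": lms.schema.name,
            "points": [{"label": n, "x": x, "y": y} for n, x, y in rows],
        }
        if lms.image_size is not None:
            payload["image_size"] = list(lms.image_size)
        path.write_text(json.dumps(payload, indent=1))
    else:
        lines = ["label,x,y"]
        lines += [f"{n},{x:.10g},{y:.10g}" for n, x, y in rows]
        path.write_text("\n".join(lines) + "\n")


def _rows_from_csv(text: str) -> list[tuple[str, float, float]]:
    rows = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].strip().lower().replace(" ", "") != "label,x,y":
        raise LandmarkParseError("expected CSV header 'label,x,y'")
    for ln in lines[1:]:
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != 3:
            raise LandmarkParseError(f"malformed row: {ln!r}")
        label, xs, ys = parts
        try:
            rows.append((label, float(xs), float(ys)))
        except ValueError:
            raise LandmarkParseError(f"non-numeric coordinate in row {ln!r}") from None
    return rows


def load_landmarks(path: str | Path, schema: LandmarkSchema = DEFAULT_SCHEMA) -> LandmarkSet:
    """Read a landmark file (CSV or JSON) and order its points per ``schema``.

    Raises :class:`SchemaMismatchError` if any schema label is missing and
    :class:`LandmarkParseError` on malformed content.
    """
    path = Path(path)
    text = path.read_text()
    image_size = None
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(text)
            rows = [(p["label"], float(p["x"]), float(p["y"])) for p in payload["points"]]
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise LandmarkParseError(f"bad landmark JSON: {exc}") from exc
        if payload.get("image_size") is not None:
            image_size = tuple(payload["image_size"])
    else:
        rows = _rows_from_csv(text)
    by_label = {label: (x, y) for label, x, y in rows}
    missing = [n for n in schema.point_names if n not in by_label]
    if missing:
        raise SchemaMismatchError(f"missing point labels: {missing[:5]}...")
    points = np.array([by_label[n] for n in schema.point_names], dtype=np.float64)
    return LandmarkSet(schema, points, image_size)


# ---------------------------------------------------------------------------
# Triangular mesh over the landmark points
# ---------------------------------------------------------------------------

def build_mesh(lms: LandmarkSet | np.ndarray) -> TriangleMesh:
    """Delaunay-triangulate the landmark points.

    The triangulation covers the convex hull of the points; for cocircular
    configurations the returned triangle set follows Qhull's resolution,
    with vertices of each triangle sorted lexicographically.  Raises
    :class:`DegenerateGeometryError` for fewer than three points or an
    all-collinear configuration.
    """
    points = lms.points if isinstance(lms, LandmarkSet) else np.asarray(lms, float)
    if len(points) < 3:
        raise DegenerateGeometryError("need at least 3 points to triangulate")
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point configuration: {exc}") from exc
    triangles = []
    for simplex in tri.simplices:
        i, j, k = sorted(int(v) for v in simplex)
        a, b, c = points[i], points[j], points[k]
        area = 0.5 * abs(
            (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
        )
        if area > 1e-12:
            triangles.append((i, j, k))
    if not triangles:
        raise DegenerateGeometryError("all points are collinear")
    triangles.sort()
    return TriangleMesh(tuple(triangles))


def convex_hull_size(points: np.ndarray) -> int:
    """Number of points on the convex hull (helper for the Euler relation
    2n - 2 - h of a planar Delaunay triangulation)."""
    from scipy.spatial import ConvexHull

    return len(ConvexHull(np.asarray(points, float)).vertices)


def mesh_triangles(mesh: TriangleMesh, points: np.ndarray) -> Iterable[np.ndarray]:
    for i, j, k in mesh.vertex_indices:
        yield np.asarray([points[i], points[j], points[k]])
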