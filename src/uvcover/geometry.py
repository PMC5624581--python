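"""Facial landmarks and analysis regions.

All geometry is anchored on a named landmark set (eye corners, brow apexes,
nose bridge/tip, chin, face-outline extremes).  From those landmarks three
rectangular analysis regions are derived: the cropped face box, the eyelid
"letterbox" spanning both eyelids, the periorbital areas and the nose
bridge, and a small square on each medial canthus centred on the inner-eye
landmark.  Coordinates are 0-based pixels, x rightward, y downward, and all
rectangles are half-open intervals [x0, x1) x [y0, y1).

Landmarks come from a pluggable provider: the shipped provider reads the
ground-truth JSON sidecars written by the phantom generator; an external
face detector can be plugged in through the same ``detect`` contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "Rect",
    "LandmarkSet",
    "RegionSet",
    "GeometryConfig",
    "NoFaceError",
    "MalformedLandmarksError",
    "SidecarProvider",
    "get_landmarks",
    "derive_regions",
]

LANDMARK_NAMES = (
    "left_outer_eye",
    "left_inner_eye",
    "right_inner_eye",
    "right_outer_eye",
    "left_brow",
    "right_brow",
    "nose_bridge",
    "nose_tip",
    "chin",
    "left_face",
    "right_face",
)


class NoFaceError(RuntimeError):
    """The landmark provider found no face in the image."""


class MalformedLandmarksError(ValueError):
    """A landmark source is incomplete or inconsistent."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open pixel rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1 - 1) / 2.0, (self.y0 + self.y1 - 1) / 2.0)

    def contains(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )

    def clip(self, width: int, height: int) -> "Rect":
        return Rect(
            max(self.x0, 0), max(self.y0, 0), min(self.x1, width), min(self.y1, height)
        )

    def slices(self) -> tuple[slice, slice]:
        """(row slice, column slice) for numpy indexing."""
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.slices()] = True
        return m


class LandmarkSet:
    """Complete named set of 2-D pixel landmarks.

    Validates completeness and left/right consistency on construction:
    every name in :data:`LANDMARK_NAMES` must be present, left-side points
    must lie left of their right-side counterparts, and the inner eye
    corners must lie between the outer corners.
    """

    def __init__(self, points: Mapping[str, tuple[float, float]],
                 image_shape: tuple[int, int] | None = None):
        missing = [n for n in LANDMARK_NAMES if n not in points]
        if missing:
            raise MalformedLandmarksError(f"missing landmarks: {missing}")
        self._points = {}
        for name in LANDMARK_NAMES:
            p = points[name]
            if len(p) != 2 or not all(math.isfinite(float(v)) for v in p):
                raise MalformedLandmarksError(f"bad coordinates for {name}: {p!r}")
            self._points[name] = (float(p[0]), float(p[1]))
        lo, li = self["left_outer_eye"], self["left_inner_eye"]
        ri, ro = self["right_inner_eye"], self["right_outer_eye"]
        if not (lo[0] < li[0] < ri[0] < ro[0]):
            raise MalformedLandmarksError("eye corners out of left-to-right order")
        if not self["left_face"][0] < self["right_face"][0]:
            raise MalformedLandmarksError("face outline extremes reversed")
        if image_shape is not None:
            h, w = image_shape
            for name, (x, y) in self._points.items():
                if not (0 <= x < w and 0 <= y < h):
                    raise MalformedLandmarksError(
                        f"landmark {name} at {(x, y)} outside {w}x{h} image"
                    )

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self._points[name]

    def __iter__(self):
        return iter(self._points)

    def __eq__(self, other) -> bool:
        return isinstance(other, LandmarkSet) and self._points == other._points

    def as_dict(self) -> dict[str, list[float]]:
        return {name: [x, y] for name, (x, y) in self._points.items()}

    def scaled(self, factor: float) -> "LandmarkSet":
        return LandmarkSet(
            {n: (x * factor, y * factor) for n, (x, y) in self._points.items()}
        )

    @property
    def eye_centers(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Midpoints of each eye's corner pair, (left, right)."""
        lo, li = self["left_outer_eye"], self["left_inner_eye"]
        ri, ro = self["right_inner_eye"], self["right_outer_eye"]
        return (
            ((lo[0] + li[0]) / 2.0, (lo[1] + li[1]) / 2.0),
            ((ri[0] + ro[0]) / 2.0, (ri[1] + ro[1]) / 2.0),
        )

    @property
    def interocular_distance(self) -> float:
        (lx, ly), (rx, ry) = self.eye_centers
        return math.hypot(rx - lx, ry - ly)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.as_dict(), indent=0, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise MalformedLandmarksError(f"unreadable sidecar {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise MalformedLandmarksError(f"sidecar {path} is not a JSON object")
        return cls(data)


class LandmarkProvider(Protocol):
    """Contract for landmark sources: detector adapters or sidecar readers."""

    def detect(self, image: np.ndarray) -> Mapping[str, tuple[float, float]]:
        """Return the full named landmark map or raise NoFaceError."""
        ...


class SidecarProvider:
    """Reads ground-truth landmarks from the generator's JSON sidecar."""

    def __init__(self, path):
        self.path = Path(path)

    def detect(self, image: np.ndarray) -> Mapping[str, tuple[float, float]]:
        if not self.path.exists():
            raise NoFaceError(f"no landmark sidecar at {self.path}")
        return {k: tuple(v) for k, v in json.loads(self.path.read_text()).items()}


def get_landmarks(image: np.ndarray, provider) -> LandmarkSet:
    """Obtain a complete, validated landmark set for one image.

    Never returns a partial set: an incomplete or inconsistent result from
    the provider raises :class:`MalformedLandmarksError`; an absent face
    raises :class:`NoFaceError`.
    """
    points = provider.detect(image)
    return LandmarkSet(points, image_shape=image.shape)


@dataclass(frozen=True)
class GeometryConfig:
    """Region-derivation parameters, as fractions of the inter-ocular
    distance (IOD) unless stated otherwise.

    face_margin          lateral/chin margin added to the outline bounding box
    face_top_pad         face-box top above the brow line
    letterbox_hpad       letterbox horizontal pad beyond the outer eye corners
    letterbox_top_pad    letterbox top above the brow line
    letterbox_bottom_frac  letterbox bottom below the eye line, as a fraction
                           of the eye-to-nose-tip distance
    canthus_frac         side of the square medial-canthus box
    """

    face_margin: float = 0.05
    face_top_pad: float = 0.25
    letterbox_hpad: float = 0.10
    letterbox_top_pad: float = 0.15
    letterbox_bottom_frac: float = 0.60
    canthus_frac: float = 0.25


@dataclass(frozen=True)
class RegionSet:
    """The analysis rectangles: face crop, eyelid letterbox, canthal boxes.

    Nesting invariants (letterbox inside face box, each canthus box inside
    the letterbox, nonempty rest-of-face) are enforced on construction.
    """

    face_box: Rect
    eyelid_letterbox: Rect
    canthus_left: Rect
    canthus_right: Rect

    def __post_init__(self):
        if not self.face_box.contains(self.eyelid_letterbox):
            raise ValueError("letterbox not contained in face box")
        for c in (self.canthus_left, self.canthus_right):
            if not self.eyelid_letterbox.contains(c):
                raise ValueError("canthus box not contained in letterbox")
        if self.face_box.area <= self.eyelid_letterbox.area:
            raise ValueError("rest-of-face region is empty")

    def as_rows(self) -> list[tuple[str, int, int, int, int]]:
        """(region_name, x0, y0, x1, y1) rows for audit export."""
        return [
            (name, r.x0, r.y0, r.x1, r.y1)
            for name, r in (
                ("face_box", self.face_box),
                ("eyelid_letterbox", self.eyelid_letterbox),
                ("canthus_left", self.canthus_left),
                ("canthus_right", self.canthus_right),
            )
        ]


def _canthus_square(center: tuple[float, float], side: int) -> Rect:
    half = side // 2
    x0 = int(round(center[0])) - half
    y0 = int(round(center[1])) - half
    return Rect(x0, y0, x0 + side, y0 + side)


def derive_regions(
    landmarks: LandmarkSet,
    image_dims: tuple[int, int],
    config: GeometryConfig | None = None,
) -> RegionSet:
    """Derive the analysis rectangles from a landmark set.

    image_dims is (height, width).  All boxes are clipped to the image, the
    letterbox to the face box and the canthal squares to the letterbox, so
    the nesting invariants hold by construction.  Degenerate landmarks
    (zero inter-ocular distance) raise ValueError.
    """
    if config is None:
        config = GeometryConfig()
    h, w = image_dims
    iod = landmarks.interocular_distance
    if iod <= 0:
        raise ValueError("degenerate landmarks: zero inter-ocular distance")

    brow_y = min(landmarks["left_brow"][1], landmarks["right_brow"][1])
    eye_y = (landmarks.eye_centers[0][1] + landmarks.eye_centers[1][1]) / 2.0
    nose_drop = landmarks["nose_tip"][1] - eye_y
    if nose_drop <= 0:
        raise ValueError("degenerate landmarks: nose tip above eye line")

    m = config.face_margin * iod
    face = Rect(
        int(round(landmarks["left_face"][0] - m)),
        int(round(brow_y - config.face_top_pad * iod)),
        int(round(landmarks["right_face"][0] + m)) + 1,
        int(round(landmarks["chin"][1] + m)) + 1,
    ).clip(w, h)

    letterbox = Rect(
        int(round(landmarks["left_outer_eye"][0] - config.letterbox_hpad * iod)),
        int(round(brow_y - config.letterbox_top_pad * iod)),
        int(round(landmarks["right_outer_eye"][0] + config.letterbox_hpad * iod)) + 1,
        int(round(eye_y + config.letterbox_bottom_frac * nose_drop)) + 1,
    )
    letterbox = Rect(
        max(letterbox.x0, face.x0),
        max(letterbox.y0, face.y0),
        min(letterbox.x1, face.x1),
        min(letterbox.y1, face.y1),
    )

    # odd side so the square is centred exactly on the inner-eye landmark
    side = max(3, int(round(config.canthus_frac * iod)) | 1)
    boxes = []
    for name in ("left_inner_eye", "right_inner_eye"):
        c = _canthus_square(landmarks[name], side)
        boxes.append(
            Rect(
                max(c.x0, letterbox.x0),
                max(c.y0, letterbox.y0),
                min(c.x1, letterbox.x1),
                min(c.y1, letterbox.y1),
            )
        )
    return RegionSet(face, letterbox, boxes[0], boxes[1])
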