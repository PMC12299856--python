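"""Exact geometry for axis-aligned bounding boxes.

Boxes live in continuous corner coordinates ``(x1, y1, x2, y2)`` with x
growing right and y growing down (image convention).  No pixel convention
(0/1-based, half-open) applies to the geometry itself: corners are reals
and areas are products of real side lengths.

Alongside the analytic primitives the module provides
:func:`rasterized_iou_oracle`, a deliberately naive pixel-center counting
estimate of IoU used as an independent cross-check in tests, and readers /
writers for the two plain-text box formats used throughout the package
(normalized YOLO rows and a 4-column corner CSV).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box",
    "BoxPairGeometry",
    "DegeneratePairError",
    "area",
    "center",
    "iou",
    "center_distance_sq",
    "enclosing_diagonal_sq",
    "pair_geometry",
    "rasterized_iou_oracle",
    "read_yolo",
    "write_yolo",
    "read_corner_csv",
    "write_corner_csv",
    "EPS",
]

#: Denominator floor for heights and the squared enclosing diagonal
#: (``max(value, EPS)`` keeps ratios exactly scale invariant away from the
#: degenerate limit while staying finite at it).
EPS = 1e-7


class DegeneratePairError(ValueError):
    """Both boxes collapse to the same single point; c^2 would be 0."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in corner format.

    Degenerate boxes (zero width or height) are permitted only when
    ``allow_degenerate=True`` is passed to :meth:`make`; the plain
    constructor validates finiteness and corner ordering.
    """

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        vals = (self.x1, self.y1, self.x2, self.y2)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite box coordinates {vals}")
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError(f"inverted box corners {vals}")

    @classmethod
    def make(cls, x1: float, y1: float, x2: float, y2: float,
             allow_degenerate: bool = True) -> "Box":
        b = cls(float(x1), float(y1), float(x2), float(y2))
        if not allow_degenerate and (b.width == 0.0 or b.height == 0.0):
            raise ValueError(f"degenerate box not permitted: {b}")
        return b

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def is_degenerate(self) -> bool:
        return self.width == 0.0 or self.height == 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.x1 + dx, self.y1 + dy, self.x2 + dx, self.y2 + dy)

    def scale(self, s: float) -> "Box":
        if s <= 0:
            raise ValueError("scale factor must be positive")
        return Box(self.x1 * s, self.y1 * s, self.x2 * s, self.y2 * s)


@dataclass(frozen=True)
class BoxPairGeometry:
    """All intermediate quantities of the penalised-IoU family for one pair.

    ``iou`` is plain intersection-over-union; ``rho_sq`` the squared center
    distance; ``c_sq`` the squared diagonal of the smallest enclosing box;
    ``v`` the angular aspect term (4/pi^2)(arctan r2 - arctan r1)^2;
    ``aspect_sq`` the squared width/height-ratio difference (r1 - r2)^2.
    All fields are symmetric under swapping the two boxes.
    """

    iou: float
    rho_sq: float
    c_sq: float
    v: float
    aspect_sq: float
    r1: float
    r2: float


def area(b: Box) -> float:
    """Area of a box; degenerate boxes return 0."""
    return b.width * b.height


def center(b: Box) -> tuple[float, float]:
    """Center point ``((x1+x2)/2, (y1+y2)/2)``."""
    return (0.5 * (b.x1 + b.x2), 0.5 * (b.y1 + b.y2))


def _intersection_area(a: Box, b: Box) -> float:
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    return iw * ih


def iou(a: Box, b: Box) -> float:
    """Intersection over union, in [0, 1].

    Two degenerate (zero-area) boxes yield 0 with a warning; a degenerate
    box against anything has IoU 0.
    """
    ia = _intersection_area(a, b)
    union = area(a) + area(b) - ia
    if union <= 0.0:
        warnings.warn("IoU of two degenerate (zero-area) boxes is defined as 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return ia / union


def center_distance_sq(a: Box, b: Box) -> float:
    """Squared Euclidean distance between box centers (rho^2)."""
    (ax, ay), (bx, by) = center(a), center(b)
    return (ax - bx) ** 2 + (ay - by) ** 2


def enclosing_diagonal_sq(a: Box, b: Box) -> float:
    """Squared diagonal c^2 = cw^2 + ch^2 of the smallest box covering both.

    Raises :class:`DegeneratePairError` when both boxes are the same single
    point (c^2 = 0 would make every normalized distance undefined).
    """
    cw = max(a.x2, b.x2) - min(a.x1, b.x1)
    ch = max(a.y2, b.y2) - min(a.y1, b.y1)
    c_sq = cw * cw + ch * ch
    if c_sq == 0.0:
        raise DegeneratePairError("degenerate pair: both boxes are one identical point")
    return c_sq


def pair_geometry(a: Box, b: Box, eps: float = EPS) -> BoxPairGeometry:
    """Compute every pairwise quantity the penalised-IoU losses consume.

    Heights are floored at ``eps`` in the ratio terms so degenerate inputs
    stay finite; ``c_sq`` is reported unguarded (the floor is applied at
    the point of division by the loss code).
    """
    c_sq = enclosing_diagonal_sq(a, b)
    r1 = a.width / max(a.height, eps)
    r2 = b.width / max(b.height, eps)
    dv = np.arctan(r2) - np.arctan(r1)
    v = float((4.0 / np.pi ** 2) * dv * dv)
    return BoxPairGeometry(
        iou=iou(a, b),
        rho_sq=center_distance_sq(a, b),
        c_sq=c_sq,
        v=v,
        aspect_sq=float((r1 - r2) ** 2),
        r1=float(r1),
        r2=float(r2),
    )


def rasterized_iou_oracle(a: Box, b: Box, grid: int = 1000) -> float:
    """Brute-force IoU estimate by pixel-center membership counting.

    A ``grid x grid`` lattice of pixel centers is laid over the enclosing
    box of the pair; intersection and union areas are estimated as counts
    of centers falling inside both / either box.  Converges to
    :func:`iou` as ``grid`` grows.  Test oracle only -- O(grid^2) per call.
    """
    if grid < 10:
        raise ValueError("grid must be >= 10")
    x_lo, x_hi = min(a.x1, b.x1), max(a.x2, b.x2)
    y_lo, y_hi = min(a.y1, b.y1), max(a.y2, b.y2)
    if x_hi <= x_lo or y_hi <= y_lo:
        return 1.0 if (a == b and not a.is_degenerate) else 0.0
    xs = x_lo + (np.arange(grid) + 0.5) * (x_hi - x_lo) / grid
    ys = y_lo + (np.arange(grid) + 0.5) * (y_hi - y_lo) / grid
    in_ax = (xs >= a.x1) & (xs <= a.x2)
    in_bx = (xs >= b.x1) & (xs <= b.x2)
    in_ay = (ys >= a.y1) & (ys <= a.y2)
    in_by = (ys >= b.y1) & (ys <= b.y2)
    in_a = in_ax[:, None] & in_ay[None, :]
    in_b = in_bx[:, None] & in_by[None, :]
    inter = np.count_nonzero(in_a & in_b)
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return inter / union


# ---------------------------------------------------------------------------
# Plain-text I/O: YOLO rows and corner CSV
# ---------------------------------------------------------------------------

def _yolo_row_to_box(cx: float, cy: float, w: float, h: float,
                     img_w: float, img_h: float) -> Box:
    cx, cy, w, h = cx * img_w, cy * img_h, w * img_w, h * img_h
    return Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def read_yolo(path: str | Path, img_size: tuple[float, float]
              ) -> list[tuple[int, Box, float | None]]:
    """Read a YOLO-format label file into denormalized corner boxes.

    Each row is ``class cx cy w h [conf]`` with coordinates normalized to
    the image; ``img_size`` is ``(width, height)`` in pixels.  Returns
    ``(class_id, Box, confidence-or-None)`` triples.
    """
    img_w, img_h = img_size
    out: list[tuple[int, Box, float | None]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (5, 6):
            raise ValueError(f"malformed YOLO row in {path!s}: {line!r}")
        cls = int(parts[0])
        cx, cy, w, h = map(float, parts[1:5])
        conf = float(parts[5]) if len(parts) == 6 else None
        out.append((cls, _yolo_row_to_box(cx, cy, w, h, img_w, img_h), conf))
    return out


def write_yolo(path: str | Path,
               rows: Iterable[tuple[int, Box, float | None]],
               img_size: tuple[float, float]) -> None:
    """Write ``(class_id, Box, confidence-or-None)`` triples as YOLO rows."""
    img_w, img_h = img_size
    lines = []
    for cls, b, conf in rows:
        cx, cy = center(b)
        fields = [str(int(cls)), f"{cx / img_w:.8f}", f"{cy / img_h:.8f}",
                  f"{b.width / img_w:.8f}", f"{b.height / img_h:.8f}"]
        if conf is not None:
            fields.append(f"{conf:.6f}")
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_corner_csv(path: str | Path) -> list[Box]:
    """Read boxes from a CSV with header ``x1,y1,x2,y2``."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames[:4]] != ["x1", "y1", "x2", "y2"]:
            raise ValueError(f"expected header 'x1,y1,x2,y2' in {path!s}")
        return [Box(float(r["x1"]), float(r["y1"]), float(r["x2"]), float(r["y2"]))
                for r in reader]


def write_corner_csv(path: str | Path, boxes: Sequence[Box]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x1", "y1", "x2", "y2"])
        for b in boxes:
            writer.writerow([repr(b.x1), repr(b.y1), repr(b.x2), repr(b.y2)])
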