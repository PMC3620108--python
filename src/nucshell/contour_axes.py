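"""Nucleus contour extraction and axis estimation.

The contour is found by scanning each image row from the left and from the
right until the first nucleus or probe pixel; the nucleus geometry is then
built from contour extremes: bounding box -> provisional midpoint -> the
contour point farthest from the midpoint (one end of the major axis) ->
the opposite perimeter intersection (the other end) -> refined midpoint ->
perpendicular minor chord.  No ellipse fitting or image moments are used;
the construction works for nuclei at arbitrary orientation.

Coordinates are 0-based, x rightward, y downward, with pixel centers at
integer positions; sub-pixel points are real-valued (x, y) pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from nucshell.errors import DegenerateNucleusError, GeometryError, NoNucleusError
from nucshell.pixel_model import NUCLEUS, PROBE, ClassGrid

Point = tuple[float, float]

SENTINEL = -1

# Sub-pixel step for marching a ray to its perimeter intersection.
MARCH_STEP = 0.25


@dataclass(frozen=True)
class Contour:
    """Per-row left/right nucleus extremes.

    ``left[y]`` (``right[y]``) is the smallest (largest) x in row y whose
    pixel is nucleus or probe, or SENTINEL (-1) when the row contains none.
    Concavities between the extremes are bridged: the enclosed region is
    everything between the two scans.
    """

    left: np.ndarray
    right: np.ndarray
    width: int

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=int)
        right = np.asarray(self.right, dtype=int)
        if left.shape != right.shape or left.ndim != 1:
            raise ValueError("left/right must be 1-D arrays of equal length")
        filled = left != SENTINEL
        if not filled.any():
            raise NoNucleusError("contour has no nucleus row")
        if (left[filled] > right[filled]).any():
            raise ValueError("left extreme exceeds right extreme in some row")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    @property
    def height(self) -> int:
        return len(self.left)

    def rows(self) -> np.ndarray:
        """Indices of rows that contain nucleus pixels."""
        return np.flatnonzero(self.left != SENTINEL)

    def points(self) -> np.ndarray:
        """All contour points as an (M, 2) array of (x, y), duplicates removed."""
        ys = self.rows()
        pts = np.concatenate(
            [
                np.column_stack([self.left[ys], ys]),
                np.column_stack([self.right[ys], ys]),
            ]
        )
        return np.unique(pts, axis=0)

    def contains(self, x: float, y: float) -> bool:
        """Whether a sub-pixel point lies inside the row-span region.

        The span edges are treated as pixel footprints (half a pixel beyond
        the extreme pixel centers) and are linearly interpolated between
        adjacent rows, which keeps the boundary well-conditioned where it
        runs nearly parallel to the scan rows.
        """
        y0 = math.floor(y)
        t = y - y0
        ok0 = 0 <= y0 < self.height and self.left[y0] != SENTINEL
        ok1 = 0 <= y0 + 1 < self.height and self.left[y0 + 1] != SENTINEL
        if ok0 and ok1:
            l = (1.0 - t) * self.left[y0] + t * self.left[y0 + 1]
            r = (1.0 - t) * self.right[y0] + t * self.right[y0 + 1]
            return l - 0.5 <= x <= r + 0.5
        if ok0 and t <= 0.5:
            return self.left[y0] - 0.5 <= x <= self.right[y0] + 0.5
        if ok1 and t >= 0.5:
            return self.left[y0 + 1] - 0.5 <= x <= self.right[y0 + 1] + 0.5
        return False

    def region_mask(self) -> np.ndarray:
        """Boolean (H, W) mask of the enclosed nucleus region."""
        mask = np.zeros((self.height, self.width), dtype=bool)
        for y in self.rows():
            mask[y, self.left[y] : self.right[y] + 1] = True
        return mask


@dataclass(frozen=True)
class BoundingBox:
    """Contour extreme points: the outermost nucleus pixels in each direction."""

    top: Point
    bottom: Point
    left: Point
    right: Point

    def __post_init__(self) -> None:
        if self.left[0] > self.right[0] or self.top[1] > self.bottom[1]:
            raise ValueError("inconsistent bounding box extremes")


@dataclass(frozen=True)
class AxesGeometry:
    """Estimated nucleus midpoint, axis endpoints, semi-axes, orientation.

    ``a`` and ``b`` are the semi-major and semi-minor lengths in pixels
    (a >= b); ``theta`` is the major-axis angle to the x axis in radians,
    normalized to [0, pi).
    """

    mpt: Point
    majpt1: Point
    majpt2: Point
    minpt1: Point
    minpt2: Point
    a: float
    b: float
    theta: float

    def __post_init__(self) -> None:
        if not self.a >= self.b > 0:
            raise GeometryError(f"invalid semi-axes a={self.a}, b={self.b}")


def find_contour(cls: ClassGrid) -> Contour:
    """Row-scan the class grid for the per-row nucleus extremes.

    Both nucleus-counterstain and probe pixels count as nucleus boundary
    (the probe may touch the nuclear rim).  Raises NoNucleusError when no
    such pixel exists anywhere.
    """
    mask = (cls.labels == NUCLEUS) | (cls.labels == PROBE)
    any_row = mask.any(axis=1)
    if not any_row.any():
        raise NoNucleusError("no nucleus or probe pixel found in image")
    left = np.where(any_row, mask.argmax(axis=1), SENTINEL)
    right = np.where(any_row, cls.width - 1 - mask[:, ::-1].argmax(axis=1), SENTINEL)
    return Contour(left, right, cls.width)


def bounding_box(contour: Contour) -> BoundingBox:
    """Extreme contour points: topmost/bottommost rows, leftmost/rightmost columns.

    Top and bottom carry the midpoint of their row's span as x; left and
    right carry the y of the first row attaining the extreme x.
    """
    ys = contour.rows()
    top_y, bot_y = int(ys[0]), int(ys[-1])
    top = ((contour.left[top_y] + contour.right[top_y]) / 2.0, float(top_y))
    bottom = ((contour.left[bot_y] + contour.right[bot_y]) / 2.0, float(bot_y))
    lx = contour.left[ys]
    rx = contour.right[ys]
    left_row = int(ys[np.argmin(lx)])
    right_row = int(ys[np.argmax(rx)])
    left = (float(lx.min()), float(left_row))
    right = (float(rx.max()), float(right_row))
    return BoundingBox(top=top, bottom=bottom, left=left, right=right)


def initial_midpoint(box: BoundingBox) -> Point:
    """Provisional nucleus midpoint from the bounding-box extremes."""
    return ((box.right[0] + box.left[0]) / 2.0, (box.top[1] + box.bottom[1]) / 2.0)


def _march_to_perimeter(contour: Contour, start: Point, direction: Point) -> Point:
    """March from an interior start along a direction in sub-pixel steps.

    The crossing is reported as the midpoint between the last interior and
    first exterior probe, which removes the half-step systematic
    underestimate a last-interior-point rule would carry.  The start must
    be interior.
    """
    if not contour.contains(*start):
        raise GeometryError(f"march start {start} lies outside the contour")
    norm = math.hypot(*direction)
    ux, uy = direction[0] / norm, direction[1] / norm
    limit = contour.width + contour.height  # no chord can be longer
    last = start
    t = MARCH_STEP
    while t <= limit:
        p = (start[0] + t * ux, start[1] + t * uy)
        if not contour.contains(*p):
            return (last[0] + 0.5 * MARCH_STEP * ux, last[1] + 0.5 * MARCH_STEP * uy)
        last = p
        t += MARCH_STEP
    return last


def major_axis(contour: Contour, mpt: Point) -> tuple[Point, Point]:
    """Locate the major-axis endpoints on the perimeter.

    The first endpoint is the contour point with maximum Euclidean distance
    from the midpoint (ties broken by smallest y, then smallest x); the
    second is where the ray from that point through the midpoint exits the
    far side of the contour.
    """
    pts = contour.points()
    if len(pts) < 2:
        raise DegenerateNucleusError("contour has fewer than 2 distinct points")
    d2 = (pts[:, 0] - mpt[0]) ** 2 + (pts[:, 1] - mpt[1]) ** 2
    best = d2.max()
    cand = pts[d2 == best]
    order = np.lexsort((cand[:, 0], cand[:, 1]))  # smallest y, then smallest x
    majpt1: Point = (float(cand[order[0], 0]), float(cand[order[0], 1]))
    direction = (mpt[0] - majpt1[0], mpt[1] - majpt1[1])
    if math.hypot(*direction) == 0.0:
        # Midpoint coincides with the farthest point: pick any contour direction.
        raise DegenerateNucleusError("midpoint coincides with farthest contour point")
    majpt2 = _march_to_perimeter(contour, mpt, direction)
    return majpt1, majpt2


def refine_midpoint(majpt1: Point, majpt2: Point) -> Point:
    """Recompute the midpoint as the center of the major chord.

    Nuclei are rarely perfect ellipses, so the bounding-box midpoint is
    replaced by the arithmetic midpoint of the two major-axis endpoints.
    """
    if majpt1 == majpt2:
        raise DegenerateNucleusError("coincident major-axis endpoints")
    return ((majpt1[0] + majpt2[0]) / 2.0, (majpt1[1] + majpt2[1]) / 2.0)


def minor_axis(contour: Contour, mpt: Point, theta: float) -> tuple[Point, Point]:
    """March perpendicular to the major axis from the refined midpoint.

    Returns the two perimeter intersections; the semi-minor length is half
    the distance between them, centered at the midpoint even when the chord
    is asymmetric about it.
    """
    if not contour.contains(*mpt):
        raise GeometryError(f"midpoint {mpt} lies outside the contour")
    perp = (-math.sin(theta), math.cos(theta))
    minpt1 = _march_to_perimeter(contour, mpt, perp)
    minpt2 = _march_to_perimeter(contour, mpt, (-perp[0], -perp[1]))
    return minpt1, minpt2


def _angle(p1: Point, p2: Point) -> float:
    """Angle of the p1->p2 direction to the x axis, normalized to [0, pi)."""
    return math.atan2(p2[1] - p1[1], p2[0] - p1[0]) % math.pi


def estimate_geometry(cls: ClassGrid) -> AxesGeometry:
    """Full geometry pipeline: contour -> bounding box -> midpoint -> axes.

    When the perpendicular chord measures marginally longer than the
    farthest-point chord (possible for near-circular nuclei, where the
    orientation is not identifiable anyway), the two chords swap roles so
    that a >= b always holds.
    """
    contour = find_contour(cls)
    box = bounding_box(contour)
    mpt0 = initial_midpoint(box)
    majpt1, majpt2 = major_axis(contour, mpt0)
    mpt = refine_midpoint(majpt1, majpt2)
    theta = _angle(majpt1, majpt2)
    minpt1, minpt2 = minor_axis(contour, mpt, theta)
    a = math.dist(majpt1, majpt2) / 2.0
    b = math.dist(minpt1, minpt2) / 2.0
    if b > a:
        majpt1, majpt2, minpt1, minpt2 = minpt1, minpt2, majpt1, majpt2
        a, b = b, a
        theta = _angle(majpt1, majpt2)
    if b <= 0.0:
        raise DegenerateNucleusError("minor chord has zero length")
    return AxesGeometry(
        mpt=mpt,
        majpt1=majpt1,
        majpt2=majpt2,
        minpt1=minpt1,
        minpt2=minpt2,
        a=a,
        b=b,
        theta=theta,
    )
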