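"""Equal-area concentric elliptical shell partitioning of the nucleus.

With the nucleus modelled as an ellipse of semi-axes A, B (area pi*A*B),
the k-th concentric ellipse of the family has semi-axes
(A*sqrt(k/N), B*sqrt(k/N)), so that its area is k/N of the total and every
ring between consecutive ellipses has equal area.  The aspect ratio A/B is
the same for every member of the family.  The outermost shell is irregular:
it is bounded on the outside by the true row-scan contour, not by an
ellipse, which makes peripheral erosion/smoothing unnecessary.

Shells are numbered 1 = periphery ... N = center.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from nucshell.contour_axes import AxesGeometry, Contour, Point
from nucshell.errors import GeometryError, ParameterError
from nucshell.pixel_model import BACKGROUND, NUCLEUS, OTHER, PROBE, ClassGrid


def shell_radii(a: float, b: float, n: int) -> list[tuple[float, float]]:
    """Semi-axes of the N-1 interior ellipses of the equal-area family.

    Returns [(a_1, b_1), ..., (a_{N-1}, b_{N-1})] with
    a_k = a*sqrt(k/N), b_k = b*sqrt(k/N); empty for N=1 (the whole nucleus
    is then a single irregular shell).
    """
    if n < 1:
        raise ParameterError(f"shell count must be >= 1, got {n}")
    if not a >= b > 0:
        raise ParameterError(f"semi-axes must satisfy a >= b > 0, got a={a}, b={b}")
    return [(a * math.sqrt(k / n), b * math.sqrt(k / n)) for k in range(1, n)]


def normalized_coord(p: Point, geom: AxesGeometry) -> float:
    """Normalized elliptical coordinate e = (x'/A)^2 + (y'/B)^2.

    The point is rotated into the axis-aligned frame about the midpoint;
    e <= k/N iff the point lies in or on the k-th concentric ellipse.
    """
    dx = p[0] - geom.mpt[0]
    dy = p[1] - geom.mpt[1]
    c, s = math.cos(geom.theta), math.sin(geom.theta)
    xp = dx * c + dy * s
    yp = -dx * s + dy * c
    return (xp / geom.a) ** 2 + (yp / geom.b) ** 2


def assign_shell(e: float, inside_contour: bool, n: int) -> int | None:
    """Map a normalized coordinate to its shell number (1=periphery, N=center).

    Points outside the contour get None.  Inside, ring-from-center
    m = ceil(e*N) clipped to [1, N]; points with e > 1 (inside the contour
    but outside the largest full ellipse) belong to the irregular outermost
    shell.  Boundary values e = k/N belong to the inner ring.
    """
    if not inside_contour:
        return None
    if e > 1.0:
        return 1
    m = min(max(math.ceil(e * n), 1), n)
    return n - m + 1


@dataclass(frozen=True)
class ShellCounts:
    """Per-shell pixel tallies by class; index 0 is shell 1 (periphery)."""

    nucleus: np.ndarray
    probe: np.ndarray
    other: np.ndarray

    def __post_init__(self) -> None:
        for name in ("nucleus", "probe", "other"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.ndim != 1 or len(arr) != len(np.asarray(self.nucleus)):
                raise ValueError("shell count arrays must be 1-D and equal length")
            object.__setattr__(self, name, arr)

    @property
    def n_shells(self) -> int:
        return len(self.nucleus)

    @property
    def all(self) -> np.ndarray:
        return self.nucleus + self.probe + self.other


@dataclass(frozen=True)
class ShellProfile:
    """Two percentage normalizations of the shell counts.

    ``pct_*_within`` is the class share of each shell's own pixel total
    (the within-shell percentage); ``pct_*_share`` is each shell's share of
    the class total over the whole nucleus (sums to 100 over shells when the
    class is present).  With equal-area shells both rank shells identically.
    """

    pct_nucleus_within: np.ndarray
    pct_probe_within: np.ndarray
    pct_other_within: np.ndarray
    pct_nucleus_share: np.ndarray
    pct_probe_share: np.ndarray
    pct_other_share: np.ndarray

    @property
    def n_shells(self) -> int:
        return len(self.pct_probe_share)


def _shell_map(cls: ClassGrid, contour: Contour, geom: AxesGeometry, n: int) -> np.ndarray:
    """Per-pixel shell assignment map: 0 outside the region, 1..N inside."""
    if n < 1:
        raise ParameterError(f"shell count must be >= 1, got {n}")
    if not contour.contains(*geom.mpt):
        raise GeometryError(f"midpoint {geom.mpt} lies outside the contour")
    mask = contour.region_mask()
    ys, xs = np.nonzero(mask)
    dx = xs - geom.mpt[0]
    dy = ys - geom.mpt[1]
    c, s = math.cos(geom.theta), math.sin(geom.theta)
    xp = dx * c + dy * s
    yp = -dx * s + dy * c
    e = (xp / geom.a) ** 2 + (yp / geom.b) ** 2
    m = np.clip(np.ceil(e * n).astype(int), 1, n)  # ring from center
    shells = n - m + 1
    shells[e > 1.0] = 1
    out = np.zeros(mask.shape, dtype=int)
    out[ys, xs] = shells
    return out


def count_shells(cls: ClassGrid, contour: Contour, geom: AxesGeometry, n: int) -> ShellCounts:
    """Tally nucleus / probe / other pixels per shell over the contour region.

    Every pixel between the row-scan extremes is assigned exactly one
    shell; background-colored pixels trapped inside the contour are counted
    as OTHER (the only bucket for unrecognized content).
    """
    shell_map = _shell_map(cls, contour, geom, n)
    inside = shell_map > 0
    labels = cls.labels.copy()
    labels[inside & (labels == BACKGROUND)] = OTHER
    counts = {}
    for name, code in (("nucleus", NUCLEUS), ("probe", PROBE), ("other", OTHER)):
        counts[name] = np.bincount(
            shell_map[inside & (labels == code)], minlength=n + 1
        )[1 : n + 1]
    return ShellCounts(**counts)


def shell_profile(counts: ShellCounts) -> ShellProfile:
    """Derive both percentage normalizations from the raw shell counts.

    Share-of-total percentages are defined as 0 in every shell when the
    class has no pixels at all (with a warning for the probe, since an
    image without probe signal usually indicates a palette mismatch).
    """
    all_ = counts.all
    if all_.sum() == 0:
        raise GeometryError("empty shell counts: no pixels in the nucleus region")
    pct = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in ("nucleus", "probe", "other"):
            arr = getattr(counts, name).astype(float)
            within = np.where(all_ > 0, 100.0 * arr / np.maximum(all_, 1), 0.0)
            total = arr.sum()
            if total > 0:
                share = 100.0 * arr / total
            else:
                share = np.zeros_like(arr)
                if name == "probe":
                    warnings.warn(
                        "no probe pixels found: probe share set to 0 in every shell",
                        stacklevel=2,
                    )
            pct[f"pct_{name}_within"] = within
            pct[f"pct_{name}_share"] = share
    return ShellProfile(**pct)
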