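"""Synthetic 2D-FISH-like images with known geometry and probe distribution.

Generates elliptical "nuclei" at arbitrary orientation with probe signal
placed at controlled normalized radial positions (discrete blobs or a
density wash), plus optional off-nucleus smudges.  Each image comes with a
GroundTruth computed by brute-force evaluation of every drawn pixel
against the TRUE generator geometry, so that geometry-recovery error and
pixel-counting error can be measured separately.

Rasterization convention: a pixel belongs to the ellipse iff its center
satisfies e <= 1 under the true geometry (centers-in), matching the
pixel-center convention used on the analysis side.  These images emulate
the color structure of flattened-nucleus FISH photographs, not their
optics: there is no point-spread blur, chromatic noise, or uneven
illumination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from nucshell.errors import ParameterError
from nucshell.pixel_model import Palette, PixelGrid

Point = tuple[float, float]


@dataclass(frozen=True)
class ProbeBlob:
    """A circular probe patch inside the nucleus.

    ``u`` is the normalized radial position of the blob center: the center
    sits at elliptical coordinate e = u**2, so u=0 is the nucleus midpoint
    and u -> 1 the perimeter.  ``phi`` is the angular position in the axis
    frame (radians) and ``radius`` the blob radius in pixels.
    """

    u: float
    phi: float
    radius: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.u < 1.0:
            raise ParameterError(f"blob radial position must be in [0, 1), got {self.u}")
        if self.radius <= 0:
            raise ParameterError(f"blob radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class Smudge:
    """A probe-colored disk outside the nucleus (stained debris)."""

    center: Point
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError(f"smudge radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class NucleusSpec:
    """Full description of one synthetic nucleus image.

    ``wash`` paints individual nucleus pixels with the probe color at a
    radially modulated Bernoulli density: mode "uniform" uses probability
    ``density`` everywhere, "interior" uses density*(1-e) (probe
    concentrated at the center), "peripheral" uses density*e.  Blobs and a
    wash may be combined.  Everything random is driven by ``seed``.
    """

    width: int = 320
    height: int = 320
    center: Point = (160.0, 160.0)
    a: float = 100.0
    b: float = 60.0
    theta: float = 0.0
    palette: Palette = field(default_factory=Palette)
    blobs: tuple[ProbeBlob, ...] = ()
    wash: tuple[str, float] | None = None
    smudges: tuple[Smudge, ...] = ()
    margin: int = 7
    n_shells: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.a >= self.b > 0:
            raise ParameterError(f"semi-axes must satisfy a >= b > 0, got {self.a}, {self.b}")
        if self.n_shells < 1:
            raise ParameterError(f"shell count must be >= 1, got {self.n_shells}")
        # The nucleus (any orientation) must keep a background margin so
        # that the image frame is background, as the smudge filter assumes.
        ext_x = math.hypot(self.a * math.cos(self.theta), self.b * math.sin(self.theta))
        ext_y = math.hypot(self.a * math.sin(self.theta), self.b * math.cos(self.theta))
        if (
            self.center[0] - ext_x < self.margin
            or self.center[0] + ext_x > self.width - 1 - self.margin
            or self.center[1] - ext_y < self.margin
            or self.center[1] + ext_y > self.height - 1 - self.margin
        ):
            raise ParameterError("nucleus does not fit in the image with the required margin")
        if self.wash is not None:
            mode, d = self.wash
            if mode not in ("uniform", "interior", "peripheral"):
                raise ParameterError(f"unknown wash mode: {mode!r}")
            if not 0.0 < d <= 1.0:
                raise ParameterError(f"wash density must be in (0, 1], got {d}")


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-shell pixel counts under the TRUE generator geometry.

    Shells are numbered 1 = periphery ... N = center, index 0 of each
    array being shell 1.  ``other`` is always zero for generated images.
    """

    n_shells: int
    nucleus: np.ndarray
    probe: np.ndarray
    center: Point
    a: float
    b: float
    theta: float

    @property
    def all(self) -> np.ndarray:
        return self.nucleus + self.probe

    @property
    def total(self) -> int:
        return int(self.all.sum())

    @property
    def probe_share(self) -> np.ndarray:
        """Per-shell probe share in percent (zeros when no probe drawn)."""
        tot = self.probe.sum()
        if tot == 0:
            return np.zeros(self.n_shells)
        return 100.0 * self.probe / tot


def _true_e(xs: np.ndarray, ys: np.ndarray, spec: NucleusSpec) -> np.ndarray:
    dx = xs - spec.center[0]
    dy = ys - spec.center[1]
    c, s = math.cos(spec.theta), math.sin(spec.theta)
    xp = dx * c + dy * s
    yp = -dx * s + dy * c
    return (xp / spec.a) ** 2 + (yp / spec.b) ** 2


def _true_shell(e: float, n: int) -> int:
    """Independent shell assignment from the true e (1 = periphery)."""
    if e > 1.0:
        return 1
    # Scan the rings outward; boundary e = k/n belongs to the inner ring.
    ring = n
    for k in range(1, n + 1):
        if e <= k / n:
            ring = k
            break
    return n - ring + 1


def make_nucleus_image(spec: NucleusSpec) -> tuple[PixelGrid, GroundTruth]:
    """Rasterize the spec and compute its brute-force ground truth.

    Deterministic given the spec (including its seed).  Raises when a blob
    leaves the nucleus or a smudge overlaps it.
    """
    ys, xs = np.mgrid[0 : spec.height, 0 : spec.width]
    e = _true_e(xs.astype(float), ys.astype(float), spec)
    nucleus_mask = e <= 1.0

    probe_mask = np.zeros_like(nucleus_mask)
    c, s = math.cos(spec.theta), math.sin(spec.theta)
    for blob in spec.blobs:
        bx = spec.a * blob.u * math.cos(blob.phi)
        by = spec.b * blob.u * math.sin(blob.phi)
        cx = spec.center[0] + bx * c - by * s
        cy = spec.center[1] + bx * s + by * c
        disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= blob.radius**2
        if (disk & ~nucleus_mask).any():
            raise ParameterError(
                f"probe blob at u={blob.u}, phi={blob.phi} extends outside the nucleus"
            )
        probe_mask |= disk

    if spec.wash is not None:
        mode, d = spec.wash
        if mode == "uniform":
            p = np.full(e.shape, d)
        elif mode == "interior":
            p = d * (1.0 - np.clip(e, 0.0, 1.0))
        else:  # peripheral
            p = d * np.clip(e, 0.0, 1.0)
        rng = np.random.default_rng(spec.seed)
        probe_mask |= nucleus_mask & (rng.random(e.shape) < p)

    img = np.empty((spec.height, spec.width, 3), dtype=float)
    img[:] = spec.palette.background
    img[nucleus_mask] = spec.palette.nucleus
    img[probe_mask & nucleus_mask] = spec.palette.probe

    for sm in spec.smudges:
        disk = (xs - sm.center[0]) ** 2 + (ys - sm.center[1]) ** 2 <= sm.radius**2
        if (disk & nucleus_mask).any():
            raise ParameterError(f"smudge at {sm.center} overlaps the nucleus")
        img[disk] = spec.palette.probe

    n = spec.n_shells
    nuc_counts = np.zeros(n, dtype=int)
    probe_counts = np.zeros(n, dtype=int)
    inner = probe_mask & nucleus_mask
    for y, x in zip(*np.nonzero(nucleus_mask)):
        shell = _true_shell(float(e[y, x]), n)
        if inner[y, x]:
            probe_counts[shell - 1] += 1
        else:
            nuc_counts[shell - 1] += 1

    truth = GroundTruth(
        n_shells=n,
        nucleus=nuc_counts,
        probe=probe_counts,
        center=spec.center,
        a=spec.a,
        b=spec.b,
        theta=spec.theta % math.pi,
    )
    return PixelGrid(img), truth


@dataclass(frozen=True)
class FixtureCase:
    """One named fixture: the generating spec (if any), image, and truth."""

    name: str
    grid: PixelGrid
    spec: NucleusSpec | None = None
    truth: GroundTruth | None = None


def _degenerate_cases() -> list[FixtureCase]:
    palette = Palette()
    white = np.ones((40, 40, 3))
    all_bg = FixtureCase("all_background", PixelGrid(white.copy()))
    one = white.copy()
    one[4, 7] = palette.nucleus
    single = FixtureCase("single_pixel", PixelGrid(one))
    return [all_bg, single]


def fixture_suite(seed: int = 0) -> dict[str, FixtureCase]:
    """The canonical named cases used across the test suite.

    Includes clean ellipses at several orientations, controlled probe
    placements, a smudged image with its clean twin, the large-smudge
    escape case, and degenerate inputs.
    """
    cases: list[FixtureCase] = []

    def add(name: str, spec: NucleusSpec) -> None:
        grid, truth = make_nucleus_image(spec)
        cases.append(FixtureCase(name, grid, spec, truth))

    add("axis_aligned_ellipse", NucleusSpec(a=100, b=50, seed=seed))
    add("rotated_ellipse_30deg", NucleusSpec(a=100, b=50, theta=math.radians(30), seed=seed))
    add("circle", NucleusSpec(a=70, b=70, seed=seed))
    add(
        "interior_blob",
        NucleusSpec(a=100, b=60, blobs=(ProbeBlob(u=0.1, phi=0.3, radius=8),), seed=seed),
    )
    add(
        "peripheral_ring",
        NucleusSpec(
            a=100,
            b=60,
            blobs=tuple(
                # e = 0.95^2 ~ 0.90: well inside the outermost ring (e > 0.8)
                ProbeBlob(u=0.95, phi=2 * math.pi * i / 8, radius=2.5)
                for i in range(8)
            ),
            seed=seed,
        ),
    )
    add("uniform_wash", NucleusSpec(a=100, b=60, wash=("uniform", 0.3), seed=seed))
    clean = NucleusSpec(a=90, b=55, theta=math.radians(20), seed=seed)
    add("smudge_clean_twin", clean)
    add(
        "smudged",
        NucleusSpec(
            a=90,
            b=55,
            theta=math.radians(20),
            smudges=(Smudge(center=(20.0, 30.0), radius=1.2), Smudge(center=(300.0, 290.0), radius=1.2)),
            seed=seed,
        ),
    )
    add(
        "large_smudge",
        NucleusSpec(
            a=90,
            b=55,
            theta=math.radians(20),
            smudges=(Smudge(center=(30.0, 280.0), radius=8.0),),
            seed=seed,
        ),
    )
    cases.extend(_degenerate_cases())
    return {case.name: case for case in cases}
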