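"""Raster loading, color classification, and annotated diagnostic output.

An input image shows a single flattened nucleus in three distinguishable
colors: background (default white), nucleus counterstain (default blue) and
chromosome paint probe (default red).  Pixels are classified into those
semantic classes by a per-channel tolerance band around each reference
color; anything unmatched is OTHER.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from nucshell.errors import InputError, ParameterError

# Semantic pixel classes.  Stored as uint8 codes in ClassGrid.labels.
BACKGROUND: int = 0
NUCLEUS: int = 1
PROBE: int = 2
OTHER: int = 3

CLASS_NAMES = {BACKGROUND: "background", NUCLEUS: "nucleus", PROBE: "probe", OTHER: "other"}

RGB = tuple[float, float, float]


@dataclass(frozen=True)
class PixelGrid:
    """A W x H raster of RGB triplets with channels normalized to [0, 1].

    ``pixels`` is indexed ``[y, x, channel]`` (row-major, y downward,
    x rightward, 0-based, pixel centers at integer coordinates).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"pixel array must be (H, W, 3), got {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise InputError(
                f"image too small ({px.shape[1]}x{px.shape[0]}); "
                "a nucleus plus background margin needs at least 3x3"
            )
        if px.min() < 0.0 or px.max() > 1.0:
            raise InputError("channel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class Palette:
    """Reference colors for the three semantic classes plus a tolerance.

    A pixel matches a class when every channel deviates from the reference
    color by at most ``tolerance``.  The three reference colors must remain
    mutually exclusive under the tolerance: for each pair of classes at
    least one channel must differ by more than ``2 * tolerance`` so that no
    pixel can match two classes at once.
    """

    background: RGB = (1.0, 1.0, 1.0)
    nucleus: RGB = (0.0, 0.0, 1.0)
    probe: RGB = (1.0, 0.0, 0.0)
    tolerance: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.tolerance < 0.5:
            raise ParameterError(f"tolerance must be in (0, 0.5), got {self.tolerance}")
        refs = {"background": self.background, "nucleus": self.nucleus, "probe": self.probe}
        for name, c in refs.items():
            if len(c) != 3 or any(not 0.0 <= v <= 1.0 for v in c):
                raise ParameterError(f"{name} color must be an RGB triplet in [0, 1], got {c}")
        for (n1, c1), (n2, c2) in itertools.combinations(refs.items(), 2):
            if all(abs(a - b) <= 2.0 * self.tolerance for a, b in zip(c1, c2)):
                raise ParameterError(
                    f"palette colors {n1}={c1} and {n2}={c2} overlap at tolerance "
                    f"{self.tolerance}: some pixel would match both classes"
                )

    def references(self) -> dict[int, RGB]:
        return {BACKGROUND: self.background, NUCLEUS: self.nucleus, PROBE: self.probe}


@dataclass(frozen=True)
class ClassGrid:
    """Per-pixel semantic labels over {BACKGROUND, NUCLEUS, PROBE, OTHER}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.uint8)
        if lab.ndim != 2:
            raise InputError(f"label array must be 2-D, got shape {lab.shape}")
        if lab.max(initial=0) > OTHER:
            raise InputError("labels must be in {BACKGROUND, NUCLEUS, PROBE, OTHER}")
        object.__setattr__(self, "labels", lab)

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def height(self) -> int:
        return self.labels.shape[0]


def load_image(path: str | Path, *, background: RGB = (1.0, 1.0, 1.0)) -> PixelGrid:
    """Load a PNG/TIFF/GIF/JPEG raster into a normalized pixel grid.

    Palettized images are expanded to RGB; an alpha channel is composited
    over ``background``; 8-bit channels are scaled by 1/255 and 16-bit by
    1/65535.  Grayscale images are rejected: the method needs three
    distinguishable color classes.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("1", "L", "LA", "I", "I;16", "F"):
                raise InputError(
                    f"{path}: grayscale image (mode {mode}); three distinguishable "
                    "colors (background / nucleus / probe) are required"
                )
            if mode == "P":
                im = im.convert("RGBA" if "transparency" in im.info else "RGB")
            arr = np.asarray(im)
    except FileNotFoundError as exc:
        raise InputError(f"cannot read image file: {path}") from exc
    except UnidentifiedImageError as exc:
        raise InputError(f"not a decodable raster image: {path}") from exc

    if arr.size == 0:
        raise InputError(f"zero-area image: {path}")
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    arr = arr.astype(float) / scale
    if arr.ndim == 3 and arr.shape[2] == 4:
        alpha = arr[:, :, 3:4]
        arr = arr[:, :, :3] * alpha + np.asarray(background, dtype=float) * (1.0 - alpha)
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"{path}: unsupported channel layout {arr.shape}")
    return PixelGrid(np.clip(arr, 0.0, 1.0))


def save_image(grid: PixelGrid, path: str | Path) -> None:
    """Write a pixel grid as an 8-bit raster; format chosen by extension."""
    arr = np.rint(grid.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path))


def classify_pixel(rgb: Sequence[float], palette: Palette) -> int:
    """Classify one RGB triplet against the palette.

    Returns PROBE / NUCLEUS / BACKGROUND when every channel is within the
    palette tolerance of the reference color, OTHER when no class matches.
    Palette construction guarantees at most one class can match.
    """
    for label, ref in palette.references().items():
        if all(abs(v - c) <= palette.tolerance for v, c in zip(rgb, ref)):
            return label
    return OTHER


def classify_grid(grid: PixelGrid, palette: Palette) -> ClassGrid:
    """Vectorized per-pixel classification of a whole image."""
    labels = np.full((grid.height, grid.width), OTHER, dtype=np.uint8)
    for label, ref in palette.references().items():
        dev = np.abs(grid.pixels - np.asarray(ref, dtype=float))
        match = (dev <= palette.tolerance).all(axis=2)
        labels[match] = label
    return ClassGrid(labels)


# Shell fill colors, listed from the nucleus center outward; cycled when
# there are more than five shells.
DEFAULT_SHELL_COLORS: tuple[RGB, ...] = (
    (1.0, 1.0, 0.0),  # yellow (innermost)
    (0.0, 1.0, 0.0),  # green
    (1.0, 0.0, 1.0),  # magenta
    (0.0, 0.0, 1.0),  # blue
    (0.0, 1.0, 1.0),  # aqua (outermost)
)


@dataclass(frozen=True)
class Overlay:
    """Diagnostic annotations drawn over a nucleus image.

    Any subset may be present: ``contour`` (per-row left/right extremes),
    ``geometry`` (axis endpoints), and ``shell_map`` (an (H, W) integer map,
    0 outside the nucleus region, shell number 1..N inside, where shell 1 is
    the periphery and shell N the center).
    """

    contour: Any = None
    geometry: Any = None
    shell_map: np.ndarray | None = None
    contour_color: RGB = (1.0, 1.0, 0.0)
    major_color: RGB = (0.0, 1.0, 0.0)
    minor_color: RGB = (0.0, 0.0, 1.0)
    shell_colors: tuple[RGB, ...] = field(default=DEFAULT_SHELL_COLORS)


def _draw_line(img: np.ndarray, p1: tuple[float, float], p2: tuple[float, float], color: RGB) -> None:
    from skimage.draw import line

    h, w = img.shape[:2]
    rr, cc = line(int(round(p1[1])), int(round(p1[0])), int(round(p2[1])), int(round(p2[0])))
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    img[rr[keep], cc[keep]] = color


def write_annotated(grid: PixelGrid, overlay: Overlay, path: str | Path) -> None:
    """Render the image with shell fills, contour, and axes, and save it.

    Shells are filled with distinct colors (innermost shell first in
    ``overlay.shell_colors``, matching the diagnostic convention of yellow
    center / aqua periphery for N=5); the contour is drawn in yellow and
    the major/minor axes in green/blue by default.  The input grid is never
    modified.
    """
    img = grid.pixels.copy()
    if overlay.shell_map is not None:
        shell_map = np.asarray(overlay.shell_map)
        if shell_map.shape != img.shape[:2]:
            raise InputError(
                f"shell map shape {shell_map.shape} does not match image {img.shape[:2]}"
            )
        n_shells = int(shell_map.max(initial=0))
        ncolors = len(overlay.shell_colors)
        for s in range(1, n_shells + 1):
            ring_from_center = n_shells - s  # 0 = innermost
            img[shell_map == s] = overlay.shell_colors[ring_from_center % ncolors]
    if overlay.contour is not None:
        cont = overlay.contour
        for y in range(len(cont.left)):
            if cont.left[y] >= 0:
                img[y, cont.left[y]] = overlay.contour_color
                img[y, cont.right[y]] = overlay.contour_color
    if overlay.geometry is not None:
        geom = overlay.geometry
        _draw_line(img, geom.majpt1, geom.majpt2, overlay.major_color)
        _draw_line(img, geom.minpt1, geom.minpt2, overlay.minor_color)
    try:
        save_image(PixelGrid(img), path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot write annotated image to {path}: {exc}") from exc
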