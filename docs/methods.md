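# Methods

## Model and assumptions

`nucshell` treats a 2D-FISH photograph of a single flattened nucleus as a
three-class color image: background, nucleus counterstain, and
chromosome-paint probe, each close to a known reference color. The
nucleus is modelled as approximately elliptical but is never forced to be
one: the analysis region is whatever lies between the per-row contour
extremes, and only the *shell boundaries* are ellipses. Radial position is
measured by the normalized elliptical coordinate

e(p) = (x′/A)² + (y′/B)²,

where (x′, y′) are the pixel's coordinates in the frame of the estimated
axes about the midpoint. The equal-area shell family uses semi-axes
(A·√(k/N), B·√(k/N)); every ring between consecutive members covers
π·A·B/N. The outermost shell is irregular — bounded outside by the true
contour — which deliberately avoids erosion/smoothing of the nuclear
periphery: depressions and protrusions are kept as imaged.

Assumptions inherited from the imaging protocol:

- one nucleus per image, framed by a background margin;
- probe signal lies within (or on the rim of) the nucleus;
- the three classes are separable by per-channel color distance.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `shells` (N) | 5 | number of equal-area shells; 1 = periphery, N = center |
| `tolerance` (τ) | 0.15 | per-channel absolute deviation allowed when matching a reference color; covers off-pure values such as probe (0.9, 0.1, 0.1) with margin while keeping white/blue/red mutually exclusive (the palette validator enforces pairwise separation > 2τ) |
| `smudge_radius` (r) | 5 px | radius of the background-circle test for debris outside the nucleus |
| `smudge_mode` | `pixel` | `pixel`: single-pass per-pixel circle test on the original labels; `component`: remove whole 8-connected off-nucleus components whose r-dilation touches only background (also removes blobs larger than r); `off` |
| march step | 0.25 px | step size when intersecting a ray with the contour region |

Shell numbering follows the biological reading (shell 1 at the periphery,
shell N at the center), and every output table labels the positions
explicitly.

## Numerical choices

- **Coordinates.** 0-based, x rightward, y downward, pixel centers at
  integer positions. All reported geometry uses this convention.
- **Contour region for ray marching.** The per-row spans are treated as
  pixel footprints (half a pixel beyond the extreme pixel centers) and
  linearly interpolated between adjacent rows. Snapping to the nearest
  row's span instead is ill-conditioned wherever the boundary runs nearly
  parallel to the scan rows (thin, slightly rotated nuclei): there the
  span edge moves several pixels per row, and snapping biased the
  semi-minor axis by up to ~0.6 px. With interpolation the mean semi-axis
  error over random ellipses is ≈ 0.01 px.
- **Ray crossing.** The march reports the midpoint between the last
  interior and first exterior probe, removing the half-step systematic
  underestimate of a last-interior-point rule.
- **Farthest-point tie-break.** Exact distance ties (e.g. circles) are
  broken by smallest y, then smallest x — deterministic and
  order-independent.
- **Near-circular nuclei.** If the perpendicular chord measures
  marginally longer than the farthest-point chord, the two swap roles so
  A ≥ B always holds; this can only trigger when the nucleus is nearly
  circular and the orientation is not meaningful anyway.
- **Boundary pixels.** e exactly equal to k/N belongs to the inner ring
  (assignment via ceil). Pixels inside the contour with background color
  are tallied as *other* — the only bucket for unrecognized content.
- **Degenerate inputs.** An image with no nucleus/probe pixel raises
  `NoNucleusError`; a contour with fewer than two distinct points (single
  pixel) raises `DegenerateNucleusError`; a midpoint outside the contour
  (e.g. when a large uncleaned smudge distorts the bounding box) raises
  `GeometryError`. In batch mode these become per-image error records and
  never abort the run.
- **SEM.** Sample standard deviation (n−1 denominator) over √n; a
  single-image group reports SEM 0 with a warning.
- **Probe-free images.** Share-of-total percentages are defined as 0 with
  a warning (usually a palette mismatch).

Both probe normalizations are emitted: the within-shell percentage
(probe / shell total) and the share of total probe per shell. With
equal-area shells they rank shells identically; histograms use the share,
which sums to 100 across shells.

## The synthetic generator

`nucshell.synthetic` draws elliptical nuclei at arbitrary orientation
(centers-in rasterization: a pixel belongs to the ellipse iff its center
satisfies e ≤ 1, matching the analysis-side pixel-center convention),
with probe placed either as circular blobs at controlled normalized
radius u (the blob center sits at e = u²) or as a Bernoulli wash whose
density is constant, ∝ (1−e) (interior bias) or ∝ e (peripheral bias).
Off-nucleus smudges are probe-colored disks. Ground truth per shell is
computed by brute force against the *generator* geometry, so
geometry-recovery error and pixel-counting error are measured separately.

The generator emulates the color structure of the real photographs, not
their optics: no point-spread blur, no chromatic noise, no uneven
illumination, hard class boundaries. Passing tests therefore demonstrate
the correctness of the geometry and counting machinery, not robustness to
staining variability; on real data the color tolerance τ and the palette
do the work the generator sidesteps.

Simulation sizes used by the test suite and the acceptance script (chosen
to exercise the stated ranges while keeping a full run in seconds on one
CPU): 50 random ellipses with semi-major axis 40–150 px and aspect ratio
up to 3 for the partition/geometry sweeps; 10 nuclei (semi-major
60–150 px) for the uniform-probe null; 100 nuclei each (semi-major
60–100 px, aspect ≤ 1.6, typical of flattened fibroblast nuclei) for the
interior- and peripheral-bias studies.

## Resolution limits (and two deliberately red checks)

Two validation bounds in the test suite are asserted at levels the
construction cannot meet at the small end of the tested range, and are
expected to fail there; they are kept unweakened because they document
real limits:

- **Equal-area balance at 2%.** The partition identity is exact (every
  nucleus pixel in exactly one shell), but per-shell *balance* is limited
  by raster resolution. The irregular outer shell absorbs the mismatch
  between π·A·B of the measured axes and the true pixel total, which is
  ≈ 4·(δA/A + δB/B) of a shell; a single marched chord carries ~0.3 px of
  irreducible quantization noise, so a nucleus with B ≈ 15–25 px can show
  3–7% imbalance in the outer shell. Even with the generator's exact
  geometry, a shell of a 40×15 px nucleus holds only ~330 pixels and
  lattice noise alone exceeds 2%. At realistic image scale (shells of
  ~12 000 pixels) the balance is comfortably within 1%.
- **Orientation at 2°.** The farthest-contour-point construction loses
  orientation precision as the aspect ratio approaches 1: the distance
  from the midpoint is nearly flat along the contour near the major
  vertex (radial drop ≈ s²·(1−(B/A)²)/2A at arc distance s), so ±0.5 px
  of raster noise can move the selected point several pixels along the
  boundary. Errors of 2–6° occur for weakly eccentric or small nuclei;
  for a circle the angle is undefined. Semi-axis lengths are unaffected
  (recovered to ~0.5 px), and the shell assignment is insensitive to θ
  exactly where θ is poorly determined (A ≈ B).

## Known limitations

- The row-scan contour sees only per-row extremes: concavities and
  interior holes are bridged and counted as nucleus area.
- Pixel counts, not fluorescence intensities, are quantified; images must
  be segmented/recolored into the three-class scheme beforehand.
- Smudges closer than r to the nucleus escape removal (small induced
  error); smudges larger than r are flagged for visual review rather than
  auto-rejected in the default mode.
- No 3D/Z-stack analysis; the method is defined for flattened nuclei.
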