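# nucshell

Quantifying the radial localization of chromosome territories in flattened
(2D-FISH) cell nuclei.

In two-dimensional fluorescence in situ hybridization, a whole-chromosome
paint probe marks one chromosome's territory inside a flattened interphase
nucleus. Whether that territory sits at the nuclear center (typical of
gene-rich chromosomes such as human chromosome 19) or at the periphery
(gene-poor chromosomes such as 18) is read out from many such images:
each nucleus is divided into **N concentric elliptical shells of equal
area** and the fraction of probe signal per shell is averaged over ~100
nuclei per chromosome. `nucshell` implements that pipeline for images in
which background, nucleus counterstain and probe are three distinguishable
colors (white / blue / red by default).

## Method

For each image:

1. **Classification.** Every pixel's RGB triplet (normalized to [0, 1]) is
   matched against a palette with per-channel tolerance τ (default 0.15):
   background, nucleus, probe, or *other*.
2. **Smudge removal.** A non-background pixel is erased if the rasterized
   circle of radius *r* (default 5 px) around it contains only background —
   stained debris outside the nucleus would otherwise corrupt the contour.
   Smudges larger than *r* escape the test and are flagged for visual
   review; an optional connected-component mode removes them too.
3. **Contour.** Each row *y* is scanned from both sides to the first
   nucleus-or-probe pixel, giving per-row extremes
   `LContour[y] <= RContour[y]`.
4. **Axes.** From the contour's bounding box a provisional midpoint
   `MPT = ((right_x+left_x)/2, (top_y+bottom_y)/2)` is computed; the
   contour point farthest from MPT is one end of the major axis, the ray
   through MPT marched to the far side gives the other; the midpoint is
   refined to the chord center, and the perpendicular chord through it is
   the minor axis. This yields semi-axes A ≥ B and orientation θ for a
   nucleus at arbitrary orientation, with no ellipse fitting.
5. **Shells.** The ellipse family with semi-axes `(A√(k/N), B√(k/N))`,
   k = 1..N−1, divides the nucleus area π·A·B into N parts of equal area.
   A pixel's shell follows from its normalized elliptical coordinate
   `e = (x′/A)² + (y′/B)²` in the axis frame about MPT; pixels inside the
   contour but beyond the largest full ellipse form the irregular
   outermost shell, so no peripheral erosion/smoothing is needed. Shells
   are numbered **1 = periphery … N = center** (default N = 5).
6. **Statistics.** Per shell: pixel counts per class, the within-shell
   percentages, and each shell's share of the total probe signal. Across
   nuclei, per-group mean ± SEM (sample SD / √n) of the probe percentages,
   written as CSV, an Excel workbook, and per-group histograms.

A rising share from shell 1 to shell 5 indicates interior localization, a
falling one peripheral localization, and a bell shape an intermediate
position.

## Worked example

Generate the synthetic demonstration suite and analyze one image with a
probe blob placed deep in the nuclear interior:

```bash
nucshell fixtures demo --seed 0
nucshell single demo/interior_blob.png
```

```
image: demo/interior_blob.png
midpoint (160.3, 160.0); semi-axes A=100.3 px, B=60.6 px; orientation 0.0 deg
smudge pixels removed: 0
Shell     Blue      Red   Others      All   %Blue    %Red  %Others  %RedShare
    1     3531        0        0     3531   100.0     0.0      0.0        0.0
    2     3848        0        0     3848   100.0     0.0      0.0        0.0
    3     3805        0        0     3805   100.0     0.0      0.0        0.0
    4     3815        0        0     3815   100.0     0.0      0.0        0.0
    5     3630      200        0     3830    94.8     5.2      0.0      100.0
(shell 1 = periphery ... shell 5 = center)
```

The five shells hold nearly equal pixel totals (`All` ≈ 3500–3850; the
nucleus was generated with A = 100, B = 60 px), and all 200 probe pixels
fall in shell 5 — the interior localization the image was built with. An
annotated PNG with the shell partition is written next to the image.

Batch mode takes a list file (one path per line, optional `,group`
column) and an output directory, mirroring a per-chromosome directory
layout:

```bash
nucshell run images.txt results/ --shells 5 --smudge-radius 5
```

which writes `results.csv` (per image), `summary.csv` (per-shell mean ±
SEM per group), `results.xlsx`, one histogram PNG per group, and a run
log. Failed images (e.g. no nucleus found) are recorded and excluded from
the group means.

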