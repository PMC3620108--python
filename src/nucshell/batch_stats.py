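"""Batch pipeline: per-image analysis and cross-nucleus aggregation.

Runs load -> classify -> smudge removal -> geometry -> shell counting ->
percentages for every listed image, captures per-image failures without
aborting the batch, and aggregates per-shell probe percentages across
nuclei within each group as mean +/- SEM (sample standard deviation over
sqrt(n)).  Results are written as CSV, a spreadsheet workbook, and one
histogram (mean probe share per shell with SEM error bars) per group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nucshell import contour_axes, pixel_model, shell_partition, smudge_filter
from nucshell.contour_axes import AxesGeometry
from nucshell.errors import NucshellError, ParameterError
from nucshell.pixel_model import Overlay, Palette
from nucshell.shell_partition import ShellCounts, ShellProfile
from nucshell.smudge_filter import SmudgeConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for a batch or single-image run."""

    n_shells: int = 5
    palette: Palette = field(default_factory=Palette)
    smudge: SmudgeConfig = field(default_factory=SmudgeConfig)
    annotate: bool = False

    def __post_init__(self) -> None:
        if self.n_shells < 1:
            raise ParameterError(f"shell count must be >= 1, got {self.n_shells}")


@dataclass(frozen=True)
class ImageRecord:
    """Outcome of the pipeline on one image; ``status`` is "ok" or the error."""

    image: str
    group: str
    status: str
    n_shells: int
    counts: ShellCounts | None = None
    profile: ShellProfile | None = None
    geometry: AxesGeometry | None = None
    removed_smudges: int = 0
    residual_smudges: int = 0

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class GroupSummary:
    """Per-shell mean and SEM of the probe percentages over one group."""

    group: str
    n_ok: int
    mean_share: np.ndarray
    sem_share: np.ndarray
    mean_within: np.ndarray
    sem_within: np.ndarray


@dataclass(frozen=True)
class BatchResult:
    records: list[ImageRecord]
    groups: dict[str, GroupSummary]
    n_shells: int


def process_image(
    path: str | Path,
    config: RunConfig,
    group: str = "",
    annotate_dir: str | Path | None = None,
) -> ImageRecord:
    """Run the full per-image pipeline, capturing any error into the record."""
    path = Path(path)
    try:
        grid = pixel_model.load_image(path, background=config.palette.background)
        cls = pixel_model.classify_grid(grid, config.palette)
        removed = 0
        if config.smudge.mode != "off":
            grid, cls, removed = smudge_filter.remove_smudges(
                grid, cls, config.smudge, config.palette
            )
        residual = len(smudge_filter.residual_smudges(cls))
        geom = contour_axes.estimate_geometry(cls)
        contour = contour_axes.find_contour(cls)
        counts = shell_partition.count_shells(cls, contour, geom, config.n_shells)
        profile = shell_partition.shell_profile(counts)
        if annotate_dir is not None:
            annotate_dir = Path(annotate_dir)
            annotate_dir.mkdir(parents=True, exist_ok=True)
            shell_map = shell_partition._shell_map(cls, contour, geom, config.n_shells)
            overlay = Overlay(contour=contour, geometry=geom, shell_map=shell_map)
            pixel_model.write_annotated(grid, overlay, annotate_dir / f"{path.stem}_shells.png")
        return ImageRecord(
            image=str(path),
            group=group,
            status="ok",
            n_shells=config.n_shells,
            counts=counts,
            profile=profile,
            geometry=geom,
            removed_smudges=removed,
            residual_smudges=residual,
        )
    except NucshellError as exc:
        logger.warning("image %s failed: %s: %s", path, type(exc).__name__, exc)
        return ImageRecord(
            image=str(path),
            group=group,
            status=f"error:{type(exc).__name__}: {exc}",
            n_shells=config.n_shells,
        )


def _mean_sem(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = rows.mean(axis=0)
    if rows.shape[0] < 2:
        warnings.warn("single image in group: SEM reported as 0", stacklevel=3)
        return mean, np.zeros_like(mean)
    sem = rows.std(axis=0, ddof=1) / np.sqrt(rows.shape[0])
    return mean, sem


def aggregate(records: list[ImageRecord], n_shells: int) -> dict[str, GroupSummary]:
    """Group-wise per-shell mean and SEM over the successful records.

    Before aggregation every ok record's probe shares are asserted to sum
    to 100 (when any probe is present).  Raises when no record succeeded.
    """
    ok = [r for r in records if r.ok]
    if not ok:
        raise NucshellError("no image was processed successfully")
    for r in ok:
        share_sum = r.profile.pct_probe_share.sum()
        if share_sum > 0:
            assert abs(share_sum - 100.0) < 1e-9, f"{r.image}: probe shares sum to {share_sum}"
    groups: dict[str, GroupSummary] = {}
    for grp in sorted({r.group for r in ok}):
        members = [r for r in ok if r.group == grp]
        share = np.vstack([r.profile.pct_probe_share for r in members])
        within = np.vstack([r.profile.pct_probe_within for r in members])
        mean_share, sem_share = _mean_sem(share)
        mean_within, sem_within = _mean_sem(within)
        groups[grp] = GroupSummary(
            group=grp,
            n_ok=len(members),
            mean_share=mean_share,
            sem_share=sem_share,
            mean_within=mean_within,
            sem_within=sem_within,
        )
    return groups


def records_frame(records: list[ImageRecord]) -> pd.DataFrame:
    """Flatten per-image records into a table (one row per image)."""
    rows = []
    for r in records:
        row: dict = {
            "image": r.image,
            "group": r.group,
            "status": r.status,
            "n_shells": r.n_shells,
            "removed_smudges": r.removed_smudges,
            "residual_smudges": r.residual_smudges,
        }
        if r.ok:
            g = r.geometry
            row.update(
                mpt_x=g.mpt[0],
                mpt_y=g.mpt[1],
                a=g.a,
                b=g.b,
                theta_deg=np.degrees(g.theta),
            )
            for i in range(r.n_shells):
                s = i + 1  # shell 1 = periphery ... N = center
                row[f"all_shell{s}"] = r.counts.all[i]
                row[f"nucleus_shell{s}"] = r.counts.nucleus[i]
                row[f"probe_shell{s}"] = r.counts.probe[i]
                row[f"other_shell{s}"] = r.counts.other[i]
                row[f"pct_probe_within_shell{s}"] = r.profile.pct_probe_within[i]
                row[f"pct_probe_share_shell{s}"] = r.profile.pct_probe_share[i]
        rows.append(row)
    return pd.DataFrame(rows)


def summary_frame(groups: dict[str, GroupSummary], n_shells: int) -> pd.DataFrame:
    """Long-format group summary: one row per (group, shell)."""
    rows = []
    for grp in sorted(groups):
        g = groups[grp]
        for i in range(n_shells):
            rows.append(
                {
                    "group": grp,
                    "shell": i + 1,
                    "shell_position": "periphery" if i == 0 else ("center" if i == n_shells - 1 else "intermediate"),
                    "n_ok": g.n_ok,
                    "mean_probe_share": g.mean_share[i],
                    "sem_probe_share": g.sem_share[i],
                    "mean_probe_within": g.mean_within[i],
                    "sem_probe_within": g.sem_within[i],
                }
            )
    return pd.DataFrame(rows)


def _plot_group(summary: GroupSummary, n_shells: int, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shells = np.arange(1, n_shells + 1)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(shells, summary.mean_share, yerr=summary.sem_share, capsize=4, color="#7a0f0f")
    ax.set_xlabel("shell (1 = periphery ... %d = center)" % n_shells)
    ax.set_ylabel("% probe signal (mean +/- SEM)")
    ax.set_title(f"{summary.group} (n = {summary.n_ok})")
    ax.set_xticks(shells)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_results(batch: BatchResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-image and summary tables (CSV + workbook), histograms, log.

    Returns the paths written, keyed by artifact name.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise NucshellError(f"cannot write to output directory {outdir}: {exc}") from exc

    results = records_frame(batch.records)
    summary = summary_frame(batch.groups, batch.n_shells)
    paths = {
        "results_csv": outdir / "results.csv",
        "summary_csv": outdir / "summary.csv",
        "workbook": outdir / "results.xlsx",
        "log": outdir / "run.log",
    }
    results.to_csv(paths["results_csv"], index=False, float_format="%.6f")
    summary.to_csv(paths["summary_csv"], index=False, float_format="%.6f")
    with pd.ExcelWriter(paths["workbook"], engine="openpyxl") as xl:
        results.to_excel(xl, sheet_name="per_image", index=False)
        summary.to_excel(xl, sheet_name="summary", index=False)
    for grp, gsum in batch.groups.items():
        safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in grp) or "group"
        p = outdir / f"histogram_{safe}.png"
        _plot_group(gsum, batch.n_shells, p)
        paths[f"histogram_{grp}"] = p
    from nucshell import __version__

    with open(paths["log"], "w") as fh:
        fh.write(f"nucshell {__version__}\n")
        fh.write(f"config: n_shells={batch.n_shells}\n")
        for r in batch.records:
            fh.write(f"{r.image}\t{r.group}\t{r.status}\n")
    return paths


def read_list_file(listfile: str | Path) -> list[tuple[str, str]]:
    """Parse a batch list: one image path per line, optional ',group' column.

    Blank lines and #-comments are ignored; the default group is the
    image's parent directory name.
    """
    entries = []
    for raw in Path(listfile).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "," in line:
            path, grp = (part.strip() for part in line.split(",", 1))
        else:
            path, grp = line, Path(line).parent.name
        entries.append((path, grp))
    return entries


def run_batch(
    listfile: str | Path, outdir: str | Path, config: RunConfig | None = None
) -> BatchResult:
    """Process every listed image, aggregate per group, and write all outputs."""
    config = config or RunConfig()
    entries = read_list_file(listfile)
    annotate_dir = Path(outdir) / "annotated" if config.annotate else None
    records = [
        process_image(path, config, group=grp, annotate_dir=annotate_dir)
        for path, grp in entries
    ]
    groups: dict[str, GroupSummary] = {}
    if any(r.ok for r in records):
        groups = aggregate(records, config.n_shells)
    batch = BatchResult(records=records, groups=groups, n_shells=config.n_shells)
    write_results(batch, outdir)
    return batch
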