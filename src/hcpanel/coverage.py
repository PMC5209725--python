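"""Per-base coverage metrics and the Sanger-fallback gap report.

Diagnostic-grade targeted sequencing requires every ROI base to reach a
minimum depth (30x by convention); any ROI of the clinically selected genes
with even a single base below that threshold falls back to Sanger
sequencing.  Two cohort-level summary metrics are computed per sample:

* C30 — the fraction of ROI bases covered at >= 30x;
* uniformity — the fraction of ROI bases whose depth lies within +/-20%
  of the sample's mean ROI depth (both endpoints inclusive).

Depth input is either the three-column samtools-depth dialect
(chrom, 1-based position, depth) or four-column bedGraph
(chrom, 0-based start, end, depth).  Positions absent from the file count
as depth 0; positions outside every ROI are ignored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .panel import ClinicalGeneSet, Panel, Roi

__all__ = [
    "DepthProfile",
    "CoverageSummary",
    "GapEntry",
    "GapReport",
    "read_depths",
    "write_depths",
    "summarize_coverage",
    "find_sanger_regions",
]

DEFAULT_MIN_DEPTH = 30
DEFAULT_UNIFORMITY_WINDOW = 0.2


@dataclass
class DepthProfile:
    """Per-base depths of one sample over every ROI of a panel.

    Depths are stored as one integer array per ROI, index-aligned with
    ``panel.rois``.  Bases shared by overlapping ROIs (e.g. two genes at one
    locus) appear in each ROI's array but are counted once for the global
    metrics.
    """

    sample: str
    panel: Panel
    per_roi: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.per_roi) != len(self.panel.rois):
            raise ValueError("per_roi arrays must align with panel ROIs")
        for roi, arr in zip(self.panel.rois, self.per_roi):
            if len(arr) != len(roi):
                raise ValueError(f"depth array length mismatch for {roi.gene}")
            if (arr < 0).any():
                raise ValueError("negative depth")

    @classmethod
    def zeros(cls, panel: Panel, sample: str) -> "DepthProfile":
        return cls(sample, panel, [np.zeros(len(r), dtype=np.int64) for r in panel.rois])

    @classmethod
    def constant(cls, panel: Panel, sample: str, depth: int) -> "DepthProfile":
        return cls(
            sample, panel, [np.full(len(r), depth, dtype=np.int64) for r in panel.rois]
        )

    def unique_base_depths(self) -> np.ndarray:
        """Depths over the distinct genomic bases of the panel (deduplicated)."""
        chrom_index = {c: i for i, c in enumerate(sorted({r.interval.chrom for r in self.panel.rois}))}
        keys, vals = [], []
        for roi, arr in zip(self.panel.rois, self.per_roi):
            ci = chrom_index[roi.interval.chrom]
            pos = np.arange(roi.interval.start, roi.interval.end, dtype=np.int64)
            keys.append(ci * np.int64(2**40) + pos)
            vals.append(arr)
        keys = np.concatenate(keys)
        vals = np.concatenate(vals)
        _, first = np.unique(keys, return_index=True)
        return vals[first]


@dataclass
class CoverageSummary:
    sample: str
    mean_depth: float
    c30: float
    uniformity: float
    n_bases: int
    min_depth_threshold: int = DEFAULT_MIN_DEPTH
    uniformity_window: float = DEFAULT_UNIFORMITY_WINDOW
    per_exon_mean: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "sample": self.sample,
            "mean_depth": self.mean_depth,
            "c30": self.c30,
            "uniformity": self.uniformity,
            "n_bases": self.n_bases,
            "min_depth_threshold": self.min_depth_threshold,
            "uniformity_window": self.uniformity_window,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    def to_tsv_row(self) -> str:
        return (
            f"{self.sample}\t{self.mean_depth:.4f}\t{self.c30:.6f}\t"
            f"{self.uniformity:.6f}\t{self.n_bases}"
        )

    TSV_HEADER = "sample\tmean_depth\tc30\tuniformity\tn_bases"


@dataclass(frozen=True)
class GapEntry:
    sample: str
    roi: Roi
    min_depth: int
    n_bases_below: int


@dataclass
class GapReport:
    """ROIs requiring Sanger fallback: any base below the depth threshold."""

    threshold: int
    entries: list[GapEntry] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["sample\tgene\tchrom\tstart\tend\texon\tmin_depth\tn_below"]
        for e in self.entries:
            iv = e.roi.interval
            lines.append(
                f"{e.sample}\t{e.roi.gene}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{e.roi.exon_ordinal}\t{e.min_depth}\t{e.n_bases_below}"
            )
        return "\n".join(lines) + "\n"

    def __len__(self) -> int:
        return len(self.entries)


def read_depths(path: str | Path, panel: Panel, sample: str | None = None) -> DepthProfile:
    """Load a per-base depth file restricted to the panel's ROIs.

    The dialect is detected per line from the column count: 3 columns is
    samtools depth (1-based position), 4 is bedGraph (0-based half-open).
    """
    path = Path(path)
    profile = DepthProfile.zeros(panel, sample or path.stem)
    known_chroms = {r.interval.chrom for r in panel.rois}
    by_chrom: dict[str, list[int]] = {}
    for i, roi in enumerate(panel.rois):
        by_chrom.setdefault(roi.interval.chrom, []).append(i)
    warned: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                chrom, pos_s, depth_s = fields
                try:
                    start = int(pos_s) - 1
                    end = start + 1
                    depth = int(float(depth_s))
                except ValueError as exc:
                    raise ValueError(f"{path.name}:{lineno}: unparseable depth line") from exc
            elif len(fields) >= 4:
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                    depth = int(float(fields[3]))
                except ValueError as exc:
                    raise ValueError(f"{path.name}:{lineno}: unparseable depth line") from exc
            else:
                raise ValueError(f"{path.name}:{lineno}: expected 3 or 4 columns")
            if depth < 0:
                raise ValueError(f"{path.name}:{lineno}: negative depth {depth}")
            if chrom not in known_chroms:
                if chrom not in warned:
                    warnings.warn(f"unknown chromosome {chrom!r} in {path.name}; skipped")
                    warned.add(chrom)
                continue
            for i in by_chrom[chrom]:
                iv = panel.rois[i].interval
                lo, hi = max(start, iv.start), min(end, iv.end)
                if lo < hi:
                    profile.per_roi[i][lo - iv.start : hi - iv.start] = depth
    return profile


def write_depths(profile: DepthProfile, path: str | Path) -> None:
    """Write a profile as samtools-depth TSV (chrom, 1-based pos, depth).

    Overlapping-ROI bases are emitted once; zero-depth bases are omitted
    (absence reads back as zero).
    """
    seen: set[tuple[str, int]] = set()
    with open(path, "w") as fh:
        for roi, arr in zip(profile.panel.rois, profile.per_roi):
            chrom = roi.interval.chrom
            for offset, depth in enumerate(arr.tolist()):
                pos0 = roi.interval.start + offset
                if depth == 0 or (chrom, pos0) in seen:
                    continue
                seen.add((chrom, pos0))
                fh.write(f"{chrom}\t{pos0 + 1}\t{depth}\n")


def summarize_coverage(
    profile: DepthProfile,
    panel: Panel | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    uniformity_window: float = DEFAULT_UNIFORMITY_WINDOW,
) -> CoverageSummary:
    """Compute mean depth, C30 and uniformity over the distinct ROI bases.

    The uniformity window is [(1-w)*mean, (1+w)*mean], inclusive at both
    ends, with the unrounded floating-point mean.
    """
    panel = panel or profile.panel
    depths = profile.unique_base_depths()
    if depths.size == 0:
        raise ValueError("panel has no ROI bases")
    mean = float(depths.mean())
    c30 = float((depths >= min_depth).mean())
    lo, hi = (1 - uniformity_window) * mean, (1 + uniformity_window) * mean
    uniformity = float(((depths >= lo) & (depths <= hi)).mean())
    per_exon = [float(a.mean()) for a in profile.per_roi]
    return CoverageSummary(
        sample=profile.sample,
        mean_depth=mean,
        c30=c30,
        uniformity=uniformity,
        n_bases=int(depths.size),
        min_depth_threshold=min_depth,
        uniformity_window=uniformity_window,
        per_exon_mean=per_exon,
    )


def find_sanger_regions(
    profile: DepthProfile,
    panel: Panel,
    geneset: ClinicalGeneSet | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> GapReport:
    """Report every analysed ROI whose minimum per-base depth is below threshold.

    The rule is deliberately strict: a single base below the threshold
    flags the whole ROI for orthogonal (Sanger) sequencing.  Only ROIs of
    the clinically selected genes are considered when a gene set is given.
    """
    if geneset is not None:
        geneset.validate_against(panel)
        genes = geneset.genes
    else:
        genes = panel.genes
    report = GapReport(threshold=min_depth)
    for roi, arr in zip(profile.panel.rois, profile.per_roi):
        if roi.gene not in genes or arr.size == 0:
            continue
        mn = int(arr.min())
        if mn < min_depth:
            report.entries.append(
                GapEntry(
                    sample=profile.sample,
                    roi=roi,
                    min_depth=mn,
                    n_bases_below=int((arr < min_depth).sum()),
                )
            )
    return report
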