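"""Panel model: genes, exons, padded regions of interest and clinical gene sets.

A targeted diagnostic panel is represented as an ordered list of regions of
interest (ROIs).  Each ROI is a coding exon extended into the flanking
introns so that the splice signals are sequenced together with the exon:
35 bases on the splice-acceptor side (upstream in transcription order) and
20 bases on the donor side (downstream).  All coordinates are 0-based
half-open, as in BED; 1-based coordinates appear only at VCF ingestion.

Clinical gene sets (e.g. the genes with established utility for hereditary
breast and ovarian cancer) restrict which panel genes are analysed for a
given patient; the full panel is always sequenced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "Roi",
    "Panel",
    "ClinicalGeneSet",
    "PanelFormatError",
    "load_panel",
    "write_panel",
    "load_geneset",
    "pad_exons",
    "merge_rois",
    "select_genes",
]

DEFAULT_PAD_UPSTREAM = 35
DEFAULT_PAD_DOWNSTREAM = 20


class PanelFormatError(ValueError):
    """Raised when a panel or gene-set file cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos0: int) -> bool:
        """True when the 0-based position lies inside the interval."""
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class Roi:
    """One padded region of interest: an exon plus intronic flanks.

    ``pad_upstream``/``pad_downstream`` are in transcription orientation:
    upstream is the splice-acceptor side of the exon (genomic left on the
    plus strand, genomic right on the minus strand).
    """

    gene: str
    exon_ordinal: int
    interval: GenomicInterval
    strand: str = "+"
    transcript: str = ""
    pad_upstream: int = 0
    pad_downstream: int = 0
    gc: float | None = None  # GC fraction of the exon, when known

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.exon_ordinal < 1:
            raise ValueError("exon_ordinal must be >= 1")
        if self.pad_upstream < 0 or self.pad_downstream < 0:
            raise ValueError("pads must be non-negative")

    @property
    def pad_left(self) -> int:
        """Genomic-left pad (depends on strand)."""
        return self.pad_upstream if self.strand == "+" else self.pad_downstream

    @property
    def pad_right(self) -> int:
        return self.pad_downstream if self.strand == "+" else self.pad_upstream

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class Panel:
    """An ordered collection of ROIs making up one capture panel version."""

    name: str
    rois: list[Roi] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rois = sorted(
            self.rois, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end)
        )

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.rois}

    @property
    def n_bases(self) -> int:
        """Total ROI bases, counting overlapping bases once per ROI."""
        return sum(len(r) for r in self.rois)

    def rois_of(self, gene: str) -> list[Roi]:
        return [r for r in self.rois if r.gene == gene]

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)


@dataclass(frozen=True)
class ClinicalGeneSet:
    """Named gene list defining the analysable scope for one condition."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def validate_against(self, panel: Panel) -> None:
        unknown = sorted(self.genes - panel.genes)
        if unknown:
            raise KeyError(
                f"gene set {self.name!r} names genes absent from panel "
                f"{panel.name!r}: {', '.join(unknown)}"
            )


# ---------------------------------------------------------------------------
# I/O


def load_panel(path: str | Path, name: str | None = None) -> Panel:
    """Read a panel from a BED-with-metadata file.

    Tab-separated, 0-based half-open.  Columns: chrom, start, end, gene,
    then optional transcript, exon ordinal, strand, pad_upstream,
    pad_downstream, gc.  Lines starting with '#' or 'track' are skipped.
    """
    path = Path(path)
    rois: list[Roi] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelFormatError(
                    f"{path.name}:{lineno}: expected >=4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, gene = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path.name}:{lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise PanelFormatError(
                    f"{path.name}:{lineno}: empty interval (start {start} >= end {end})"
                )
            transcript = fields[4] if len(fields) > 4 and fields[4] != "." else ""
            try:
                ordinal = int(fields[5]) if len(fields) > 5 and fields[5] != "." else 1
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path.name}:{lineno}: non-integer exon ordinal"
                ) from exc
            strand = fields[6] if len(fields) > 6 and fields[6] else "+"
            pad_up = int(fields[7]) if len(fields) > 7 and fields[7] != "." else 0
            pad_down = int(fields[8]) if len(fields) > 8 and fields[8] != "." else 0
            gc = float(fields[9]) if len(fields) > 9 and fields[9] != "." else None
            try:
                rois.append(
                    Roi(
                        gene=gene,
                        transcript=transcript,
                        exon_ordinal=ordinal,
                        interval=GenomicInterval(chrom, start, end),
                        strand=strand,
                        pad_upstream=pad_up,
                        pad_downstream=pad_down,
                        gc=gc,
                    )
                )
            except ValueError as exc:
                raise PanelFormatError(f"{path.name}:{lineno}: {exc}") from exc
    return Panel(name=name or path.stem, rois=rois)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel in the BED-with-metadata dialect read by load_panel."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tgene\ttranscript\texon\tstrand"
            "\tpad_upstream\tpad_downstream\tgc\n"
        )
        for r in panel.rois:
            gc = f"{r.gc:.4f}" if r.gc is not None else "."
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.gene}\t{r.transcript or '.'}\t{r.exon_ordinal}\t{r.strand}\t"
                f"{r.pad_upstream}\t{r.pad_downstream}\t{gc}\n"
            )


def load_geneset(
    path: str | Path, name: str | None = None, panel: Panel | None = None
) -> ClinicalGeneSet:
    """Read a gene set from a plain-text file (one symbol per line, '#' comments)."""
    path = Path(path)
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                genes.add(sym)
    gs = ClinicalGeneSet(name=name or path.stem, genes=frozenset(genes))
    if panel is not None:
        gs.validate_against(panel)
    return gs


# ---------------------------------------------------------------------------
# Operations


def pad_exons(
    exons: Iterable[Roi],
    pad5: int = DEFAULT_PAD_UPSTREAM,
    pad3: int = DEFAULT_PAD_DOWNSTREAM,
    strand_aware: bool = True,
) -> list[Roi]:
    """Extend unpadded exons into the flanking introns.

    With ``strand_aware`` (the default) pad5 bases are added on the
    splice-acceptor side and pad3 on the donor side of each exon, i.e. the
    genomic sides swap on the minus strand.  With ``strand_aware=False``
    pad5 is applied on the genomic left and pad3 on the genomic right
    regardless of strand.  Padding that would cross position 0 is clamped
    with a warning.
    """
    out: list[Roi] = []
    for roi in exons:
        if strand_aware and roi.strand == "-":
            left, right = pad3, pad5
        else:
            left, right = pad5, pad3
        start = roi.interval.start - left
        if start < 0:
            warnings.warn(
                f"padding of {roi.gene} exon {roi.exon_ordinal} crosses "
                "position 0; clamped",
                stacklevel=2,
            )
            start = 0
        new_iv = GenomicInterval(roi.interval.chrom, start, roi.interval.end + right)
        out.append(
            replace(
                roi,
                interval=new_iv,
                pad_upstream=max(roi.pad_upstream + pad5, 0),
                pad_downstream=max(roi.pad_downstream + pad3, 0),
            )
        )
    return out


def unpad_exons(rois: Iterable[Roi], strand_aware: bool = True) -> list[Roi]:
    """Inverse of :func:`pad_exons` using each ROI's recorded pads."""
    out = []
    for roi in rois:
        left = roi.pad_left if strand_aware else roi.pad_upstream
        right = roi.pad_right if strand_aware else roi.pad_downstream
        iv = GenomicInterval(
            roi.interval.chrom, roi.interval.start + left, roi.interval.end - right
        )
        out.append(replace(roi, interval=iv, pad_upstream=0, pad_downstream=0))
    return out


def merge_rois(panel: Panel) -> Panel:
    """Union overlapping or adjacent ROIs per gene.

    Isoforms of one gene frequently share exons; for coverage and
    copy-number purposes each genomic base should belong to at most one ROI
    of a gene.  Exon ordinals are reassigned consecutively along the
    transcription direction.  Total covered bases per gene are unchanged.
    """
    merged: list[Roi] = []
    by_gene: dict[str, list[Roi]] = {}
    for roi in panel.rois:
        by_gene.setdefault(roi.gene, []).append(roi)
    for gene, rois in by_gene.items():
        by_chrom: dict[str, list[Roi]] = {}
        for r in rois:
            by_chrom.setdefault(r.interval.chrom, []).append(r)
        gene_merged: list[Roi] = []
        for chrom, group in by_chrom.items():
            group.sort(key=lambda r: (r.interval.start, r.interval.end))
            cur = group[0]
            cur_start, cur_end = cur.interval.start, cur.interval.end
            for r in group[1:]:
                if r.interval.start <= cur_end:  # overlap or adjacency
                    cur_end = max(cur_end, r.interval.end)
                else:
                    gene_merged.append(
                        replace(
                            cur,
                            interval=GenomicInterval(chrom, cur_start, cur_end),
                            transcript="",
                        )
                    )
                    cur, cur_start, cur_end = r, r.interval.start, r.interval.end
            gene_merged.append(
                replace(cur, interval=GenomicInterval(chrom, cur_start, cur_end), transcript="")
            )
        # renumber in transcription order: plus strand 5'->3' is genomic order
        gene_merged.sort(key=lambda r: (r.interval.chrom, r.interval.start))
        strand = gene_merged[0].strand
        ordered = gene_merged if strand == "+" else list(reversed(gene_merged))
        for i, r in enumerate(ordered, start=1):
            merged.append(replace(r, exon_ordinal=i))
    return Panel(name=panel.name, rois=merged)


def select_genes(panel: Panel, geneset: ClinicalGeneSet) -> Panel:
    """Restrict a panel to the ROIs of a clinical gene set."""
    geneset.validate_against(panel)
    rois = [r for r in panel.rois if r.gene in geneset.genes]
    return Panel(name=f"{panel.name}[{geneset.name}]", rois=rois)
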