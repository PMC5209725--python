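"""Exon-level read-depth copy-number calling for multi-sample panel batches.

Constitutional deletions and duplications spanning one exon up to a whole
gene leave a multiplicative footprint on capture depth.  The caller works
on an exon x sample matrix of mean per-base depths and proceeds in
successive normalization steps:

1. library-size normalization — each sample's column is divided by its
   median exon depth, removing sequencing-yield differences;
2. exon reference normalization — each exon's normalized depth is divided
   by a robust across-sample reference for that exon.  By default the
   reference is the leave-one-out median, so a genuine event in the tested
   sample cannot contaminate its own reference in small batches; an
   all-sample median mode is also available;
3. log2 transform with a floor at ratio 2^-8 for zeros.

Samples whose log2 ratios are over-dispersed (median absolute deviation
above ``max_mad``) are excluded from calling.  Per-exon copy states are
assigned by thresholding the copy ratio around the expected values 1.0
(neutral), 0.5 (heterozygous deletion), 0.0 (homozygous deletion) and 1.5
(single-copy duplication), and consecutive same-state exons of one gene are
merged into events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .coverage import DepthProfile
from .panel import Panel, Roi

__all__ = [
    "CoverageMatrix",
    "RatioMatrix",
    "SampleCnvQc",
    "CnvCall",
    "build_matrix",
    "normalize",
    "qc_samples",
    "call_exons",
    "merge_calls",
    "call_cnvs",
]

# copy-ratio thresholds: midpoints between expected states with guard bands
HET_DEL_MAX = 0.65
HOM_DEL_MAX = 0.25
DUP_MIN = 1.35
MAX_MAD = 0.15
LOG2_FLOOR_RATIO = 2.0**-8

State = Literal["neutral", "het_del", "hom_del", "dup"]


@dataclass
class CoverageMatrix:
    """Exon x sample matrix of mean per-base depths."""

    exons: list[Roi]
    samples: list[str]
    depth: np.ndarray  # shape (n_exons, n_samples)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.exons), len(self.samples)):
            raise ValueError("depth matrix shape must be (n_exons, n_samples)")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    def to_tsv(self) -> str:
        header = ["gene", "chrom", "start", "end", "exon"] + list(self.samples)
        lines = ["\t".join(header)]
        for roi, row in zip(self.exons, self.depth):
            iv = roi.interval
            lines.append(
                "\t".join(
                    [roi.gene, iv.chrom, str(iv.start), str(iv.end), str(roi.exon_ordinal)]
                    + [f"{v:.4f}" for v in row]
                )
            )
        return "\n".join(lines) + "\n"


@dataclass
class RatioMatrix:
    exons: list[Roi]
    samples: list[str]
    ratio: np.ndarray       # copy ratios, NaN on masked exons
    log2_ratio: np.ndarray  # floored log2 of ratio
    masked: np.ndarray      # bool per exon: no usable reference

    def __post_init__(self) -> None:
        if self.ratio.shape != (len(self.exons), len(self.samples)):
            raise ValueError("ratio matrix shape mismatch")


@dataclass(frozen=True)
class SampleCnvQc:
    sample: str
    dispersion: float  # MAD of log2 ratios over unmasked exons
    passed: bool


@dataclass(frozen=True)
class CnvCall:
    sample: str
    gene: str
    exon_first: int
    exon_last: int
    state: State
    mean_ratio: float
    n_exons: int
    whole_gene: bool
    confidence: Literal["high", "low"]

    @property
    def exon_span(self) -> tuple[int, int]:
        return (self.exon_first, self.exon_last)


def build_matrix(profiles: Sequence[DepthProfile], panel: Panel) -> CoverageMatrix:
    """Collapse per-base profiles to an exon x sample mean-depth matrix."""
    if len(profiles) < 2:
        raise ValueError("at least 2 samples are required to form a reference")
    samples = [p.sample for p in profiles]
    depth = np.empty((len(panel.rois), len(profiles)), dtype=float)
    for j, prof in enumerate(profiles):
        if len(prof.per_roi) != len(panel.rois):
            raise ValueError(f"profile {prof.sample} does not match the panel")
        depth[:, j] = [a.mean() if a.size else 0.0 for a in prof.per_roi]
    return CoverageMatrix(exons=list(panel.rois), samples=samples, depth=depth)


def _loo_median(r: np.ndarray) -> np.ndarray:
    """Leave-one-out median across columns, per cell."""
    n = r.shape[1]
    ref = np.empty_like(r)
    for s in range(n):
        ref[:, s] = np.median(np.delete(r, s, axis=1), axis=1)
    return ref


def normalize(
    matrix: CoverageMatrix,
    reference: Literal["loo_median", "all_median"] = "loo_median",
) -> RatioMatrix:
    """Turn raw exon depths into copy ratios via successive normalization."""
    depth = matrix.depth
    sample_median = np.median(depth, axis=0)
    bad = sample_median <= 0
    if bad.any():
        names = [s for s, b in zip(matrix.samples, bad) if b]
        raise ValueError(f"sample(s) with zero median depth: {', '.join(names)}")
    r = depth / sample_median  # step 1: library-size scaling

    all_ref = np.median(r, axis=1)
    masked = all_ref <= 0
    if masked.any():
        warnings.warn(f"{int(masked.sum())} exon(s) masked: zero reference depth")

    if reference == "loo_median":
        ref = _loo_median(r)
        # an extreme batch can zero a LOO cell; fall back to the global median
        zero_cells = ref <= 0
        if zero_cells.any():
            ref = np.where(zero_cells, all_ref[:, None], ref)
    elif reference == "all_median":
        ref = np.broadcast_to(all_ref[:, None], r.shape).copy()
    else:
        raise ValueError(f"unknown reference mode {reference!r}")

    ratio = np.full_like(r, np.nan)
    ok = ~masked
    ratio[ok] = r[ok] / ref[ok]
    log2 = np.full_like(ratio, np.nan)
    log2[ok] = np.log2(np.maximum(ratio[ok], LOG2_FLOOR_RATIO))
    return RatioMatrix(
        exons=list(matrix.exons),
        samples=list(matrix.samples),
        ratio=ratio,
        log2_ratio=log2,
        masked=masked,
    )


def qc_samples(ratios: RatioMatrix, max_mad: float = MAX_MAD) -> list[SampleCnvQc]:
    """Per-sample dispersion QC: MAD of log2 ratios over unmasked exons."""
    out = []
    ok = ~ratios.masked
    for j, sample in enumerate(ratios.samples):
        col = ratios.log2_ratio[ok, j]
        if col.size == 0:
            out.append(SampleCnvQc(sample, float("inf"), False))
            continue
        mad = float(np.median(np.abs(col - np.median(col))))
        out.append(SampleCnvQc(sample, mad, mad <= max_mad))
    return out


def call_exons(
    ratios: RatioMatrix,
    qc: Sequence[SampleCnvQc] | None = None,
    het_del_max: float = HET_DEL_MAX,
    hom_del_max: float = HOM_DEL_MAX,
    dup_min: float = DUP_MIN,
) -> np.ndarray:
    """Assign a copy state per (exon, sample); None for masked/failed cells.

    Thresholds are inclusive on the event side: ratio == het_del_max is a
    heterozygous deletion.
    """
    qc_by_sample = {q.sample: q.passed for q in qc} if qc is not None else {}
    states = np.full(ratios.ratio.shape, None, dtype=object)
    for j, sample in enumerate(ratios.samples):
        if qc is not None and not qc_by_sample.get(sample, False):
            continue
        for i in range(len(ratios.exons)):
            if ratios.masked[i]:
                continue
            v = ratios.ratio[i, j]
            if v <= hom_del_max:
                states[i, j] = "hom_del"
            elif v <= het_del_max:
                states[i, j] = "het_del"
            elif v >= dup_min:
                states[i, j] = "dup"
            else:
                states[i, j] = "neutral"
    return states


def merge_calls(states: np.ndarray, ratios: RatioMatrix) -> list[CnvCall]:
    """Merge consecutive same-state exons of one gene into events.

    A run covering every exon of its gene is flagged ``whole_gene``;
    single-exon events are marked low confidence.
    """
    calls: list[CnvCall] = []
    # group matrix rows per gene, ordered by exon ordinal
    gene_rows: dict[str, list[int]] = {}
    for i, roi in enumerate(ratios.exons):
        gene_rows.setdefault(roi.gene, []).append(i)
    for rows in gene_rows.values():
        rows.sort(key=lambda i: ratios.exons[i].exon_ordinal)
    n_exons_of_gene = {g: len(rows) for g, rows in gene_rows.items()}

    for j, sample in enumerate(ratios.samples):
        for gene, rows in gene_rows.items():
            run: list[int] = []
            run_state: str | None = None

            def flush() -> None:
                nonlocal run, run_state
                if run_state in ("het_del", "hom_del", "dup"):
                    ords = [ratios.exons[i].exon_ordinal for i in run]
                    mean_ratio = float(np.mean([ratios.ratio[i, j] for i in run]))
                    calls.append(
                        CnvCall(
                            sample=sample,
                            gene=gene,
                            exon_first=min(ords),
                            exon_last=max(ords),
                            state=run_state,  # type: ignore[arg-type]
                            mean_ratio=mean_ratio,
                            n_exons=len(run),
                            whole_gene=len(run) == n_exons_of_gene[gene],
                            confidence="low" if len(run) == 1 else "high",
                        )
                    )
                run, run_state = [], None

            for i in rows:
                st = states[i, j]
                if st is None or st != run_state:
                    flush()
                    run_state = st
                    run = [i] if st is not None else []
                else:
                    run.append(i)
            flush()
    return calls


def call_cnvs(
    matrix: CoverageMatrix,
    reference: Literal["loo_median", "all_median"] = "loo_median",
    max_mad: float = MAX_MAD,
    het_del_max: float = HET_DEL_MAX,
    hom_del_max: float = HOM_DEL_MAX,
    dup_min: float = DUP_MIN,
) -> tuple[list[CnvCall], list[SampleCnvQc]]:
    """Full pipeline: normalize, QC, per-exon states, merged events."""
    ratios = normalize(matrix, reference=reference)
    qc = qc_samples(ratios, max_mad=max_mad)
    states = call_exons(
        ratios, qc, het_del_max=het_del_max, hom_del_max=hom_del_max, dup_min=dup_min
    )
    return merge_calls(states, ratios), qc


def evaluate_recovery(
    truth_events: Sequence, calls: Sequence[CnvCall]
) -> tuple[int, int, int]:
    """Event-level benchmarking of calls against spiked truth.

    A truth event is recovered when some call has the same sample, gene and
    state and an overlapping exon span (edge exons of an event may
    individually miss a ratio threshold under capture noise without the
    event itself being missed).  A call matching no truth event is a false
    positive.  Returns (n_truth, n_recovered, n_false_positive).
    """

    def overlaps(call: CnvCall, ev) -> bool:
        return (
            call.sample == ev.sample
            and call.gene == ev.gene
            and call.state == ev.state
            and call.exon_first <= ev.exon_last
            and ev.exon_first <= call.exon_last
        )

    recovered = sum(1 for ev in truth_events if any(overlaps(c, ev) for c in calls))
    false_pos = sum(1 for c in calls if not any(overlaps(c, ev) for ev in truth_events))
    return len(truth_events), recovered, false_pos


def calls_to_tsv(calls: Sequence[CnvCall]) -> str:
    lines = ["sample\tgene\texon_first\texon_last\tstate\tmean_ratio\tn_exons\twhole_gene\tconfidence"]
    for c in sorted(calls, key=lambda c: (c.sample, c.gene, c.exon_first)):
        lines.append(
            f"{c.sample}\t{c.gene}\t{c.exon_first}\t{c.exon_last}\t{c.state}\t"
            f"{c.mean_ratio:.4f}\t{c.n_exons}\t{int(c.whole_gene)}\t{c.confidence}"
        )
    return "\n".join(lines) + "\n"


def qc_to_tsv(qc: Sequence[SampleCnvQc]) -> str:
    lines = ["sample\tdispersion\tpassed"]
    for q in qc:
        lines.append(f"{q.sample}\t{q.dispersion:.6f}\t{int(q.passed)}")
    return "\n".join(lines) + "\n"
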