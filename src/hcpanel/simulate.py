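"""Synthetic panels, coverage profiles and annotated variant tables.

Every module in the package is exercisable without downloads: this
generator produces inputs with the statistical structure the methods
assume, together with truth records for recovery tests.

Coverage model.  Per-base depth in sample ``s`` at base ``b`` of exon
``e`` is negative-binomial with mean

    mean_depth * library_scale(s) * gc_factor(e) * exon_effect(e) * falloff(b)

where ``library_scale`` is a log-normal per-sample yield factor (removed by
the caller's first normalization step), ``gc_factor`` penalises exons whose
GC fraction departs from 0.45 (depth falls off at both GC extremes in
hybridization capture), ``exon_effect`` is a log-normal per-exon capture
efficiency shared across samples, and ``falloff`` ramps linearly from
``boundary_falloff`` at the outer edge of each intronic flank to 1.0 at the
exon boundary (capture depth decays across intron/exon boundaries).

Variant model.  Each sample carries a truncated-Poisson number (mean 5,
support [1, 9]) of rare non-causal variants spread over the panel genes in
proportion to target size, plus exactly one causal (disease-causing)
mutation in a gene linked to its clinical condition, plus decoy variants
designed to be removed by each filter: common (MAF >= 1%), off-target
(deep intronic) and low-quality calls.

All randomness derives from a single integer seed; the same seed
reproduces every downstream number bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .coverage import DepthProfile
from .panel import ClinicalGeneSet, GenomicInterval, Panel, Roi
from .variants import (
    PREDICTORS,
    AnnotatedVariant,
    VariantSupport,
)

__all__ = [
    "CONDITIONS",
    "SimulationConfig",
    "CnvEvent",
    "TruthSet",
    "simulate_panel",
    "simulate_genesets",
    "simulate_conditions",
    "simulate_coverage",
    "spike_cnv",
    "simulate_variant_tables",
    "default_cnv_events",
]

CONDITIONS = ("HBOC", "Lynch", "FAP", "NF")

# rng stream tags: one independent stream per generative stage
_TAG_PANEL, _TAG_COVERAGE, _TAG_CNV, _TAG_VARIANTS = 11, 13, 17, 19

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    """Knobs of the generative model, with defaults in the target regime
    (mean depth ~400, C30 ~0.98, burden mean 5 on [1, 9])."""

    seed: int = 0
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (2, 12)       # uniform inclusive bounds
    exon_length_log_mean: float = 5.0               # log-normal, ~150 bp median
    exon_length_log_sd: float = 0.35
    exon_length_bounds: tuple[int, int] = (60, 500)
    n_samples: int = 16
    mean_depth: float = 400.0
    depth_dispersion: float = 10.0                  # NB size parameter
    sample_depth_sd: float = 0.15                   # log-normal sigma, library size
    gc_bias_strength: float = 3.0                   # quadratic penalty vs GC 0.45
    boundary_falloff: float = 0.3                   # depth fraction at flank edges
    exon_effect_sd: float = 0.05                    # log-normal sigma per exon
    pad_upstream: int = 35
    pad_downstream: int = 20
    cnv_events: list["CnvEvent"] = field(default_factory=list)
    variant_burden: float = 5.0
    burden_range: tuple[int, int] = (1, 9)
    maf_novel_fraction: float = 0.3
    common_variant_rate: float = 1.0                # mean common decoys per sample
    offtarget_variant_rate: float = 0.5
    lowqual_variant_rate: float = 0.5


@dataclass(frozen=True)
class CnvEvent:
    sample: str
    gene: str
    exon_first: int
    exon_last: int
    state: Literal["het_del", "hom_del", "dup"]

    def __post_init__(self) -> None:
        if self.exon_first > self.exon_last:
            raise ValueError("exon_first must be <= exon_last")


_CNV_FACTOR = {"het_del": 0.5, "hom_del": 0.02, "dup": 1.5}


@dataclass
class TruthSet:
    cnv_truth: list[CnvEvent] = field(default_factory=list)
    variant_truth: list[AnnotatedVariant] = field(default_factory=list)
    causal_truth: dict[str, tuple] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "cnv_truth": [asdict(e) for e in self.cnv_truth],
            "variant_truth": [
                list(v.key) + [v.consequence, int(v.causal)] for v in self.variant_truth
            ],
            "causal_truth": {s: list(k) for s, k in self.causal_truth.items()},
        }
        return json.dumps(d, indent=2, sort_keys=True)


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


# ---------------------------------------------------------------------------
# panel


def simulate_panel(config: SimulationConfig) -> Panel:
    """A single-chromosome panel of genes with varying exon counts/lengths.

    Exon GC fractions are drawn around 0.45 and attached to each ROI so the
    coverage model can apply its GC penalty.
    """
    rng = _rng(config, _TAG_PANEL)
    rois: list[Roi] = []
    cursor = 10_000
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        lo, hi = config.exons_per_gene
        n_exons = int(rng.integers(lo, hi + 1))
        intervals = []
        for _ in range(n_exons):
            length = int(
                np.clip(
                    rng.lognormal(config.exon_length_log_mean, config.exon_length_log_sd),
                    *config.exon_length_bounds,
                )
            )
            intervals.append((cursor, cursor + length))
            cursor += length + int(rng.integers(500, 2000))
        cursor += int(rng.integers(5_000, 20_000))  # intergenic gap
        # transcription order: minus-strand genes number exons right-to-left
        ordered = intervals if strand == "+" else list(reversed(intervals))
        for ordinal, (s, e) in enumerate(ordered, start=1):
            gc = float(np.clip(rng.beta(0.45 * 40, 0.55 * 40), 0.2, 0.8))
            left = config.pad_upstream if strand == "+" else config.pad_downstream
            right = config.pad_downstream if strand == "+" else config.pad_upstream
            rois.append(
                Roi(
                    gene=gene,
                    exon_ordinal=ordinal,
                    interval=GenomicInterval("chr1", s - left, e + right),
                    strand=strand,
                    pad_upstream=config.pad_upstream,
                    pad_downstream=config.pad_downstream,
                    gc=gc,
                )
            )
    return Panel(name=f"simpanel-seed{config.seed}", rois=rois)


def simulate_conditions(config: SimulationConfig) -> dict[str, str]:
    """Round-robin assignment of samples to clinical conditions."""
    return {
        f"S{i + 1:03d}": CONDITIONS[i % len(CONDITIONS)]
        for i in range(config.n_samples)
    }


def simulate_genesets(panel: Panel, config: SimulationConfig) -> dict[str, ClinicalGeneSet]:
    """Partition panel genes round-robin into condition-linked gene sets."""
    genes = sorted(panel.genes)
    sets: dict[str, set[str]] = {c: set() for c in CONDITIONS}
    for i, g in enumerate(genes):
        sets[CONDITIONS[i % len(CONDITIONS)]].add(g)
    return {
        c: ClinicalGeneSet(name=c, genes=frozenset(gs)) for c, gs in sets.items() if gs
    }


# ---------------------------------------------------------------------------
# coverage


def _falloff_profile(roi: Roi, boundary_falloff: float) -> np.ndarray:
    """Per-base depth multiplier across one ROI: flank ramps, flat exon."""
    n = len(roi)
    prof = np.ones(n)
    left, right = roi.pad_left, roi.pad_right
    if left > 0:
        # exactly boundary_falloff at the outer flank edge, 1.0 at the exon
        prof[:left] = boundary_falloff + (1 - boundary_falloff) * np.arange(left) / left
    if right > 0:
        prof[n - right :] = (
            boundary_falloff
            + (1 - boundary_falloff) * np.arange(right - 1, -1, -1) / right
        )
    return prof


def _gc_factor(gc: float | None, strength: float) -> float:
    if gc is None:
        return 1.0
    return math.exp(-strength * (gc - 0.45) ** 2)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draw with mean ``mean`` and dispersion size r."""
    mean = np.maximum(mean, 1e-9)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_coverage(panel: Panel, config: SimulationConfig) -> list[DepthProfile]:
    """Per-base depth profiles for every sample of the batch."""
    rng = _rng(config, _TAG_COVERAGE)
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    # per-(exon, sample) capture-efficiency noise: does not cancel in the
    # across-sample reference, so downstream recovery tests are non-trivial
    exon_effects = np.exp(
        rng.normal(0.0, config.exon_effect_sd, size=(len(panel.rois), config.n_samples))
    )
    falloffs = [_falloff_profile(r, config.boundary_falloff) for r in panel.rois]
    gc_factors = np.array(
        [_gc_factor(r.gc, config.gc_bias_strength) for r in panel.rois]
    )
    profiles = []
    for j, sample in enumerate(samples):
        scale = float(np.exp(rng.normal(0.0, config.sample_depth_sd)))
        per_roi = []
        for i, roi in enumerate(panel.rois):
            mean = (
                config.mean_depth * scale * gc_factors[i] * exon_effects[i, j] * falloffs[i]
            )
            per_roi.append(_nb_draw(rng, mean, config.depth_dispersion).astype(np.int64))
        profiles.append(DepthProfile(sample=sample, panel=panel, per_roi=per_roi))
    return profiles


def default_cnv_events(panel: Panel, config: SimulationConfig) -> list[CnvEvent]:
    """The standard spike-in: one whole-gene heterozygous deletion, one
    two-exon heterozygous deletion and one three-exon duplication, each in
    a distinct sample.  Genes are chosen deterministically from the panel
    (first genes with enough exons)."""
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    if len(samples) < 3:
        raise ValueError("need >= 3 samples for the default spike-in")
    by_gene: dict[str, int] = {}
    for roi in panel.rois:
        by_gene[roi.gene] = max(by_gene.get(roi.gene, 0), roi.exon_ordinal)
    genes = sorted(by_gene)
    whole = next(g for g in genes if by_gene[g] >= 1)
    two = next(g for g in genes if g != whole and by_gene[g] >= 2)
    three = next(g for g in genes if g not in (whole, two) and by_gene[g] >= 3)
    return [
        CnvEvent(samples[0], whole, 1, by_gene[whole], "het_del"),
        CnvEvent(samples[1], two, 1, 2, "het_del"),
        CnvEvent(samples[2], three, 1, 3, "dup"),
    ]


def spike_cnv(
    profiles: Sequence[DepthProfile],
    events: Sequence[CnvEvent],
    seed: int,
) -> tuple[list[DepthProfile], TruthSet]:
    """Scale depths inside event spans (0.5 het del, 0.02 hom del, 1.5 dup).

    Scaling uses binomial thinning/boosting of the observed counts so the
    spiked depths keep integer counting noise; the expected mean scales by
    exactly the event factor.
    """
    seen: set[tuple[str, str]] = set()
    for e in events:
        if (e.sample, e.gene) in seen:
            raise ValueError(f"overlapping events for {e.sample}/{e.gene}")
        seen.add((e.sample, e.gene))
    rng = np.random.default_rng([seed, _TAG_CNV])
    by_sample = {p.sample: p for p in profiles}
    out = []
    spiked: dict[str, dict[tuple[str, int], float]] = {}
    for e in events:
        if e.sample not in by_sample:
            raise KeyError(f"event references unknown sample {e.sample}")
        factors = spiked.setdefault(e.sample, {})
        panel = by_sample[e.sample].panel
        hit = [
            r
            for r in panel.rois
            if r.gene == e.gene and e.exon_first <= r.exon_ordinal <= e.exon_last
        ]
        if not hit:
            raise KeyError(f"event references unknown span {e.gene}:{e.exon_first}-{e.exon_last}")
        for r in hit:
            factors[(e.gene, r.exon_ordinal)] = _CNV_FACTOR[e.state]
    for p in profiles:
        factors = spiked.get(p.sample, {})
        new_arrays = []
        for roi, arr in zip(p.panel.rois, p.per_roi):
            f = factors.get((roi.gene, roi.exon_ordinal))
            if f is None:
                new_arrays.append(arr.copy())
            elif f <= 1.0:
                new_arrays.append(rng.binomial(arr, f).astype(np.int64))
            else:
                new_arrays.append((arr + rng.binomial(arr, f - 1.0)).astype(np.int64))
        out.append(DepthProfile(sample=p.sample, panel=p.panel, per_roi=new_arrays))
    return out, TruthSet(cnv_truth=list(events))


# ---------------------------------------------------------------------------
# variants


def _truncated_poisson(rng: np.random.Generator, mean: float, lo: int, hi: int) -> int:
    while True:
        k = int(rng.poisson(mean))
        if lo <= k <= hi:
            return k


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _draw_predictions(rng: np.random.Generator, consequence: str) -> dict[str, str]:
    """Predictor verdicts correlated with the variant class."""
    if consequence == "missense":
        damaging_latent = rng.random() < 0.4
        p_match = 0.85
    elif consequence in ("nonsense", "frameshift", "splicing"):
        damaging_latent, p_match = True, 0.9
    else:
        damaging_latent, p_match = False, 0.9
    preds: dict[str, str] = {}
    for p in PREDICTORS:
        u = rng.random()
        if u < 0.1:
            preds[p] = "missing"
        elif rng.random() < p_match:
            preds[p] = "damaging" if damaging_latent else "neutral"
        else:
            preds[p] = "neutral" if damaging_latent else "damaging"
    return preds


def _draw_support(rng: np.random.Generator, good: bool = True) -> VariantSupport:
    depth = max(12, int(rng.negative_binomial(10, 10 / (10 + 400))))
    if good:
        vaf = float(np.clip(rng.normal(0.5, 0.05), 0.15, 0.95))
        qual = float(np.clip(rng.normal(32, 3), 20, 40))
    else:
        # deliberately fails at least one locked caller threshold
        vaf = float(rng.uniform(0.01, 0.05))
        qual = float(np.clip(rng.normal(32, 3), 20, 40))
    alt = max(0, min(depth, int(round(vaf * depth))))
    if good:
        alt = max(alt, 2)
    fwd = int(rng.binomial(alt, 0.5))
    return VariantSupport(
        depth=depth,
        alt_reads=alt,
        vaf=alt / depth if depth else 0.0,
        mean_alt_base_quality=qual,
        strand_alt_fwd=fwd,
        strand_alt_rev=alt - fwd,
        mean_mismatches_alt=float(rng.exponential(0.7)),
        read_position_sd=float(np.clip(rng.normal(60, 10), 20, 120)),
    )


def _draw_maf(rng: np.random.Generator, novel_fraction: float, rare: bool) -> dict[str, float]:
    if rare and rng.random() < novel_fraction:
        return {}
    pops = ("1000G_EUR", "1000G_AFR", "ExAC_NFE", "ExAC_EAS")
    lo, hi = (1e-5, 0.009) if rare else (0.01, 0.05)
    out = {}
    for p in pops:
        if rng.random() < 0.75:
            out[p] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if not out:  # guarantee at least one population entry for non-novel draws
        out[pops[0]] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return out


_CLASS_PROBS = (
    ("missense", 0.50),
    ("synonymous", 0.25),
    ("splicing", 0.10),
    ("frameshift", 0.08),
    ("nonsense", 0.07),
)


def _draw_consequence(rng: np.random.Generator) -> str:
    u = rng.random()
    acc = 0.0
    for cls, p in _CLASS_PROBS:
        acc += p
        if u < acc:
            return cls
    return "missense"


def _pick_position(rng: np.random.Generator, roi: Roi) -> int:
    """1-based position inside the ROI (exon body preferred)."""
    iv = roi.interval
    lo = iv.start + roi.pad_left
    hi = iv.end - roi.pad_right
    if lo >= hi:
        lo, hi = iv.start, iv.end
    return int(rng.integers(lo, hi)) + 1


def _make_variant(
    rng: np.random.Generator,
    sample: str,
    roi: Roi,
    consequence: str,
    rare: bool,
    novel_fraction: float,
    good_support: bool = True,
    causal: bool = False,
    pos: int | None = None,
) -> AnnotatedVariant:
    if pos is None:
        pos = _pick_position(rng, roi)
    if consequence == "frameshift":
        ref, alt = _snv_alleles(rng)
        ref = ref + alt  # simple 1-bp deletion representation
        alt = ref[0]
    else:
        ref, alt = _snv_alleles(rng)
    return AnnotatedVariant(
        sample=sample,
        gene=roi.gene,
        chrom=roi.interval.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=consequence,
        zygosity="hom" if rng.random() < 0.1 else "het",
        maf={} if causal else _draw_maf(rng, novel_fraction, rare),
        predictions=_draw_predictions(rng, consequence),
        support=_draw_support(rng, good=good_support),
        causal=causal,
    )


def simulate_variant_tables(
    panel: Panel,
    config: SimulationConfig,
    conditions: Mapping[str, str] | None = None,
) -> tuple[list[AnnotatedVariant], TruthSet]:
    """Annotated variant tables with truth records.

    Returns all generated variants (truth burden + causal + decoys) in a
    deterministic order, plus the truth set (rare in-ROI variants and the
    causal mutation per sample).  Decoys guarantee that each filter removes
    at least one variant on the default configuration: a common-MAF variant,
    a deep-intronic (off-target) variant and a low-quality call are always
    present for the first sample.
    """
    rng = _rng(config, _TAG_VARIANTS)
    conditions = dict(conditions or simulate_conditions(config))
    genesets = simulate_genesets(panel, config)
    rois = list(panel.rois)
    gene_lengths: dict[str, int] = {}
    for r in rois:
        gene_lengths[r.gene] = gene_lengths.get(r.gene, 0) + len(r)
    genes = sorted(gene_lengths)
    weights = np.array([gene_lengths[g] for g in genes], dtype=float)
    weights /= weights.sum()
    rois_by_gene: dict[str, list[Roi]] = {}
    for r in rois:
        rois_by_gene.setdefault(r.gene, []).append(r)

    variants: list[AnnotatedVariant] = []
    truth = TruthSet()
    lo, hi = config.burden_range
    for idx, sample in enumerate(sorted(conditions)):
        cond = conditions[sample]
        # rare non-causal burden, gene choice weighted by target size
        k = _truncated_poisson(rng, config.variant_burden, lo, hi)
        for _ in range(k):
            gene = genes[int(rng.choice(len(genes), p=weights))]
            roi = rois_by_gene[gene][int(rng.integers(len(rois_by_gene[gene])))]
            v = _make_variant(
                rng, sample, roi, _draw_consequence(rng), rare=True,
                novel_fraction=config.maf_novel_fraction,
            )
            variants.append(v)
            truth.variant_truth.append(v)
        # exactly one causal mutation in a condition-linked gene
        cond_genes = sorted(genesets[cond].genes) if cond in genesets else genes
        cgene = cond_genes[int(rng.integers(len(cond_genes)))]
        croi = rois_by_gene[cgene][int(rng.integers(len(rois_by_gene[cgene])))]
        causal_cls = ("nonsense", "frameshift", "splicing")[int(rng.integers(3))]
        cv = _make_variant(
            rng, sample, croi, causal_cls, rare=True,
            novel_fraction=1.0, causal=True,
        )
        variants.append(cv)
        truth.variant_truth.append(cv)
        truth.causal_truth[sample] = cv.key

        # decoys (forced for the first sample so every filter branch fires)
        n_common = int(rng.poisson(config.common_variant_rate))
        n_off = int(rng.poisson(config.offtarget_variant_rate))
        n_lowq = int(rng.poisson(config.lowqual_variant_rate))
        if idx == 0:
            n_common, n_off, n_lowq = max(n_common, 1), max(n_off, 1), max(n_lowq, 1)
        for _ in range(n_common):
            gene = genes[int(rng.choice(len(genes), p=weights))]
            roi = rois_by_gene[gene][int(rng.integers(len(rois_by_gene[gene])))]
            variants.append(
                _make_variant(
                    rng, sample, roi, _draw_consequence(rng), rare=False,
                    novel_fraction=0.0,
                )
            )
        for _ in range(n_off):
            gene = genes[int(rng.choice(len(genes), p=weights))]
            roi = rois_by_gene[gene][int(rng.integers(len(rois_by_gene[gene])))]
            pos = roi.interval.end + int(rng.integers(50, 200)) + 1  # deep intronic
            variants.append(
                _make_variant(
                    rng, sample, roi, "other", rare=True,
                    novel_fraction=config.maf_novel_fraction, pos=pos,
                )
            )
        for _ in range(n_lowq):
            gene = genes[int(rng.choice(len(genes), p=weights))]
            roi = rois_by_gene[gene][int(rng.integers(len(rois_by_gene[gene])))]
            variants.append(
                _make_variant(
                    rng, sample, roi, _draw_consequence(rng), rare=True,
                    novel_fraction=config.maf_novel_fraction, good_support=False,
                )
            )
    return variants, truth
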