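"""Clinically driven variant filtering, consensus classification and QC flags.

The diagnostic strategy sequences the whole panel but analyses only the
genes relevant to each patient's clinical indication.  Variant tables
arriving from the upstream caller/annotator pass through a chain of pure
filters, each of which records what it removed and why:

* sanity filter — re-asserts the caller's locked parameters
  (depth >= 10, alternate reads >= 2, mean alternate base quality >= 15,
  variant allele fraction >= 0.10);
* gene-set filter — restricts to the clinical gene list;
* region filter — restricts to the padded exon ROIs;
* rarity filter — keeps variants whose minor allele frequency is below 1%
  in every reference population (no frequency record counts as rare).

Missense variants are classified by a consensus over five in-silico
predictors (PolyPhen2 HDIV and HVAR, SIFT, PROVEAN, MutationTaster) under
two policies that the diagnostic workflow applies in different places:

* ``landscape``: neutral iff more than 3 of the 5 predictors say neutral,
  otherwise possibly damaging;
* ``report``: deleterious iff at least 3 predictors say damaging,
  otherwise not deleterious.

Missing predictor verdicts count toward neither threshold, so the two
policies can legitimately disagree (2 damaging / 3 neutral is possibly
damaging under ``landscape`` but not deleterious under ``report``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

__all__ = [
    "PREDICTORS",
    "CONSEQUENCES",
    "SEVERITY_ORDER",
    "VariantSupport",
    "AnnotatedVariant",
    "FilterConfig",
    "QualityFlagConfig",
    "ConsensusVerdict",
    "FilterAudit",
    "normalize_variant",
    "ingest_variants",
    "variants_to_tsv",
    "sanity_filter",
    "filter_by_geneset",
    "filter_by_region",
    "rare_filter",
    "consensus_prediction",
    "display_class",
    "most_damaging",
    "quality_flags",
]

PREDICTORS = (
    "PolyPhen2-HDIV",
    "PolyPhen2-HVAR",
    "SIFT",
    "PROVEAN",
    "MutationTaster",
)

CONSEQUENCES = (
    "nonsense",
    "frameshift",
    "splicing",
    "missense",
    "synonymous",
    "other",
    "cnv",
)

# severity ranking for the "most damaging variant per cell" rule; missense is
# split by the landscape consensus.  CNV at the top is this package's
# convention.
SEVERITY_ORDER = (
    "other",
    "synonymous",
    "missense_neutral",
    "missense_possibly_damaging",
    "splicing",
    "frameshift",
    "nonsense",
    "cnv",
)
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


@dataclass(frozen=True)
class VariantSupport:
    """Read-level evidence for one variant call."""

    depth: int
    alt_reads: int
    vaf: float
    mean_alt_base_quality: float
    strand_alt_fwd: int = 0
    strand_alt_rev: int = 0
    mean_mismatches_alt: float = 0.0
    read_position_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.alt_reads > self.depth:
            raise ValueError("alt_reads exceeds depth")


@dataclass(frozen=True)
class AnnotatedVariant:
    sample: str
    gene: str
    chrom: str
    pos: int  # 1-based, left-aligned
    ref: str
    alt: str
    consequence: str
    zygosity: Literal["het", "hom"] = "het"
    maf: Mapping[str, float] = field(default_factory=dict)
    predictions: Mapping[str, str] = field(default_factory=dict)
    support: VariantSupport | None = None
    causal: bool = False

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for pop, f in self.maf.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"MAF out of [0,1] for {pop}: {f}")
        for pred, verdict in self.predictions.items():
            if verdict not in ("damaging", "neutral", "missing"):
                raise ValueError(f"unknown predictor verdict {verdict!r}")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Sanity thresholds mirroring the caller's locked parameters."""

    maf_cutoff: float = 0.01
    min_depth: int = 10
    min_alt_reads: int = 2
    min_avg_qual: float = 15.0
    min_vaf: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_cutoff < 1.0:
            raise ValueError("maf_cutoff must be in (0,1)")


@dataclass(frozen=True)
class QualityFlagConfig:
    low_vaf_below: float = 0.2
    strand_bias_min_alt: int = 5
    low_base_quality_below: float = 20.0
    mismatch_rich_above: float = 3.0
    positional_clustering_sd_fraction: float = 0.05
    read_length: int = 250


@dataclass(frozen=True)
class ConsensusVerdict:
    policy: Literal["landscape", "report"]
    label: str
    n_neutral: int
    n_damaging: int
    n_missing: int

    def __post_init__(self) -> None:
        if self.n_neutral + self.n_damaging + self.n_missing != len(PREDICTORS):
            raise ValueError("verdict counts must total the number of predictors")


class FilterAudit:
    """Records every removed variant with the rule that removed it."""

    def __init__(self) -> None:
        self.removed: list[tuple[tuple, str]] = []
        self.flags: list[tuple[tuple, str]] = []

    def log_removed(self, variant: AnnotatedVariant, rule: str) -> None:
        self.removed.append((variant.key, rule))

    def log_flag(self, variant: AnnotatedVariant, note: str) -> None:
        self.flags.append((variant.key, note))

    def rules_applied(self) -> set[str]:
        return {rule for _, rule in self.removed}

    def to_tsv(self) -> str:
        lines = ["sample\tchrom\tpos\tref\talt\trule"]
        for key, rule in self.removed:
            lines.append("\t".join(str(x) for x in key) + f"\t{rule}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# normalization


def normalize_variant(
    pos: int, ref: str, alt: str, ref_seq: str | None = None
) -> tuple[int, str, str]:
    """Left-align and trim a variant to its canonical representation.

    ``pos`` is 1-based; ``ref_seq`` is the 0-based chromosome sequence and
    is required to shift indels left through repeat tracts.  Without it the
    variant is only prefix/suffix-trimmed.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError("empty ref or alt allele; use anchored representation")
    if ref_seq is not None:
        while True:
            if ref and alt and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
                if not ref or not alt:
                    if pos <= 1:
                        raise ValueError("cannot left-extend past position 1")
                    pos -= 1
                    base = ref_seq[pos - 1].upper()
                    ref, alt = base + ref, base + alt
                continue
            break
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# ingestion

_TSV_COLUMNS = [
    "sample",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "zygosity",
    "maf",
    "predictions",
    "depth",
    "alt_reads",
    "vaf",
    "mean_alt_base_quality",
    "strand_alt_fwd",
    "strand_alt_rev",
    "mean_mismatches_alt",
    "read_position_sd",
    "causal",
]


def _parse_mapping(text: str, cast=float) -> dict:
    """Parse 'KEY:val;KEY:val' cells; empty means no data."""
    text = (text or "").strip()
    if not text or text == ".":
        return {}
    out = {}
    for item in text.split(";"):
        k, _, v = item.partition(":")
        out[k.strip()] = cast(v.strip()) if cast is not str else v.strip()
    return out


def _format_mapping(m: Mapping, fmt="{:.6g}") -> str:
    if not m:
        return "."
    items = []
    for k in sorted(m):
        v = m[k]
        items.append(f"{k}:{fmt.format(v) if not isinstance(v, str) else v}")
    return ";".join(items)


def ingest_variants(
    path: str | Path,
    sample: str | None = None,
    ref_seqs: Mapping[str, str] | None = None,
) -> list[AnnotatedVariant]:
    """Load an annotated variant table (TSV) or a VCF.

    TSV is the native annotated-export dialect written by
    :func:`variants_to_tsv`.  VCF records are read through pysam with
    annotations taken from INFO keys (GENE, CSQ_CLASS, MAF_*, PRED_*).
    Variants are normalized (left-aligned when reference sequence is
    available, always trimmed); a reference-allele mismatch against
    ``ref_seqs`` is a validation error.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        return _ingest_vcf(path, sample, ref_seqs)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("sample", "gene", "chrom", "pos", "ref", "alt", "consequence") if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns: {', '.join(missing)}")
    variants: list[AnnotatedVariant] = []
    for idx, row in df.iterrows():
        try:
            variants.append(_row_to_variant(row, sample, ref_seqs))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path.name}: record {idx + 1}: {exc}") from exc
    return variants


def _row_to_variant(row, sample, ref_seqs) -> AnnotatedVariant:
    chrom = row["chrom"]
    pos, ref, alt = int(row["pos"]), row["ref"], row["alt"]
    seq = ref_seqs.get(chrom) if ref_seqs else None
    if seq is not None and seq[pos - 1 : pos - 1 + len(ref)].upper() != ref.upper():
        raise ValueError(f"reference mismatch at {chrom}:{pos} (ref={ref})")
    pos, ref, alt = normalize_variant(pos, ref, alt, seq)
    preds = _parse_mapping(row.get("predictions", ""), cast=str)
    support = None
    if str(row.get("depth", "")).strip() not in ("", "."):
        support = VariantSupport(
            depth=int(row["depth"]),
            alt_reads=int(row["alt_reads"]),
            vaf=float(row["vaf"]),
            mean_alt_base_quality=float(row["mean_alt_base_quality"]),
            strand_alt_fwd=int(row.get("strand_alt_fwd", 0) or 0),
            strand_alt_rev=int(row.get("strand_alt_rev", 0) or 0),
            mean_mismatches_alt=float(row.get("mean_mismatches_alt", 0) or 0),
            read_position_sd=float(row.get("read_position_sd", 0) or 0),
        )
    return AnnotatedVariant(
        sample=sample or row["sample"],
        gene=row["gene"],
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=row["consequence"],
        zygosity=row.get("zygosity", "het") or "het",
        maf=_parse_mapping(row.get("maf", "")),
        predictions=preds,
        support=support,
        causal=str(row.get("causal", "0")).strip().lower() in ("1", "true", "yes"),
    )


def _ingest_vcf(path: Path, sample, ref_seqs) -> list[AnnotatedVariant]:
    import pysam

    variants: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf, start=1):
            try:
                info = rec.info
                for alt in rec.alts or ():
                    chrom = rec.chrom
                    seq = ref_seqs.get(chrom) if ref_seqs else None
                    pos, ref, a = normalize_variant(rec.pos, rec.ref, alt, seq)
                    maf = {
                        k[4:]: float(info[k])
                        for k in info.keys()
                        if k.startswith("MAF_")
                    }
                    preds = {
                        k[5:].replace("_", "-"): str(info[k])
                        for k in info.keys()
                        if k.startswith("PRED_")
                    }
                    variants.append(
                        AnnotatedVariant(
                            sample=sample or (list(rec.samples)[0] if rec.samples else "NA"),
                            gene=str(info.get("GENE", "NA")),
                            chrom=chrom,
                            pos=pos,
                            ref=ref,
                            alt=a,
                            consequence=str(info.get("CSQ_CLASS", "other")),
                            maf=maf,
                            predictions=preds,
                        )
                    )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path.name}: record {i}: {exc}") from exc
    return variants


def variants_to_tsv(variants: Iterable[AnnotatedVariant]) -> str:
    lines = ["\t".join(_TSV_COLUMNS)]
    for v in variants:
        s = v.support
        lines.append(
            "\t".join(
                [
                    v.sample,
                    v.gene,
                    v.chrom,
                    str(v.pos),
                    v.ref,
                    v.alt,
                    v.consequence,
                    v.zygosity,
                    _format_mapping(v.maf),
                    _format_mapping(v.predictions),
                    str(s.depth) if s else ".",
                    str(s.alt_reads) if s else ".",
                    f"{s.vaf:.4f}" if s else ".",
                    f"{s.mean_alt_base_quality:.2f}" if s else ".",
                    str(s.strand_alt_fwd) if s else ".",
                    str(s.strand_alt_rev) if s else ".",
                    f"{s.mean_mismatches_alt:.3f}" if s else ".",
                    f"{s.read_position_sd:.2f}" if s else ".",
                    str(int(v.causal)),
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# filters (pure predicates; order-independent by construction)


def sanity_filter(
    variants: Sequence[AnnotatedVariant],
    config: FilterConfig = FilterConfig(),
    audit: FilterAudit | None = None,
) -> list[AnnotatedVariant]:
    """Re-apply the caller's locked read-support thresholds.

    A variant with no support metrics is kept (the filter cannot be
    applied) and flagged in the audit.
    """
    kept = []
    for v in variants:
        s = v.support
        if s is None:
            if audit:
                audit.log_flag(v, "sanity_filter_not_applied:missing_support")
            kept.append(v)
            continue
        if s.depth < config.min_depth:
            if audit:
                audit.log_removed(v, f"sanity:depth<{config.min_depth}")
        elif s.alt_reads < config.min_alt_reads:
            if audit:
                audit.log_removed(v, f"sanity:alt_reads<{config.min_alt_reads}")
        elif s.mean_alt_base_quality < config.min_avg_qual:
            if audit:
                audit.log_removed(v, f"sanity:avg_qual<{config.min_avg_qual}")
        elif s.vaf < config.min_vaf:
            if audit:
                audit.log_removed(v, f"sanity:vaf<{config.min_vaf}")
        else:
            kept.append(v)
    return kept


def filter_by_geneset(
    variants: Sequence[AnnotatedVariant],
    geneset,
    audit: FilterAudit | None = None,
) -> list[AnnotatedVariant]:
    """Keep variants in genes with clinical utility for the indication."""
    kept = []
    for v in variants:
        if v.gene in geneset.genes:
            kept.append(v)
        elif audit:
            audit.log_removed(v, f"geneset:{geneset.name}")
    return kept


def filter_by_region(
    variants: Sequence[AnnotatedVariant],
    panel,
    audit: FilterAudit | None = None,
) -> list[AnnotatedVariant]:
    """Keep variants whose (0-based) position falls inside any panel ROI."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for roi in panel.rois:
        by_chrom.setdefault(roi.interval.chrom, []).append(
            (roi.interval.start, roi.interval.end)
        )
    kept = []
    for v in variants:
        pos0 = v.pos - 1
        inside = any(s <= pos0 < e for s, e in by_chrom.get(v.chrom, ()))
        if inside:
            kept.append(v)
        elif audit:
            audit.log_removed(v, "region:outside_roi")
    return kept


def rare_filter(
    variants: Sequence[AnnotatedVariant],
    maf_cutoff: float = 0.01,
    audit: FilterAudit | None = None,
) -> list[AnnotatedVariant]:
    """Keep variants rare (< cutoff, strict) in every reference population.

    A variant with no frequency record is kept: absence from the databases
    cannot make a variant common.
    """
    kept = []
    for v in variants:
        if all(f < maf_cutoff for f in v.maf.values()):
            kept.append(v)
        elif audit:
            pop = max(v.maf, key=v.maf.get)
            audit.log_removed(v, f"maf:{pop}>={maf_cutoff}")
    return kept


# ---------------------------------------------------------------------------
# classification


def consensus_prediction(
    variant_or_predictions: AnnotatedVariant | Mapping[str, str],
    policy: Literal["landscape", "report"] = "landscape",
) -> ConsensusVerdict:
    """Combine the five predictor verdicts under one of the two policies."""
    preds = (
        variant_or_predictions.predictions
        if isinstance(variant_or_predictions, AnnotatedVariant)
        else variant_or_predictions
    )
    n_neutral = n_damaging = 0
    for p in PREDICTORS:
        verdict = preds.get(p, "missing")
        if verdict == "neutral":
            n_neutral += 1
        elif verdict == "damaging":
            n_damaging += 1
    n_missing = len(PREDICTORS) - n_neutral - n_damaging
    if policy == "landscape":
        label = "neutral" if n_neutral > 3 else "possibly_damaging"
    elif policy == "report":
        label = "deleterious" if n_damaging >= 3 else "not_deleterious"
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return ConsensusVerdict(policy, label, n_neutral, n_damaging, n_missing)


def display_class(variant: AnnotatedVariant) -> str:
    """Severity class for display: missense split by landscape consensus."""
    if variant.consequence == "missense":
        verdict = consensus_prediction(variant, "landscape")
        return f"missense_{verdict.label}"
    return variant.consequence


def most_damaging(variants: Sequence[AnnotatedVariant]) -> AnnotatedVariant:
    """The most severe variant of a (sample, gene) group.

    Ties in severity are broken by smaller genomic position for
    determinism.
    """
    if not variants:
        raise ValueError("most_damaging on an empty group")
    return max(variants, key=lambda v: (_SEVERITY_RANK[display_class(v)], -v.pos))


def severity_rank(class_name: str) -> int:
    return _SEVERITY_RANK[class_name]


def quality_flags(
    variant: AnnotatedVariant, config: QualityFlagConfig = QualityFlagConfig()
) -> set[str]:
    """Indicator labels guiding orthogonal validation of a variant call."""
    s = variant.support
    if s is None:
        raise ValueError("quality_flags requires support metrics")
    flags: set[str] = set()
    if s.vaf < config.low_vaf_below:
        flags.add("low_vaf")
    one_strand = (s.strand_alt_fwd == 0) != (s.strand_alt_rev == 0)
    if one_strand and s.alt_reads >= config.strand_bias_min_alt:
        flags.add("strand_bias")
    if s.mean_alt_base_quality < config.low_base_quality_below:
        flags.add("low_base_quality")
    if s.mean_mismatches_alt > config.mismatch_rich_above:
        flags.add("mismatch_rich")
    if s.read_position_sd < config.positional_clustering_sd_fraction * config.read_length:
        flags.add("positional_clustering")
    return flags
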