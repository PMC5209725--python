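"""Diagnostic-accuracy statistics with exact binomial confidence intervals.

Panel validation compares the variant set observed by the pipeline against
variants previously established by orthogonal methods.  Sensitivity and
specificity are reported with two-sided Clopper-Pearson (exact) intervals,
i.e. the Beta-quantile construction

    lower = BetaInv(alpha/2; x, n - x + 1)        (0 when x = 0)
    upper = BetaInv(1 - alpha/2; x + 1, n - x)    (1 when x = n)

Repeatability (within-run) and reproducibility (between-run) are measured
as the number of variants common to two runs divided by the total number
of distinct variants the runs identified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Literal

from scipy import stats

from .cnv import CnvCall
from .variants import AnnotatedVariant

__all__ = [
    "BinomialCi",
    "DetectionComparison",
    "PrecisionResult",
    "variant_key",
    "compare_detections",
    "clopper_pearson",
    "sensitivity",
    "specificity",
    "concordance",
]


@dataclass(frozen=True)
class BinomialCi:
    x: int
    n: int
    level: float
    lower: float
    upper: float
    method: str = "clopper-pearson"

    def as_pct(self, ndigits: int = 1) -> tuple[float, float]:
        """Interval endpoints as percentages at report precision."""
        return (round(100 * self.lower, ndigits), round(100 * self.upper, ndigits))


@dataclass
class DetectionComparison:
    expected: frozenset
    observed: frozenset

    @property
    def tp(self) -> frozenset:
        return self.expected & self.observed

    @property
    def fn(self) -> frozenset:
        return self.expected - self.observed

    @property
    def fp(self) -> frozenset:
        return self.observed - self.expected


@dataclass(frozen=True)
class PrecisionResult:
    kind: Literal["repeatability", "reproducibility"]
    concordance: float
    ci: BinomialCi
    n_common: int
    n_total: int


def variant_key(variant: AnnotatedVariant | CnvCall) -> tuple:
    """Stable identity of a variant across files and representations.

    SNVs/indels are keyed by (sample, chrom, pos, ref, alt) after
    left-alignment; copy-number events by (sample, gene, exon span, state).
    """
    if isinstance(variant, CnvCall):
        return (variant.sample, variant.gene, variant.exon_first, variant.exon_last, variant.state)
    return variant.key


def compare_detections(
    expected: Iterable[Hashable], observed: Iterable[Hashable]
) -> DetectionComparison:
    return DetectionComparison(frozenset(expected), frozenset(observed))


def clopper_pearson(x: int, n: int, level: float = 0.95) -> BinomialCi:
    """Exact two-sided binomial confidence interval for x successes in n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must be in [0, n]")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return BinomialCi(x=x, n=n, level=level, lower=lower, upper=upper)


def sensitivity(
    comparison: DetectionComparison, level: float = 0.95
) -> tuple[float, BinomialCi]:
    """Fraction of expected variants detected, with exact CI."""
    n = len(comparison.expected)
    if n == 0:
        raise ValueError("sensitivity undefined: no expected variants")
    x = len(comparison.tp)
    return x / n, clopper_pearson(x, n, level)


def specificity(
    comparison: DetectionComparison, n_negatives: int, level: float = 0.95
) -> tuple[float, BinomialCi]:
    """Fraction of negative sites free of false-positive calls, with exact CI.

    ``n_negatives`` is the number of assessed positions/tests known to carry
    no variant; it is study metadata, not derivable from the key sets.
    """
    if n_negatives < 1:
        raise ValueError("specificity undefined: n_negatives must be >= 1")
    tn = n_negatives - len(comparison.fp)
    if tn < 0:
        raise ValueError("more false positives than negative sites")
    return tn / n_negatives, clopper_pearson(tn, n_negatives, level)


def concordance(
    run_a: Iterable[Hashable],
    run_b: Iterable[Hashable],
    kind: Literal["repeatability", "reproducibility"] = "repeatability",
    level: float = 0.95,
) -> PrecisionResult:
    """Common variants over the union of two runs' variant sets."""
    a, b = frozenset(run_a), frozenset(run_b)
    total = a | b
    if not total:
        raise ValueError("concordance undefined for two empty runs")
    common = a & b
    frac = len(common) / len(total)
    return PrecisionResult(
        kind=kind,
        concordance=frac,
        ci=clopper_pearson(len(common), len(total), level),
        n_common=len(common),
        n_total=len(total),
    )
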