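"""Gene x sample rare-variant landscape matrix and summary statistics.

Beyond the disease-causing mutation, hereditary-cancer genes carry a rich
background of rare variation.  The landscape matrix summarises the rare
(MAF < 1%) variants retained for a cohort: each row is a gene, each column
a sample, and each non-empty cell shows the class of the most damaging
variant found there, the number of variants, and whether the cell holds
the sample's disease-causing mutation.

Ordering conventions (deterministic):

* genes descend by total non-causal variants, ties broken alphabetically —
  the causal mutation is excluded so the background variation drives the
  ordering;
* samples are grouped by clinical condition, then descend by total variant
  count, ties broken by sample id.

Summary statistics cover the per-sample burden of coexisting (non-causal)
variation, per-gene totals, the share of variants concentrated in the top
10% of genes, and multi-hit tallies (one patient with more than one
variant in the same gene).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .variants import AnnotatedVariant, display_class, most_damaging

__all__ = [
    "LandscapeCell",
    "LandscapeMatrix",
    "LandscapeStats",
    "build_landscape",
    "landscape_stats",
    "export_landscape",
]


@dataclass(frozen=True)
class LandscapeCell:
    display_class: str
    n_variants: int       # all variants in the cell, causal included
    n_causal: int

    @property
    def causal_present(self) -> bool:
        return self.n_causal > 0


@dataclass
class LandscapeMatrix:
    genes: list[str]      # ordered, descending non-causal totals
    samples: list[str]    # ordered by condition then total variants
    cells: dict[tuple[str, str], LandscapeCell]
    conditions: dict[str, str] = field(default_factory=dict)

    def column_total(self, sample: str) -> int:
        return sum(c.n_variants for (g, s), c in self.cells.items() if s == sample)

    def row_total(self, gene: str, include_causal: bool = False) -> int:
        tot = 0
        for (g, s), c in self.cells.items():
            if g == gene:
                tot += c.n_variants if include_causal else c.n_variants - c.n_causal
        return tot

    @property
    def total_variants(self) -> int:
        return sum(c.n_variants for c in self.cells.values())


@dataclass
class LandscapeStats:
    """Summary of the coexisting (non-causal) rare variation.

    ``per_sample_counts`` and the derived mean/range count non-causal
    variants only, matching the gene ordering convention; causal mutations
    are tracked separately in ``n_causal``.  Multi-hit tallies count every
    variant in a (gene, sample) cell holding two or more.
    """

    per_sample_counts: dict[str, int]
    range: tuple[int, int]
    mean_per_sample: float
    per_gene_totals: dict[str, int]
    top_decile_share: float
    multihit_pairs: int
    multihit_variants: int
    n_causal: int
    total_variants: int

    def to_json(self) -> str:
        d = {
            "per_sample_counts": self.per_sample_counts,
            "range": list(self.range),
            "mean_per_sample": self.mean_per_sample,
            "per_gene_totals": self.per_gene_totals,
            "top_decile_share": self.top_decile_share,
            "multihit_pairs": self.multihit_pairs,
            "multihit_variants": self.multihit_variants,
            "n_causal": self.n_causal,
            "total_variants": self.total_variants,
        }
        return json.dumps(d, indent=2, sort_keys=True)


def build_landscape(
    variants: Sequence[AnnotatedVariant],
    conditions: Mapping[str, str] | None = None,
) -> LandscapeMatrix:
    """Assemble the matrix from rare-filtered variants.

    ``conditions`` maps sample id to clinical condition; samples without a
    label fall into an "unknown" group (warned via the returned mapping).
    """
    conditions = dict(conditions or {})
    groups: dict[tuple[str, str], list[AnnotatedVariant]] = {}
    samples_seen: list[str] = []
    for v in variants:
        groups.setdefault((v.gene, v.sample), []).append(v)
        if v.sample not in samples_seen:
            samples_seen.append(v.sample)
    for s in samples_seen:
        conditions.setdefault(s, "unknown")

    cells: dict[tuple[str, str], LandscapeCell] = {}
    for (gene, sample), vs in groups.items():
        top = most_damaging(vs)
        cells[(gene, sample)] = LandscapeCell(
            display_class=display_class(top),
            n_variants=len(vs),
            n_causal=sum(v.causal for v in vs),
        )

    noncausal_totals: dict[str, int] = {}
    for (gene, _), cell in cells.items():
        noncausal_totals[gene] = (
            noncausal_totals.get(gene, 0) + cell.n_variants - cell.n_causal
        )
    genes = sorted(noncausal_totals, key=lambda g: (-noncausal_totals[g], g))

    col_totals = {s: 0 for s in samples_seen}
    for (_, sample), cell in cells.items():
        col_totals[sample] += cell.n_variants
    samples = sorted(
        samples_seen, key=lambda s: (conditions[s], -col_totals[s], s)
    )
    return LandscapeMatrix(genes=genes, samples=samples, cells=cells, conditions=conditions)


def landscape_stats(matrix: LandscapeMatrix) -> LandscapeStats:
    """Burden, concentration and multi-hit statistics of the landscape."""
    if not matrix.cells:
        raise ValueError("landscape matrix is empty")
    per_sample = {s: 0 for s in matrix.samples}
    n_causal = 0
    for (_, sample), cell in matrix.cells.items():
        per_sample[sample] += cell.n_variants - cell.n_causal
        n_causal += cell.n_causal
    counts = list(per_sample.values())
    per_gene = {g: matrix.row_total(g) for g in matrix.genes}

    with_variants = [g for g in matrix.genes if per_gene[g] >= 1]
    total_noncausal = sum(per_gene.values())
    if with_variants and total_noncausal > 0:
        k = math.ceil(0.10 * len(with_variants))
        ranked = sorted(with_variants, key=lambda g: (-per_gene[g], g))
        top_share = sum(per_gene[g] for g in ranked[:k]) / total_noncausal
    else:
        top_share = 0.0

    multihit_pairs = sum(1 for c in matrix.cells.values() if c.n_variants >= 2)
    multihit_variants = sum(
        c.n_variants for c in matrix.cells.values() if c.n_variants >= 2
    )
    return LandscapeStats(
        per_sample_counts=per_sample,
        range=(min(counts), max(counts)),
        mean_per_sample=sum(counts) / len(counts),
        per_gene_totals=per_gene,
        top_decile_share=top_share,
        multihit_pairs=multihit_pairs,
        multihit_variants=multihit_variants,
        n_causal=n_causal,
        total_variants=matrix.total_variants,
    )


def export_landscape(matrix: LandscapeMatrix) -> tuple[str, str]:
    """Long-form TSV (one row per non-empty cell) and wide matrix TSV.

    Both are byte-deterministic for a given matrix.
    """
    long_lines = ["gene\tsample\tcondition\tdisplay_class\tn_variants\tcausal_present"]
    for gene in matrix.genes:
        for sample in matrix.samples:
            cell = matrix.cells.get((gene, sample))
            if cell is None:
                continue
            long_lines.append(
                f"{gene}\t{sample}\t{matrix.conditions.get(sample, 'unknown')}\t"
                f"{cell.display_class}\t{cell.n_variants}\t{int(cell.causal_present)}"
            )
    wide_lines = ["gene\t" + "\t".join(matrix.samples)]
    for gene in matrix.genes:
        row = [gene]
        for sample in matrix.samples:
            cell = matrix.cells.get((gene, sample))
            row.append(cell.display_class if cell else ".")
        wide_lines.append("\t".join(row))
    return "\n".join(long_lines) + "\n", "\n".join(wide_lines) + "\n"
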