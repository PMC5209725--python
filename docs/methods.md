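# Methods

This note documents the models, conventions and numerical choices behind
hcpanel, and what the synthetic-data generator does and does not emulate.

## Panel model and coordinates

All intervals are 0-based half-open internally (BED convention); 1-based
coordinates appear only when variants are ingested (VCF convention). An
ROI is a coding exon padded into the flanking introns: 35 bases on the
splice-acceptor side and 20 on the donor side, interpreted in
*transcription orientation*, so the genomic sides swap on minus-strand
genes. The orientation convention is a package decision — the padding
widths alone do not determine strandedness — and `pad_exons` therefore
also offers a strand-agnostic (genomic left/right) mode. Overlapping
isoform exons of one gene are unioned per gene for coverage and CNV work
(`merge_rois`); after merging, exon ordinals are renumbered consecutively
along the transcription direction.

## Coverage metrics

C30 and uniformity are computed over the *distinct* genomic bases of the
panel: a base shared by ROIs of two genes counts once in the global
metrics, but gap reporting is per-ROI, because the Sanger-fallback action
is taken per exon of an analysed gene. The uniformity window
[(1−w)·μ, (1+w)·μ] is inclusive at both endpoints and uses the unrounded
floating-point mean; there is no defensible rounding rule to inherit, and
inclusive endpoints make results reproducible across platforms. Positions
absent from a depth file are depth 0; unknown chromosomes are skipped with
a warning rather than an error, since depth files routinely carry
off-panel contigs.

The gap (Sanger-fallback) rule is strict by design: one base below the
threshold flags the whole ROI. With default simulator settings this fires
occasionally even at C30 ≈ 100%, which is the intended behaviour of a
diagnostic contract, not a bug.

## CNV calling

The caller assumes events are rare in a batch, exon means are
multiplicatively perturbed, and at least two (in practice ≥ 8) samples
are co-processed.

Normalization is two-step: per-sample median scaling (removes library
size), then division by an across-sample per-exon reference. The
reference is the **leave-one-out median** by default: in a 16-sample batch
a whole-gene deletion contributes 1/16 of the reference under a plain
mean/median and shifts its own expected ratio; excluding the tested
sample removes that contamination entirely. An `all_median` mode is
provided and agrees with leave-one-out on clean batches (tested). The
median was chosen over the mean throughout for robustness to single
outlier samples.

Parameters, defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| `het_del_max` | 0.65 | midpoint of expected ratios 0.5/1.0 (0.75) pulled toward 0.5 as a guard band |
| `hom_del_max` | 0.25 | well below 0.5, above the 2⁻⁸ log floor |
| `dup_min` | 1.35 | toward 1.5 from the 1.0/1.5 midpoint (1.25) |
| `max_mad` | 0.15 | MAD of log₂ ratios; passes clean batches (MAD ≈ 0.07 at 5% exon noise), rejects samples with log₂ scatter ≳ N(0, 0.25) |
| log₂ floor | 2⁻⁸ | keeps zero-depth cells finite without dominating MAD |

Threshold comparisons are inclusive on the event side (ratio = 0.65 is a
het deletion). Exons whose across-sample reference is zero are masked and
reported as uncallable: zero depth everywhere is capture dropout, not
biology. A zero-depth exon in a *single* passing sample, by contrast,
yields ratio ≈ 0 and is called as a homozygous-deletion candidate; if it
is a single-exon event it carries `confidence = low`, which is the
package's one-size flag for single-exon calls. (An alternative — suppress
single-exon zero calls entirely unless two consecutive exons are zero —
was considered and rejected: it hides true single-exon homozygous
deletions, and the low-confidence flag already routes such calls to
orthogonal confirmation.)

Event merging joins maximal runs of same-state consecutive exons within
one gene. For recovery benchmarking (`evaluate_recovery`) a truth event is
recovered when a call matches its sample, gene and state with an
*overlapping* exon span: with per-exon capture noise, an edge exon of a
multi-exon event can individually miss a ratio threshold without the event
being missed, and overlap matching is the standard event-level convention
in read-depth CNV benchmarking.

## Variant pipeline

Filters are pure predicates and therefore commute; each removal is logged
with the rule that removed it (audit contract). Boundary conventions:
keep-side comparisons are inclusive (VAF = 0.10 is kept), except the MAF
cutoff which is strict (< 1%), because "below 1%" defines rarity.
Variants with no population-frequency record are kept: absence of a
database record cannot make a variant common, and novel variants are
exactly the interesting ones.

Missing predictor verdicts count toward neither consensus threshold. The
two policies are deliberately asymmetric and can disagree (2 damaging /
3 neutral is "possibly damaging" for display, "not deleterious" for
reporting); both are exposed because they serve different steps of the
workflow, and neither is asserted as the single correct rule.

Severity order for "most damaging variant per cell":
cnv > nonsense > frameshift > splicing > missense (possibly damaging) >
missense (neutral) > synonymous > other. Placing CNV at the top is a
package convention (a structural event is at least as disruptive as a
nonsense change); ties break by smaller genomic position for determinism.

Indel identity across files uses left-alignment against the reference
sequence with prefix/suffix trimming; without a reference only trimming is
applied. Reference-allele mismatches at ingestion are hard errors.

## Validation statistics

Clopper–Pearson intervals use the Beta-quantile closed form via
`scipy.stats.beta.ppf`; the degenerate endpoints (x = 0, x = n) use their
closed forms exactly. Report output rounds percentages to one decimal;
full precision is retained internally. Replicate concordance divides the
common variants by the **union** of the two runs' sets — the only reading
of "common / total identified" that is ≤ 1 for asymmetric runs; this is an
interpretation, recorded as such.

## Landscape

Gene ordering excludes causal (disease-causing) mutations from the totals,
so the background variation drives the picture; sample ordering groups by
clinical condition, then descending total count. The summary statistics
count the *non-causal* burden per sample (causal mutations are tallied
separately): the per-individual burden of coexisting variation is the
quantity of interest, and every sample in a diagnostic cohort carries its
causal mutation by construction. Matrix cell counts include causal
variants, and the exported totals reconcile exactly (tested). The top
decile is ⌈0.10 · n⌉ of the genes with ≥ 1 non-causal variant (ceiling
chosen so a 1–10-gene landscape still has a non-empty top decile); gene
ties break alphabetically. Multi-hit tallies count every variant in cells
holding ≥ 2.

## Synthetic-data generator

The generator reproduces the *statistical regime* of a capture-panel
diagnostic batch, not any real dataset. Per-base depth is negative
binomial with mean

    mean_depth · library_scale(s) · gc_factor(e) · exon_effect(e,s) · falloff(b)

- `library_scale` ~ log-normal(σ = 0.15): per-sample yield; removed by
  step-1 normalization, so it must not affect calls (tested).
- `gc_factor` = exp(−3 · (GC − 0.45)²): hybridization capture loses depth
  at both GC extremes; a smooth symmetric penalty is the simplest shape
  with that property.
- `exon_effect` ~ log-normal(σ = 0.05) **per exon and sample**: capture
  efficiency noise that does *not* cancel in the across-sample reference;
  this is what makes CNV recovery a non-trivial test.
- `falloff` ramps linearly from 0.3 at the outer edge of each intronic
  flank to 1.0 at the exon boundary, emulating the depth decay across
  intron/exon boundaries.
- NB dispersion (size) 10 at mean 400 gives per-base SD ≈ 130, in the
  regime of real capture data.

Defaults (12 genes, 2–12 exons of log-normal length ≈ 150 bp, 16 samples,
mean depth 400) land at C30 ≈ 0.98–1.00 — a deliberately well-behaved
batch, matching a passing diagnostic run.

CNV spike-ins scale observed counts by binomial thinning (factor ≤ 1) or
boosting (adding Binomial(depth, f−1) for factor f > 1): the expected
depth scales by exactly the event factor while integer counting noise is
preserved, without re-running the full depth model.

The variant generator gives each sample a truncated-Poisson(5) burden on
[1, 9] of rare variants (gene choice proportional to target size; classes
≈ 50% missense, 25% synonymous, 10% splicing, 8% frameshift, 7%
nonsense), exactly one causal mutation in a condition-linked gene, and
decoy variants that each filter must remove: common variants with MAF
drawn log-uniformly on [0.01, 0.05], deep-intronic variants 50–200 bp
past an ROI, and low-quality calls with VAF below the caller's locked
threshold. Burden-variant MAFs are drawn strictly below the 1% cutoff
(30% have no database record at all): the burden *is defined as* the rare
variation, so rarity is built in rather than left to chance — otherwise
the rarity filter would remove a random share of the burden and the
recovered mean would not be interpretable. Predictor verdicts are drawn
from a latent damaging/benign state per variant with 10% missingness and
15% predictor disagreement.

What the generator does **not** emulate: alignment and calling artifacts
(homopolymer errors, mapping ambiguity in segmental duplications — the
classic PMS2 problem), pseudogene interference, batch effects between
runs, correlated GC waves along chromosomes, and real gene-level variation
hotspots. Consequently, passing recovery tests demonstrates the
correctness and calibration of the algorithms under their stated noise
model, not clinical performance; the uniformity of real capture data
(≈ 0.31) is also not reproduced, since the simulated depth distribution is
narrower than real bait-efficiency spread. Cohort-level published figures
that depend on unpublished sequencing data are out of reach by
construction and are covered instead by property tests at matched
parameter regimes.

## Problem sizes and determinism

Recovery suites run 20 seeded batches of 16 samples (CNV) and 20 cohorts
of 60 samples (landscape burden); oracle-equivalence suites use 100
random profiles and the full 3⁵ predictor-verdict space. These sizes give
stable statistics (burden grand-mean SE ≈ 0.065) while keeping the whole
suite in tens of seconds. All randomness flows from a single integer seed
through per-stage `numpy` Generator streams, so one seed reproduces every
output byte-identically; run manifests carry a wall-clock timestamp and
are excluded from byte-level comparisons.
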