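import itertools

import pytest

from hcpanel import (
    AnnotatedVariant,
    ClinicalGeneSet,
    FilterAudit,
    FilterConfig,
    VariantSupport,
    consensus_prediction,
    filter_by_geneset,
    filter_by_region,
    ingest_variants,
    most_damaging,
    normalize_variant,
    quality_flags,
    rare_filter,
    sanity_filter,
    variants_to_tsv,
)
from hcpanel.variants import PREDICTORS, QualityFlagConfig, display_class


def make_variant(**kw):
    defaults = dict(
        sample="S1",
        gene="BRCA1",
        chrom="chr17",
        pos=150,
        ref="A",
        alt="G",
        consequence="missense",
        support=VariantSupport(
            depth=100, alt_reads=48, vaf=0.48, mean_alt_base_quality=35.0,
            strand_alt_fwd=24, strand_alt_rev=24, mean_mismatches_alt=0.5,
            read_position_sd=60.0,
        ),
    )
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


class TestNormalizeVariant:
    REF = "GGGCACACACACTAGTCGATCGATCGATCG"  # CA repeat from position 4 (1-based)

    def test_snv_untouched(self):
        assert normalize_variant(10, "A", "G", self.REF) == (10, "A", "G")

    def test_prefix_suffix_trimming_without_reference(self):
        assert normalize_variant(10, "CAG", "CTG", None) == (11, "A", "T")

    def test_left_aligns_repeat_deletion(self):
        # a dinucleotide deletion anywhere in the CA tract canonicalises to
        # the leftmost anchored representation
        assert normalize_variant(8, "CAC", "C", self.REF) == (3, "GCA", "G")

    def test_exhaustive_shift_oracle(self):
        """Every right-shifted representation of a CA deletion in the repeat
        tract normalizes to the identical canonical form."""
        canonical = normalize_variant(4, "CAC", "C", self.REF)
        # representations anchored at successive positions in the tract
        for anchor in range(4, 10, 2):
            ref = self.REF[anchor - 1 : anchor + 2]
            rep = normalize_variant(anchor, ref, ref[0], self.REF)
            assert rep == canonical

    def test_insertion_left_aligned(self):
        a = normalize_variant(8, "C", "CAC", self.REF)
        b = normalize_variant(6, "C", "CAC", self.REF)
        assert a == b == (3, "G", "GCA")

    def test_empty_allele_rejected(self):
        with pytest.raises(ValueError):
            normalize_variant(5, "", "A", self.REF)


class TestSanityFilter:
    def test_clean_variant_kept(self):
        assert sanity_filter([make_variant()]) == [make_variant()]

    @pytest.mark.parametrize(
        "support,rule",
        [
            (dict(depth=9, alt_reads=4, vaf=0.44, mean_alt_base_quality=30.0), "depth"),
            (dict(depth=100, alt_reads=1, vaf=0.01, mean_alt_base_quality=30.0), "alt_reads"),
            (dict(depth=100, alt_reads=40, vaf=0.4, mean_alt_base_quality=14.0), "avg_qual"),
            (dict(depth=100, alt_reads=5, vaf=0.05, mean_alt_base_quality=30.0), "vaf"),
        ],
    )
    def test_each_threshold_removes_and_is_audited(self, support, rule):
        v = make_variant(support=VariantSupport(**support))
        audit = FilterAudit()
        assert sanity_filter([v], audit=audit) == []
        assert len(audit.removed) == 1
        assert rule in audit.removed[0][1]

    def test_boundaries_inclusive_on_keep_side(self):
        v = make_variant(
            support=VariantSupport(depth=10, alt_reads=2, vaf=0.10,
                                   mean_alt_base_quality=15.0, strand_alt_fwd=1,
                                   strand_alt_rev=1)
        )
        assert sanity_filter([v]) == [v]

    def test_missing_support_kept_and_flagged(self):
        v = make_variant(support=None)
        audit = FilterAudit()
        assert sanity_filter([v], audit=audit) == [v]
        assert audit.flags and "missing_support" in audit.flags[0][1]


class TestGeneRegionRareFilters:
    def test_geneset_filter(self, tiny_geneset):
        vs = [make_variant(), make_variant(gene="MLH1", chrom="chr3", pos=1050)]
        audit = FilterAudit()
        kept = filter_by_geneset(vs, tiny_geneset, audit)
        assert [v.gene for v in kept] == ["BRCA1"]
        assert audit.removed[0][1].startswith("geneset")

    def test_region_filter_half_open_convention(self, tiny_panel):
        at_start = make_variant(pos=101)   # 0-based 100 = ROI start, kept
        at_end = make_variant(pos=201)     # 0-based 200 = ROI end, removed
        deep = make_variant(pos=260)       # 50+ bp past the ROI, removed
        kept = filter_by_region([at_start, at_end, deep], tiny_panel)
        assert kept == [at_start]

    @pytest.mark.parametrize(
        "maf,kept",
        [
            ({"EUR": 0.005, "AFR": 0.02}, False),  # one population common
            ({}, True),                            # novel: absence is rare
            ({"EUR": 0.009, "AFR": 0.009}, True),  # strictly below cutoff
            ({"EUR": 0.01}, False),                # boundary is strict
        ],
    )
    def test_rare_filter(self, maf, kept):
        v = make_variant(maf=maf)
        assert (rare_filter([v]) == [v]) is kept

    def test_filters_commute(self, tiny_panel, tiny_geneset):
        vs = [
            make_variant(pos=150),
            make_variant(pos=550, maf={"EUR": 0.05}),
            make_variant(gene="MLH1", chrom="chr3", pos=1050),
            make_variant(pos=300),  # outside ROIs
        ]
        orders = [
            lambda x: rare_filter(filter_by_region(filter_by_geneset(x, tiny_geneset), tiny_panel)),
            lambda x: filter_by_geneset(filter_by_region(rare_filter(x), tiny_panel), tiny_geneset),
            lambda x: filter_by_region(rare_filter(filter_by_geneset(x, tiny_geneset)), tiny_panel),
        ]
        results = [f(list(vs)) for f in orders]
        assert results[0] == results[1] == results[2]


def oracle_consensus(preds, policy):
    """Brute-force re-statement of the two consensus rules."""
    n_neutral = sum(1 for p in PREDICTORS if preds.get(p) == "neutral")
    n_damaging = sum(1 for p in PREDICTORS if preds.get(p) == "damaging")
    if policy == "landscape":
        return "neutral" if n_neutral > 3 else "possibly_damaging"
    return "deleterious" if n_damaging >= 3 else "not_deleterious"


class TestConsensus:
    def test_all_neutral(self):
        preds = {p: "neutral" for p in PREDICTORS}
        assert consensus_prediction(preds, "landscape").label == "neutral"
        assert consensus_prediction(preds, "report").label == "not_deleterious"

    def test_four_neutral_one_damaging_is_neutral(self):
        preds = {p: "neutral" for p in PREDICTORS}
        preds["SIFT"] = "damaging"
        assert consensus_prediction(preds, "landscape").label == "neutral"

    def test_policies_disagree_at_three_neutral_two_damaging(self):
        preds = dict(zip(PREDICTORS, ["neutral"] * 3 + ["damaging"] * 2))
        assert consensus_prediction(preds, "landscape").label == "possibly_damaging"
        assert consensus_prediction(preds, "report").label == "not_deleterious"

    def test_matches_oracle_on_all_243_assignments(self):
        for combo in itertools.product(("damaging", "neutral", "missing"), repeat=5):
            preds = dict(zip(PREDICTORS, combo))
            for policy in ("landscape", "report"):
                verdict = consensus_prediction(preds, policy)
                assert verdict.label == oracle_consensus(preds, policy), combo
                assert verdict.n_neutral + verdict.n_damaging + verdict.n_missing == 5


class TestMostDamaging:
    def test_nonsense_beats_synonymous(self):
        a = make_variant(consequence="synonymous", pos=10)
        b = make_variant(consequence="nonsense", pos=20)
        assert most_damaging([a, b]) is b

    def test_possibly_damaging_missense_beats_neutral_missense(self):
        neutral = make_variant(pos=10, predictions={p: "neutral" for p in PREDICTORS})
        damaging = make_variant(pos=20, predictions={p: "damaging" for p in PREDICTORS})
        assert most_damaging([neutral, damaging]) is damaging
        assert display_class(damaging) == "missense_possibly_damaging"

    def test_frameshift_beats_splicing(self):
        fs = make_variant(consequence="frameshift", ref="AT", alt="A")
        sp = make_variant(consequence="splicing", pos=99)
        assert most_damaging([sp, fs]) is fs

    def test_invariant_to_input_order(self):
        vs = [
            make_variant(consequence="synonymous", pos=5),
            make_variant(consequence="nonsense", pos=9),
            make_variant(consequence="splicing", pos=7),
        ]
        for perm in itertools.permutations(vs):
            assert most_damaging(list(perm)).consequence == "nonsense"

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            most_damaging([])


class TestQualityFlags:
    def test_clean_het_snv_has_no_flags(self):
        assert quality_flags(make_variant()) == set()

    def test_low_vaf(self):
        v = make_variant(
            support=VariantSupport(depth=100, alt_reads=12, vaf=0.12,
                                   mean_alt_base_quality=35.0, strand_alt_fwd=6,
                                   strand_alt_rev=6, read_position_sd=60.0)
        )
        assert quality_flags(v) == {"low_vaf"}

    def test_strand_bias_needs_enough_alt_reads(self):
        one_sided = VariantSupport(depth=100, alt_reads=12, vaf=0.4,
                                   mean_alt_base_quality=35.0, strand_alt_fwd=12,
                                   strand_alt_rev=0, read_position_sd=60.0)
        assert "strand_bias" in quality_flags(make_variant(support=one_sided))
        few = VariantSupport(depth=100, alt_reads=3, vaf=0.4,
                             mean_alt_base_quality=35.0, strand_alt_fwd=3,
                             strand_alt_rev=0, read_position_sd=60.0)
        assert "strand_bias" not in quality_flags(make_variant(support=few))

    def test_positional_clustering(self):
        v = make_variant(
            support=VariantSupport(depth=100, alt_reads=40, vaf=0.4,
                                   mean_alt_base_quality=35.0, strand_alt_fwd=20,
                                   strand_alt_rev=20, read_position_sd=5.0)
        )
        assert "positional_clustering" in quality_flags(v)
        cfg = QualityFlagConfig(positional_clustering_sd_fraction=0.01)
        assert "positional_clustering" not in quality_flags(v, cfg)


class TestIngestRoundtrip:
    def test_tsv_roundtrip_preserves_variants(self, tmp_path):
        vs = [
            make_variant(),
            make_variant(pos=550, consequence="nonsense", maf={"EUR": 0.002},
                         predictions={"SIFT": "damaging"}),
            make_variant(gene="MLH1", chrom="chr3", pos=1050, causal=True),
        ]
        path = tmp_path / "v.tsv"
        path.write_text(variants_to_tsv(vs))
        back = ingest_variants(path)
        assert [v.key for v in back] == [v.key for v in vs]
        assert back[1].predictions.get("SIFT") == "damaging"
        assert back[1].predictions.get("PROVEAN", "missing") == "missing"
        assert back[2].causal

    def test_missing_predictor_column_reads_as_missing(self, tmp_path):
        v = make_variant(predictions={})
        path = tmp_path / "v.tsv"
        path.write_text(variants_to_tsv([v]))
        (back,) = ingest_variants(path)
        verdict = consensus_prediction(back, "landscape")
        assert verdict.n_missing == 5

    def test_reference_mismatch_is_an_error(self, tmp_path):
        v = make_variant(pos=3, ref="T", alt="G")
        path = tmp_path / "v.tsv"
        path.write_text(variants_to_tsv([v]))
        with pytest.raises(ValueError, match="record 1"):
            ingest_variants(path, ref_seqs={"chr17": "AAAAAAAA"})

    def test_vcf_ingestion(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="c">\n'
            '##INFO=<ID=MAF_EUR,Number=1,Type=Float,Description="f">\n'
            '##INFO=<ID=PRED_SIFT,Number=1,Type=String,Description="p">\n'
            "##contig=<ID=chr17>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr17\t150\t.\tA\tG\t.\t.\tGENE=BRCA1;CSQ_CLASS=missense;"
            "MAF_EUR=0.004;PRED_SIFT=damaging\n"
        )
        (v,) = ingest_variants(vcf, sample="S1")
        assert (v.chrom, v.pos, v.ref, v.alt) == ("chr17", 150, "A", "G")
        assert v.gene == "BRCA1"
        assert v.maf["EUR"] == pytest.approx(0.004)
        assert v.predictions["SIFT"] == "damaging"
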