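import numpy as np
import pytest

from hcpanel import (
    CoverageMatrix,
    DepthProfile,
    GenomicInterval,
    Panel,
    Roi,
    SimulationConfig,
    build_matrix,
    call_cnvs,
    call_exons,
    default_cnv_events,
    evaluate_recovery,
    merge_calls,
    normalize,
    qc_samples,
    simulate_coverage,
    simulate_panel,
    spike_cnv,
)


def flat_matrix(n_exons=20, n_samples=8, depth=100.0, gene="G"):
    rois = [
        Roi(gene, i + 1, GenomicInterval("chr1", 1000 * i, 1000 * i + 200), "+")
        for i in range(n_exons)
    ]
    return CoverageMatrix(
        exons=rois,
        samples=[f"S{j}" for j in range(n_samples)],
        depth=np.full((n_exons, n_samples), depth),
    )


class TestBuildMatrix:
    def test_constant_profiles(self, tiny_panel):
        profs = [DepthProfile.constant(tiny_panel, f"S{i}", 100) for i in range(3)]
        m = build_matrix(profs, tiny_panel)
        assert (m.depth == 100).all()

    def test_exon_mean_is_arithmetic_mean(self):
        panel = Panel("p", [Roi("G", 1, GenomicInterval("chr1", 0, 3), "+")])
        p1 = DepthProfile("a", panel, [np.array([10, 20, 30])])
        p2 = DepthProfile("b", panel, [np.array([0, 0, 0])])
        m = build_matrix([p1, p2], panel)
        assert m.depth[0, 0] == pytest.approx(20.0)
        assert m.depth[0, 1] == 0.0

    def test_single_sample_rejected(self, tiny_panel):
        with pytest.raises(ValueError, match="2 samples"):
            build_matrix([DepthProfile.constant(tiny_panel, "S0", 10)], tiny_panel)


class TestNormalize:
    def test_identical_samples_give_unit_ratios(self):
        r = normalize(flat_matrix())
        assert r.ratio == pytest.approx(np.ones_like(r.ratio))
        assert r.log2_ratio == pytest.approx(np.zeros_like(r.log2_ratio))

    def test_library_size_scaling_is_removed(self):
        m = flat_matrix()
        m.depth[:, 3] *= 0.5  # one shallow library
        r = normalize(m)
        assert r.ratio[:, 3] == pytest.approx(np.ones(m.depth.shape[0]))

    def test_spiked_gene_recovered_at_half_ratio(self):
        # 16 flat samples, one with a 4-exon region at half depth
        m = flat_matrix(n_exons=24, n_samples=16)
        m.depth[4:8, 0] *= 0.5
        r = normalize(m)
        assert r.ratio[4:8, 0] == pytest.approx(0.5, abs=0.05)
        neutral = np.delete(r.ratio, [4, 5, 6, 7], axis=0)
        assert neutral == pytest.approx(1.0, abs=0.05)

    def test_zero_reference_exon_is_masked(self):
        m = flat_matrix(n_exons=6, n_samples=6)
        m.depth[2, :] = 0.0
        with pytest.warns(UserWarning, match="masked"):
            r = normalize(m)
        assert r.masked[2]
        assert not r.masked[[0, 1, 3, 4, 5]].any()
        assert np.isnan(r.ratio[2]).all()

    def test_zero_median_sample_is_an_error(self):
        m = flat_matrix(n_exons=6, n_samples=4)
        m.depth[:, 1] = 0.0
        with pytest.raises(ValueError, match="S1"):
            normalize(m)

    def test_loo_and_all_median_agree_on_clean_batches(self):
        m = flat_matrix(n_exons=12, n_samples=10)
        m.depth[0:3, 2] *= 0.5
        calls_loo, _ = call_cnvs(m, reference="loo_median")
        calls_all, _ = call_cnvs(m, reference="all_median")
        assert {(c.sample, c.gene, c.exon_span, c.state) for c in calls_loo} == {
            (c.sample, c.gene, c.exon_span, c.state) for c in calls_all
        }


class TestSampleQc:
    def test_noise_free_cohort_passes_with_zero_dispersion(self):
        qc = qc_samples(normalize(flat_matrix()))
        assert all(q.passed for q in qc)
        assert all(q.dispersion == pytest.approx(0.0) for q in qc)

    def test_overdispersed_sample_fails(self):
        # log2 ratios ~ Normal(0, 0.5): MAD ~= 0.674 * 0.5 = 0.34 > 0.15
        rng = np.random.default_rng(5)
        m = flat_matrix(n_exons=200, n_samples=8)
        m.depth[:, 0] *= 2 ** rng.normal(0.0, 0.5, size=200)
        qc = qc_samples(normalize(m))
        assert not qc[0].passed
        assert qc[0].dispersion == pytest.approx(0.34, abs=0.08)
        assert all(q.passed for q in qc[1:])

    def test_failed_sample_produces_no_calls(self):
        rng = np.random.default_rng(5)
        m = flat_matrix(n_exons=200, n_samples=8)
        m.depth[:, 0] *= 2 ** rng.normal(0.0, 0.5, size=200)
        calls, qc = call_cnvs(m)
        assert not qc[0].passed
        assert all(c.sample != "S0" for c in calls)


class TestCallExons:
    @pytest.mark.parametrize(
        "ratio,state",
        [
            (1.0, "neutral"),
            (0.5, "het_del"),
            (0.0, "hom_del"),
            (1.5, "dup"),
            (0.65, "het_del"),  # inclusive bound
            (0.25, "hom_del"),
            (1.35, "dup"),
            (0.66, "neutral"),
            (1.34, "neutral"),
        ],
    )
    def test_threshold_application(self, ratio, state):
        m = flat_matrix(n_exons=4, n_samples=6)
        m.depth[1, 0] *= ratio
        r = normalize(m)
        r.ratio[1, 0] = ratio  # exact boundary value under test
        states = call_exons(r, qc=None)
        assert states[1, 0] == state


class TestMergeCalls:
    def _states_for(self, m, pattern):
        r = normalize(m)
        states = np.full(r.ratio.shape, "neutral", dtype=object)
        for (i, j), st in pattern.items():
            states[i, j] = st
        return states, r

    def test_adjacent_same_state_exons_merge(self):
        m = flat_matrix(n_exons=6, n_samples=4)
        states, r = self._states_for(m, {(1, 0): "het_del", (2, 0): "het_del"})
        calls = merge_calls(states, r)
        assert len(calls) == 1
        c = calls[0]
        assert (c.exon_first, c.exon_last, c.n_exons) == (2, 3, 2)
        assert c.confidence == "high"
        assert not c.whole_gene

    def test_whole_gene_flag(self):
        m = flat_matrix(n_exons=5, n_samples=4)
        states, r = self._states_for(m, {(i, 1): "het_del" for i in range(5)})
        calls = merge_calls(states, r)
        assert len(calls) == 1
        assert calls[0].whole_gene
        assert calls[0].n_exons == 5

    def test_single_exon_event_low_confidence(self):
        m = flat_matrix(n_exons=5, n_samples=4)
        states, r = self._states_for(m, {(2, 0): "dup"})
        calls = merge_calls(states, r)
        assert len(calls) == 1
        assert calls[0].n_exons == 1
        assert calls[0].confidence == "low"

    def test_runs_do_not_cross_gene_boundaries(self):
        rois = [
            Roi("A", 1, GenomicInterval("chr1", 0, 100), "+"),
            Roi("A", 2, GenomicInterval("chr1", 200, 300), "+"),
            Roi("B", 1, GenomicInterval("chr1", 400, 500), "+"),
        ]
        m = CoverageMatrix(rois, ["S0", "S1", "S2"], np.full((3, 3), 100.0))
        r = normalize(m)
        states = np.full((3, 3), "neutral", dtype=object)
        states[1, 0] = states[2, 0] = "het_del"
        calls = merge_calls(states, r)
        assert {(c.gene, c.n_exons) for c in calls} == {("A", 1), ("B", 1)}


class TestProperties:
    def test_scaling_one_sample_changes_no_calls(self, sim_config):
        panel = simulate_panel(sim_config)
        profiles = simulate_coverage(panel, sim_config)
        events = default_cnv_events(panel, sim_config)
        profiles, _ = spike_cnv(profiles, events, seed=sim_config.seed)
        base = build_matrix(profiles, panel)
        calls0, _ = call_cnvs(base)
        for c in (0.5, 2.0):
            m = CoverageMatrix(base.exons, base.samples, base.depth.copy())
            m.depth[:, 5] *= c
            calls, _ = call_cnvs(m)
            assert {
                (x.sample, x.gene, x.exon_span, x.state) for x in calls
            } == {(x.sample, x.gene, x.exon_span, x.state) for x in calls0}

    def test_permuting_samples_permutes_calls(self, sim_config):
        panel = simulate_panel(sim_config)
        profiles = simulate_coverage(panel, sim_config)
        events = default_cnv_events(panel, sim_config)
        profiles, _ = spike_cnv(profiles, events, seed=sim_config.seed)
        m = build_matrix(profiles, panel)
        perm = np.random.default_rng(0).permutation(len(m.samples))
        mp = CoverageMatrix(m.exons, [m.samples[j] for j in perm], m.depth[:, perm])
        calls, _ = call_cnvs(m)
        calls_p, _ = call_cnvs(mp)
        key = lambda c: (c.sample, c.gene, c.exon_span, c.state)
        assert sorted(map(key, calls)) == sorted(map(key, calls_p))

    def test_recovery_on_simulated_batches(self):
        """Whole-gene del, two-exon del and three-exon dup are recovered with
        no false positives across seeded 16-sample batches."""
        n_truth = n_rec = n_fp = 0
        for seed in range(5):
            cfg = SimulationConfig(seed=seed)
            panel = simulate_panel(cfg)
            profiles = simulate_coverage(panel, cfg)
            events = default_cnv_events(panel, cfg)
            profiles, truth = spike_cnv(profiles, events, seed=seed)
            calls, _ = call_cnvs(build_matrix(profiles, panel))
            t, r, f = evaluate_recovery(truth.cnv_truth, calls)
            n_truth += t
            n_rec += r
            n_fp += f
        assert n_rec == n_truth
        assert n_fp == 0
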