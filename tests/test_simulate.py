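"""Fragmentation simulator: determinism, conservation, and bias injection."""

import numpy as np
import pytest
from scipy import stats

from covbias.hunc import HuncConfig, call_hunc_regions, score_series
from covbias.simulate import (
    SimConfig,
    expected_interior_depth,
    generate_transcriptome,
    inject_anomalies,
    make_synthetic_rrna,
    simulate_dilution_experiment,
    simulate_fragment_coverage,
    simulate_library_panel,
)


def small_cfg(**kw):
    defaults = dict(
        n_transcripts=20, length_range=(700, 1500), n_fragments=30_000, seed=0
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenerateTranscriptome:
    def test_same_seed_identical_outputs(self):
        cfg = small_cfg(seed=9)
        m1, s1, t1 = generate_transcriptome(cfg)
        m2, s2, t2 = generate_transcriptome(cfg)
        assert s1 == s2
        assert {t: m.exons for t, m in m1.items()} == {
            t: m.exons for t, m in m2.items()
        }
        assert t1.weights == t2.weights

    def test_gc_extremes(self):
        _, seqs, _ = generate_transcriptome(small_cfg(gc_target=1.0))
        assert all(set(s) <= {"G", "C"} for s in seqs.values())
        _, seqs, _ = generate_transcriptome(small_cfg(gc_target=0.0))
        assert all(set(s) <= {"A", "T"} for s in seqs.values())

    def test_gc_half_within_binomial_error(self):
        cfg = small_cfg(n_transcripts=2, length_range=(10_000, 10_001), seed=3)
        _, seqs, _ = generate_transcriptome(cfg)
        for seq in seqs.values():
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            assert gc == pytest.approx(0.5, abs=0.02)

    def test_models_non_overlapping_and_zero_transcripts_ok(self):
        from covbias.models import find_overlapping

        models, _, _ = generate_transcriptome(small_cfg())
        assert find_overlapping(models.values()) == set()
        models, seqs, truth = generate_transcriptome(small_cfg(n_transcripts=0))
        assert models == {} and seqs == {} and truth.weights == {}

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(gc_target=1.5)

    def test_low_complexity_segments_recorded(self):
        cfg = small_cfg(low_complexity=3, seed=4)
        _, seqs, truth = generate_transcriptome(cfg)
        assert len(truth.low_complexity) == 3
        for tid, (start, end) in truth.low_complexity.items():
            segment = seqs[tid][start:end]
            assert len(set(segment)) <= 2  # homopolymer or dinucleotide repeat

    def test_rrna_segments_match_reference(self):
        refs = make_synthetic_rrna(5)
        cfg = small_cfg(rrna_insert=4, seed=5)
        _, seqs, truth = generate_transcriptome(cfg, rrna_refs=refs)
        assert len(truth.rrna_segments) == 4
        for tid, (start, end) in truth.rrna_segments.items():
            segment = seqs[tid][start:end]
            assert any(segment in ref for ref in refs.values())


class TestFragmentCoverage:
    def test_fragment_conservation_single_transcript(self):
        cfg = small_cfg(n_transcripts=1, n_fragments=5000)
        models, _, truth = generate_transcriptome(cfg)
        _, table = simulate_fragment_coverage(models, truth.weights, cfg)
        assert table["fragments"].sum() == 5000

    def test_total_fragments_conserved_across_transcripts(self):
        cfg = small_cfg()
        models, _, truth = generate_transcriptome(cfg)
        cov, table = simulate_fragment_coverage(models, truth.weights, cfg)
        assert table["fragments"].sum() == cfg.n_fragments
        # each fragment contributes exactly 2 * read_length depth
        total_depth = sum(c.depths.sum() for c in cov.values())
        assert total_depth == 2 * cfg.read_length * cfg.n_fragments

    def test_interior_depth_matches_closed_form(self):
        """Deep-interior mean depth equals the eligible-start expectation."""
        length, n_frag = 1000, 10_000
        cfg = SimConfig(
            n_transcripts=1, length_range=(length, length + 1),
            n_fragments=n_frag, seed=6,
        )
        models, _, truth = generate_transcriptome(cfg)
        tid = next(iter(models))
        cov, _ = simulate_fragment_coverage(models, truth.weights, cfg)
        interior = cov[tid].depths[400:600].mean()
        expected = expected_interior_depth(cfg, length, n_frag)
        assert interior == pytest.approx(expected, rel=0.05)

    def test_counts_multinomially_consistent_with_weights(self):
        cfg = small_cfg(n_fragments=100_000, seed=7)
        models, _, truth = generate_transcriptome(cfg)
        rng = np.random.default_rng(70)
        weights = {t: float(rng.uniform(0.5, 2.0)) for t in models}
        _, table = simulate_fragment_coverage(models, weights, cfg)
        lengths = np.array([models[t].length for t in table["transcript_id"]])
        w = np.array([weights[t] for t in table["transcript_id"]])
        probs = w * lengths / (w * lengths).sum()
        gof = stats.chisquare(table["fragments"], probs * cfg.n_fragments)
        assert gof.pvalue > 0.001

    def test_zero_weights_with_fragments_errors(self):
        cfg = small_cfg()
        models, _, truth = generate_transcriptome(cfg)
        with pytest.raises(ValueError, match="zero"):
            simulate_fragment_coverage(models, {t: 0.0 for t in models}, cfg)


class TestDilutionExperiment:
    def test_conditions_are_scaled_copies_with_zero_mouse(self):
        cfg = small_cfg(seed=8)
        models, _, truth = generate_transcriptome(cfg)
        rep1, rep2, mouse_fpkm = simulate_dilution_experiment(models, truth, cfg)
        tid = next(iter(models))
        base = rep1.coverage["ivt_only"][tid].depths
        np.testing.assert_allclose(rep1.coverage["1:2"][tid].depths, base / 3)
        assert np.all(rep1.coverage["mouse_only"][tid].depths == 0)
        assert mouse_fpkm[0][tid] == 0.0
        # replicates are independent realizations
        assert not np.array_equal(base, rep2.coverage["ivt_only"][tid].depths)

    def test_null_series_yields_no_hunc_regions(self):
        cfg = small_cfg(length_range=(900, 1600), seed=9)
        models, _, truth = generate_transcriptome(cfg)
        rep1, rep2, mouse_fpkm = simulate_dilution_experiment(models, truth, cfg)
        hcfg = HuncConfig()
        s1, _ = score_series(rep1, hcfg)
        s2, _ = score_series(rep2, hcfg)
        mouse_cov = [
            {t: r.coverage["mouse_only"][t].depths for t in r.transcript_ids}
            for r in (rep1, rep2)
        ]
        result = call_hunc_regions(s1, s2, mouse_fpkm, mouse_cov, hcfg)
        assert result.regions == [] and result.rejected == []

    def test_out_of_bounds_injection_rejected(self):
        from covbias.simulate import HuncInjection

        cfg = small_cfg()
        models, _, truth = generate_transcriptome(cfg)
        tid = next(iter(models))
        truth.hunc_injections.append(
            HuncInjection(tid, 0, models[tid].length + 50, {"1:1": 0.2})
        )
        with pytest.raises(ValueError, match="outside"):
            simulate_dilution_experiment(models, truth, cfg)

    def test_decoy_gets_mouse_background_at_recorded_fpkm(self):
        cfg = small_cfg(n_fragments=100_000, seed=10)
        models, _, truth = generate_transcriptome(cfg)
        decoy = sorted(models)[0]
        truth.decoys[decoy] = 20.0
        rep1, _, mouse_fpkm = simulate_dilution_experiment(models, truth, cfg)
        assert rep1.coverage["mouse_only"][decoy].depths.sum() > 0
        assert mouse_fpkm[0][decoy] == pytest.approx(20.0, rel=0.05)

    def test_injection_pattern_identical_across_replicates(self):
        cfg = small_cfg(length_range=(1300, 2000), seed=11)
        models, _, truth = generate_transcriptome(cfg)
        rng = np.random.default_rng(110)
        (inj,) = inject_anomalies(
            truth, models, rng, 1, hunc_cfg_trims=(100, 300, 250)
        )
        rep1, rep2, _ = simulate_dilution_experiment(models, truth, cfg)
        for rep in (rep1, rep2):
            for cond, factor in inj.amplitudes.items():
                share = truth.mixing_shares[cond]
                if share == 0:
                    continue
                full = rep.coverage["ivt_only"][inj.transcript_id].depths
                got = rep.coverage[cond][inj.transcript_id].depths
                # suppression factor applied exactly once, on top of the share
                ratio = got[inj.start : inj.end].sum() / max(
                    full[inj.start : inj.end].sum(), 1e-12
                )
                expected = share * factor / inj.amplitudes.get("ivt_only", 1.0)
                assert ratio == pytest.approx(expected, rel=1e-9)


class TestLibraryPanel:
    def test_variability_ordering_matches_protocol_roughness(self):
        from covbias.metrics import base_cv

        cfg = small_cfg(n_fragments=150_000, seed=12)
        models, _, truth = generate_transcriptome(cfg)
        panel = simulate_library_panel(models, truth, cfg)
        med_cv = {
            name: float(
                np.median([base_cv(c) for c in cov.values()])
            )
            for name, (cov, _) in panel.items()
        }
        assert (
            med_cv["simulated"]
            < med_cv["plasmid"]
            < med_cv["no_selection"]
            < med_cv["rrna_depleted"]
        )

    def test_polya_library_shows_three_prime_bias(self):
        from covbias.metrics import processivity_ratio

        cfg = small_cfg(n_fragments=150_000, seed=13)
        models, _, truth = generate_transcriptome(cfg)
        panel = simulate_library_panel(models, truth, cfg)
        ratios = [
            processivity_ratio(c, fpkm=1e9)
            for c in panel["polya"][0].values()
        ]
        assert np.median(ratios) > 1.3

    def test_rrna_segments_suppressed_in_depleted_library_only(self):
        cfg = small_cfg(n_fragments=150_000, rrna_insert=5, seed=14)
        refs = make_synthetic_rrna(cfg.seed)
        models, _, truth = generate_transcriptome(cfg, rrna_refs=refs)
        panel = simulate_library_panel(models, truth, cfg)
        dep = panel["rrna_depleted"][0]
        ns = panel["no_selection"][0]
        for tid, (start, end) in truth.rrna_segments.items():
            in_seg = dep[tid].depths[start:end].mean()
            outside = np.delete(dep[tid].depths, slice(start, end)).mean()
            assert in_seg < 0.35 * outside
            ns_in = ns[tid].depths[start:end].mean()
            ns_out = np.delete(ns[tid].depths, slice(start, end)).mean()
            assert ns_in > 0.35 * ns_out
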