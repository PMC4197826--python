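"""Sliding-window MAD scoring and hunc region calling."""

import numpy as np
import pytest
from scipy.stats import median_abs_deviation

from covbias.hunc import (
    HuncConfig,
    HuncRegion,
    WindowScores,
    call_hunc_regions,
    difference_regions,
    mad_constant1,
    score_series,
    windowed_mad_scores,
)
from covbias.models import TranscriptCoverage

from conftest import make_series
from oracles import mad_oracle, windowed_mad_oracle


class TestMadConstant1:
    def test_hand_example(self):
        assert mad_constant1([1, 2, 3, 4, 5]) == 1.0

    def test_constant_vector(self):
        assert mad_constant1([7.0] * 9) == 0.0

    def test_single_value(self):
        assert mad_constant1([3.5]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad_constant1([])

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            values = rng.normal(size=int(rng.integers(1, 40)))
            assert mad_constant1(values) == pytest.approx(
                median_abs_deviation(values, scale=1.0)
            )


class TestWindowedMadScores:
    def test_identical_conditions_score_zero(self):
        rng = np.random.default_rng(11)
        base = rng.gamma(5, 10, 900)
        series = make_series(1, {"T": base}, shares={c: 1.0 for c in (
            "ivt_only", "1:1", "1:2", "1:10", "mouse_only")})
        ws = windowed_mad_scores(series, "T", HuncConfig())
        assert np.all(ws.scores == 0.0)

    def test_scaled_copies_score_zero(self):
        """Proportional conditions carry no across-condition deviation."""
        rng = np.random.default_rng(12)
        base = rng.gamma(5, 10, 900)
        series = make_series(1, {"T": base})
        ws = windowed_mad_scores(series, "T", HuncConfig())
        assert np.all(ws.scores == 0.0)

    def test_too_short_transcript_excluded(self):
        series = make_series(1, {"T": np.ones(600)})
        with pytest.raises(ValueError, match="no scored windows"):
            windowed_mad_scores(series, "T", HuncConfig())
        scores, skipped = score_series(series, HuncConfig())
        assert scores == {} and "T" in skipped

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        """Normalization, per-base MAD, window means and trimming agree with
        a plain-loop recomputation on 100 random condition stacks."""
        rng = np.random.default_rng(13)
        cfg = HuncConfig(window=20, trim_head=5, trim_tail=4, mad_floor=0.0)
        for _ in range(100):
            length = int(rng.integers(40, 140))
            mat = rng.gamma(2.0, 5.0, size=(5, length)).round(3)
            series = make_series(
                1,
                {"T": mat[0]},
                shares={c: 1.0 for c in (
                    "ivt_only", "1:1", "1:2", "1:10", "mouse_only")},
            )
            # overwrite conditions with independent rows
            for row, cond in zip(
                mat, ("ivt_only", "1:1", "1:2", "1:10", "mouse_only")
            ):
                series.coverage[cond]["T"] = TranscriptCoverage("T", row)
            centers, scores = windowed_mad_oracle(
                mat, cfg.window, cfg.trim_head, cfg.trim_tail
            )
            if not centers:
                with pytest.raises(ValueError):
                    windowed_mad_scores(series, "T", cfg)
                continue
            ws = windowed_mad_scores(series, "T", cfg)
            np.testing.assert_array_equal(ws.centers, centers)
            np.testing.assert_allclose(ws.scores, scores, atol=1e-12)

    def test_scores_invariant_to_scaling_one_condition(self):
        rng = np.random.default_rng(14)
        mat = rng.gamma(2.0, 5.0, size=(5, 1000))
        conditions = ("ivt_only", "1:1", "1:2", "1:10", "mouse_only")

        def build(scale_first):
            series = make_series(1, {"T": mat[0]})
            for i, cond in enumerate(conditions):
                row = mat[i] * (scale_first if i == 0 else 1.0)
                series.coverage[cond]["T"] = TranscriptCoverage("T", row)
            return windowed_mad_scores(series, "T", HuncConfig()).scores

        np.testing.assert_allclose(build(1.0), build(37.5), atol=1e-12)


def _inject(series, tid, start, end, factors):
    """Suppress depth over [start, end) in the given conditions."""
    for cond, f in factors.items():
        series.coverage[cond][tid].depths[start:end] *= f


def _mouse_zero(tids):
    return [{t: 0.0 for t in tids}, {t: 0.0 for t in tids}]


def _mouse_cov_from(series_pair):
    return [
        {t: s.coverage["mouse_only"][t].depths for t in s.transcript_ids}
        for s in series_pair
    ]


class TestCallHuncRegions:
    def _scored_pair(self, depth_by_tid, injections=(), seed=0):
        rng = np.random.default_rng(seed)
        pair = []
        for rep in (1, 2):
            base = {
                tid: np.asarray(d, float) * (1 + 0.001 * rng.random(len(d)))
                for tid, d in depth_by_tid.items()
            }
            series = make_series(rep, base)
            for tid, start, end, factors in injections:
                _inject(series, tid, start, end, factors)
            pair.append(series)
        cfg = HuncConfig()
        scores = [score_series(s, cfg)[0] for s in pair]
        return pair, scores, cfg

    def test_no_anomaly_no_regions(self):
        rng = np.random.default_rng(20)
        depth = {f"T{i}": rng.gamma(5, 20, 1500) for i in range(6)}
        pair, (s1, s2), cfg = self._scored_pair(depth)
        result = call_hunc_regions(
            s1, s2, _mouse_zero(depth), _mouse_cov_from(pair), cfg
        )
        assert result.regions == []

    def test_injected_anomaly_recovered_with_overlap(self):
        rng = np.random.default_rng(21)
        depth = {f"T{i}": rng.gamma(5, 20, 1500) for i in range(6)}
        inj = ("T3", 500, 680, {"ivt_only": 0.2, "1:2": 0.3})
        pair, (s1, s2), cfg = self._scored_pair(depth, injections=[inj])
        result = call_hunc_regions(
            s1, s2, _mouse_zero(depth), _mouse_cov_from(pair), cfg
        )
        assert len(result.regions) == 1
        region = result.regions[0]
        assert region.transcript_id == "T3"
        covered = min(region.end, 680) - max(region.start, 500)
        assert covered / 180 >= 0.5
        jaccard = covered / (max(region.end, 680) - min(region.start, 500))
        assert jaccard >= 0.43

    def test_mouse_fpkm_filter_drops_with_provenance(self):
        rng = np.random.default_rng(22)
        depth = {f"T{i}": rng.gamma(5, 20, 1500) for i in range(6)}
        inj = ("T3", 500, 680, {"ivt_only": 0.2, "1:2": 0.3})
        pair, (s1, s2), cfg = self._scored_pair(depth, injections=[inj])
        mouse_fpkm = _mouse_zero(depth)
        mouse_fpkm[1]["T3"] = 20.0  # either replicate triggers the filter
        result = call_hunc_regions(
            s1, s2, mouse_fpkm, _mouse_cov_from(pair), cfg
        )
        assert result.regions == []
        assert [r.status for r in result.rejected] == ["failed:mouse_fpkm"]

    def test_mouse_coverage_filter_checks_flanks(self):
        rng = np.random.default_rng(23)
        depth = {f"T{i}": rng.gamma(5, 20, 1500) for i in range(6)}
        inj = ("T3", 500, 680, {"ivt_only": 0.2, "1:2": 0.3})
        pair, (s1, s2), cfg = self._scored_pair(depth, injections=[inj])
        clean = call_hunc_regions(
            s1, s2, _mouse_zero(depth), _mouse_cov_from(pair), cfg
        )
        assert len(clean.regions) == 1
        region = clean.regions[0]
        # depth 12 only in the 100-bp flank just downstream of the region
        mouse_cov = _mouse_cov_from(pair)
        mouse_cov[0]["T3"] = mouse_cov[0]["T3"].copy()
        mouse_cov[0]["T3"][region.end : region.end + cfg.flank] = 12.0
        result = call_hunc_regions(s1, s2, _mouse_zero(depth), mouse_cov, cfg)
        assert result.regions == []
        assert [r.status for r in result.rejected] == ["failed:mouse_coverage"]

    def test_replicate_intersection_required(self):
        rng = np.random.default_rng(24)
        depth = {f"T{i}": rng.gamma(5, 20, 1500) for i in range(6)}
        inj = ("T3", 500, 680, {"ivt_only": 0.2, "1:2": 0.3})
        pair = []
        for rep in (1, 2):
            series = make_series(rep, {
                tid: d * (1 + 0.001 * rng.random(len(d)))
                for tid, d in depth.items()
            })
            if rep == 1:  # anomaly in replicate 1 only
                _inject(series, *inj[:3], inj[3])
            pair.append(series)
        cfg = HuncConfig()
        s1, _ = score_series(pair[0], cfg)
        s2, _ = score_series(pair[1], cfg)
        result = call_hunc_regions(
            s1, s2, _mouse_zero(depth), _mouse_cov_from(pair), cfg
        )
        assert result.regions == []


class TestDifferenceRegions:
    def _pair_with_rep1_anomaly(self, seed=30):
        rng = np.random.default_rng(seed)
        depth = {f"T{i}": rng.gamma(5, 20, 1500) for i in range(6)}
        pair = []
        for rep in (1, 2):
            series = make_series(rep, {
                tid: d * (1 + 0.001 * rng.random(len(d)))
                for tid, d in depth.items()
            })
            if rep == 1:
                _inject(series, "T2", 500, 680, {"ivt_only": 0.2, "1:2": 0.3})
            pair.append(series)
        cfg = HuncConfig()
        return depth, pair, [score_series(s, cfg)[0] for s in pair], cfg

    def test_identical_replicates_no_regions(self):
        rng = np.random.default_rng(31)
        depth = {f"T{i}": rng.gamma(5, 20, 1500) for i in range(4)}
        series = make_series(1, depth)
        cfg = HuncConfig()
        scores, _ = score_series(series, cfg)
        result = difference_regions(
            scores, scores, [], _mouse_zero(depth), [{}, {}], cfg
        )
        assert result.regions == []

    def test_rep1_only_anomaly_found(self):
        depth, pair, (s1, s2), cfg = self._pair_with_rep1_anomaly()
        result = difference_regions(
            s1, s2, [], _mouse_zero(depth), _mouse_cov_from(pair), cfg
        )
        assert [r.transcript_id for r in result.regions] == ["T2"]
        region = result.regions[0]
        assert region.source == "difference" and not region.replicate_support
        assert min(region.end, 680) - max(region.start, 500) > 0

    def test_exclusion_zone_around_called_hunc(self):
        depth, pair, (s1, s2), cfg = self._pair_with_rep1_anomaly()
        # a hunc called 150 bases downstream of the anomaly span
        hunc = [HuncRegion("T2", 830, 900, mean_mad=0.2)]
        result = difference_regions(
            s1, s2, hunc, _mouse_zero(depth), _mouse_cov_from(pair), cfg
        )
        assert result.regions == []
        assert any(r.status == "failed:near_hunc" for r in result.rejected)
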