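"""Reference study runners: the package's end-to-end validation experiments.

Each function builds its own synthetic inputs from a seed, runs the
relevant pipeline stages, and returns summary numbers. They are shared by
the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .association import pearson_r2, rank_sum_test
from .hunc import HuncConfig, call_hunc_regions, score_series
from .metrics import (
    MetricsConfig,
    base_cv,
    compute_fpkm,
    fold_change_summary,
    processivity_ratio,
    within_transcript_fold_change,
)
from .models import TranscriptModel, filter_transcripts, find_overlapping
from .seqfeat import RRNA_SCORING, coverage_drop_table, rrna_similarity
from .simulate import (
    SimConfig,
    SimTruth,
    generate_transcriptome,
    inject_anomalies,
    make_synthetic_rrna,
    simulate_dilution_experiment,
    simulate_fragment_coverage,
    simulate_library_panel,
)

__all__ = [
    "clone_filter_study",
    "null_coverage_study",
    "hunc_recovery_study",
    "ranksum_calibration_study",
    "rrna_drop_study",
]


def clone_filter_study(
    n_clones: int = 1062, n_multi_locus: int = 11, n_overlapping: int = 88
) -> dict[str, int]:
    """Transcript-filter arithmetic on a synthetic clone pool.

    Builds ``n_clones`` single-exon models of which ``n_overlapping`` lie in
    genuinely overlapping pairs (found by overlap detection) and
    ``n_multi_locus`` carry a multi-locus flag (an explicit removal list, as
    multi-mapping cannot be derived from gene models alone), then applies
    the filter and counts the survivors.
    """
    if n_overlapping % 2:
        raise ValueError("overlapping transcripts come in pairs")
    models: dict[str, TranscriptModel] = {}
    pos = 0
    multi_ids = []
    for i in range(n_clones):
        tid = f"CLONE{i:04d}"
        if i < n_overlapping and i % 2 == 1:
            start = pos - 500  # overlap the previous clone by 500 bases
        else:
            start = pos
        models[tid] = TranscriptModel(tid, "chr1", "+", ((start, start + 1000),))
        pos = start + 1000 + 200
        if n_overlapping <= i < n_overlapping + n_multi_locus:
            multi_ids.append(tid)
    overlapping = find_overlapping(models.values())
    if len(overlapping) != n_overlapping:
        raise RuntimeError("synthetic pool does not reproduce the overlap count")
    retained = filter_transcripts(models, overlapping | set(multi_ids))
    return {
        "total": n_clones,
        "multi_locus": len(multi_ids),
        "overlapping": len(overlapping),
        "retained": len(retained),
    }


def null_coverage_study(
    seed: int,
    n_seeds: int = 10,
    cfg: SimConfig | None = None,
) -> dict:
    """Fold-change and processivity statistics of bias-free simulations.

    For each seed, simulates fragmentation-only coverage (no injected
    bias), computes the within-transcript fold change of every detected
    transcript and summarizes at the (2, 10, 100) thresholds, and computes
    the median 3'/5' processivity ratio. Deviations from uniform coverage
    come only from fragmentation randomness, so the expectation is a
    (0, 0, 0) summary and a median processivity of ~1.
    """
    cfg = cfg or SimConfig()
    mcfg = MetricsConfig()
    summaries = []
    processivity_medians = []
    n_evaluated = 0
    for k in range(n_seeds):
        run_cfg = replace(cfg, seed=int(seed) + k)
        models, _, truth = generate_transcriptome(run_cfg)
        cov, table = simulate_fragment_coverage(models, truth.weights, run_cfg)
        fpkm = {
            row.transcript_id: compute_fpkm(
                row.fragments, models[row.transcript_id].length, run_cfg.n_fragments
            )
            for row in table.itertuples()
        }
        fold_changes = []
        ratios = []
        for tid in sorted(models):
            if fpkm[tid] < mcfg.fpkm_detect_threshold:
                continue
            fc = within_transcript_fold_change(cov[tid], mcfg)
            if not isinstance(fc, str):
                fold_changes.append(fc)
                n_evaluated += 1
            pr = processivity_ratio(cov[tid], fpkm[tid], mcfg)
            if not isinstance(pr, str) and np.isfinite(pr):
                ratios.append(pr)
        summaries.append(fold_change_summary(fold_changes, mcfg.fc_thresholds))
        processivity_medians.append(float(np.median(ratios)))
    totals = tuple(int(sum(s[i] for s in summaries)) for i in range(3))
    return {
        "per_seed_summaries": summaries,
        "total_counts": totals,
        "processivity_medians": processivity_medians,
        "median_processivity": float(np.median(processivity_medians)),
        "n_transcripts_evaluated": n_evaluated,
    }


def _truth_recovered(inj, regions, min_cover: float = 0.5) -> bool:
    width = inj.end - inj.start
    for region in regions:
        if region.transcript_id != inj.transcript_id:
            continue
        overlap = min(region.end, inj.end) - max(region.start, inj.start)
        if overlap / width >= min_cover:
            return True
    return False


def hunc_recovery_study(
    seed: int,
    n_seeds: int = 20,
    n_transcripts: int = 60,
    n_injected: int = 8,
    decoy_fpkm: float = 20.0,
    decoy_local_depth: float = 25.0,
) -> dict:
    """Recovery of planted anomalies by the hunc caller over many seeds.

    Each seed simulates a two-replicate dilution series with
    ``n_injected`` replicate-consistent anomalies (amplitude 3-6x, width
    150-300 bases), one anomaly-bearing decoy with high mouse-only FPKM and
    one with localized mouse-only coverage. Reports sensitivity (a truth
    anomaly counts as recovered when a surviving region covers >= 50% of
    it), false-positive regions on un-injected transcripts, and whether the
    two mouse filters removed their decoys in every seed.
    """
    hcfg = HuncConfig()
    n_recovered = 0
    n_truth = 0
    false_positives = 0
    fpkm_decoy_filtered = 0
    cov_decoy_filtered = 0
    for k in range(n_seeds):
        cfg = SimConfig(
            n_transcripts=n_transcripts,
            length_range=(1200, 3000),
            n_fragments=120_000,
            seed=int(seed) + 10_000 + k,
        )
        models, _, truth = generate_transcriptome(cfg)
        rng = np.random.default_rng([cfg.seed, 5])
        injections = inject_anomalies(
            truth, models, rng, n_injected,
            hunc_cfg_trims=(hcfg.window, hcfg.trim_head, hcfg.trim_tail),
        )
        # decoy 1: anomaly on a transcript with high mouse-only FPKM
        fpkm_decoy = inject_anomalies(
            truth, models, rng, 1,
            hunc_cfg_trims=(hcfg.window, hcfg.trim_head, hcfg.trim_tail),
        )[0]
        truth.decoys[fpkm_decoy.transcript_id] = decoy_fpkm
        # decoy 2: anomaly on a transcript with localized mouse-only coverage
        cov_decoy = inject_anomalies(
            truth, models, rng, 1,
            hunc_cfg_trims=(hcfg.window, hcfg.trim_head, hcfg.trim_tail),
        )[0]

        rep1, rep2, mouse_fpkm = simulate_dilution_experiment(models, truth, cfg)
        for series in (rep1, rep2):
            depths = series.coverage["mouse_only"][cov_decoy.transcript_id].depths
            depths[cov_decoy.start : cov_decoy.end] += decoy_local_depth

        scores1, _ = score_series(rep1, hcfg)
        scores2, _ = score_series(rep2, hcfg)
        mouse_cov = [
            {t: rep.coverage["mouse_only"][t].depths for t in rep.transcript_ids}
            for rep in (rep1, rep2)
        ]
        result = call_hunc_regions(scores1, scores2, mouse_fpkm, mouse_cov, hcfg)

        n_truth += len(injections)
        n_recovered += sum(
            _truth_recovered(inj, result.regions) for inj in injections
        )
        injected_ids = {inj.transcript_id for inj in truth.hunc_injections}
        false_positives += sum(
            1 for r in result.regions if r.transcript_id not in injected_ids
        )
        if any(
            r.transcript_id == fpkm_decoy.transcript_id
            and r.status == "failed:mouse_fpkm"
            for r in result.rejected
        ) and all(
            r.transcript_id != fpkm_decoy.transcript_id for r in result.regions
        ):
            fpkm_decoy_filtered += 1
        if any(
            r.transcript_id == cov_decoy.transcript_id
            and r.status == "failed:mouse_coverage"
            for r in result.rejected
        ) and all(
            r.transcript_id != cov_decoy.transcript_id for r in result.regions
        ):
            cov_decoy_filtered += 1
    return {
        "n_seeds": n_seeds,
        "n_truth": n_truth,
        "n_recovered": n_recovered,
        "sensitivity": n_recovered / n_truth if n_truth else float("nan"),
        "false_positives": false_positives,
        "fpkm_decoy_filtered": fpkm_decoy_filtered,
        "cov_decoy_filtered": cov_decoy_filtered,
    }


def ranksum_calibration_study(
    seed: int, n_sims: int = 10_000, n: int = 100, alpha: float = 0.05
) -> dict:
    """Type-I error of the rank-sum test under the null at significance alpha."""
    rng = np.random.default_rng([int(seed), 6])
    rejections = 0
    for _ in range(n_sims):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        _, p = rank_sum_test(x, y)
        rejections += p < alpha
    return {"n_sims": n_sims, "alpha": alpha, "rejection_rate": rejections / n_sims}


def rrna_drop_study(seed: int, n_transcripts: int = 200) -> dict:
    """Correlation between rRNA similarity and depletion coverage drop.

    Generates transcripts of which half carry a planted rRNA-homologous
    segment, simulates the library panel (the rRNA-depleted library
    suppresses those segments), and correlates each transcript's best
    Smith-Waterman score against the synthetic rRNA references with its
    no-selection vs rRNA-depleted coverage drop.
    """
    cfg = SimConfig(
        n_transcripts=n_transcripts,
        length_range=(1000, 1600),
        n_fragments=100_000,
        rrna_insert=n_transcripts // 2,
        rrna_insert_length=(100, 600),
        seed=int(seed) + 20_000,
    )
    refs = make_synthetic_rrna(cfg.seed)
    models, seqs, truth = generate_transcriptome(cfg, rrna_refs=refs)
    panel = simulate_library_panel(models, truth, cfg)
    no_sel_cov, _ = panel["no_selection"]
    dep_cov, _ = panel["rrna_depleted"]
    drops = coverage_drop_table(no_sel_cov, dep_cov).dropna()
    tids = sorted(drops.index)
    scores = np.array([rrna_similarity(seqs[t], refs, RRNA_SCORING) for t in tids])
    drop_vals = drops.loc[tids].to_numpy()
    r2 = pearson_r2(scores, drop_vals)
    slope = float(np.polyfit(scores, drop_vals, 1)[0])
    from scipy import stats as _st

    p = float(_st.pearsonr(scores, drop_vals).pvalue)
    return {
        "n": len(tids),
        "r2": r2,
        "p_value": p,
        "direction": 1 if slope > 0 else (-1 if slope < 0 else 0),
    }
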