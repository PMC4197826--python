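"""End-to-end orchestration: config, logging, and the full report bundle.

``run_all`` goes from a config + seed to metrics, hunc calls, sequence
features and association reports, writing a run manifest with the config
hash and per-stage counts. In simulate-first mode all inputs are generated
by the fragmentation simulator; otherwise coverage is read from a sample
manifest of bedGraph paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import association_report
from .hunc import HuncConfig, call_hunc_regions, difference_regions, score_series
from .metrics import MetricsConfig, compute_fpkm, fold_change_summary, metrics_table
from .models import CONDITIONS, DilutionSeries, project_to_transcript
from .seqfeat import AlignScoring, coverage_drop_table, feature_table
from .simulate import (
    SimConfig,
    generate_transcriptome,
    inject_anomalies,
    make_synthetic_rrna,
    simulate_dilution_experiment,
    simulate_library_panel,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: str) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat, JSON-serializable configuration of a full run."""

    outdir: str = "covbias_run"
    seed: int = 0
    simulate_first: bool = True
    n_injected: int = 6
    sim: SimConfig = field(default_factory=SimConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    hunc: HuncConfig = field(default_factory=HuncConfig)
    scoring: AlignScoring = field(default_factory=AlignScoring)
    # manifest rows: {sample, condition, replicate, bedgraph}; required when
    # simulate_first is false, together with models/sequences paths.
    manifest: list[dict] = field(default_factory=list)
    models_bed: str | None = None
    sequences_fasta: str | None = None
    rrna_fasta: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key, sub in (
            ("sim", SimConfig),
            ("metrics", MetricsConfig),
            ("hunc", HuncConfig),
            ("scoring", AlignScoring),
        ):
            if key in raw and isinstance(raw[key], dict):
                section = raw[key]
                for name, value in section.items():
                    if isinstance(value, list):
                        section[name] = tuple(value)
                raw[key] = sub(**section)
        return cls(**raw)

    def to_json_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_json_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _validate_manifest(config: PipelineConfig) -> None:
    seen = set()
    by_rep: dict[int, set[str]] = {1: set(), 2: set()}
    for row in config.manifest:
        label = row.get("sample")
        if label in seen:
            raise PipelineError("config", f"duplicate sample label {label!r}")
        seen.add(label)
        by_rep.setdefault(int(row["replicate"]), set()).add(row["condition"])
    for rep, conditions in by_rep.items():
        missing = set(CONDITIONS) - conditions
        if missing:
            raise PipelineError(
                "config",
                f"replicate {rep} manifest missing condition(s): {sorted(missing)}",
            )


def _load_series(config: PipelineConfig, models) -> tuple[DilutionSeries, DilutionSeries]:
    per_rep: dict[int, dict[str, dict]] = {1: {}, 2: {}}
    for row in config.manifest:
        track = io.read_bedgraph(row["bedgraph"])
        per_rep[int(row["replicate"])][row["condition"]] = {
            tid: project_to_transcript(track, m) for tid, m in models.items()
        }
    return (
        DilutionSeries(1, per_rep[1]),
        DilutionSeries(2, per_rep[2]),
    )


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest dict.

    Outputs under ``config.outdir``: metrics.tsv, hunc_regions.tsv/.bed,
    difference_regions.tsv, hunc_score_traces.tsv, features.tsv,
    association.tsv, truth_injections.tsv (simulate-first mode), and
    manifest.json recording the config hash, seed, stage counts, and the
    per-replicate score cutoffs. Deterministic given config + seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate_first:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            rrna_refs = make_synthetic_rrna(config.seed)
            models, seqs, truth = generate_transcriptome(sim_cfg, rrna_refs)
            if config.n_injected:
                rng = np.random.default_rng([config.seed, 7])
                inject_anomalies(
                    truth, models, rng, config.n_injected,
                    hunc_cfg_trims=(
                        config.hunc.window,
                        config.hunc.trim_head,
                        config.hunc.trim_tail,
                    ),
                )
            rep1, rep2, mouse_fpkm = simulate_dilution_experiment(
                models, truth, sim_cfg
            )
            panel = simulate_library_panel(models, truth, sim_cfg)
            truth.injections_to_frame().to_csv(
                outdir / "truth_injections.tsv", sep="\t", index=False
            )
            io.write_gene_models(models, outdir / "models.bed")
            io.write_fasta(seqs, outdir / "transcripts.fa")
        else:
            _validate_manifest(config)
            if not (config.models_bed and config.sequences_fasta):
                raise PipelineError("config", "models_bed and sequences_fasta required")
            models = io.read_gene_models(config.models_bed)
            seqs = io.read_fasta(config.sequences_fasta)
            rrna_refs = (
                io.read_fasta(config.rrna_fasta)
                if config.rrna_fasta
                else make_synthetic_rrna(config.seed)
            )
            rep1, rep2 = _load_series(config, models)
            mouse_fpkm = [
                {t: 0.0 for t in models}, {t: 0.0 for t in models}
            ]
            panel = None
            truth = None
        counts["transcripts"] = len(models)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(stage, str(exc)) from exc

    # ---- metrics ----------------------------------------------------------
    stage = "metrics"
    try:
        frames = []
        if panel is not None:
            for name, (cov, fpkm) in sorted(panel.items()):
                frames.append(metrics_table(cov, fpkm, name, config.metrics))
        for rep, series in ((1, rep1), (2, rep2)):
            cov = series.coverage["ivt_only"]
            total = sum(c.depths.sum() for c in cov.values()) / (
                2 * config.sim.read_length
            )
            fpkm = {
                t: compute_fpkm(
                    c.depths.sum() / (2 * config.sim.read_length),
                    len(c),
                    max(total, 1.0),
                )
                for t, c in cov.items()
            }
            frames.append(
                metrics_table(cov, fpkm, f"ivt_only_rep{rep}", config.metrics)
            )
        metrics_df = pd.concat(frames, ignore_index=True)
        metrics_df.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        fc_vals = metrics_df.loc[
            metrics_df["sample"] == "simulated", "fold_change"
        ].dropna()
        counts["fold_change_summary_simulated"] = list(
            fold_change_summary(fc_vals, config.metrics.fc_thresholds)
        ) if len(fc_vals) else None
        counts["metrics_rows"] = int(len(metrics_df))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- hunc calling -----------------------------------------------------
    stage = "hunc"
    try:
        scores1, skipped1 = score_series(rep1, config.hunc)
        scores2, skipped2 = score_series(rep2, config.hunc)
        mouse_cov = [
            {t: rep.coverage["mouse_only"][t].depths for t in rep.transcript_ids}
            for rep in (rep1, rep2)
        ]
        result = call_hunc_regions(
            scores1, scores2, mouse_fpkm, mouse_cov, config.hunc
        )
        logger.info(
            "hunc cutoffs: replicate 1 %.8f, replicate 2 %.8f", *result.cutoffs
        )
        diff = difference_regions(
            scores1, scores2, result.regions, mouse_fpkm, mouse_cov, config.hunc
        )
        _write_regions_tsv(result, outdir / "hunc_regions.tsv")
        _write_regions_tsv(diff, outdir / "difference_regions.tsv")
        io.write_regions_bed(result.regions, models, outdir / "hunc_regions.bed")
        _write_score_traces(result, scores1, scores2, outdir / "hunc_score_traces.tsv")
        counts["hunc_regions"] = len(result.regions)
        counts["hunc_rejected"] = len(result.rejected)
        counts["difference_regions"] = len(diff.regions)
        counts["hunc_cutoffs"] = list(result.cutoffs)
        counts["transcripts_skipped_rep1"] = len(skipped1)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- sequence features ------------------------------------------------
    stage = "seqfeat"
    try:
        features = feature_table(seqs, rrna_refs, config.scoring)
        if panel is not None:
            drops = coverage_drop_table(
                panel["no_selection"][0], panel["rrna_depleted"][0]
            )
            features = features.merge(
                drops.rename("coverage_drop"),
                left_on="transcript_id",
                right_index=True,
                how="left",
            )
        features.to_csv(outdir / "features.tsv", sep="\t", index=False)
        counts["features_rows"] = int(len(features))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- association ------------------------------------------------------
    stage = "associate"
    try:
        n_extreme = min(100, counts["transcripts"] // 3)
        reports = []
        for sample in sorted(metrics_df["sample"].unique()):
            sub = metrics_df[metrics_df["sample"] == sample]
            try:
                reports.append(
                    association_report(
                        sub, features, library=sample, n=n_extreme
                    )
                )
            except ValueError as exc:
                logger.info("association skipped for %s: %s", sample, exc)
        assoc = (
            pd.concat(reports, ignore_index=True) if reports else pd.DataFrame()
        )
        assoc.to_csv(outdir / "association.tsv", sep="\t", index=False)
        counts["association_rows"] = int(len(assoc))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _write_regions_tsv(result, path: Path) -> None:
    rows = [
        {
            "transcript_id": r.transcript_id,
            "start": r.start,
            "end": r.end,
            "mean_mad": r.mean_mad,
            "replicate_support": r.replicate_support,
            "source": r.source,
            "direction": r.direction,
            "status": r.status,
        }
        for r in (*result.regions, *result.rejected)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "start", "end", "mean_mad",
            "replicate_support", "source", "direction", "status",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_score_traces(result, scores1, scores2, path: Path) -> None:
    """Window-score traces around surviving regions (the manual-check aid)."""
    rows = []
    for r in result.regions:
        for rep, scores in ((1, scores1), (2, scores2)):
            ws = scores.get(r.transcript_id)
            if ws is None:
                continue
            pad = 200
            sel = (ws.centers >= r.start - pad) & (ws.centers < r.end + pad)
            for center, score in zip(ws.centers[sel], ws.scores[sel]):
                rows.append(
                    {
                        "transcript_id": r.transcript_id,
                        "replicate": rep,
                        "center": int(center),
                        "score": float(score),
                        "in_region": bool(r.start <= center < r.end),
                    }
                )
    pd.DataFrame(
        rows,
        columns=["transcript_id", "replicate", "center", "score", "in_region"],
    ).to_csv(path, sep="\t", index=False)
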