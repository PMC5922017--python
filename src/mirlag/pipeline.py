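"""End-to-end orchestration: normalize -> DE -> profiles/clustering ->
target prediction + validation filter -> delayed anti-correlation ->
network, with per-stage count logging (the funnel report)."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from mirlag import anticorr, de, io_model, profiles, targeting
from mirlag.simulate import SimConfig, SyntheticDataset, generate_dataset

log = logging.getLogger("mirlag")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the workflow, with study defaults."""

    seed: int = 0
    use_rin: bool = False
    fdr_threshold: float = 0.05
    significance: str = "fdr"          # "fdr" or "p"
    global_bh: bool = False
    score_threshold: float = -0.7
    remove_positive_time_matched: bool = True
    require_mrna_significant: bool = True
    clusters_mirna: int = 4
    clusters_mrna: int = 6
    fuzzifier: float | None = None
    sim: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineReport:
    seed: int
    use_rin: bool
    stage_counts: dict[str, int]
    outputs: dict[str, str]
    runtime_s: float
    config: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    cfg: PipelineConfig,
    dataset: SyntheticDataset | None = None,
    outdir: str | Path | None = None,
    make_plots: bool = False,
) -> tuple[PipelineReport, dict[str, Any]]:
    """Run the full workflow on a dataset (simulated when not supplied).

    Returns (report, artifacts); artifacts holds the in-memory products
    (DE tables, cluster models, scored network, ...).
    """
    t0 = time.time()
    outputs: dict[str, str] = {}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name: str):
        log.info("stage %s", name)
        return name

    try:
        stage = _stage("simulate")
        if dataset is None:
            dataset = generate_dataset(SimConfig(seed=cfg.seed, **cfg.sim))

        stage = _stage("normalize")
        norm_mi = de.upper_quartile_normalize(dataset.mirna_counts)
        norm_mr = de.upper_quartile_normalize(dataset.mrna_counts)

        stage = _stage("differential_expression")
        de_mi = de.test_differential_expression(
            norm_mi, use_rin=cfg.use_rin, significance=cfg.significance,
            threshold=cfg.fdr_threshold, global_bh=cfg.global_bh)
        de_mr = de.test_differential_expression(
            norm_mr, use_rin=cfg.use_rin, significance=cfg.significance,
            threshold=cfg.fdr_threshold, global_bh=cfg.global_bh)

        stage = _stage("profiles")
        sig_mi = de_mi.loc[de_mi["significant"], "entity_id"].tolist()
        sig_mr = de_mr.loc[de_mr["significant"], "entity_id"].tolist()
        fc_mi = {s.entity_id: s for s in profiles.compute_log2fc_series(norm_mi, sig_mi)}
        fc_mr = {s.entity_id: s for s in profiles.compute_log2fc_series(norm_mr, sig_mr)}

        stage = _stage("clustering")
        cluster_mi = cluster_mr = None
        if len(sig_mi) >= cfg.clusters_mirna:
            cluster_mi = profiles.cluster_profiles(
                list(fc_mi.values()), cfg.clusters_mirna, m=cfg.fuzzifier,
                seed=cfg.seed)
        if len(sig_mr) >= cfg.clusters_mrna:
            cluster_mr = profiles.cluster_profiles(
                list(fc_mr.values()), cfg.clusters_mrna, m=cfg.fuzzifier,
                seed=cfg.seed)

        stage = _stage("target_prediction")
        predicted, sites = targeting.predict_seed_sites(
            dataset.mirna_fasta, dataset.utr_fasta)

        stage = _stage("anticorrelation")
        ac_cfg = anticorr.AntiCorrConfig(
            threshold=cfg.score_threshold,
            remove_positive_time_matched=cfg.remove_positive_time_matched)
        network, counts = anticorr.build_pair_network(
            de_mi, de_mr, predicted, dataset.validated.frame,
            fc_mi, fc_mr, ac_cfg,
            require_mrna_significant=cfg.require_mrna_significant)

        stage = _stage("write_outputs")
        if outdir is not None:
            de.write_de_results(de_mi, outdir / "de_mirna.tsv")
            de.write_de_results(de_mr, outdir / "de_mrna.tsv")
            outputs["de_mirna"] = str(outdir / "de_mirna.tsv")
            outputs["de_mrna"] = str(outdir / "de_mrna.tsv")
            io_model.write_network(network, outdir / "network.tsv")
            outputs["network"] = str(outdir / "network.tsv")
            if cluster_mi is not None:
                profiles.memberships_frame(cluster_mi).to_csv(
                    outdir / "clusters_mirna.tsv", sep="\t")
                outputs["clusters_mirna"] = str(outdir / "clusters_mirna.tsv")
            if cluster_mr is not None:
                profiles.memberships_frame(cluster_mr).to_csv(
                    outdir / "clusters_mrna.tsv", sep="\t")
                outputs["clusters_mrna"] = str(outdir / "clusters_mrna.tsv")
            if make_plots:
                from mirlag import plotting
                for label, model, fcs in (("mirna", cluster_mi, fc_mi),
                                          ("mrna", cluster_mr, fc_mr)):
                    if model is None:
                        continue
                    p = outdir / f"clusters_{label}.png"
                    plotting.plot_clusters(model, p)
                    outputs[f"clusters_{label}_plot"] = str(p)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(stage, exc) from exc

    stage_counts = {
        "de_mirna": counts["de_mirna"],
        "de_mrna": counts["de_mrna"],
        "predicted_pairs": counts["predicted_pairs"],
        "de_filtered_pairs": counts["de_filtered_pairs"],
        "validated_pairs": counts["validated_pairs"],
        "scored_pairs": counts["scored_pairs"],
        "passing_pairs": counts["passing_pairs"],
    }
    report = PipelineReport(
        seed=cfg.seed,
        use_rin=cfg.use_rin,
        stage_counts=stage_counts,
        outputs=outputs,
        runtime_s=round(time.time() - t0, 3),
        config={k: v for k, v in asdict(cfg).items()},
    )
    if outdir is not None:
        (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
    artifacts = {
        "dataset": dataset,
        "de_mirna": de_mi,
        "de_mrna": de_mr,
        "fc_mirna": fc_mi,
        "fc_mrna": fc_mr,
        "cluster_mirna": cluster_mi,
        "cluster_mrna": cluster_mr,
        "predicted": predicted,
        "sites": sites,
        "network": network,
    }
    return report, artifacts


def compare_rin(
    cfg: PipelineConfig,
    dataset: SyntheticDataset | None = None,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the pipeline with and without the RIN covariate and diff the
    funnel counts (uncorrected vs corrected workflow comparison)."""
    if dataset is None:
        dataset = generate_dataset(SimConfig(seed=cfg.seed, **cfg.sim))
    rows = {}
    for use_rin in (False, True):
        sub = PipelineConfig(**{**asdict(cfg), "use_rin": use_rin})
        sub_out = None
        if outdir is not None:
            sub_out = Path(outdir) / ("with_rin" if use_rin else "no_rin")
        report, _ = run_pipeline(sub, dataset=dataset, outdir=sub_out)
        rows["with_rin" if use_rin else "no_rin"] = report.stage_counts
    table = pd.DataFrame(rows)
    table.index.name = "stage"
    if outdir is not None:
        table.to_csv(Path(outdir) / "rin_comparison.tsv", sep="\t")
    return table
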