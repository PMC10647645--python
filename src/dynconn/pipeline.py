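"""End-to-end pipeline: simulate (or ingest) -> FC -> graph metrics ->
summaries -> group statistics, with reproducible configuration and
provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .fc import DEFAULT_THRESHOLDS, SlidingWindowConnectivity
from .graph import GraphMetricsExtractor
from .networks import NetworkDefinition, default_network_map
from .stats import GroupThresholdAnova
from .summarize import WindowSummarizer
from .synth import CohortSpec, simulate_cohort
from . import io as dio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to rerun the analysis; defaults reproduce the
    reference parameterization (2000 ms windows, 90% overlap, thresholds
    0.1–0.6, CV in percent, alpha 0.05)."""

    epochs_dir: str | None = None  # ingest instead of simulating when set
    n_per_group: int = 20
    conditions: tuple[str, ...] = ("MW", "OT")
    epochs_per_condition: int = 10
    epoch_duration_s: float = 50.0
    sampling_rate_hz: float = 500.0
    roi_count: int | None = None  # None -> the shipped 68-ROI default map
    network_map_path: str | None = None
    window_ms: float = 2000.0
    overlap_fraction: float = 0.9
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    networks: tuple[str, ...] | None = None
    metrics: tuple[str, ...] | None = None
    cv_ddof: int = 1
    pooling: str = "per_epoch"
    engine: str = "mixed"
    n_perm: int = 999
    alpha: float = 0.05
    posthoc_fdr_scope: str = "within_cell"
    seed: int = 0
    write_epochs: bool = True
    write_fc: bool = False

    def network_map(self) -> NetworkDefinition:
        if self.network_map_path:
            return NetworkDefinition.from_yaml(self.network_map_path)
        if self.roi_count is not None:
            return NetworkDefinition.evenly_partitioned(self.roi_count)
        return default_network_map()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        clean = {
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        }
        return cls(**clean)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    manifest: pd.DataFrame
    metrics: pd.DataFrame
    summary: pd.DataFrame
    results: pd.DataFrame
    posthoc: pd.DataFrame
    significance: pd.DataFrame
    out_dir: Path | None = None


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run every stage; when ``out_dir`` is given, each artifact is written
    as delimited text with a provenance JSON."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    network_map = config.network_map()
    if config.epochs_dir:
        logger.info("stage ingest: reading epochs from %s", config.epochs_dir)
        epochs, manifest = dio.read_cohort(config.epochs_dir)
    else:
        logger.info("stage simulate: synthetic cohort (seed=%d)", config.seed)
        spec = CohortSpec(
            network_map=network_map,
            n_per_group=config.n_per_group,
            conditions=tuple(config.conditions),
            epochs_per_condition=config.epochs_per_condition,
            epoch_duration_s=config.epoch_duration_s,
            sampling_rate_hz=config.sampling_rate_hz,
            seed=config.seed,
        )
        epochs, manifest = simulate_cohort(spec)
        if out is not None and config.write_epochs:
            dio.write_cohort(epochs, manifest, out / "epochs")

    logger.info("stage fc: %d epochs", len(epochs))
    fc = SlidingWindowConnectivity(config.window_ms, config.overlap_fraction)
    fc_series = fc.transform(epochs)
    if out is not None and config.write_fc:
        for fcs in fc_series:
            dio.write_fc_series(fcs, out / "fc")
    nan_pairs = sum(f.nan_pair_count for f in fc_series)
    if nan_pairs:
        logger.warning("stage fc: %d NaN ROI pairs across the cohort", nan_pairs)

    logger.info("stage metrics: %d thresholds", len(config.thresholds))
    extractor = GraphMetricsExtractor(
        network_map=network_map,
        thresholds=tuple(config.thresholds),
        networks=config.networks,
        metrics=config.metrics,
    )
    metrics = extractor.fit().transform(fc_series)

    logger.info("stage summarize: pooling=%s", config.pooling)
    summarizer = WindowSummarizer(ddof=config.cv_ddof, pooling=config.pooling)
    summary = summarizer.fit().transform(metrics)

    logger.info("stage stats: engine=%s", config.engine)
    anova = GroupThresholdAnova(
        engine=config.engine,
        alpha=config.alpha,
        n_perm=config.n_perm,
        posthoc_fdr_scope=config.posthoc_fdr_scope,
        random_state=config.seed,
    ).fit(summary)

    result = PipelineResult(
        config=config,
        manifest=manifest,
        metrics=metrics,
        summary=summary,
        results=anova.results_,
        posthoc=anova.posthoc_,
        significance=anova.significance_,
        out_dir=out,
    )
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        metrics.to_csv(out / "metrics.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        anova.results_.to_csv(out / "stats_results.csv", index=False)
        anova.posthoc_.to_csv(out / "posthoc.csv", index=False)
        anova.significance_.to_csv(out / "significance.csv", index=False)
        provenance = {
            "package_version": __version__,
            "config_hash": config.hash(),
            "seed": config.seed,
            "config": config.to_dict(),
            "n_epochs": len(epochs),
            "n_windows_per_epoch": fc_series[0].plan.n_windows if fc_series else 0,
            "n_thresholds": len(config.thresholds),
            "nan_pair_count": nan_pairs,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return result
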