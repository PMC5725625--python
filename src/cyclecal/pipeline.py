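"""End-to-end pipeline: simulate → derive → fit → evaluate → report.

Each stage materialises its output as CSV (or JSON for fits and the
final report) so intermediate results can be audited; given a fixed
seed and inputs the whole run is deterministic, including byte-level
file content.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import evaluation, predictors, records, synth
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path = Path("cyclecal_out")
    events_path: Path | None = None  # default: <out_dir>/events.csv
    simulate: bool = True
    generator: synth.GeneratorConfig = field(default_factory=synth.cohort_preset)
    screen_lo: int = records.SCREEN_LO
    screen_hi: int = records.SCREEN_HI
    allowed_bases: frozenset[str] = records.DEFAULT_ALLOWED_BASES
    duplicate_policy: str = "drop"
    k_range: Sequence[int] = tuple(range(1, 9))
    methods: Sequence[str] = predictors.METHODS
    errors: Sequence[int] = (0, 1, 2)
    estimator: str = "gls_re"
    hausman_rule: str = "reject_random_if_p_large"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.events_path is not None:
            self.events_path = Path(self.events_path)
        if any(k < 1 for k in self.k_range):
            raise ConfigError("k values must be >= 1")
        if any(e < 0 for e in self.errors):
            raise ConfigError("error levels must be non-negative integers")
        unknown = set(self.methods) - set(predictors.METHODS)
        if unknown:
            raise ConfigError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"pipeline config {path} must be a mapping")
        gen = raw.pop("generator", None)
        if gen is not None:
            for key in ("basis_probs", "clip"):
                if key in gen and isinstance(gen[key], list):
                    gen[key] = tuple(gen[key])
            raw["generator"] = synth.GeneratorConfig(**gen)
        if "allowed_bases" in raw:
            raw["allowed_bases"] = frozenset(raw["allowed_bases"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config {path}: {exc}") from None

    @property
    def resolved_events_path(self) -> Path:
        return self.events_path if self.events_path is not None else self.out_dir / "events.csv"


def _require(path: Path, stage: str) -> Path:
    if not Path(path).exists():
        raise DataError(f"stage {stage!r}: input file not found: {path}")
    return Path(path)


def stage_simulate(cfg: PipelineConfig) -> Path:
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    gen = cfg.generator if cfg.seed is None else cfg.generator.replace(seed=cfg.seed)
    histories = synth.generate_population(gen)
    path = cfg.resolved_events_path
    records.write_event_csv(histories, path)
    n_events = sum(h.record_length + len(h.ovulations) for h in histories)
    logger.info(
        "stage=simulate seed=%s women=%d events=%d -> %s",
        gen.seed, len(histories), n_events, path,
    )
    return path


def stage_derive(cfg: PipelineConfig) -> Path:
    path = _require(cfg.resolved_events_path, "derive")
    histories = records.read_event_csv(path)
    cycles = records.derive_cycles(
        histories,
        lo=cfg.screen_lo,
        hi=cfg.screen_hi,
        allowed_bases=cfg.allowed_bases,
        duplicate_policy=cfg.duplicate_policy,
    )
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    out = cfg.out_dir / "cycles.csv"
    records.write_cycles_csv(cycles, out)
    n_dated = sum(1 for cy in cycles if cy.f is not None)
    logger.info(
        "stage=derive women=%d cycles=%d ovulation_dated=%d -> %s",
        len(histories), len(cycles), n_dated, out,
    )
    return out


def stage_fit(cfg: PipelineConfig) -> Path:
    cycles = records.read_cycles_csv(_require(cfg.out_dir / "cycles.csv", "fit"))
    fits = [predictors.fit_optimized(cycles, k, cfg.estimator) for k in cfg.k_range]
    out = cfg.out_dir / "optimized_fits.json"
    predictors.write_fits_json(fits, out)
    logger.info("stage=fit estimator=%s k=%s -> %s", cfg.estimator, list(cfg.k_range), out)
    return out


def stage_evaluate(cfg: PipelineConfig) -> dict:
    cycles = records.read_cycles_csv(_require(cfg.out_dir / "cycles.csv", "evaluate"))
    fits_path = cfg.out_dir / "optimized_fits.json"
    fits = (
        {f.k: f for f in predictors.read_fits_json(fits_path)}
        if fits_path.exists()
        else None
    )
    summary = evaluation.summarize_by_cycle_length(cycles)
    summary.to_csv(cfg.out_dir / "phase_summary.csv", index=False)
    counts = evaluation.past_record_counts(cycles, k_max=max(cfg.k_range))
    counts.to_csv(cfg.out_dir / "record_depth_counts.csv", index=False)
    perk = evaluation.per_k_fits(cycles, cfg.k_range, hausman_rule=cfg.hausman_rule)
    perk.to_csv(cfg.out_dir / "per_k_fits.csv", index=False)
    cells, means = evaluation.accuracy_report(
        cycles,
        methods=cfg.methods,
        errors=cfg.errors,
        k_range=cfg.k_range,
        estimator=cfg.estimator,
        fits=fits,
    )
    cells.to_csv(cfg.out_dir / "accuracy_cells.csv", index=False)
    means.to_csv(cfg.out_dir / "accuracy_means.csv", index=False)
    correlations = {
        target: {
            int(k): dict(zip(("r", "p"), evaluation.correlation_with_mean(cycles, k, target)))
            for k in cfg.k_range
        }
        for target in ("next_cycle", "follicular", "luteal")
    }
    n_dated = sum(1 for cy in cycles if cy.f is not None)
    result = {
        "counts": {
            "women": len({cy.woman_id for cy in cycles}),
            "cycles": len(cycles),
            "ovulation_dated": n_dated,
            "per_k_total": evaluation.depth_totals(counts),
        },
        "correlations": correlations,
        "per_k_fits": perk.to_dict(orient="records"),
        "mean_accuracy": means.to_dict(orient="records"),
    }
    logger.info(
        "stage=evaluate cycles=%d ovulation_dated=%d combos=%d",
        len(cycles), n_dated, len(means),
    )
    return result


def stage_report(cfg: PipelineConfig, evaluation_result: dict | None = None) -> Path:
    if evaluation_result is None:
        evaluation_result = stage_evaluate(cfg)
    report = {
        "seed": cfg.seed if cfg.seed is not None else cfg.generator.seed,
        "config": {
            "screen": [cfg.screen_lo, cfg.screen_hi],
            "allowed_bases": sorted(cfg.allowed_bases),
            "k_range": list(cfg.k_range),
            "methods": list(cfg.methods),
            "errors": list(cfg.errors),
            "estimator": cfg.estimator,
            "hausman_rule": cfg.hausman_rule,
        },
        "results": evaluation_result,
    }
    out = cfg.out_dir / "report.json"
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("stage=report -> %s", out)
    return out


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage in order and return the report path."""
    if cfg.simulate:
        stage_simulate(cfg)
    stage_derive(cfg)
    stage_fit(cfg)
    result = stage_evaluate(cfg)
    return stage_report(cfg, result)
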