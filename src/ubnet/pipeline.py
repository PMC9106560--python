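"""End-to-end pipeline: build -> mine -> select -> features -> classify.

Four arms are supported:

``uncertain``
    probabilistic networks throughout (mining under expected support,
    confidence selection, containment-probability features);
``certain``
    networks binarized at one sparsity (frequency-support mining,
    frequency-difference selection, presence features);
``threshold_compare``
    discriminative patterns selected on the uncertain networks are mapped
    onto binarized networks across a sparsity grid and both representations
    are classified (threshold-direction comparison table);
``weight_compare``
    discriminative patterns selected on binarized networks at each sparsity
    are mapped back onto the uncertain networks and both representations
    are classified (weight-direction comparison table).

All randomness flows from one root seed.  Every run writes versioned JSON /
CSV outputs plus a log of parameters, seeds and per-stage wall-clock.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .build import pearson_correlation_matrix, threshold_by_sparsity, to_uncertain_network
from .classify import CVConfig, repeated_cv_evaluate
from .estimators import SubgraphFeatureExtractor
from .features import probability_features, threshold_map, weight_map
from .graph import Cohort
from .io import read_cohort, write_cohort, write_features, write_mining_results, write_selection
from .simulate import SyntheticConfig, generate_timeseries_cohort, generate_uncertain_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

SPARSITY_GRID = tuple(round(0.05 * i, 2) for i in range(1, 9))  # 0.05 .. 0.40


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source is used: an existing cohort ``manifest``, or a
    ``synthetic`` configuration (optionally routed through time-series
    generation with ``from_timeseries`` to exercise the Pearson build).
    ``repeats`` applies to the main arm's repeated CV and ``sweep_repeats``
    to each grid cell of the comparison tables (a scaled-down setting so
    sweeps stay cheap; raise it for production runs).
    """

    out_dir: str = "ubnet_run"
    manifest: str | None = None
    synthetic: SyntheticConfig | None = None
    from_timeseries: bool = False
    n_timepoints: int = 248
    arm: str = "uncertain"
    minsup: float = 0.25
    growth_mode: str = "increasing"
    top_k: int = 15
    certain_sparsity: float = 0.2
    sparsity_grid: tuple = SPARSITY_GRID
    certain_max_pattern_edges: int | None = 3
    folds: int = 10
    repeats: int = 10
    sweep_repeats: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.arm not in ("uncertain", "certain", "threshold_compare", "weight_compare"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.manifest is None and self.synthetic is None:
            raise ValueError("either a manifest or a synthetic config is required")
        for s in self.sparsity_grid:
            if not 0.0 < s < 1.0:
                raise ValueError("sparsity grid values must be in (0, 1)")


def _load_cohort(config: PipelineConfig, out: Path) -> Cohort:
    if config.manifest is not None:
        return read_cohort(config.manifest)
    syn = config.synthetic
    if config.from_timeseries:
        series, truth = generate_timeseries_cohort(syn, config.n_timepoints)
        labels = np.asarray(truth["labels"])
        nets = [to_uncertain_network(pearson_correlation_matrix(ts)) for ts in series]
        cohort = Cohort(nets, labels)
    else:
        cohort, truth = generate_uncertain_cohort(syn)
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "planted": truth["planted"],
                "seed": truth["seed"],
                "from_timeseries": config.from_timeseries,
            },
            indent=1,
            default=str,
        )
    )
    write_cohort(cohort, out / "cohort")
    return cohort


def _evaluate(X, y, config: PipelineConfig, repeats: int) -> dict:
    cv = CVConfig(folds=config.folds, repeats=repeats, seed=config.seed, mode="pooled")
    report = repeated_cv_evaluate(X, y, cv)
    return report.to_dict()


def _fit_extractor(cohort: Cohort, config: PipelineConfig, *, sparsity=None) -> SubgraphFeatureExtractor:
    ext = SubgraphFeatureExtractor(
        minsup=config.minsup,
        top_k=config.top_k,
        growth_mode=config.growth_mode,
        score="confidence" if sparsity is None else "frequency_difference",
        sparsity=sparsity,
        max_pattern_edges=None if sparsity is None else config.certain_max_pattern_edges,
    )
    ext.fit(cohort.networks, cohort.labels)
    return ext


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured arm; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.time() - t_start

    cohort = _load_cohort(config, out)
    y = cohort.labels
    stage("load")

    results: dict = {"arm": config.arm}
    if config.arm in ("uncertain", "threshold_compare"):
        ext = _fit_extractor(cohort, config)
        write_mining_results(ext.frequent_pos_, out / "freq_pos.json", "pos")
        write_mining_results(ext.frequent_neg_, out / "freq_neg.json", "neg")
        write_selection(ext.discriminative_, out / "disc.json")
        stage("mine_select")
        fm = probability_features(ext.feature_patterns_, cohort.networks)
        fm.subject_ids = cohort.subject_ids
        write_features(fm, out / "features.csv")
        results["uncertain"] = _evaluate(fm.values, y, config, config.repeats)
        stage("classify")
        if config.arm == "threshold_compare":
            rows = []
            for s in config.sparsity_grid:
                fm_c = threshold_map(ext.discriminative_, cohort.networks, s)
                rep_c = _evaluate(fm_c.values, y, config, config.sweep_repeats)
                rep_u = _evaluate(fm.values, y, config, config.sweep_repeats)
                rows.append(
                    {
                        "sparsity": s,
                        "n_features": fm.n_features,
                        "accuracy_certain": rep_c["accuracy"],
                        "accuracy_uncertain": rep_u["accuracy"],
                    }
                )
            _write_table(rows, out / "sweep_threshold.csv")
            results["threshold_sweep"] = rows
            stage("sweep")
    elif config.arm == "certain":
        ext = _fit_extractor(cohort, config, sparsity=config.certain_sparsity)
        write_mining_results(ext.frequent_pos_, out / "freq_pos.json", "pos")
        write_mining_results(ext.frequent_neg_, out / "freq_neg.json", "neg")
        write_selection(ext.discriminative_, out / "disc.json")
        stage("mine_select")
        X = ext.transform(cohort.networks)
        results["certain"] = _evaluate(X, y, config, config.repeats)
        stage("classify")
    elif config.arm == "weight_compare":
        rows = []
        for s in config.sparsity_grid:
            ext = _fit_extractor(cohort, config, sparsity=s)
            X_c = ext.transform(cohort.networks)
            rep_c = _evaluate(X_c, y, config, config.sweep_repeats)
            fm_u = weight_map(ext.discriminative_, cohort.networks)
            rep_u = _evaluate(fm_u.values, y, config, config.sweep_repeats)
            rows.append(
                {
                    "sparsity": s,
                    "n_features": X_c.shape[1],
                    "accuracy_certain": rep_c["accuracy"],
                    "accuracy_uncertain": rep_u["accuracy"],
                }
            )
        _write_table(rows, out / "sweep_weight.csv")
        results["weight_sweep"] = rows
        stage("sweep")

    (out / "report.json").write_text(json.dumps(results, indent=1))
    log = {
        "ubnet_version": __version__,
        "config": _config_dict(config),
        "stage_elapsed_s": timings,
        "total_elapsed_s": time.time() - t_start,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    logger.info("pipeline arm %s finished in %.1fs", config.arm, log["total_elapsed_s"])
    return out


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    if config.synthetic is not None:
        syn = asdict(config.synthetic)
        syn["planted_patterns"] = [
            {"edges": [list(e) for e in p.edges], "delta": dl, "target_group": g}
            for p, dl, g in config.synthetic.planted_patterns
        ]
        d["synthetic"] = syn
    return d


def _write_table(rows: list[dict], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, index=False)
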