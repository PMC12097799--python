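"""Multi-run experiment driver: the 30 agents x 100 iterations x 30 runs
protocol for any dataset / optimizer-variant / transfer combination.

Each run redraws its stratified split and swarm trajectory from
``base_seed + run_index``, so a study is a pure function of its
configuration.  Outputs are plain CSV: per-run records, mean/std
summaries, convergence curves, and — when two or more optimizers are
configured — a win/tie/loss + Friedman comparison report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import LabeledDataset, SyntheticSpec, generate_synthetic, load_dataset
from .feature_selection import FitnessConfig, FSResult, select_features
from .metrics import aggregate_runs
from .optimizers import OptimizerConfig
from .stats_compare import friedman_mean_ranks, win_tie_loss

__all__ = ["ExperimentConfig", "run_experiment", "improvement_rate", "run_study"]

log = logging.getLogger("magpiefs")

METRIC_COLUMNS = ["fitness", "accuracy", "sensitivity", "specificity", "f_score", "n_selected"]


@dataclass
class ExperimentConfig:
    """One study: datasets x optimizer variants x transfer rules x runs."""

    datasets: dict[str, LabeledDataset] = field(default_factory=dict)
    optimizers: tuple[str, ...] = ("irbmo",)
    transfers: tuple[str, ...] = ("threshold",)
    pop_size: int = 30
    max_iter: int = 100
    n_runs: int = 30
    base_seed: int = 0
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for v in self.optimizers:
            if v not in ("rbmo", "irbmo"):
                raise ValueError(f"unknown optimizer variant {v!r}")


def _record_from_result(res: FSResult, seed: int) -> dict:
    return {
        "seed": seed,
        "fitness": res.fitness,
        "accuracy": res.accuracy,
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "f_score": res.f_score,
        "n_selected": res.n_selected,
    }


def run_study(
    data: LabeledDataset,
    variant: str = "irbmo",
    transfer: str = "threshold",
    pop_size: int = 30,
    max_iter: int = 100,
    n_runs: int = 30,
    base_seed: int = 0,
    fitness: FitnessConfig = FitnessConfig(),
) -> tuple[list[dict], list[FSResult]]:
    """Run ``n_runs`` independent selections (seed = base_seed + index)."""
    records, results = [], []
    for r in range(n_runs):
        seed = base_seed + r
        cfg = OptimizerConfig(dim=data.n_features, pop_size=pop_size, max_iter=max_iter, seed=seed)
        t0 = time.perf_counter()
        res = select_features(data, cfg, fitness, transfer, variant)
        log.info(
            "run=%d seed=%d variant=%s transfer=%s best_fitness=%.6f dur=%.2fs",
            r, seed, variant, transfer, res.fitness, time.perf_counter() - t0,
        )
        records.append(_record_from_result(res, seed))
        results.append(res)
    return records, results


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full study and (optionally) write the CSV outputs.

    Returns a nested dict ``{dataset: {(variant, transfer): {"records",
    "summary", "curves"}}}`` plus a ``"comparison"`` entry per metric when
    at least two optimizer variants are configured.
    """
    out_dir = None
    if config.output_dir is not None:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        try:
            probe.write_text("")
            probe.unlink()
        except OSError as exc:
            raise OSError(f"output directory {out_dir} is not writable") from exc

    study: dict = {}
    fitness_samples: dict[str, dict[str, np.ndarray]] = {}
    for ds_name, data in config.datasets.items():
        study[ds_name] = {}
        for variant in config.optimizers:
            for transfer in config.transfers:
                records, results = run_study(
                    data, variant, transfer,
                    config.pop_size, config.max_iter, config.n_runs,
                    config.base_seed, config.fitness,
                )
                summary = aggregate_runs(records, n_features=data.n_features)
                curves = np.vstack([r.curve for r in results])
                key = f"{variant}_{transfer}"
                study[ds_name][key] = {"records": records, "summary": summary, "curves": curves}
                fitness_samples.setdefault(key, {})[ds_name] = np.array(
                    [r["fitness"] for r in records]
                )
                if out_dir is not None:
                    stem = f"{ds_name}_{key}"
                    pd.DataFrame(records).to_csv(out_dir / f"{stem}_runs.csv", index=False)
                    pd.DataFrame(summary).T.to_csv(out_dir / f"{stem}_summary.csv")
                    pd.DataFrame(curves).to_csv(out_dir / f"{stem}_curves.csv", index=False)

    report: dict = {"study": study}
    algo_keys = sorted(fitness_samples)
    if len(algo_keys) >= 2:
        table = pd.DataFrame(
            {k: {d: fitness_samples[k][d].mean() for d in config.datasets} for k in algo_keys}
        )
        ranks = friedman_mean_ranks(table, lower_is_better=True)
        reference = algo_keys[0]
        wtl = {
            other: win_tie_loss(fitness_samples[reference], fitness_samples[other])
            for other in algo_keys[1:]
        }
        report["comparison"] = {"reference": reference, "friedman": ranks, "win_tie_loss": wtl}
        if out_dir is not None:
            ranks.to_csv(out_dir / "friedman_ranks.csv")
            flat = {
                other: {k: v for k, v in res.items() if k != "per_problem"}
                for other, res in wtl.items()
            }
            (out_dir / "win_tie_loss.json").write_text(json.dumps(flat, indent=2))
    return report


def improvement_rate(
    baseline_means: dict[str, float],
    improved_means: dict[str, float],
) -> tuple[dict[str, float], float]:
    """Percentage improvement of a lower-is-better metric per dataset.

    ``100 * (baseline - improved) / baseline`` per dataset, plus the
    arithmetic mean over datasets; a zero baseline yields NaN for that
    dataset and is excluded from the overall mean.
    """
    if set(baseline_means) != set(improved_means):
        raise ValueError("dataset lists must match")
    per = {}
    for name, base in baseline_means.items():
        per[name] = (
            100.0 * (base - improved_means[name]) / base if base != 0 else float("nan")
        )
    vals = [v for v in per.values() if not np.isnan(v)]
    overall = float(np.mean(vals)) if vals else float("nan")
    return per, overall


def build_datasets(
    data_paths: list[str] | None = None,
    label_column: str | int = -1,
    synthetic: list[SyntheticSpec] | None = None,
) -> dict[str, LabeledDataset]:
    """Assemble the dataset dict for an experiment from files and/or specs."""
    datasets: dict[str, LabeledDataset] = {}
    for p in data_paths or []:
        datasets[Path(p).stem] = load_dataset(p, label_column)
    for i, spec in enumerate(synthetic or []):
        data, _ = generate_synthetic(spec)
        datasets[f"synthetic_{i}"] = data
    if not datasets:
        raise ValueError("no datasets configured")
    return datasets
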