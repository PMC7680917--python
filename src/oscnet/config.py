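"""Structured-text (YAML) run configuration and the experiment driver.

A run configuration bundles every tunable of a classification experiment:
Oregonator constants, the network genome, integrator and peak-detector
settings, GA settings, the dataset recipe and a global seed.  Every default
is the published value where one exists, so an empty file is a valid
configuration.  The global seed expands deterministically into independent
per-stage seeds (data sampling, GA) so each stage can be reproduced in
isolation.
"""

from __future__ import annotations

import json
import os
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .classifier import (DecisionRule, NetworkGenome, ResponseTable,
                         accuracy, fit_decision_rule, respond_batch)
from .datasets import LabeledDataset, sample_flag, sample_horned
from .dynamics import IntegratorConfig, OregonatorParams, PeakConfig
from .evolution import DEFAULT_GENE_RANGES, GAConfig
from .infotheory import joint_counts, network_fitness

__all__ = ["RunConfig", "load_config", "save_config", "run_experiment"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class OregonatorSection(_Section):
    epsilon: float = 0.2
    q_const: float = 0.0002
    f_stoich: float = 1.1

    def build(self) -> OregonatorParams:
        return OregonatorParams(**self.model_dump())


class GenomeSection(_Section):
    role3: str = "normal"
    t_ilum3: float = 6.37
    t_start: float = 3.78
    t_end: float = 12.10
    t_max: float = 20.23
    alpha: float = 0.849
    beta: float = 0.251

    @model_validator(mode="after")
    def _ordered(self) -> "GenomeSection":
        if not self.t_start < self.t_end:
            raise ValueError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})")
        return self

    def build(self) -> NetworkGenome:
        return NetworkGenome(**self.model_dump())


class IntegratorSection(_Section):
    h: float = 1e-4
    store_stride: int = 100

    def build(self, t_max: float) -> IntegratorConfig:
        return IntegratorConfig(t_max=t_max, **self.model_dump())


class PeakSection(_Section):
    height_threshold: float = 0.05

    def build(self) -> PeakConfig:
        return PeakConfig(**self.model_dump())


class GASection(_Section):
    population_size: int = 200
    elite_fraction: float = 0.20
    parent_pool_fraction: float = 0.50
    generations: int = 1000
    expected_mutations_per_genome: float = 1.0
    max_relative_mutation: float = 0.10
    gene_ranges: dict[str, tuple[float, float]] = dict(DEFAULT_GENE_RANGES)

    def build(self, rng_seed: int) -> GAConfig:
        return GAConfig(rng_seed=rng_seed, **self.model_dump())


class DataSection(_Section):
    problem: str = "japan"     # japan | horned
    n_train: int = 800
    n_test: int = 0
    train_path: str | None = None  # overrides generation when set
    test_path: str | None = None


class RunConfig(_Section):
    seed: int = 0
    oregonator: OregonatorSection = OregonatorSection()
    genome: GenomeSection = GenomeSection()
    integrator: IntegratorSection = IntegratorSection()
    peaks: PeakSection = PeakSection()
    ga: GASection = GASection()
    data: DataSection = DataSection()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        stages = {"data_train": 0, "data_test": 1, "ga": 2}
        ss = np.random.SeedSequence(self.seed)
        return int(ss.spawn(3)[stages[stage]].generate_state(1)[0] % (2**31))


def load_config(path) -> RunConfig:
    """Parse and validate a YAML configuration; unknown keys are rejected
    with a message naming the key, an empty file yields pure defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def _load_dataset(cfg: RunConfig, split: str) -> LabeledDataset:
    data = cfg.data
    path = data.train_path if split == "train" else data.test_path
    if path is not None:
        return LabeledDataset.from_csv(path)
    n = data.n_train if split == "train" else data.n_test
    seed = cfg.stage_seed(f"data_{split}")
    if data.problem == "japan":
        return sample_flag(n, seed)
    if data.problem == "horned":
        return sample_horned(n, seed)
    raise ValueError(f"unknown problem {data.problem!r}")


def run_experiment(cfg: RunConfig, out_dir) -> dict:
    """Classify a dataset with the configured genome and write the bundle.

    Produces ``responses.csv`` (x, y, g, o1..o3, pred), ``metrics.json``
    (accuracy, per-oscillator MI, confusion counts by (g, o)) and
    ``run.log``; outputs are written atomically (temp file + rename).
    Returns the metrics dictionary.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.oregonator.build()
    genome = cfg.genome.build()
    icfg = cfg.integrator.build(genome.t_max)
    pk = cfg.peaks.build()

    train = _load_dataset(cfg, "train")
    table = respond_batch(genome, train, params, icfg, pk)
    report = network_fitness(table)
    rule = fit_decision_rule(table, report.output_index)
    pred = rule.predict(table.counts[:, report.output_index])
    acc = accuracy(table, rule, report.output_index)
    joint = joint_counts(table.g, table.counts[:, report.output_index])
    o_values = np.unique(table.counts[:, report.output_index])

    metrics = {
        "version": __version__,
        "seed": cfg.seed,
        "n_records": len(table),
        "accuracy": acc,
        "mi_bits": list(report.mi_bits),
        "selected_output": report.output_index + 1,  # 1-based, as o1..o3
        "rule": {str(k): int(v) for k, v in rule.mapping.items()},
        "confusion": {
            f"g={g},o={int(o)}": int(joint[gi, oi])
            for gi, g in enumerate((0, 1)) for oi, o in enumerate(o_values)
        },
    }

    def _atomic_write(name: str, writer) -> None:
        tmp = out / (name + ".tmp")
        writer(tmp)
        os.replace(tmp, out / name)

    _atomic_write("responses.csv", lambda p: table.to_csv(p, pred=pred))
    _atomic_write("metrics.json",
                  lambda p: Path(p).write_text(json.dumps(metrics, indent=2,
                                                          sort_keys=True)))
    log_lines = [
        f"oscnet {__version__}",
        f"seed: {cfg.seed}",
        f"records: {len(table)}",
        f"selected output oscillator: #{report.output_index + 1}",
        f"accuracy: {acc:.4f}",
        f"wall time: {time.time() - t0:.1f} s",
    ]
    _atomic_write("run.log", lambda p: Path(p).write_text("\n".join(log_lines) + "\n"))
    return metrics
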