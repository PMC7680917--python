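"""Input encoding, network responses and the majority-rule classifier.

A three-oscillator network classifies a point (x, y) of the unit square as
follows: oscillators #1 and #2 are inhibited for times affine in x and y,

    t_ilum(1) = t_start + (t_end - t_start) * x
    t_ilum(2) = t_start + (t_end - t_start) * y,

oscillator #3 is either inhibited for a fixed time (a "normal" oscillator)
or acts as a second input channel, and the number of activator maxima on
each oscillator within [0, t_max] is the discrete readout.  A decision rule
maps the count observed on the output oscillator to a class; the rule is
fitted on training data by per-count label majority.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .datasets import LabeledDataset
from .dynamics import (IlluminationSchedule, IntegratorConfig, NetworkSpec,
                       OregonatorParams, PeakConfig, SimulationError,
                       integrate_counts, steady_state)

__all__ = [
    "ROLE3_CHOICES", "NetworkGenome", "Record", "ResponseTable",
    "DecisionRule", "MAJORITY_RULE", "load_preset",
    "encode_inputs", "respond", "respond_batch",
    "fit_decision_rule", "accuracy",
]

ROLE3_CHOICES = ("normal", "input_x", "input_y")


@dataclass
class NetworkGenome:
    """The seven optimizable traits of a three-oscillator classifier.

    ``t_ilum3`` is dormant (kept but unused) when ``role3`` is an input
    role, so the genome length is constant under crossover and mutation.
    """

    role3: str = "normal"
    t_ilum3: float = 6.37
    t_start: float = 3.78
    t_end: float = 12.10
    t_max: float = 20.23
    alpha: float = 0.849
    beta: float = 0.251

    def __post_init__(self) -> None:
        if self.role3 not in ROLE3_CHOICES:
            raise ValueError(f"role3 must be one of {ROLE3_CHOICES}")
        if not 0 <= self.t_start < self.t_end:
            raise ValueError("need 0 <= t_start < t_end")
        if not self.t_max > 0:
            raise ValueError("t_max must be positive")
        if self.t_ilum3 < 0:
            raise ValueError("t_ilum3 must be >= 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkGenome":
        return cls(**d)

    def to_json(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "NetworkGenome":
        from pathlib import Path
        return cls.from_dict(json.loads(Path(path).read_text()))

    def network(self) -> NetworkSpec:
        """All-to-all three-oscillator network with this genome's rates."""
        return NetworkSpec(n_osc=3, alpha=self.alpha, beta=self.beta)

    def integrator(self, h: float = 1e-4, store_stride: int = 100) -> IntegratorConfig:
        return IntegratorConfig(t_max=self.t_max, h=h, store_stride=store_stride)


def load_preset(name: str) -> NetworkGenome:
    """Load a packaged genome preset, e.g. ``japan_optimized`` (the published
    optimum of the Japanese-flag network)."""
    text = resources.files("oscnet").joinpath(f"presets/{name}.json").read_text()
    return NetworkGenome.from_dict(json.loads(text))


@dataclass(frozen=True)
class Record:
    """One labeled input point; g=1 means red/sun."""

    x: float
    y: float
    g: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.x <= 1 and 0 <= self.y <= 1):
            raise ValueError("coordinates must lie in [0, 1]")
        if self.g not in (0, 1):
            raise ValueError("g must be 0 or 1")


def _t_ilum_matrix(genome: NetworkGenome, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    span = genome.t_end - genome.t_start
    t = np.empty((x.size, 3))
    t[:, 0] = genome.t_start + span * x
    t[:, 1] = genome.t_start + span * y
    if genome.role3 == "normal":
        t[:, 2] = genome.t_ilum3
    elif genome.role3 == "input_x":
        t[:, 2] = genome.t_start + span * x
    else:
        t[:, 2] = genome.t_start + span * y
    return t


def encode_inputs(genome: NetworkGenome, x: float, y: float) -> IlluminationSchedule:
    """Affine encoding of a point as per-oscillator switch-off times."""
    if not (0 <= x <= 1 and 0 <= y <= 1):
        raise ValueError("coordinates must lie in [0, 1]")
    t = _t_ilum_matrix(genome, np.atleast_1d(float(x)), np.atleast_1d(float(y)))
    return IlluminationSchedule(t_ilum=t[0])


@dataclass
class ResponseTable:
    """Per-record maxima counts (o1..on) aligned with labels, plus inputs."""

    counts: np.ndarray  # (N, n_osc) non-negative ints
    g: np.ndarray       # (N,)
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.g = np.asarray(self.g, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.g.size:
            raise ValueError("counts must be (N, n_osc) with N == len(g)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.g.size

    @property
    def n_osc(self) -> int:
        return self.counts.shape[1]

    def to_frame(self, pred=None) -> pd.DataFrame:
        cols = {}
        if self.x is not None:
            cols["x"] = self.x
            cols["y"] = self.y
        cols["g"] = self.g
        for j in range(self.n_osc):
            cols[f"o{j + 1}"] = self.counts[:, j]
        df = pd.DataFrame(cols)
        if pred is not None:
            df["pred"] = np.asarray(pred, dtype=int)
        return df

    def to_csv(self, path, pred=None) -> None:
        self.to_frame(pred).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ResponseTable":
        df = pd.read_csv(path)
        osc = [c for c in df.columns if c.startswith("o") and c[1:].isdigit()]
        osc.sort(key=lambda c: int(c[1:]))
        return cls(counts=df[osc].to_numpy(), g=df["g"].to_numpy(),
                   x=df["x"].to_numpy() if "x" in df else None,
                   y=df["y"].to_numpy() if "y" in df else None)


def respond_batch(genome: NetworkGenome, dataset: LabeledDataset,
                  params: OregonatorParams = OregonatorParams(),
                  cfg: IntegratorConfig | None = None,
                  pk: PeakConfig = PeakConfig()) -> ResponseTable:
    """Simulate the network for every record and collect maxima counts.

    ``cfg`` supplies the step size and storage stride; its window must equal
    the genome's t_max (pass None to build it from the genome).  Each record
    starts from the illuminated steady state at its own phi_j(0).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if cfg is None:
        cfg = genome.integrator()
    elif abs(cfg.t_max - genome.t_max) > 1e-12:
        raise ValueError("cfg.t_max must equal genome.t_max")
    net = genome.network()
    t_il = _t_ilum_matrix(genome, dataset.x, dataset.y)
    sched_template = IlluminationSchedule(t_ilum=np.zeros(3))
    # initial state: per-oscillator steady state under phi_j(0); phi(0) only
    # depends on t_ilum through the saturating tanh, so cache by its value
    phi0 = sched_template.amp * (sched_template.offset
                                 + np.tanh(sched_template.steepness * t_il))
    u0 = np.empty_like(phi0)
    cache: dict[float, float] = {}
    for val in np.unique(phi0):
        cache[float(val)] = steady_state(float(val), params, net.alpha)[0]
    for key, ust in cache.items():
        u0[phi0 == key] = ust
    counts, status = integrate_counts(params, net, t_il, cfg, pk,
                                      u0, u0.copy(),
                                      sched_template=sched_template)
    if np.any(status != 0):
        bad = int(np.nonzero(status)[0][0])
        raise SimulationError(f"integration failed for record index {bad}")
    return ResponseTable(counts=counts, g=dataset.g,
                         x=dataset.x.copy(), y=dataset.y.copy())


def respond(genome: NetworkGenome, rec: Record,
            params: OregonatorParams = OregonatorParams(),
            cfg: IntegratorConfig | None = None,
            pk: PeakConfig = PeakConfig()) -> tuple[int, ...]:
    """Maxima counts (o1, o2, o3) of one record; deterministic."""
    ds = LabeledDataset(np.array([rec.x]), np.array([rec.y]),
                        np.array([rec.g]))
    table = respond_batch(genome, ds, params, cfg, pk)
    return tuple(int(c) for c in table.counts[0])


@dataclass
class DecisionRule:
    """Mapping from an observed maxima count to a class, with a fallback for
    counts never seen in training."""

    mapping: dict[int, int]
    fallback: int = 0

    def predict(self, counts) -> np.ndarray:
        c = np.asarray(counts, dtype=int)
        out = np.full(c.shape, self.fallback, dtype=int)
        for k, v in self.mapping.items():
            out[c == k] = v
        return out

    def to_json(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(
            {"mapping": {str(k): int(v) for k, v in self.mapping.items()},
             "fallback": int(self.fallback)}, indent=2))

    @classmethod
    def from_json(cls, path) -> "DecisionRule":
        from pathlib import Path
        d = json.loads(Path(path).read_text())
        return cls(mapping={int(k): int(v) for k, v in d["mapping"].items()},
                   fallback=int(d["fallback"]))


#: the published rule: one maximum -> sun (1), two maxima -> white (0)
MAJORITY_RULE = DecisionRule(mapping={1: 1, 2: 0}, fallback=0)


def fit_decision_rule(table: ResponseTable, osc_index: int) -> DecisionRule:
    """Majority rule: each count maps to the majority label among training
    rows showing that count; ties and unseen counts go to class 0."""
    if len(table) == 0:
        raise ValueError("response table is empty")
    o = table.counts[:, osc_index]
    mapping: dict[int, int] = {}
    for c in np.unique(o):
        sel = table.g[o == c]
        ones = int((sel == 1).sum())
        zeros = int(sel.size - ones)
        mapping[int(c)] = 1 if ones > zeros else 0
    return DecisionRule(mapping=mapping, fallback=0)


def accuracy(table: ResponseTable, rule: DecisionRule, osc_index: int) -> float:
    """Fraction of records whose predicted class equals the label."""
    pred = rule.predict(table.counts[:, osc_index])
    return float((pred == table.g).mean())
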