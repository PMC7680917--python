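"""Plug-in Shannon entropy and mutual information for count readouts.

The classifier's output symbol is a small non-negative integer (a maxima
count), so all quantities here are discrete, estimated by the plug-in
(maximum-likelihood) estimator from a contingency table, in bits.  With
N ~ 800 records and a handful of count categories the plug-in bias is
negligible, and no correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.stats import entropy as _scipy_entropy

if TYPE_CHECKING:  # pragma: no cover
    from .classifier import ResponseTable

__all__ = ["entropy", "joint_counts", "mutual_information",
           "FitnessReport", "network_fitness"]


def entropy(counts) -> float:
    """Shannon entropy, in bits, of a discrete distribution given as counts.

    H = -sum p log2 p over the nonzero cells (0 log 0 = 0).  Accepts any
    array shape; an all-zero or negative table is rejected.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if c.size == 0 or np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if c.sum() <= 0:
        raise ValueError("counts must sum to a positive total")
    return float(_scipy_entropy(c, base=2))


def joint_counts(g, o) -> np.ndarray:
    """Contingency table of two integer-valued sequences (rows: g, cols: o)."""
    g = np.asarray(g)
    o = np.asarray(o)
    if g.shape != o.shape or g.size == 0:
        raise ValueError("g and o must be equal-length and non-empty")
    gu, gi = np.unique(g, return_inverse=True)
    ou, oi = np.unique(o, return_inverse=True)
    table = np.zeros((gu.size, ou.size), dtype=np.int64)
    np.add.at(table, (gi, oi), 1)
    return table


def mutual_information(joint) -> float:
    """Mutual information I = H(G) + H(O) - H(G,O), in bits.

    ``joint`` is a 2-D contingency table of non-negative counts.  The result
    is clipped at zero to absorb the ~1e-16 negative residue of cancellation
    in the entropy differences.
    """
    j = np.asarray(joint, dtype=float)
    if j.ndim != 2:
        raise ValueError("joint must be a 2-D table")
    h_g = entropy(j.sum(axis=1))
    h_o = entropy(j.sum(axis=0))
    h_go = entropy(j)
    return max(0.0, h_g + h_o - h_go)


@dataclass(frozen=True)
class FitnessReport:
    """Per-oscillator mutual information and the selected output channel.

    ``output_index`` is 0-based (oscillator #3 of the three-oscillator
    network is index 2); ties are broken toward the lowest index.  ``fitness_bits`` is
    the maximum of ``mi_bits``.
    """

    mi_bits: tuple[float, ...]
    output_index: int
    fitness_bits: float


def network_fitness(table: "ResponseTable") -> FitnessReport:
    """MI between the labels and each oscillator's maxima counts.

    The oscillator with maximal I(G; O_j) becomes the network output and its
    MI the network fitness, the quantity the evolutionary search maximizes.
    """
    if len(table) == 0:
        raise ValueError("response table is empty")
    mis = tuple(mutual_information(joint_counts(table.g, table.counts[:, j]))
                for j in range(table.n_osc))
    best = int(np.argmax(mis))  # argmax takes the first of tied maxima
    return FitnessReport(mi_bits=mis, output_index=best,
                         fitness_bits=mis[best])
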