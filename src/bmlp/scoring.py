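"""Hypotheses over gene-function facts and their MDL-style scores.

A hypothesis is a set of ground facts ``function(gene, reaction)`` asserting
that a gene catalyses a reaction whose annotation is masked. Scoring follows
a minimum-description-length compression: small hypotheses that cover many
positives and few labelled negatives compress best, and the posterior over a
candidate set is a base-2 softmax of compressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Hypothesis",
    "LabeledExample",
    "ScoreRecord",
    "coverage_counts",
    "compression",
    "prior",
    "posterior",
    "entropy_term",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class Hypothesis:
    """A set of ``function(gene, reaction)`` facts with size = |facts|."""

    facts: frozenset[tuple[str, str]]
    id: str

    @classmethod
    def empty(cls) -> "Hypothesis":
        return cls(frozenset(), "empty")

    @classmethod
    def from_facts(cls, facts: Iterable[tuple[str, str]]) -> "Hypothesis":
        fs = frozenset((str(g), str(r)) for g, r in facts)
        if not fs:
            return cls.empty()
        hid = "+".join(f"{g}:{r}" for g, r in sorted(fs))
        return cls(fs, hid)

    @property
    def size(self) -> int:
        return len(self.facts)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.facts)


@dataclass(frozen=True)
class LabeledExample:
    """An experiment outcome: label 1 = phenotypic effect, 0 = none."""

    experiment_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")


@dataclass
class ScoreRecord:
    hypothesis_id: str
    size: int
    pc: int
    fp: int
    compression: float
    posterior: float


def coverage_counts(
    pred_row: np.ndarray,
    labels: Sequence[LabeledExample],
    experiment_index: Mapping[str, int],
) -> tuple[int, int]:
    """(pc, fp) for one hypothesis.

    pc counts positive predictions over ALL candidate experiments (labelled
    and unlabelled); fp counts labelled negatives that the row predicts
    positive.
    """
    pred_row = np.asarray(pred_row, dtype=bool)
    pc = int(pred_row.sum())
    fp = 0
    for ex in labels:
        if ex.experiment_id not in experiment_index:
            raise ValueError(f"label for unknown experiment {ex.experiment_id!r}")
        if ex.label == 0 and pred_row[experiment_index[ex.experiment_id]]:
            fp += 1
    return pc, fp


def compression(h, n_pos: int, pc: int, fp: int) -> float:
    """|E+| - (|E+|/pc) * (size(h) + fp).

    pc = 0 with positives present is a degenerate hypothesis (explains no
    positive): returns -inf so its posterior weight is 0. With no positives
    yet, every hypothesis compresses to 0.
    """
    size = h.size if hasattr(h, "size") else int(h)
    if min(n_pos, pc, fp, size) < 0:
        raise ValueError("counts must be non-negative")
    if n_pos == 0:
        return 0.0
    if pc == 0:
        return NEG_INF
    return n_pos - (n_pos / pc) * (size + fp)


def prior(h) -> float:
    """2^(-size(h)): shorter hypotheses are a-priori more probable."""
    size = h.size if hasattr(h, "size") else int(h)
    return 2.0 ** (-size)


def posterior(compressions: Sequence[float]) -> np.ndarray:
    """Base-2 softmax of compression scores (max-shifted for stability).

    -inf entries get probability 0; an all--inf input is an empty effective
    version space and raises.
    """
    c = np.asarray(compressions, dtype=float)
    if c.size == 0:
        raise ValueError("empty compression list")
    finite = np.isfinite(c)
    if not finite.any():
        raise ValueError("all compressions are -inf: empty effective version space")
    shift = c[finite].max()
    w = np.zeros_like(c)
    w[finite] = np.exp2(c[finite] - shift)
    return w / w.sum()


def entropy_term(member_posteriors: Sequence[float]) -> float:
    """-sum p*log2(p) with 0*log2(0) = 0, over (possibly a subset of) posteriors.

    Values are NOT renormalized within the subset.
    """
    total = 0.0
    for p in member_posteriors:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"posterior {p} outside [0, 1]")
        if p > 0.0:
            total -= p * math.log2(p)
    return total
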