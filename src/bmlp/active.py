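"""Cost-aware active learning over a hypothesis version space.

Predictions for every (hypothesis, experiment) pair are precomputed into a
Boolean matrix by running the reachability engine; the learner then selects
experiments minimising an expected-cost heuristic (reagent cost plus
cost-weighted residual entropy of the two outcome branches), queries an
oracle, prunes inconsistent hypotheses, and rescoring continues until the
version space is a singleton or experiments run out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import bmlp_ie
from .network import MetabolicNetwork, encode_matrices, evaluate_gpr, medium_vector
from .scoring import Hypothesis, LabeledExample, compression, entropy_term, posterior

__all__ = [
    "Experiment",
    "PredictionMatrix",
    "VersionSpace",
    "TraceStep",
    "LearningTrace",
    "prediction_matrix",
    "outcome_probability",
    "expected_cost",
    "select_experiment",
    "prune",
    "minimal_reduction_ratio",
    "run_active_learning",
    "run_random_baseline",
    "sample_complexity_ratios",
    "aggregate_complexity_curves",
    "empirical_phi",
]


@dataclass(frozen=True)
class Experiment:
    """A gene-deletion experiment with optional added nutrients and a cost."""

    id: str
    deleted: frozenset[str]
    nutrients: frozenset[str] = frozenset()
    cost: float = 0.0

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"experiment {self.id!r}: negative cost")


@dataclass
class PredictionMatrix:
    """|H| x |T| Boolean matrix: entry (i, j) = hypothesis i predicts a
    phenotypic effect for experiment j."""

    values: np.ndarray
    hypotheses: list[Hypothesis]
    experiments: list[Experiment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.hypotheses), len(self.experiments)):
            raise ValueError("prediction matrix shape mismatch")

    @property
    def experiment_index(self) -> dict[str, int]:
        return {t.id: j for j, t in enumerate(self.experiments)}


@dataclass
class VersionSpace:
    """Hypothesis list with alive flags; alive = consistent with all labels."""

    hypotheses: list[Hypothesis]
    alive: np.ndarray

    @classmethod
    def full(cls, hypotheses: Sequence[Hypothesis]) -> "VersionSpace":
        return cls(list(hypotheses), np.ones(len(hypotheses), dtype=bool))

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def alive_hypotheses(self) -> list[Hypothesis]:
        return [h for h, a in zip(self.hypotheses, self.alive) if a]


@dataclass
class TraceStep:
    step: int
    experiment_id: str
    cost: float
    label: int
    version_space_size: int
    min_reduction_ratio: float
    best_hypothesis_id: str
    best_compression: float
    cumulative_cost: float
    heldout_accuracy: float


@dataclass
class LearningTrace:
    """Per-iteration record of one learning run."""

    strategy: str
    seed: int
    steps: list[TraceStep] = field(default_factory=list)
    final_hypothesis: Hypothesis | None = None
    converged: bool = False
    total_cost: float = 0.0
    aborted: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "step",
            "strategy",
            "experiment_id",
            "cost",
            "label",
            "version_space_size",
            "min_reduction_ratio",
            "best_hypothesis_id",
            "best_compression",
            "cumulative_cost",
            "heldout_accuracy",
        ]
        rows = [
            {
                "step": s.step,
                "strategy": self.strategy,
                "experiment_id": s.experiment_id,
                "cost": s.cost,
                "label": s.label,
                "version_space_size": s.version_space_size,
                "min_reduction_ratio": s.min_reduction_ratio,
                "best_hypothesis_id": s.best_hypothesis_id,
                "best_compression": s.best_compression,
                "cumulative_cost": s.cumulative_cost,
                "heldout_accuracy": s.heldout_accuracy,
            }
            for s in self.steps
        ]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Prediction matrix
# ---------------------------------------------------------------------------


def prediction_matrix(
    network: MetabolicNetwork,
    hypotheses: Sequence[Hypothesis],
    experiments: Sequence[Experiment],
    base_medium: Iterable[str],
    essential: Iterable[str],
) -> PredictionMatrix:
    """Predict the phenotype of every (hypothesis, experiment) pair.

    Entry (i, j) = 1 iff, under hypothesis i, the mutant of experiment j
    fails to produce some essential metabolite while the undeleted strain
    (same hypothesis, same medium) produces all of them. Fixpoint results
    are memoized on (reaction mask, medium) since identical masks give
    identical producible sets.
    """
    base_medium = frozenset(base_medium)
    essential = list(essential)
    R1, R2 = encode_matrices(network)
    ess_idx = np.array([network.metabolite_index[m] for m in essential], dtype=int)

    media: dict[frozenset[str], np.ndarray] = {}

    def medium_vec(nutrients: frozenset[str]) -> np.ndarray:
        if nutrients not in media:
            media[nutrients] = medium_vector(network, base_medium | nutrients)
        return media[nutrients]

    # base activity per deletion set is hypothesis-independent; the
    # hypothesis only flips bits of the reactions its facts name.
    base_masks: dict[frozenset[str], np.ndarray] = {}

    def base_mask(deleted: frozenset[str]) -> np.ndarray:
        if deleted not in base_masks:
            for g in deleted:
                if g not in network.gene_set:
                    raise ValueError(f"unknown gene {g!r} in deletion set")
            base_masks[deleted] = np.fromiter(
                (evaluate_gpr(r.rule, deleted) for r in network.reactions),
                dtype=bool,
                count=network.n_reactions,
            )
        return base_masks[deleted]

    fact_cols = {}
    for h in hypotheses:
        cols = []
        for gene, rid in h.facts:
            if gene not in network.gene_set:
                raise ValueError(f"hypothesis {h.id!r} names unknown gene {gene!r}")
            if rid not in network.reaction_index:
                raise ValueError(f"hypothesis {h.id!r} names unknown reaction {rid!r}")
            cols.append((gene, network.reaction_index[rid]))
        fact_cols[h.id] = cols

    fails_cache: dict[tuple[bytes, frozenset[str]], bool] = {}

    def fails(mask: np.ndarray, nutrients: frozenset[str]) -> bool:
        key = (mask.tobytes(), nutrients)
        if key not in fails_cache:
            vstar = bmlp_ie(medium_vec(nutrients), R1, R2, mask).vstar
            fails_cache[key] = not bool(vstar[ess_idx].all())
        return fails_cache[key]

    values = np.zeros((len(hypotheses), len(experiments)), dtype=bool)
    for j, t in enumerate(experiments):
        bmask = base_mask(t.deleted)
        for i, h in enumerate(hypotheses):
            mut = bmask.copy()
            for gene, ridx in fact_cols[h.id]:
                if gene not in t.deleted:
                    mut[ridx] = True
            ctl = base_mask(frozenset()).copy()
            for gene, ridx in fact_cols[h.id]:
                ctl[ridx] = True
            values[i, j] = fails(mut, t.nutrients) and not fails(ctl, t.nutrients)
    return PredictionMatrix(values, list(hypotheses), list(experiments))


# ---------------------------------------------------------------------------
# Selection primitives
# ---------------------------------------------------------------------------


def outcome_probability(col: np.ndarray, posteriors: Sequence[float]) -> float:
    """p(t): posterior mass of alive hypotheses predicting a positive outcome."""
    col = np.asarray(col, dtype=bool)
    posteriors = np.asarray(posteriors, dtype=float)
    if col.shape != posteriors.shape:
        raise ValueError("column / posterior length mismatch")
    return float(posteriors[col].sum())


def expected_cost(
    t: Experiment,
    T_remaining: Sequence[Experiment],
    split: tuple[float, float, float],
) -> float:
    """C_t + p*mean_cost*J_pos + (1-p)*mean_cost*J_neg.

    `split` = (J_pos, J_neg, p_t); the mean is over the remaining candidate
    experiments excluding t itself (0 when t is the last one).
    """
    j_pos, j_neg, p_t = split
    others = [x.cost for x in T_remaining if x.id != t.id]
    mean_other = float(np.mean(others)) if others else 0.0
    return t.cost + p_t * mean_other * j_pos + (1.0 - p_t) * mean_other * j_neg


def minimal_reduction_ratio(col: np.ndarray) -> float:
    """Minority fraction of the alive set split by a column; in [0, 1/2]."""
    col = np.asarray(col, dtype=bool)
    if col.size == 0:
        raise ValueError("empty alive set")
    ones = int(col.sum())
    return min(ones, col.size - ones) / col.size


def prune(V: VersionSpace, col: np.ndarray, label: int) -> VersionSpace:
    """Keep only hypotheses whose prediction equals the observed label."""
    col = np.asarray(col, dtype=bool)
    if col.shape[0] != len(V.hypotheses):
        raise ValueError("column not aligned to version space")
    return VersionSpace(V.hypotheses, V.alive & (col == bool(label)))


def select_experiment(
    pm: PredictionMatrix,
    alive: np.ndarray,
    posteriors: np.ndarray,
    labelled: set[str],
    budget_remaining: float,
    order: Sequence[int],
) -> int | None:
    """Index of the affordable unlabelled experiment minimising expected cost.

    Vectorised over candidates: the split entropies of every column come
    from one matrix product against the -p*log2(p) vector. Ties are broken
    by the (seeded) shuffled order; None when nothing is affordable.
    `posteriors` is aligned to the alive subset.
    """
    unlab = np.array(
        [j for j in range(len(pm.experiments)) if pm.experiments[j].id not in labelled],
        dtype=int,
    )
    if unlab.size == 0:
        return None
    costs = np.array([pm.experiments[j].cost for j in unlab])
    afford = costs <= budget_remaining
    if not afford.any():
        return None
    posteriors = np.asarray(posteriors, dtype=float)
    plogp = np.where(posteriors > 0.0, -posteriors * np.log2(np.where(posteriors > 0.0, posteriors, 1.0)), 0.0)
    M = pm.values[alive][:, unlab].astype(float)
    j_pos = plogp @ M
    j_neg = plogp.sum() - j_pos
    p_t = posteriors @ M
    mean_other = (costs.sum() - costs) / (unlab.size - 1) if unlab.size > 1 else np.zeros_like(costs)
    ec = costs + p_t * mean_other * j_pos + (1.0 - p_t) * mean_other * j_neg
    rank_of = {j: r for r, j in enumerate(order)}
    ranks = np.array([rank_of[j] for j in unlab])
    ec = np.where(afford, ec, np.inf)
    best = np.lexsort((ranks, ec))[0]
    return int(unlab[best])


def _select_random(
    pm: PredictionMatrix,
    labelled: set[str],
    budget_remaining: float,
    rng: np.random.Generator,
) -> int | None:
    affordable = [
        j
        for j in range(len(pm.experiments))
        if pm.experiments[j].id not in labelled and pm.experiments[j].cost <= budget_remaining
    ]
    if not affordable:
        return None
    return int(rng.choice(affordable))


def _select_fixed_init(
    pm: PredictionMatrix,
    alive: np.ndarray,
    labelled: set[str],
    budget_remaining: float,
    order: Sequence[int],
) -> int | None:
    """Cheapest discriminative affordable experiment (fixed initialisation)."""
    rank = {j: r for r, j in enumerate(order)}
    best = None
    for j in range(len(pm.experiments)):
        t = pm.experiments[j]
        if t.id in labelled or t.cost > budget_remaining:
            continue
        if minimal_reduction_ratio(pm.values[alive, j]) <= 0.0:
            continue
        key = (t.cost, rank[j])
        if best is None or key < best[0]:
            best = (key, j)
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Learning loops
# ---------------------------------------------------------------------------


def _score_alive(
    pm: PredictionMatrix,
    alive: np.ndarray,
    labels: dict[str, int],
) -> tuple[np.ndarray, np.ndarray]:
    """(compressions, posteriors) aligned to the alive subset."""
    exp_index = pm.experiment_index
    n_pos = sum(1 for v in labels.values() if v == 1)
    neg_idx = np.array(
        [exp_index[eid] for eid, v in labels.items() if v == 0], dtype=int
    )
    rows = pm.values[alive]
    pcs = rows.sum(axis=1)
    fps = rows[:, neg_idx].sum(axis=1) if neg_idx.size else np.zeros(len(rows), dtype=int)
    alive_h = [h for h, a in zip(pm.hypotheses, alive) if a]
    comps = np.array(
        [compression(h, n_pos, int(pc), int(fp)) for h, pc, fp in zip(alive_h, pcs, fps)]
    )
    return comps, posterior(comps)


def _best_hypothesis(
    pm: PredictionMatrix, alive: np.ndarray, comps: np.ndarray
) -> tuple[int, Hypothesis, float]:
    """Argmax compression among alive; ties -> smaller size, then input order."""
    alive_idx = np.flatnonzero(alive)
    best = min(
        range(len(alive_idx)),
        key=lambda k: (-comps[k], pm.hypotheses[alive_idx[k]].size, alive_idx[k]),
    )
    gi = int(alive_idx[best])
    return gi, pm.hypotheses[gi], float(comps[best])


def _run_loop(
    pm: PredictionMatrix,
    oracle: Callable[[Experiment], int],
    *,
    strategy: str,
    budget: float,
    seed: int,
    fixed_init: bool,
) -> LearningTrace:
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(pm.experiments)))
    V = VersionSpace.full(pm.hypotheses)
    labels: dict[str, int] = {}
    label_records: list[LabeledExample] = []
    trace = LearningTrace(strategy=strategy, seed=seed)

    # held-out labels on all of T, from the oracle, for accuracy reporting
    try:
        truth = np.array([oracle(t) for t in pm.experiments], dtype=bool)
    except Exception:
        trace.aborted = True
        return trace

    spent = 0.0
    step = 0
    while V.n_alive > 1 and len(labels) < len(pm.experiments):
        comps, posts = _score_alive(pm, V.alive, labels)
        remaining_budget = budget - spent
        if strategy == "active":
            if fixed_init and step == 0:
                j = _select_fixed_init(pm, V.alive, set(labels), remaining_budget, order)
                if j is None:
                    j = select_experiment(pm, V.alive, posts, set(labels), remaining_budget, order)
            else:
                j = select_experiment(pm, V.alive, posts, set(labels), remaining_budget, order)
        else:
            j = _select_random(pm, set(labels), remaining_budget, rng)
        if j is None:
            break
        t = pm.experiments[j]
        ratio = minimal_reduction_ratio(pm.values[V.alive, j])
        try:
            label = int(oracle(t))
        except Exception:
            trace.aborted = True
            break
        V = prune(V, pm.values[:, j], label)
        labels[t.id] = label
        label_records.append(LabeledExample(t.id, label))
        spent += t.cost
        step += 1
        comps, _ = _score_alive(pm, V.alive, labels)
        gi, best, best_comp = _best_hypothesis(pm, V.alive, comps)
        accuracy = float((pm.values[gi] == truth).mean())
        trace.steps.append(
            TraceStep(
                step=step,
                experiment_id=t.id,
                cost=t.cost,
                label=label,
                version_space_size=V.n_alive,
                min_reduction_ratio=ratio,
                best_hypothesis_id=best.id,
                best_compression=best_comp,
                cumulative_cost=spent,
                heldout_accuracy=accuracy,
            )
        )

    comps, _ = _score_alive(pm, V.alive, labels)
    _, final, _ = _best_hypothesis(pm, V.alive, comps)
    trace.final_hypothesis = final
    trace.converged = V.n_alive == 1
    trace.total_cost = spent
    return trace


def run_active_learning(
    network: MetabolicNetwork,
    hypotheses: Sequence[Hypothesis],
    experiments: Sequence[Experiment],
    oracle: Callable[[Experiment], int],
    base_medium: Iterable[str],
    essential: Iterable[str],
    *,
    budget: float = math.inf,
    seed: int = 0,
    fixed_init: bool = False,
    prediction: PredictionMatrix | None = None,
) -> LearningTrace:
    """Expected-cost-driven active learning until the version space is a
    singleton, the budget is exhausted, or every experiment is labelled."""
    if not hypotheses or not experiments:
        raise ValueError("hypotheses and experiments must be non-empty")
    pm = prediction or prediction_matrix(network, hypotheses, experiments, base_medium, essential)
    return _run_loop(pm, oracle, strategy="active", budget=budget, seed=seed, fixed_init=fixed_init)


def run_random_baseline(
    network: MetabolicNetwork,
    hypotheses: Sequence[Hypothesis],
    experiments: Sequence[Experiment],
    oracle: Callable[[Experiment], int],
    base_medium: Iterable[str],
    essential: Iterable[str],
    *,
    budget: float = math.inf,
    seed: int = 0,
    prediction: PredictionMatrix | None = None,
) -> LearningTrace:
    """Same loop with uniformly random affordable experiment selection."""
    if not hypotheses or not experiments:
        raise ValueError("hypotheses and experiments must be non-empty")
    pm = prediction or prediction_matrix(network, hypotheses, experiments, base_medium, essential)
    return _run_loop(pm, oracle, strategy="random", budget=budget, seed=seed, fixed_init=False)


# ---------------------------------------------------------------------------
# Sample-complexity diagnostics
# ---------------------------------------------------------------------------


def empirical_phi(trace: LearningTrace) -> float:
    """Minimum recorded reduction ratio over the selected experiments."""
    if not trace.steps:
        raise ValueError("trace has no steps")
    return min(s.min_reduction_ratio for s in trace.steps)


def _steps_to_error(trace: LearningTrace, eps: float) -> float:
    for s in trace.steps:
        if 1.0 - s.heldout_accuracy <= eps + 1e-12:
            return float(s.step)
    return math.nan


def aggregate_complexity_curves(
    actives: Sequence[LearningTrace], passives: Sequence[LearningTrace]
) -> pd.DataFrame:
    """Median-aggregated ratio curves over many paired runs.

    Per error level (union over all traces): median first-step-to-error per
    strategy, with phi = the minimum reduction ratio any active run selected.
    """
    phi = min(empirical_phi(t) for t in actives)
    levels = sorted(
        {
            round(1.0 - s.heldout_accuracy, 12)
            for trace in (*actives, *passives)
            for s in trace.steps
        }
    )
    rows = []
    for eps in levels:
        s_a = float(np.median([_steps_to_error(t, eps) for t in actives]))
        s_p = float(np.median([_steps_to_error(t, eps) for t in passives]))
        rows.append(
            {
                "epsilon": eps,
                "phi": phi,
                "s_active": s_a,
                "s_passive": s_p,
                "ratio_active": eps / s_a if s_a == s_a else math.nan,
                "ratio_passive": (eps + phi) / s_p if s_p == s_p else math.nan,
            }
        )
    return pd.DataFrame(rows)


def sample_complexity_ratios(
    active: LearningTrace, passive: LearningTrace, phi: float
) -> pd.DataFrame:
    """Per error level eps: first steps s_active/s_passive reaching error <=
    eps and the two ratio curves eps/s_active and (eps+phi)/s_passive."""
    for trace in (active, passive):
        if not trace.steps:
            raise ValueError("trace lacks accuracy records")
    levels = sorted(
        {round(1.0 - s.heldout_accuracy, 12) for s in active.steps}
        | {round(1.0 - s.heldout_accuracy, 12) for s in passive.steps}
    )
    rows = []
    for eps in levels:
        s_a = _steps_to_error(active, eps)
        s_p = _steps_to_error(passive, eps)
        rows.append(
            {
                "epsilon": eps,
                "s_active": s_a,
                "s_passive": s_p,
                "ratio_active": eps / s_a if s_a == s_a else math.nan,
                "ratio_passive": (eps + phi) / s_p if s_p == s_p else math.nan,
            }
        )
    return pd.DataFrame(rows)
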