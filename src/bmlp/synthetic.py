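"""Seeded generator of ground-truth metabolic networks for learning tasks.

Builds a layered reaction network whose wild type produces every essential
metabolite from the base medium, with gene rules including isoenzyme (OR)
pairs. A designated reaction on an essential pathway is the masking target:
its annotation is removed from the background network and becomes the
hypothesis h* that learning must recover. Optional nutrients (existing
metabolites supplied in the medium) carry log-uniform reagent costs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .active import Experiment
from .engine import producible_set
from .network import (
    GprRule,
    MetabolicNetwork,
    Reaction,
    parse_costs,
    parse_medium,
    parse_network_tsv,
    reaction_mask,
    serialize_network_tsv,
)
from .scoring import Hypothesis

__all__ = [
    "GemParams",
    "GroundTruthGem",
    "GenerationError",
    "generate_gem",
    "mask_annotations",
    "enumerate_hypotheses",
    "enumerate_experiments",
    "oracle_label",
    "build_task",
    "LearningTask",
    "save_gem",
    "load_gem",
]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GemParams:
    n_layers: int = 3
    metabolites_per_layer: int = 4
    n_reactions: int = 16
    max_reactants: int = 2
    n_genes: int = 8
    isoenzyme_fraction: float = 0.3
    n_optional_nutrients: int = 2
    n_essential: int = 2

    def validate(self) -> None:
        if min(
            self.n_layers,
            self.metabolites_per_layer,
            self.n_reactions,
            self.max_reactants,
            self.n_genes,
            self.n_essential,
        ) < 1:
            raise GenerationError("all size parameters must be positive")
        if not 0.0 <= self.isoenzyme_fraction <= 1.0:
            raise GenerationError("isoenzyme_fraction must lie in [0, 1]")
        if self.n_optional_nutrients < 0:
            raise GenerationError("n_optional_nutrients must be >= 0")


@dataclass
class GroundTruthGem:
    """Complete network plus the learning-task metadata around it."""

    network: MetabolicNetwork
    base_medium: frozenset[str]
    nutrient_costs: dict[str, float]
    essential: list[str]
    masked_targets: list[str]
    mode: str  # 'monogenic' | 'digenic'
    seed: int
    params: GemParams = field(default_factory=GemParams)


def generate_gem(params: GemParams, seed: int) -> GroundTruthGem:
    """Generate a layered ground-truth network, deterministic under seed.

    Layer 0 metabolites form the base medium. Every metabolite in layers
    >= 1 has one backbone reaction producing it from earlier layers, so the
    wild type reaches everything. The backbone reaction of the first
    essential metabolite is the designated mask target; its genes are
    reserved (used nowhere else) so that single/double deletion phenotypes
    isolate the target annotation.
    """
    params.validate()
    rng = np.random.default_rng(seed)

    n_backbone = params.n_layers * params.metabolites_per_layer
    if params.n_reactions < n_backbone:
        raise GenerationError(
            f"n_reactions={params.n_reactions} cannot cover the "
            f"{n_backbone} backbone reactions"
        )

    digenic = params.isoenzyme_fraction > 0.0
    n_reserved = 2 if digenic else 1
    if params.n_genes < n_reserved + (0 if params.n_genes == n_reserved else 1):
        raise GenerationError("not enough genes for the reserved target rule")

    width = len(str(params.n_layers))
    mwidth = len(str(params.metabolites_per_layer - 1)) if params.metabolites_per_layer > 1 else 1
    layers: list[list[str]] = []
    for layer in range(params.n_layers + 1):
        layers.append(
            [f"m{layer:0{width}d}_{i:0{mwidth}d}" for i in range(params.metabolites_per_layer)]
        )
    metabolites = [m for layer in layers for m in layer]
    gwidth = len(str(params.n_genes - 1))
    genes = [f"g{i:0{gwidth}d}" for i in range(params.n_genes)]
    reserved = genes[params.n_genes - n_reserved :]
    pool = genes[: params.n_genes - n_reserved] or reserved

    met_idx = {m: i for i, m in enumerate(metabolites)}
    base_medium = frozenset(layers[0])

    # essential metabolites: drawn from the top layer first, then downward
    candidates: list[str] = []
    for layer in range(params.n_layers, 0, -1):
        candidates.extend(layers[layer])
    if params.n_essential > len(candidates):
        raise GenerationError("n_essential exceeds non-source metabolites")
    target_met = layers[params.n_layers][int(rng.integers(len(layers[params.n_layers])))]
    others = [m for m in candidates if m != target_met]
    extra = [others[k] for k in rng.permutation(len(others))[: params.n_essential - 1]]
    essential = [target_met] + sorted(extra, key=met_idx.get)

    def random_rule() -> GprRule:
        if len(pool) >= 2 and rng.random() < params.isoenzyme_fraction:
            a, b = rng.choice(len(pool), size=2, replace=False)
            return GprRule.or_(GprRule.leaf(pool[a]), GprRule.leaf(pool[b]))
        if len(pool) >= 2 and rng.random() < 0.5:
            a, b = rng.choice(len(pool), size=2, replace=False)
            return GprRule.and_(GprRule.leaf(pool[a]), GprRule.leaf(pool[b]))
        return GprRule.leaf(pool[int(rng.integers(len(pool)))])

    reactions: list[Reaction] = []
    target_rid: str | None = None
    for layer in range(1, params.n_layers + 1):
        earlier = [m for lv in range(layer) for m in layers[lv]]
        for mid in layers[layer]:
            k = int(rng.integers(1, min(params.max_reactants, len(earlier)) + 1))
            picks = rng.choice(len(earlier), size=k, replace=False)
            reactants = frozenset(met_idx[earlier[p]] for p in picks)
            rid = f"Rb_{mid}"
            if mid == target_met:
                target_rid = rid
                rule = (
                    GprRule.or_(GprRule.leaf(reserved[0]), GprRule.leaf(reserved[1]))
                    if digenic
                    else GprRule.leaf(reserved[0])
                )
            else:
                rule = random_rule()
            reactions.append(Reaction(rid, reactants, frozenset({met_idx[mid]}), rule))
    assert target_rid is not None

    # distractor reactions: random edges avoiding essential products so the
    # backbone stays the sole producer of every essential metabolite
    non_essential = [m for m in metabolites if m not in essential and m not in base_medium]
    n_distractors = params.n_reactions - n_backbone
    for d in range(n_distractors):
        k = int(rng.integers(1, params.max_reactants + 1))
        picks = rng.choice(len(metabolites), size=min(k, len(metabolites)), replace=False)
        reactants = frozenset(met_idx[metabolites[p]] for p in picks)
        if non_essential:
            prod = non_essential[int(rng.integers(len(non_essential)))]
        else:
            prod = metabolites[int(rng.integers(len(metabolites)))]
        rule = GprRule.spontaneous() if rng.random() < 0.1 else random_rule()
        reactions.append(Reaction(f"Rd_{d:03d}", reactants, frozenset({met_idx[prod]}), rule))

    network = MetabolicNetwork(metabolites, genes, reactions)

    # optional nutrients: the target essential first (a rescue reagent),
    # then random intermediates; log-uniform cost in [1, 100]
    nutrient_ids: list[str] = []
    if params.n_optional_nutrients >= 1:
        nutrient_ids.append(target_met)
        rest = [m for m in metabolites if m not in base_medium and m != target_met]
        picks = rng.permutation(len(rest))[: params.n_optional_nutrients - 1]
        nutrient_ids.extend(sorted((rest[p] for p in picks), key=met_idx.get))
    nutrient_costs = {
        mid: float(np.round(math.exp(rng.uniform(0.0, math.log(100.0))), 4))
        for mid in nutrient_ids
    }

    gem = GroundTruthGem(
        network=network,
        base_medium=base_medium,
        nutrient_costs=nutrient_costs,
        essential=essential,
        masked_targets=[target_rid],
        mode="digenic" if digenic else "monogenic",
        seed=seed,
        params=params,
    )
    _validate_gem(gem)
    return gem


def _validate_gem(gem: GroundTruthGem) -> None:
    mask = reaction_mask(gem.network, None, frozenset())
    produced = producible_set(gem.network, gem.base_medium, mask)
    missing = [m for m in gem.essential if m not in produced]
    if missing:
        raise GenerationError(f"wild type cannot produce essential metabolites {missing}")


# ---------------------------------------------------------------------------
# Masking and enumeration
# ---------------------------------------------------------------------------


def mask_annotations(
    gt: GroundTruthGem,
    target_reactions: list[str] | None = None,
    mode: str | None = None,
) -> tuple[MetabolicNetwork, Hypothesis]:
    """Replace target rules by UNKNOWN; h* is the removed annotation.

    monogenic: target rule must be a single gene, h* has one fact.
    digenic: target rule must be an OR of two genes, h* has two facts.
    """
    targets = gt.masked_targets if target_reactions is None else target_reactions
    mode = gt.mode if mode is None else mode
    if mode not in ("monogenic", "digenic"):
        raise ValueError(f"bad mode {mode!r}")
    net = gt.network
    facts: list[tuple[str, str]] = []
    new_reactions = list(net.reactions)
    for rid in targets:
        if rid not in net.reaction_index:
            raise ValueError(f"unknown target reaction {rid!r}")
        j = net.reaction_index[rid]
        rule = net.reactions[j].rule
        if rule.is_spontaneous or rule.is_unknown:
            raise ValueError(f"reaction {rid!r} has no gene annotation to mask")
        rule_genes = rule.genes()
        if mode == "monogenic":
            if rule.kind != "gene":
                raise ValueError(f"monogenic mask requires a single-gene rule on {rid!r}")
            facts.append((rule_genes[0], rid))
        else:
            if rule.kind != "or" or len(rule_genes) != 2:
                raise ValueError(f"digenic mask requires an OR pair rule on {rid!r}")
            facts.extend((g, rid) for g in rule_genes)
        old = new_reactions[j]
        new_reactions[j] = Reaction(old.id, old.reactants, old.products, GprRule.unknown())
    bk = MetabolicNetwork(list(net.metabolites), list(net.genes), new_reactions)
    return bk, Hypothesis.from_facts(facts)


def enumerate_hypotheses(
    masked: list[str], candidate_genes: list[str], mode: str
) -> list[Hypothesis]:
    """All candidate annotations for the masked reactions, plus the empty
    hypothesis; digenic mode adds every unordered gene pair per reaction."""
    if not candidate_genes:
        raise ValueError("candidate_genes must be non-empty")
    out = [Hypothesis.empty()]
    for rid in masked:
        for g in candidate_genes:
            out.append(Hypothesis.from_facts([(g, rid)]))
    if mode == "digenic":
        for rid in masked:
            for g1, g2 in itertools.combinations(candidate_genes, 2):
                out.append(Hypothesis.from_facts([(g1, rid), (g2, rid)]))
    elif mode != "monogenic":
        raise ValueError(f"bad mode {mode!r}")
    return out


def enumerate_experiments(
    gt: GroundTruthGem, max_deletions: int = 1, nutrient_subsets_up_to: int = 1
) -> list[Experiment]:
    """Cartesian grid: gene-deletion sets (size <= max_deletions, including
    the no-deletion control) x optional-nutrient subsets. Cost = sum of the
    added nutrients' prices normalized by the cheapest nutrient."""
    if max_deletions < 0 or nutrient_subsets_up_to < 0:
        raise ValueError("bounds must be >= 0")
    genes = list(gt.network.genes)
    nutrients = sorted(gt.nutrient_costs)
    cheapest = min(gt.nutrient_costs.values()) if gt.nutrient_costs else 1.0
    deletions = [
        frozenset(combo)
        for k in range(max_deletions + 1)
        for combo in itertools.combinations(genes, k)
    ]
    additions = [
        frozenset(combo)
        for k in range(nutrient_subsets_up_to + 1)
        for combo in itertools.combinations(nutrients, k)
    ]
    out = []
    for deleted in deletions:
        for added in additions:
            cost = sum(gt.nutrient_costs[n] / cheapest for n in added)
            did = ",".join(sorted(deleted)) or "-"
            nid = ",".join(sorted(added)) or "-"
            out.append(
                Experiment(
                    id=f"del:{did}|add:{nid}",
                    deleted=deleted,
                    nutrients=added,
                    cost=cost,
                )
            )
    return out


def oracle_label(gt: GroundTruthGem, t: Experiment) -> int:
    """Ground-truth label: 1 iff the mutant fails to produce some essential
    metabolite on base medium plus the experiment's nutrients."""
    mask = reaction_mask(gt.network, None, t.deleted)
    produced = producible_set(gt.network, gt.base_medium | t.nutrients, mask)
    return int(any(m not in produced for m in gt.essential))


@dataclass
class LearningTask:
    """Everything a learning run needs, derived from one ground-truth gem."""

    gem: GroundTruthGem
    bk: MetabolicNetwork
    hstar: Hypothesis
    hypotheses: list[Hypothesis]
    experiments: list[Experiment]
    oracle: Callable[[Experiment], int]


def build_task(
    gt: GroundTruthGem,
    max_deletions: int | None = None,
    nutrient_subsets_up_to: int = 1,
) -> LearningTask:
    """Mask the gem's target, enumerate hypotheses/experiments, bind the oracle."""
    if max_deletions is None:
        max_deletions = 2 if gt.mode == "digenic" else 1
    bk, hstar = mask_annotations(gt)
    hypotheses = enumerate_hypotheses(gt.masked_targets, list(gt.network.genes), gt.mode)
    experiments = enumerate_experiments(gt, max_deletions, nutrient_subsets_up_to)
    return LearningTask(
        gem=gt,
        bk=bk,
        hstar=hstar,
        hypotheses=hypotheses,
        experiments=experiments,
        oracle=lambda t: oracle_label(gt, t),
    )


# ---------------------------------------------------------------------------
# Bundle I/O (plain text)
# ---------------------------------------------------------------------------


def save_gem(gt: GroundTruthGem, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "network.tsv").write_text(serialize_network_tsv(gt.network))
    (outdir / "medium.txt").write_text("\n".join(sorted(gt.base_medium)) + "\n")
    (outdir / "costs.tsv").write_text(
        "".join(f"{mid}\t{cost}\n" for mid, cost in sorted(gt.nutrient_costs.items()))
    )
    manifest = {
        "seed": gt.seed,
        "params": vars(gt.params),
        "essential": gt.essential,
        "masked_targets": gt.masked_targets,
        "mode": gt.mode,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def load_gem(indir: str | Path) -> GroundTruthGem:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    return GroundTruthGem(
        network=parse_network_tsv((indir / "network.tsv").read_text()),
        base_medium=frozenset(parse_medium((indir / "medium.txt").read_text())),
        nutrient_costs=parse_costs((indir / "costs.tsv").read_text()),
        essential=list(manifest["essential"]),
        masked_targets=list(manifest["masked_targets"]),
        mode=manifest["mode"],
        seed=int(manifest["seed"]),
        params=GemParams(**manifest["params"]),
    )
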