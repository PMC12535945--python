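"""Metabolic networks with gene-reaction rules and their Boolean-matrix encoding.

A network is a list of directed reactions, each consuming a set of reactant
metabolites and producing a set of product metabolites, gated by a
gene-reaction boolean rule (OR = isoenzymes, AND = enzyme complexes).
Reactions are encoded as two Boolean matrices: a reactant matrix ``R1`` and a
product matrix ``R2``, both of shape (#reactions, #metabolites).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GprRule",
    "Reaction",
    "MetabolicNetwork",
    "NetworkParseError",
    "parse_rule",
    "parse_network_tsv",
    "serialize_network_tsv",
    "import_bigg_json",
    "evaluate_gpr",
    "reaction_mask",
    "encode_matrices",
    "decode_matrices",
    "medium_vector",
    "parse_medium",
    "parse_costs",
]


class NetworkParseError(ValueError):
    """Raised for malformed network text inputs; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Gene-reaction rules
# ---------------------------------------------------------------------------

_SPONT = "spontaneous"
_UNKNOWN = "unknown"
_GENE = "gene"
_AND = "and"
_OR = "or"


@dataclass(frozen=True)
class GprRule:
    """Expression tree over genes with AND/OR internal nodes.

    Two distinguished leaves exist besides genes: SPONTANEOUS (reaction
    requires no enzyme, always active) and UNKNOWN (catalysis is masked;
    inactive unless a hypothesis supplies a gene).
    """

    kind: str
    gene: str | None = None
    children: tuple["GprRule", ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (_SPONT, _UNKNOWN, _GENE, _AND, _OR):
            raise ValueError(f"bad rule kind {self.kind!r}")
        if self.kind == _GENE and not self.gene:
            raise ValueError("gene leaf requires a gene id")
        if self.kind in (_AND, _OR) and len(self.children) < 2:
            raise ValueError(f"{self.kind} node requires >=2 children")

    # -- constructors ------------------------------------------------------
    @classmethod
    def leaf(cls, gene: str) -> "GprRule":
        return cls(_GENE, gene=gene)

    @classmethod
    def and_(cls, *children: "GprRule") -> "GprRule":
        return cls(_AND, children=tuple(children))

    @classmethod
    def or_(cls, *children: "GprRule") -> "GprRule":
        return cls(_OR, children=tuple(children))

    @classmethod
    def spontaneous(cls) -> "GprRule":
        return cls(_SPONT)

    @classmethod
    def unknown(cls) -> "GprRule":
        return cls(_UNKNOWN)

    # -- predicates --------------------------------------------------------
    @property
    def is_spontaneous(self) -> bool:
        return self.kind == _SPONT

    @property
    def is_unknown(self) -> bool:
        return self.kind == _UNKNOWN

    def genes(self) -> list[str]:
        """All gene ids appearing in the rule, in left-to-right order."""
        if self.kind == _GENE:
            return [self.gene]  # type: ignore[list-item]
        out: list[str] = []
        for child in self.children:
            out.extend(child.genes())
        return out

    def evaluate(self, deleted: Iterable[str]) -> bool:
        return evaluate_gpr(self, deleted)

    def to_string(self) -> str:
        if self.kind == _SPONT:
            return ""
        if self.kind == _UNKNOWN:
            return "?"
        if self.kind == _GENE:
            return self.gene  # type: ignore[return-value]
        parts = []
        for child in self.children:
            s = child.to_string()
            # 'and' binds tighter than 'or': parenthesise OR under AND
            if self.kind == _AND and child.kind == _OR:
                s = f"({s})"
            parts.append(s)
        return f" {self.kind} ".join(parts)


def evaluate_gpr(rule: GprRule, deleted: Iterable[str]) -> bool:
    """Evaluate a rule under a set of deleted genes.

    SPONTANEOUS is always true; UNKNOWN is always false (a masked reaction
    with no hypothesised gene has no enzyme).
    """
    deleted = deleted if isinstance(deleted, (set, frozenset)) else set(deleted)
    return _eval(rule, deleted)


def _eval(rule: GprRule, deleted: set[str] | frozenset[str]) -> bool:
    if rule.kind == _SPONT:
        return True
    if rule.kind == _UNKNOWN:
        return False
    if rule.kind == _GENE:
        return rule.gene not in deleted
    if rule.kind == _AND:
        return all(_eval(c, deleted) for c in rule.children)
    return any(_eval(c, deleted) for c in rule.children)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_rule(text: str) -> GprRule:
    """Parse a rule string: ``expr := term (" or " term)*``,
    ``term := atom (" and " atom)*``, atoms are gene ids, parenthesised
    expressions, ``""`` (SPONTANEOUS) or ``"?"`` (UNKNOWN)."""
    text = text.strip()
    if text == "":
        return GprRule.spontaneous()
    if text == "?":
        return GprRule.unknown()
    tokens = _TOKEN_RE.findall(text)
    rule, pos = _parse_expr(tokens, 0)
    if pos != len(tokens):
        raise NetworkParseError(f"unexpected token {tokens[pos]!r} in rule {text!r}")
    return rule


def _parse_expr(tokens: list[str], pos: int) -> tuple[GprRule, int]:
    terms = []
    term, pos = _parse_term(tokens, pos)
    terms.append(term)
    while pos < len(tokens) and tokens[pos].lower() == "or":
        term, pos = _parse_term(tokens, pos + 1)
        terms.append(term)
    return (terms[0] if len(terms) == 1 else GprRule.or_(*terms)), pos


def _parse_term(tokens: list[str], pos: int) -> tuple[GprRule, int]:
    atoms = []
    atom, pos = _parse_atom(tokens, pos)
    atoms.append(atom)
    while pos < len(tokens) and tokens[pos].lower() == "and":
        atom, pos = _parse_atom(tokens, pos + 1)
        atoms.append(atom)
    return (atoms[0] if len(atoms) == 1 else GprRule.and_(*atoms)), pos


def _parse_atom(tokens: list[str], pos: int) -> tuple[GprRule, int]:
    if pos >= len(tokens):
        raise NetworkParseError("unexpected end of rule")
    tok = tokens[pos]
    if tok == "(":
        expr, pos = _parse_expr(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise NetworkParseError("missing ')' in rule")
        return expr, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise NetworkParseError(f"unexpected token {tok!r} in rule")
    if tok == "?":
        return GprRule.unknown(), pos + 1
    return GprRule.leaf(tok), pos + 1


# ---------------------------------------------------------------------------
# Network types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """A directed reaction: reactant indices -> product indices, gated by a rule."""

    id: str
    reactants: frozenset[int]
    products: frozenset[int]
    rule: GprRule

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError(f"reaction {self.id!r} has no products")


@dataclass
class MetabolicNetwork:
    """Ordered metabolites, genes and reactions; index i <-> id bijection."""

    metabolites: list[str]
    genes: list[str]
    reactions: list[Reaction]
    metabolite_index: dict[str, int] = field(init=False, repr=False)
    gene_set: frozenset[str] = field(init=False, repr=False)
    reaction_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.metabolites)) != len(self.metabolites):
            raise ValueError("duplicate metabolite id")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene id")
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction id")
        self.metabolite_index = {m: i for i, m in enumerate(self.metabolites)}
        self.gene_set = frozenset(self.genes)
        self.reaction_index = {r.id: j for j, r in enumerate(self.reactions)}
        n = len(self.metabolites)
        for r in self.reactions:
            for i in r.reactants | r.products:
                if not (0 <= i < n):
                    raise ValueError(f"reaction {r.id!r}: metabolite index {i} out of range")
            for g in r.rule.genes():
                if g not in self.gene_set:
                    raise ValueError(f"reaction {r.id!r}: unknown gene {g!r}")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite_ids(self, indices: Iterable[int]) -> list[str]:
        return [self.metabolites[i] for i in sorted(indices)]


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------


def _split_ids(fieldtext: str) -> list[str]:
    fieldtext = fieldtext.strip()
    if not fieldtext:
        return []
    return [tok.strip() for tok in fieldtext.split(",")]


def parse_network_tsv(text: str) -> MetabolicNetwork:
    """Parse the 4-column network TSV dialect.

    Columns: reaction id, comma-separated reactants, comma-separated
    products, rule string. Metabolite and gene orderings follow first
    appearance. Lines starting with '#' and blank lines are skipped.
    """
    metabolites: list[str] = []
    met_idx: dict[str, int] = {}
    genes: list[str] = []
    gene_seen: set[str] = set()
    reactions: list[Reaction] = []
    seen_rids: set[str] = set()

    def met(mid: str) -> int:
        if mid not in met_idx:
            met_idx[mid] = len(metabolites)
            metabolites.append(mid)
        return met_idx[mid]

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise NetworkParseError(
                f"expected 4 tab-separated fields, got {len(parts)}", line=lineno
            )
        rid, reac_field, prod_field, rule_field = parts
        rid = rid.strip()
        if not rid:
            raise NetworkParseError("empty reaction id", line=lineno)
        if rid in seen_rids:
            raise NetworkParseError(f"duplicate reaction id {rid!r}", line=lineno)
        seen_rids.add(rid)
        reactants = frozenset(met(m) for m in _split_ids(reac_field))
        products = frozenset(met(m) for m in _split_ids(prod_field))
        if not products:
            raise NetworkParseError(f"reaction {rid!r} has no products", line=lineno)
        try:
            rule = parse_rule(rule_field)
        except NetworkParseError as exc:
            raise NetworkParseError(str(exc), line=lineno) from exc
        for g in rule.genes():
            if g not in gene_seen:
                gene_seen.add(g)
                genes.append(g)
        reactions.append(Reaction(rid, reactants, products, rule))
    return MetabolicNetwork(metabolites, genes, reactions)


def serialize_network_tsv(network: MetabolicNetwork) -> str:
    """Inverse of :func:`parse_network_tsv` up to gene-list ordering."""
    lines = []
    for r in network.reactions:
        reac = ",".join(network.metabolites[i] for i in sorted(r.reactants))
        prod = ",".join(network.metabolites[i] for i in sorted(r.products))
        lines.append(f"{r.id}\t{reac}\t{prod}\t{r.rule.to_string()}")
    return "\n".join(lines) + "\n"


def import_bigg_json(document: Mapping) -> MetabolicNetwork:
    """Import a BiGG-style GEM JSON document.

    Negative-coefficient metabolites become reactants, positive become
    products. A reaction with a negative lower flux bound is split into
    forward/reverse directed reactions (ids suffixed ``_fwd``/``_rev``)
    sharing the same rule. Empty gene_reaction_rule means SPONTANEOUS.
    Directed reactions with no products (pure sinks) are dropped.
    """
    for key in ("metabolites", "reactions"):
        if key not in document:
            raise NetworkParseError(f"GEM JSON missing required key {key!r}")
    metabolites = [m["id"] for m in document["metabolites"]]
    met_idx = {m: i for i, m in enumerate(metabolites)}
    genes: list[str] = [g["id"] for g in document.get("genes", [])]
    gene_seen = set(genes)
    reactions: list[Reaction] = []
    for entry in document["reactions"]:
        for key in ("id", "metabolites"):
            if key not in entry:
                raise NetworkParseError(f"GEM reaction missing required key {key!r}")
        rid = entry["id"]
        rule = parse_rule(entry.get("gene_reaction_rule", ""))
        for g in rule.genes():
            if g not in gene_seen:
                gene_seen.add(g)
                genes.append(g)
        reactants, products = set(), set()
        for mid, coeff in entry["metabolites"].items():
            if mid not in met_idx:
                raise NetworkParseError(f"reaction {rid!r}: unknown metabolite {mid!r}")
            if coeff < 0:
                reactants.add(met_idx[mid])
            elif coeff > 0:
                products.add(met_idx[mid])
        lb = entry.get("lower_bound", 0.0)
        ub = entry.get("upper_bound", 1000.0)
        forward = ub > 0 and bool(products)
        reverse = lb < 0 and bool(reactants)
        if forward and reverse:
            reactions.append(Reaction(rid + "_fwd", frozenset(reactants), frozenset(products), rule))
            reactions.append(Reaction(rid + "_rev", frozenset(products), frozenset(reactants), rule))
        elif forward:
            reactions.append(Reaction(rid, frozenset(reactants), frozenset(products), rule))
        elif reverse:
            reactions.append(Reaction(rid, frozenset(products), frozenset(reactants), rule))
    return MetabolicNetwork(metabolites, genes, reactions)


# ---------------------------------------------------------------------------
# Boolean encodings
# ---------------------------------------------------------------------------


def encode_matrices(network: MetabolicNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Return (R1, R2): reactant and product matrices, shape (#reactions, #metabolites)."""
    r, m = network.n_reactions, network.n_metabolites
    R1 = np.zeros((r, m), dtype=bool)
    R2 = np.zeros((r, m), dtype=bool)
    for j, reaction in enumerate(network.reactions):
        for i in reaction.reactants:
            R1[j, i] = True
        for i in reaction.products:
            R2[j, i] = True
    return R1, R2


def decode_matrices(R1: np.ndarray, R2: np.ndarray) -> list[tuple[frozenset[int], frozenset[int]]]:
    """Recover per-reaction (reactant, product) index sets from (R1, R2)."""
    if R1.shape != R2.shape:
        raise ValueError("R1/R2 shape mismatch")
    return [
        (frozenset(np.flatnonzero(R1[j]).tolist()), frozenset(np.flatnonzero(R2[j]).tolist()))
        for j in range(R1.shape[0])
    ]


def _hypothesis_facts(hypothesis) -> Iterator[tuple[str, str]]:
    if hypothesis is None:
        return iter(())
    facts = getattr(hypothesis, "facts", hypothesis)
    return iter(facts)


def reaction_mask(network: MetabolicNetwork, hypothesis, deleted: Iterable[str]) -> np.ndarray:
    """Boolean vector over reactions: active under `deleted` given `hypothesis`.

    Reaction j is active iff its rule evaluates true under the deletions, OR
    the hypothesis contains a fact ``function(g, j)`` with g not deleted.
    `hypothesis` is None, an iterable of (gene, reaction_id) pairs, or an
    object with a ``facts`` attribute of such pairs.
    """
    deleted = frozenset(deleted)
    for g in deleted:
        if g not in network.gene_set:
            raise ValueError(f"unknown gene {g!r} in deletion set")
    mask = np.fromiter(
        (evaluate_gpr(r.rule, deleted) for r in network.reactions),
        dtype=bool,
        count=network.n_reactions,
    )
    for gene, rid in _hypothesis_facts(hypothesis):
        if gene not in network.gene_set:
            raise ValueError(f"hypothesis names unknown gene {gene!r}")
        if rid not in network.reaction_index:
            raise ValueError(f"hypothesis names unknown reaction {rid!r}")
        if gene not in deleted:
            mask[network.reaction_index[rid]] = True
    return mask


def medium_vector(network: MetabolicNetwork, medium: Iterable[str]) -> np.ndarray:
    """Boolean vector over metabolites marking the growth-medium members."""
    v = np.zeros(network.n_metabolites, dtype=bool)
    for mid in medium:
        if mid not in network.metabolite_index:
            raise ValueError(f"unknown metabolite {mid!r}")
        v[network.metabolite_index[mid]] = True
    return v


# ---------------------------------------------------------------------------
# Auxiliary plain-text inputs
# ---------------------------------------------------------------------------


def parse_medium(text: str) -> list[str]:
    """Medium file: one metabolite id per line; '#' comments allowed."""
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def parse_costs(text: str) -> dict[str, float]:
    """Cost TSV: ``nutrient_id <TAB> cost`` per line, cost >= 0."""
    costs: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkParseError("expected 2 tab-separated fields", line=lineno)
        value = float(parts[1])
        if value < 0:
            raise NetworkParseError(f"negative cost for {parts[0]!r}", line=lineno)
        costs[parts[0]] = value
    return costs
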