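"""Boolean-matrix kernels, transitive closure, and the iterative-extension fixpoint.

The engine answers reachability queries over a reaction network by pure
Boolean matrix arithmetic (elementwise OR, Boolean product, equality test).
The iterative-extension fixpoint starts from a source-metabolite vector and
repeatedly fires every enabled reaction whose reactants are all available,
until the producible set stops growing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .network import MetabolicNetwork, encode_matrices, medium_vector

__all__ = [
    "bool_elementwise",
    "bool_mul",
    "transitive_closure",
    "FixpointTrace",
    "bmlp_ie",
    "forward_chain_oracle",
]


def _as_bool(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.dtype != bool:
        if not np.isin(a, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        a = a.astype(bool)
    return a


def bool_elementwise(kind: str, A: np.ndarray, B: np.ndarray | None = None):
    """Elementwise Boolean kernels: ADD (OR), NOT (complement), EQ (all-equal)."""
    A = _as_bool(A)
    if kind == "NOT":
        return ~A
    if B is None:
        raise ValueError(f"{kind} requires two operands")
    B = _as_bool(B)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if kind == "ADD":
        return A | B
    if kind == "EQ":
        return bool(np.array_equal(A, B))
    raise ValueError(f"unknown kernel kind {kind!r}")


def bool_mul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Boolean matrix product: (AB)_{ik} = OR_j (A_ij AND B_jk)."""
    A, B = _as_bool(A), _as_bool(B)
    a2 = A[None, :] if A.ndim == 1 else A
    b2 = B[:, None] if B.ndim == 1 else B
    if a2.shape[-1] != b2.shape[0]:
        raise ValueError(f"inner dimensions disagree: {A.shape} x {B.shape}")
    out = (a2.astype(np.uint8) @ b2.astype(np.uint8)) > 0
    if A.ndim == 1:
        out = out[0]
    if B.ndim == 1:
        out = out[..., 0]
    return out


def transitive_closure(R: np.ndarray, square: bool = False) -> np.ndarray:
    """Transitive closure R+ of a square Boolean relation (>=1 step paths).

    ``square=True`` uses repeated squaring (T <- T OR T.T); otherwise a
    linear sweep (T <- T OR T.R). Both converge to the same fixpoint.
    """
    R = _as_bool(R)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"closure requires a square matrix, got {R.shape}")
    T = R.copy()
    while True:
        step = bool_mul(T, T) if square else bool_mul(T, R)
        T_next = T | step
        if bool_elementwise("EQ", T_next, T):
            return T_next
        T = T_next


@dataclass
class FixpointTrace:
    """The monotone vector sequence v_0 <= v_1 <= ... <= v_K of a fixpoint run."""

    vectors: list[np.ndarray]

    @property
    def iterations(self) -> int:
        return len(self.vectors) - 1

    @property
    def vstar(self) -> np.ndarray:
        return self.vectors[-1]


def bmlp_ie(
    v0: np.ndarray, R1: np.ndarray, R2: np.ndarray, mask: np.ndarray
) -> FixpointTrace:
    """Iterative extension: grow the producible-metabolite vector to fixpoint.

    Each round: a reaction is *blocked* iff it has a reactant outside the
    current vector (one Boolean product against the complement), *enabled*
    iff unblocked and mask-on; products of enabled reactions are OR-ed in.
    Stops when two successive vectors are equal; at most n+1 rounds for n
    metabolites (each round adds a metabolite or terminates).
    """
    v0, R1, R2, mask = _as_bool(v0), _as_bool(R1), _as_bool(R2), _as_bool(mask)
    n = v0.shape[0]
    if R1.shape != R2.shape or R1.shape[1] != n or mask.shape[0] != R1.shape[0]:
        raise ValueError(
            f"dimension mismatch: v0 {v0.shape}, R1 {R1.shape}, R2 {R2.shape}, mask {mask.shape}"
        )
    trace = [v0]
    v = v0
    for _ in range(n + 1):
        blocked = bool_mul(R1, ~v)
        enabled = mask & ~blocked
        produced = bool_mul(R2.T, enabled)
        v_next = bool_elementwise("ADD", v, produced)
        trace.append(v_next)
        if bool_elementwise("EQ", v_next, v):
            return FixpointTrace(trace)
        v = v_next
    raise RuntimeError("fixpoint not reached within n+1 iterations (internal error)")


def forward_chain_oracle(
    network: MetabolicNetwork, medium: Iterable[str], mask: np.ndarray
) -> set[str]:
    """Reference semantics: naive saturation over metabolite-id sets.

    Repeatedly fires any mask-active reaction whose reactant set is within
    the current set, adding products, until no change. Independent of the
    matrix engine; used as the testing oracle.
    """
    mask = _as_bool(mask)
    have = {network.metabolite_index[m] for m in medium}
    changed = True
    while changed:
        changed = False
        for j, reaction in enumerate(network.reactions):
            if not mask[j]:
                continue
            if reaction.reactants <= have and not reaction.products <= have:
                have |= reaction.products
                changed = True
    return {network.metabolites[i] for i in have}


def producible_set(
    network: MetabolicNetwork, medium: Iterable[str], mask: np.ndarray
) -> set[str]:
    """Convenience wrapper: run the fixpoint and return metabolite ids."""
    R1, R2 = encode_matrices(network)
    v0 = medium_vector(network, medium)
    vstar = bmlp_ie(v0, R1, R2, mask).vstar
    return {network.metabolites[i] for i in np.flatnonzero(vstar)}
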