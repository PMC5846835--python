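"""Exhaustive enumeration of degeneracy-preserving alternative genetic codes.

An alternative code is obtained by applying one bijection of {A,C,G,T} at each
of the three codon positions and reading labels off the base code:

    new_code(b1, b2, b3) = base_code(pi1(b1), pi2(b2), pi3(b3))

There are 24 bijections per position, hence 24**3 = 13,824 permutation
triples; excluding the identity triple leaves 13,823 alternatives.  Triples
are counted as triples (not deduplicated by resulting codon map): each triple
yields a distinct position-wise codon bijection, and per-label degeneracy is
preserved by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterator, List, Tuple

import numpy as np

from .code_tables import ALL_CODONS, BASES, GeneticCode

#: The 24 permutations of (A,C,G,T), in ``itertools.permutations`` order; the
#: identity permutation is first.
BASE_PERMUTATIONS: Tuple[Tuple[str, str, str, str], ...] = tuple(
    itertools.permutations(BASES)
)

N_TRIPLES = len(BASE_PERMUTATIONS) ** 3  # 13,824
N_ALTERNATIVES = N_TRIPLES - 1  # 13,823


@dataclass(frozen=True)
class BasePermutationTriple:
    """One bijection of {A,C,G,T} per codon position."""

    pi1: Tuple[str, str, str, str]
    pi2: Tuple[str, str, str, str]
    pi3: Tuple[str, str, str, str]

    @property
    def is_identity(self) -> bool:
        return self.pi1 == BASES and self.pi2 == BASES and self.pi3 == BASES

    def apply(self, codon: str) -> str:
        """Image of ``codon`` under the position-wise permutations."""
        maps = (
            dict(zip(BASES, self.pi1)),
            dict(zip(BASES, self.pi2)),
            dict(zip(BASES, self.pi3)),
        )
        return "".join(maps[i][b] for i, b in enumerate(codon))

    def inverse(self) -> "BasePermutationTriple":
        def inv(pi: Tuple[str, ...]) -> Tuple[str, str, str, str]:
            m = dict(zip(pi, BASES))
            return tuple(m[b] for b in BASES)  # type: ignore[return-value]

        return BasePermutationTriple(inv(self.pi1), inv(self.pi2), inv(self.pi3))


def enumerate_triples() -> Iterator[BasePermutationTriple]:
    """All 13,824 permutation triples in a stable order, identity first.

    The order is the triple product of ``itertools.permutations`` order with
    the position-3 permutation varying fastest; because the identity
    permutation sorts first, the identity triple is the first element.
    """
    for pi1, pi2, pi3 in itertools.product(BASE_PERMUTATIONS, repeat=3):
        yield BasePermutationTriple(pi1, pi2, pi3)


def build_code(triple: BasePermutationTriple, base_code: GeneticCode) -> GeneticCode:
    """The alternative code induced by ``triple`` over ``base_code``."""
    assignment = {
        codon: base_code.translate(triple.apply(codon)) for codon in ALL_CODONS
    }
    tag = "identity" if triple.is_identity else "alt"
    return GeneticCode(assignment, name=f"{base_code.name}:{tag}")


# --------------------------------------------------------------------------
# Vectorized form: codon-index permutation matrix for the whole ensemble
# --------------------------------------------------------------------------

_PERM_IDX = np.array(
    [[BASES.index(b) for b in pi] for pi in BASE_PERMUTATIONS], dtype=np.int64
)  # (24, 4): _PERM_IDX[k, i] = index of pi_k(base_i)


def codon_permutation_matrix(triple_slice: slice | None = None) -> np.ndarray:
    """Codon-index maps for (a slice of) the 13,824 triples.

    Returns an ``(n_triples, 64)`` int16 array ``P`` with
    ``P[k, codon] = codon_index(pi1(b1), pi2(b2), pi3(b3))`` — i.e. row ``k``
    is the codon cube bijection of triple ``k`` in ``enumerate_triples``
    order.  ``triple_slice`` selects a contiguous block of triples so callers
    can stream the ensemble with bounded memory.
    """
    start, stop, _ = (triple_slice or slice(0, N_TRIPLES)).indices(N_TRIPLES)
    ks = np.arange(start, stop, dtype=np.int64)
    k1, rem = np.divmod(ks, 24 * 24)
    k2, k3 = np.divmod(rem, 24)

    b1, r = np.divmod(np.arange(64), 16)
    b2, b3 = np.divmod(r, 4)
    p1 = _PERM_IDX[k1][:, b1]  # (n, 64)
    p2 = _PERM_IDX[k2][:, b2]
    p3 = _PERM_IDX[k3][:, b3]
    return (16 * p1 + 4 * p2 + p3).astype(np.int16)
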