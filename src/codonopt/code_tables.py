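"""Canonical genetic code, codon arithmetic, and single-base transition bookkeeping.

Codons are 3-letter strings over the DNA alphabet ``ACGT`` (``U`` is accepted on
input and normalized to ``T`` so that DNA and RNA share one codon space).  The
64 codons are indexed lexicographically in ``ACGT`` order; that fixed indexing
is what the vectorized ensemble machinery in :mod:`codonopt.optimization_test`
relies on.

A :class:`GeneticCode` maps every codon to one of 21 labels (20 amino acids
plus ``STOP``).  ``STOP`` is treated as an ordinary 21st label with degeneracy
3: a stop-to-stop substitution is synonymous, and a stop/amino-acid swap is
nonsynonymous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np

BASES: Tuple[str, str, str, str] = ("A", "C", "G", "T")
BASE_INDEX: Dict[str, int] = {b: i for i, b in enumerate(BASES)}
COMPLEMENT: Dict[str, str] = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: All 64 codons in lexicographic ACGT order; position in this tuple is the
#: codon's integer index used throughout the package.
ALL_CODONS: Tuple[str, ...] = tuple(
    "".join(bases) for bases in itertools.product(BASES, repeat=3)
)
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(ALL_CODONS)}

STOP_LABEL = "STOP"


class CodonError(ValueError):
    """Raised for malformed codons or malformed code tables."""


def normalize_codon(codon: str) -> str:
    """Validate ``codon`` and return its canonical DNA form (U -> T, uppercase).

    Raises
    ------
    CodonError
        If the input is not exactly three characters of ``ACGTU``.
    """
    if not isinstance(codon, str):
        raise CodonError(f"codon must be a string, got {type(codon).__name__}")
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in BASE_INDEX for b in c):
        raise CodonError(f"invalid codon {codon!r}: expected 3 bases from A/C/G/T/U")
    return c


def codon_to_index(codon: str) -> int:
    """Integer index (0..63) of a codon in the fixed lexicographic order."""
    return CODON_INDEX[normalize_codon(codon)]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, read 5'->3'."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper().replace("U", "T")))
    except KeyError as exc:  # pragma: no cover - defensive
        raise CodonError(f"invalid base {exc.args[0]!r} in {seq!r}") from exc


def gc_count(codon: str) -> int:
    """Number of G or C bases in the codon (0..3)."""
    c = normalize_codon(codon)
    return sum(1 for b in c if b in "GC")


@dataclass(frozen=True)
class GeneticCode:
    """A complete assignment of the 64 codons to 21 labels.

    Parameters
    ----------
    assignment
        Mapping from codon string to label.  Must cover all 64 codons.
    name
        Free-text identifier recorded in outputs.
    """

    assignment: Mapping[str, str]
    name: str = "unnamed"
    # label array in codon-index order, for vectorized work
    _labels: Tuple[str, ...] = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        normalized = {normalize_codon(c): str(lab) for c, lab in self.assignment.items()}
        if len(normalized) != 64:
            missing = sorted(set(ALL_CODONS) - set(normalized))
            raise CodonError(
                f"genetic code {self.name!r} must assign all 64 codons; "
                f"missing {len(missing)}: {missing[:5]}..."
            )
        object.__setattr__(self, "assignment", normalized)
        object.__setattr__(
            self, "_labels", tuple(normalized[c] for c in ALL_CODONS)
        )

    def translate(self, codon: str) -> str:
        """Label assigned to ``codon`` (raises :class:`CodonError` if invalid)."""
        return self._labels[codon_to_index(codon)]

    def labels(self) -> Tuple[str, ...]:
        """Labels for all 64 codons in codon-index order."""
        return self._labels

    def label_codes(self, label_order: Tuple[str, ...] | None = None) -> np.ndarray:
        """Labels encoded as small integers, suitable for vectorized comparison."""
        if label_order is None:
            label_order = tuple(sorted(set(self._labels)))
        lut = {lab: i for i, lab in enumerate(label_order)}
        return np.array([lut[lab] for lab in self._labels], dtype=np.int8)

    def degeneracy(self) -> Dict[str, int]:
        """Count of codons per label."""
        out: Dict[str, int] = {}
        for lab in self._labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    def to_table(self, path: str | Path) -> None:
        """Write the code in the packaged two-column text format."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# Genetic code table: {self.name}\n")
            for codon in ALL_CODONS:
                fh.write(f"{codon}\t{self.assignment[codon]}\n")


def load_code_table(path: str | Path, name: str | None = None) -> GeneticCode:
    """Load a genetic code from a two-column ``codon<TAB>label`` text file.

    Lines starting with ``#`` and blank lines are ignored.
    """
    path = Path(path)
    assignment: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise CodonError(f"{path}:{lineno}: expected 'codon<TAB>label', got {line!r}")
            codon, label = parts
            codon = normalize_codon(codon)
            if codon in assignment:
                raise CodonError(f"{path}:{lineno}: duplicate codon {codon}")
            assignment[codon] = label
    return GeneticCode(assignment, name=name or path.stem)


def standard_code() -> GeneticCode:
    """The canonical (standard) genetic code, loaded from the packaged table."""
    ref = resources.files("codonopt").joinpath("data/standard_code.tsv")
    with resources.as_file(ref) as path:
        return load_code_table(path, name="standard")


# --------------------------------------------------------------------------
# Transitions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonTransition:
    """A directed single-base substitution between two codons.

    ``position`` is 1-based (1..3).  Coding/strand classes are not stored on
    the transition because they depend on the genetic code in force; use
    :func:`classify_transition` / :func:`strand_classify`.
    """

    from_codon: str
    to_codon: str
    position: int

    def __post_init__(self) -> None:
        f = normalize_codon(self.from_codon)
        t = normalize_codon(self.to_codon)
        object.__setattr__(self, "from_codon", f)
        object.__setattr__(self, "to_codon", t)
        diff = [i for i in range(3) if f[i] != t[i]]
        if diff != [self.position - 1]:
            raise CodonError(
                f"transition {f}->{t} must differ exactly at position {self.position}"
            )

    def reversed(self) -> "CodonTransition":
        return CodonTransition(self.to_codon, self.from_codon, self.position)

    def complement(self) -> "CodonTransition":
        """The induced substitution on the complementary strand.

        The complementary codon is the reverse complement of the codon itself,
        read 5'->3'; a substitution at position p maps to position 4-p.
        """
        return CodonTransition(
            reverse_complement(self.from_codon),
            reverse_complement(self.to_codon),
            4 - self.position,
        )


def enumerate_transitions() -> List[CodonTransition]:
    """All 576 directed single-base codon substitutions, in a stable order.

    Ordered by from-codon index, then position, then target base.
    """
    out: List[CodonTransition] = []
    for codon in ALL_CODONS:
        for pos in range(3):
            for b in BASES:
                if b != codon[pos]:
                    to = codon[:pos] + b + codon[pos + 1:]
                    out.append(CodonTransition(codon, to, pos + 1))
    return out


def classify_transition(t: CodonTransition, code: GeneticCode) -> str:
    """``"S"`` if both codons share a label under ``code``, else ``"N"``."""
    return "S" if code.translate(t.from_codon) == code.translate(t.to_codon) else "N"


def strand_classify(t: CodonTransition, code: GeneticCode) -> str:
    """Joint coding/complementary-strand class: ``"SS"``, ``"NN"`` or ``"SN"``.

    The coding-strand substitution and the induced reverse-complement
    substitution are each classified synonymous/nonsynonymous under the same
    code; mixed outcomes pool to ``"SN"`` regardless of order.
    """
    a = classify_transition(t, code)
    b = classify_transition(t.complement(), code)
    if a == b == "S":
        return "SS"
    if a == b == "N":
        return "NN"
    return "SN"


# --------------------------------------------------------------------------
# Vectorized transition index arrays (used by impact/ensemble machinery)
# --------------------------------------------------------------------------

def transition_index_arrays() -> Dict[str, np.ndarray]:
    """Codon-index views of the 576 transitions.

    Returns a dict with int arrays of length 576:

    ``from_idx`` / ``to_idx``
        codon indices of the substitution endpoints;
    ``rc_from_idx`` / ``rc_to_idx``
        codon indices of the reverse-complement endpoints;
    ``position``
        1-based substitution position;
    ``reverse_perm``
        index of each transition's reversal within the enumeration order.
    """
    trans = enumerate_transitions()
    from_idx = np.array([CODON_INDEX[t.from_codon] for t in trans], dtype=np.int64)
    to_idx = np.array([CODON_INDEX[t.to_codon] for t in trans], dtype=np.int64)
    rc_from = np.array(
        [CODON_INDEX[reverse_complement(t.from_codon)] for t in trans], dtype=np.int64
    )
    rc_to = np.array(
        [CODON_INDEX[reverse_complement(t.to_codon)] for t in trans], dtype=np.int64
    )
    pos = np.array([t.position for t in trans], dtype=np.int64)
    key = {(f, t): i for i, (f, t) in enumerate(zip(from_idx, to_idx))}
    reverse_perm = np.array(
        [key[(t, f)] for f, t in zip(from_idx, to_idx)], dtype=np.int64
    )
    return {
        "from_idx": from_idx,
        "to_idx": to_idx,
        "rc_from_idx": rc_from,
        "rc_to_idx": rc_to,
        "position": pos,
        "reverse_perm": reverse_perm,
    }


def category_masks(code: GeneticCode) -> Dict[str, np.ndarray]:
    """Boolean masks over the 576 transitions for S, N, SS, NN and SN."""
    idx = transition_index_arrays()
    labels = np.asarray(code.labels(), dtype=object)
    syn = labels[idx["from_idx"]] == labels[idx["to_idx"]]
    syn_rc = labels[idx["rc_from_idx"]] == labels[idx["rc_to_idx"]]
    return {
        "S": syn,
        "N": ~syn,
        "SS": syn & syn_rc,
        "NN": ~syn & ~syn_rc,
        "SN": syn ^ syn_rc,
    }
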