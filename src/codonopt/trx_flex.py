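"""Sequence-based DNA flexibility scoring and per-transition impacts (dTRX).

The flexibility of a sequence is the mean, over its phosphate linkages, of a
16-entry dinucleotide scale giving the percent of time each step spends in
the BII backbone conformation (0 = stiff, 43 = very flexible):

    TRX(seq) = sum_i table[seq[i:i+2]] / (L - 1)

The impact of a single-base codon substitution (dTRX) is the absolute shift
in the TRX score of the 5-mer mask (codon plus one flanking base each side),
averaged over all 16 left x right flanking-base pairs so that no arbitrary
sequence context is baked in.  Dinucleotides are read 5'->3' on the coding
strand only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

from .code_tables import (
    BASES,
    CodonTransition,
    GeneticCode,
    category_masks,
    enumerate_transitions,
    normalize_codon,
)
from .impact_metrics import ImpactTable

DINUCLEOTIDES: Tuple[str, ...] = tuple(a + b for a in BASES for b in BASES)


@dataclass(frozen=True)
class TRXTable:
    """Percent-BII occupancy for each of the 16 dinucleotide steps."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        norm = {}
        for k, v in self.entries.items():
            kk = k.upper().replace("U", "T")
            if kk not in DINUCLEOTIDES:
                raise ValueError(f"invalid dinucleotide {k!r}")
            norm[kk] = float(v)
        missing = sorted(set(DINUCLEOTIDES) - set(norm))
        if missing:
            raise ValueError(f"TRX table missing dinucleotides: {missing}")
        bad = {k: v for k, v in norm.items() if not 0.0 <= v <= 43.0}
        if bad:
            raise ValueError(f"TRX values must lie in [0, 43]: {bad}")
        object.__setattr__(self, "entries", norm)

    def __getitem__(self, dinucleotide: str) -> float:
        return self.entries[dinucleotide.upper().replace("U", "T")]


def load_trx_table(path: str | Path) -> TRXTable:
    """Read a ``MN<TAB>value`` 16-line table; '#' comments and blanks skipped."""
    entries: Dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'MN<TAB>value'")
            try:
                entries[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value {parts[1]!r}") from exc
    return TRXTable(entries)


def packaged_trx_table() -> TRXTable:
    """The transcribed published percent-BII scale shipped with the package."""
    ref = resources.files("codonopt").joinpath("data/trx_bii.tsv")
    with resources.as_file(ref) as path:
        return load_trx_table(path)


def trx_score(seq: str, table: TRXTable) -> float:
    """Mean dinucleotide %BII over the L-1 phosphate linkages of ``seq``."""
    s = seq.upper().replace("U", "T")
    if len(s) < 2:
        raise ValueError("sequence must have length >= 2")
    if any(b not in "ACGT" for b in s):
        raise ValueError(f"invalid base in sequence {seq!r}")
    total = sum(table[s[i : i + 2]] for i in range(len(s) - 1))
    return total / (len(s) - 1)


def dtrx_transition(
    t: CodonTransition, table: TRXTable, flanks: str = "average"
) -> float:
    """Flexibility impact of one substitution over the 5-mer mask.

    With the default ``flanks="average"`` policy the absolute before/after
    TRX shift is computed for each of the 16 flanking-base pairs and
    averaged.  A 2-character string (left+right base) pins a fixed context.
    """
    if flanks == "average":
        pairs = itertools.product(BASES, repeat=2)
    else:
        if len(flanks) != 2:
            raise ValueError("flanks must be 'average' or a 2-base string")
        pairs = [(flanks[0].upper(), flanks[1].upper())]
    shifts = []
    for left, right in pairs:
        before = trx_score(left + t.from_codon + right, table)
        after = trx_score(left + t.to_codon + right, table)
        shifts.append(abs(before - after))
    return float(np.mean(shifts))


def dtrx_impact_table(table: TRXTable, flanks: str = "average") -> ImpactTable:
    """The 576-entry dTRX impact table (%BII units)."""
    values = np.array(
        [dtrx_transition(t, table, flanks=flanks) for t in enumerate_transitions()],
        dtype=float,
    )
    return ImpactTable(metric="dTRX", values=values)


def dtrx_category_mean(
    code: GeneticCode,
    table: TRXTable,
    category: str,
    flanks: str = "average",
) -> float:
    """Mean dTRX over one transition category under ``code``."""
    impacts = dtrx_impact_table(table, flanks=flanks)
    masks = category_masks(code)
    if category not in masks:
        raise ValueError(f"unknown category {category!r}")
    sel = impacts.values[masks[category]]
    if sel.size == 0:
        raise ValueError(f"category {category} is empty under code {code.name!r}")
    return float(sel.mean())


def scan_sequence(
    seq: str, table: TRXTable, window: int = 5
) -> Iterator[Tuple[int, float]]:
    """Sliding-window TRX profile of a long sequence.

    Yields ``(start, score)`` for each window of length ``window`` (0-based
    start).  Used by the CLI FASTA scan mode.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    s = seq.upper().replace("U", "T")
    for start in range(0, len(s) - window + 1):
        yield start, trx_score(s[start : start + window], table)
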