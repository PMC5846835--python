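"""Parsers for trajectory-analysis summary tables and the consolidated profile format.

Real MD post-processing leaves behind per-codon text artifacts: two-column
per-atom fluctuation tables and square atomic correlation matrices (the
whitespace-delimited dialects written by common trajectory analysis tools).
This module turns those, or their synthetic stand-ins, into
:class:`~codonopt.impact_metrics.CodonMDProfile` objects, and round-trips 64
profiles through one consolidated TSV so synthetic and real data enter the
pipeline identically.

Inputs are assumed to be production-window summaries (any equilibration
trimming happens upstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .code_tables import ALL_CODONS, normalize_codon
from .impact_metrics import CodonMDProfile


@dataclass(frozen=True)
class RmsfRecord:
    """One per-atom fluctuation entry (Angstrom)."""

    atom_index: int
    fluctuation: float


@dataclass(frozen=True)
class MaskSpec:
    """Atom indices of the 5-nucleotide backbone mask.

    Indices refer to ``atom_index`` values in the fluctuation tables and to
    row/column order in the correlation matrices.
    """

    atom_indices: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.atom_indices) == 0:
            raise ValueError("mask must contain at least one atom")
        object.__setattr__(self, "atom_indices", tuple(int(i) for i in self.atom_indices))


def read_rmsf(path: str | Path) -> List[RmsfRecord]:
    """Parse a two-column ``atom_index fluctuation`` table.

    Comment lines starting with '#' and blank lines are skipped.  Malformed
    rows raise with the offending line number; atom indices must be strictly
    increasing and fluctuations non-negative.
    """
    path = Path(path)
    records: List[RmsfRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                idx, val = int(float(parts[0])), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
            if val < 0:
                raise ValueError(f"{path}:{lineno}: negative fluctuation {val}")
            if records and idx <= records[-1].atom_index:
                raise ValueError(f"{path}:{lineno}: atom indices must be strictly increasing")
            records.append(RmsfRecord(idx, val))
    return records


def read_corr_matrix(path: str | Path, atol: float = 1e-6) -> np.ndarray:
    """Parse a whitespace-delimited square correlation matrix.

    The matrix is symmetrized (average of itself and its transpose) after
    checking symmetry within ``atol``; the unit diagonal is checked within
    ``atol`` and then snapped to exactly 1.
    """
    path = Path(path)
    rows: List[List[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rows.append([float(x) for x in line.split()])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row") from exc
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    n = len(rows)
    if any(len(r) != n for r in rows):
        raise ValueError(f"{path}: matrix is not square ({n} rows)")
    mat = np.array(rows, dtype=float)
    if not np.allclose(mat, mat.T, atol=atol):
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance {atol}")
    mat = 0.5 * (mat + mat.T)
    if not np.allclose(np.diag(mat), 1.0, atol=atol):
        raise ValueError(f"{path}: diagonal deviates from 1 beyond tolerance {atol}")
    np.fill_diagonal(mat, 1.0)
    return mat


def _fisher_z_mean(stack: np.ndarray) -> np.ndarray:
    clipped = np.clip(stack, -0.999999, 0.999999)
    z = np.arctanh(clipped)
    mean = np.tanh(z.mean(axis=0))
    np.fill_diagonal(mean, 1.0)
    return mean


def build_profiles(
    replicate_files: Mapping[str, Sequence[Tuple[str | Path, str | Path]]],
    mask: MaskSpec,
    corr_average: str = "entrywise",
) -> Dict[str, CodonMDProfile]:
    """Assemble the 64 replicate-averaged profiles from per-codon file pairs.

    Parameters
    ----------
    replicate_files
        ``codon -> [(rmsf_path, corr_path), ...]`` with at least one
        replicate pair per codon; all 64 codons must be present.
    mask
        Backbone atom indices to retain.
    corr_average
        ``"entrywise"`` (default) or ``"fisher_z"`` replicate averaging of
        correlation matrices.
    """
    if corr_average not in ("entrywise", "fisher_z"):
        raise ValueError(f"unknown corr_average {corr_average!r}")
    normalized = {normalize_codon(c): files for c, files in replicate_files.items()}
    missing = [c for c in ALL_CODONS if c not in normalized]
    if missing:
        raise ValueError(f"missing replicate files for codons: {missing}")

    profiles: Dict[str, CodonMDProfile] = {}
    for codon in ALL_CODONS:
        pairs = normalized[codon]
        if len(pairs) == 0:
            raise ValueError(f"codon {codon}: at least one replicate required")
        flux_reps, corr_reps = [], []
        for rmsf_path, corr_path in pairs:
            records = read_rmsf(rmsf_path)
            by_index = {r.atom_index: r.fluctuation for r in records}
            absent = [i for i in mask.atom_indices if i not in by_index]
            if absent:
                raise ValueError(f"{rmsf_path}: mask atoms {absent} not present")
            flux_reps.append([by_index[i] for i in mask.atom_indices])
            corr = read_corr_matrix(corr_path)
            if corr.shape[0] < max(mask.atom_indices) + 1:
                raise ValueError(
                    f"{corr_path}: matrix of size {corr.shape[0]} too small for mask"
                )
            sel = np.ix_(mask.atom_indices, mask.atom_indices)
            corr_reps.append(corr[sel])
        flux_arr = np.asarray(flux_reps, dtype=float)
        corr_arr = np.asarray(corr_reps, dtype=float)
        if len({a.shape for a in map(np.asarray, flux_reps)}) > 1:
            raise ValueError(f"codon {codon}: inconsistent replicate dimensions")
        corr_mean = (
            corr_arr.mean(axis=0)
            if corr_average == "entrywise"
            else _fisher_z_mean(corr_arr)
        )
        profiles[codon] = CodonMDProfile(
            codon=codon,
            flux=flux_arr.mean(axis=0),
            corr=corr_mean,
            n_replicates=len(pairs),
        )
    return profiles


# --------------------------------------------------------------------------
# Consolidated profile TSV (the format `simulate` writes)
# --------------------------------------------------------------------------

def write_profiles(profiles: Mapping[str, CodonMDProfile], path: str | Path) -> None:
    """Serialize 64 profiles into one long-form TSV.

    Columns: ``codon``, ``field`` (flux | corr | n_replicates), ``i``, ``j``
    (``-1`` where not applicable) and ``value``.  Full float precision is
    kept so a round-trip is lossless.
    """
    rows = []
    for codon in sorted(profiles, key=lambda c: ALL_CODONS.index(normalize_codon(c))):
        p = profiles[codon]
        rows.append((p.codon, "n_replicates", -1, -1, float(p.n_replicates)))
        for i, v in enumerate(p.flux):
            rows.append((p.codon, "flux", i, -1, v))
        for i in range(p.corr.shape[0]):
            for j in range(p.corr.shape[1]):
                rows.append((p.codon, "corr", i, j, p.corr[i, j]))
    df = pd.DataFrame(rows, columns=["codon", "field", "i", "j", "value"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_profiles(path: str | Path) -> Dict[str, CodonMDProfile]:
    """Read a consolidated profile TSV back into profile objects."""
    df = pd.read_csv(path, sep="\t")
    expected = {"codon", "field", "i", "j", "value"}
    if set(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    profiles: Dict[str, CodonMDProfile] = {}
    for codon, grp in df.groupby("codon", sort=False):
        flux_rows = grp[grp["field"] == "flux"].sort_values("i")
        flux = flux_rows["value"].to_numpy()
        corr_rows = grp[grp["field"] == "corr"]
        n = flux.size
        corr = np.full((n, n), np.nan)
        corr[corr_rows["i"].to_numpy(int), corr_rows["j"].to_numpy(int)] = (
            corr_rows["value"].to_numpy()
        )
        if np.isnan(corr).any():
            raise ValueError(f"{path}: incomplete correlation matrix for {codon}")
        meta = grp[grp["field"] == "n_replicates"]
        n_rep = int(meta["value"].iloc[0]) if len(meta) else 1
        profiles[str(codon)] = CodonMDProfile(
            codon=str(codon), flux=flux, corr=corr, n_replicates=n_rep
        )
    missing = [c for c in ALL_CODONS if c not in profiles]
    if missing:
        raise ValueError(f"{path}: profiles missing for codons {missing}")
    return profiles
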