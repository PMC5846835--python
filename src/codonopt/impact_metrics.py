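"""Per-transition mutational impacts on molecular dynamics (dFLUX, dCORR).

Each codon carries a replicate-averaged MD summary profile over the backbone
atoms of a 5-nucleotide mask (codon plus one flanking base each side).  A
profile is reduced to a scalar — the mask mean of per-atom fluctuations
(FLUX, in Angstrom) or the mean off-diagonal atomic correlation (CORR, in r)
— and the impact of a substitution is the absolute difference of the scalars
before and after the mutation.  Category totals follow the aggregation rule
of the respective metric: sums for dFLUX/dCORR, means for dTRX.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .code_tables import (
    ALL_CODONS,
    CODON_INDEX,
    GeneticCode,
    category_masks,
    enumerate_transitions,
    normalize_codon,
    transition_index_arrays,
)

Metric = Literal["dFLUX", "dCORR", "dTRX"]
Category = Literal["S", "N", "SS", "NN", "SN"]
CATEGORIES: tuple = ("N", "S", "NN", "SN", "SS")

#: default aggregation per metric: MD impacts are summed, flexibility
#: impacts are averaged.
DEFAULT_MODE: Dict[str, str] = {"dFLUX": "sum", "dCORR": "sum", "dTRX": "mean"}


@dataclass
class CodonMDProfile:
    """Replicate-averaged MD summary for one codon's 5-mer mask.

    Attributes
    ----------
    codon
        The codon the 25-bp construct was centered on.
    flux
        Per-atom fluctuation vector (Angstrom), one entry per backbone atom
        in the mask; entries must be non-negative.
    corr
        Square atomic correlation matrix over the same atoms; symmetric with
        unit diagonal, entries in [-1, 1].
    n_replicates
        Number of production replicates averaged into the profile.
    """

    codon: str
    flux: np.ndarray
    corr: np.ndarray
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.codon = normalize_codon(self.codon)
        self.flux = np.asarray(self.flux, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.flux.ndim != 1 or self.flux.size == 0:
            raise ValueError("flux must be a non-empty 1-D vector")
        if np.any(self.flux < 0):
            raise ValueError("flux entries must be non-negative")
        if self.corr.ndim != 2 or self.corr.shape[0] != self.corr.shape[1]:
            raise ValueError("corr must be a square matrix")
        if self.corr.shape[0] != self.flux.size:
            raise ValueError("corr dimension must match flux length")


def summarize_flux(profile: CodonMDProfile, stat: str = "mean") -> float:
    """Mask-level FLUX scalar (Angstrom).

    ``stat="mean"`` (default, scale-stable across mask sizes) or ``"sum"``.
    """
    if profile.flux.size == 0:
        raise ValueError("empty mask")
    if stat == "mean":
        return float(np.mean(profile.flux))
    if stat == "sum":
        return float(np.sum(profile.flux))
    raise ValueError(f"stat must be 'mean' or 'sum', got {stat!r}")


def summarize_corr(
    profile: CodonMDProfile, pairs: str = "all", atol: float = 1e-8
) -> float:
    """Mask-level CORR scalar: mean off-diagonal correlation.

    ``pairs="all"`` averages every strictly off-diagonal entry;
    ``pairs="adjacent"`` restricts to nearest-neighbour atom pairs (the
    first off-diagonal).
    """
    c = profile.corr
    if not np.allclose(c, c.T, atol=atol):
        raise ValueError("correlation matrix must be symmetric")
    n = c.shape[0]
    if n < 2:
        return 0.0
    if pairs == "all":
        off = ~np.eye(n, dtype=bool)
        return float(np.mean(c[off]))
    if pairs == "adjacent":
        return float(np.mean(np.diagonal(c, offset=1)))
    raise ValueError(f"pairs must be 'all' or 'adjacent', got {pairs!r}")


def transition_impact(before: float, after: float) -> float:
    """Absolute before/after difference of a mask scalar."""
    if not (np.isfinite(before) and np.isfinite(after)):
        raise ValueError("impact inputs must be finite")
    return abs(before - after)


@dataclass
class ImpactTable:
    """Scalar impact for each of the 576 directed transitions, one metric.

    ``values`` is aligned with :func:`codonopt.code_tables.enumerate_transitions`
    order.  Impacts are non-negative and symmetric under transition reversal.
    """

    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (576,):
            raise ValueError("impact table must have exactly 576 entries")
        if np.any(self.values < 0):
            raise ValueError("impacts must be non-negative")

    def as_frame(self, code: GeneticCode | None = None) -> pd.DataFrame:
        """Tabular view; adds coding/strand classes when a code is given."""
        trans = enumerate_transitions()
        df = pd.DataFrame(
            {
                "from_codon": [t.from_codon for t in trans],
                "to_codon": [t.to_codon for t in trans],
                "position": [t.position for t in trans],
                "metric": self.metric,
                "value": self.values,
            }
        )
        if code is not None:
            masks = category_masks(code)
            df.insert(3, "coding_class", np.where(masks["S"], "S", "N"))
            strand = np.where(masks["SS"], "SS", np.where(masks["NN"], "NN", "SN"))
            df.insert(4, "strand_class", strand)
        return df

    def to_tsv(self, path: str | Path, code: GeneticCode | None = None) -> None:
        self.as_frame(code).to_csv(path, sep="\t", index=False)


def _codon_scalars(
    profiles: Mapping[str, CodonMDProfile], summarize
) -> np.ndarray:
    missing = [c for c in ALL_CODONS if c not in profiles]
    if missing:
        raise ValueError(f"profiles missing for {len(missing)} codons: {missing[:5]}")
    return np.array([summarize(profiles[c]) for c in ALL_CODONS], dtype=float)


def impact_table_from_profiles(
    profiles: Mapping[str, CodonMDProfile],
    metric: str,
    flux_stat: str = "mean",
    corr_pairs: str = "all",
) -> ImpactTable:
    """Build the 576-entry dFLUX or dCORR table from 64 codon profiles."""
    if metric == "dFLUX":
        scalars = _codon_scalars(profiles, lambda p: summarize_flux(p, flux_stat))
    elif metric == "dCORR":
        scalars = _codon_scalars(profiles, lambda p: summarize_corr(p, corr_pairs))
    else:
        raise ValueError(f"unknown profile metric {metric!r}")
    idx = transition_index_arrays()
    values = np.abs(scalars[idx["from_idx"]] - scalars[idx["to_idx"]])
    return ImpactTable(metric=metric, values=values)


def category_total(
    impacts: ImpactTable,
    code: GeneticCode,
    category: str,
    mode: str | None = None,
) -> float:
    """Sum or mean of impacts over one transition category under ``code``.

    ``mode`` defaults to the metric's convention (sum for dFLUX/dCORR, mean
    for dTRX).  An empty category yields 0 for sums and raises for means.
    """
    if mode is None:
        mode = DEFAULT_MODE.get(impacts.metric, "sum")
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    masks = category_masks(code)
    if category not in masks:
        raise ValueError(f"unknown category {category!r}")
    sel = impacts.values[masks[category]]
    if sel.size == 0:
        if mode == "sum":
            return 0.0
        raise ValueError(f"category {category} is empty; mean undefined")
    return float(sel.sum() if mode == "sum" else sel.mean())
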