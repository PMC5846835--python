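"""Canonical-code category totals vs. the exhaustive alternative-code ensemble.

For a fixed 576-entry impact table, every one of the 13,823 alternative codes
induces its own synonymous/nonsynonymous split of the transitions, hence its
own category totals.  The canonical code's total is located within the
ensemble distribution via the empirical CDF (proportion of ensemble values
less than or equal to the observed value, ties included).

The evaluation streams over blocks of permutation triples, so memory stays
bounded by one block of code tables plus the accumulated totals; the full
ensemble is exhaustive, never sampled, and the result is deterministic for a
given impact table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .alt_codes import N_ALTERNATIVES, N_TRIPLES, codon_permutation_matrix
from .code_tables import GeneticCode, standard_code, transition_index_arrays
from .impact_metrics import CATEGORIES, DEFAULT_MODE, ImpactTable


def ecdf_p(observed: float, ensemble: Sequence[float] | np.ndarray) -> float:
    """Empirical CDF value of ``observed`` within ``ensemble`` (ties count as <=).

    NaN ensemble entries (codes under which the category was empty) are
    excluded from the denominator, mirroring how sorting-based ECDF
    implementations drop missing values.
    """
    arr = np.asarray(ensemble, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("ensemble must contain at least one finite value")
    return float(np.count_nonzero(arr <= observed) / arr.size)


@dataclass
class EnsembleTestResult:
    """Outcome of one metric/category ensemble comparison."""

    metric: str
    category: str
    mode: str
    canonical_value: float
    ensemble_values: np.ndarray
    empirical_p: float

    @property
    def n_alternatives(self) -> int:
        return int(self.ensemble_values.size)


def ensemble_category_totals(
    values: np.ndarray,
    categories: Sequence[str] = CATEGORIES,
    mode: str = "sum",
    base_code: GeneticCode | None = None,
    chunk_size: int = 1536,
) -> Dict[str, np.ndarray]:
    """Category totals for every permutation triple, identity included.

    Parameters
    ----------
    values
        Impact values aligned with transition enumeration order; shape
        ``(576,)`` for one table or ``(576, m)`` for ``m`` tables evaluated
        in a single streamed pass.
    mode
        ``"sum"`` or ``"mean"`` aggregation within each category.
    base_code
        Code whose cube is permuted (canonical by default).
    chunk_size
        Number of triples materialized per block.

    Returns
    -------
    dict
        ``category -> array`` of shape ``(13824,)`` (or ``(13824, m)``),
        indexed in ``enumerate_triples`` order — row 0 is the identity
        triple, rows 1: are the 13,823 alternatives.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    vals = np.asarray(values, dtype=float)
    squeeze = vals.ndim == 1
    if squeeze:
        vals = vals[:, None]
    if vals.shape[0] != 576:
        raise ValueError("impact values must have 576 rows")

    code = base_code if base_code is not None else standard_code()
    label_codes = code.label_codes()
    idx = transition_index_arrays()
    f, t = idx["from_idx"], idx["to_idx"]
    rf, rt = idx["rc_from_idx"], idx["rc_to_idx"]

    out = {
        cat: np.empty((N_TRIPLES, vals.shape[1]), dtype=float) for cat in categories
    }
    for start in range(0, N_TRIPLES, chunk_size):
        block = slice(start, min(start + chunk_size, N_TRIPLES))
        labels = label_codes[codon_permutation_matrix(block)]  # (n, 64)
        syn = labels[:, f] == labels[:, t]  # (n, 576)
        need_strand = any(c in ("SS", "NN", "SN") for c in categories)
        syn_rc = (labels[:, rf] == labels[:, rt]) if need_strand else None
        for cat in categories:
            if cat == "S":
                mask = syn
            elif cat == "N":
                mask = ~syn
            elif cat == "SS":
                mask = syn & syn_rc
            elif cat == "NN":
                mask = ~syn & ~syn_rc
            elif cat == "SN":
                mask = syn ^ syn_rc
            else:
                raise ValueError(f"unknown category {cat!r}")
            m = mask.astype(float)
            totals = m @ vals  # (n, m_tables)
            if mode == "mean":
                # strand-class membership varies across codes and can be empty
                # (the reverse-complement map does not commute with the cube
                # permutation); an empty category has no mean -> NaN, dropped
                # later from the ECDF.
                counts = m.sum(axis=1, keepdims=True)
                with np.errstate(invalid="ignore", divide="ignore"):
                    totals = np.where(counts > 0, totals / counts, np.nan)
            out[cat][block] = totals
    if squeeze:
        out = {cat: arr[:, 0] for cat, arr in out.items()}
    return out


def run_ensemble_test(
    impacts: ImpactTable,
    categories: Sequence[str] = CATEGORIES,
    mode: str | None = None,
    base_code: GeneticCode | None = None,
    chunk_size: int = 1536,
) -> List[EnsembleTestResult]:
    """Evaluate the canonical code against all 13,823 alternatives.

    ``mode`` defaults to the metric's convention (sum for dFLUX/dCORR, mean
    for dTRX).  The identity triple provides the canonical value and is
    excluded from the ensemble.
    """
    if mode is None:
        mode = DEFAULT_MODE.get(impacts.metric, "sum")
    totals = ensemble_category_totals(
        impacts.values, categories, mode=mode, base_code=base_code,
        chunk_size=chunk_size,
    )
    results = []
    for cat in categories:
        arr = totals[cat]
        canonical, ensemble = float(arr[0]), arr[1:]
        results.append(
            EnsembleTestResult(
                metric=impacts.metric,
                category=cat,
                mode=mode,
                canonical_value=canonical,
                ensemble_values=ensemble,
                empirical_p=ecdf_p(canonical, ensemble),
            )
        )
    return results


def metric_correlation(a: ImpactTable, b: ImpactTable) -> float:
    """Pearson correlation between two impact tables across the 576 transitions."""
    x, y = a.values, b.values
    if x.shape != y.shape:
        raise ValueError("impact tables must cover the same transitions")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance impact table")
    return float(stats.pearsonr(x, y)[0])
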