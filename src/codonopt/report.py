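"""Result tables, positional impact profiles, run manifests and figures."""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .alt_codes import N_ALTERNATIVES
from .code_tables import GeneticCode, category_masks, transition_index_arrays
from .impact_metrics import CodonMDProfile, summarize_corr
from .optimization_test import EnsembleTestResult

#: which tail is "optimized" per metric: MD impacts are minimized, the
#: flexibility impact is maximized (reported alongside raw p to avoid
#: ambiguity about what "outperforms" means).
OPTIMIZED_DIRECTION = {"dFLUX": "minimized", "dCORR": "minimized", "dTRX": "maximized"}


def positional_impact_profile(
    profiles: Mapping[str, CodonMDProfile],
    code: GeneticCode,
    category: str,
    metric: str = "dFLUX",
) -> np.ndarray:
    """Per-atom mean absolute before/after difference for one category.

    For ``dFLUX`` the per-atom quantity is the fluctuation itself; for
    ``dCORR`` it is the atom's mean off-diagonal correlation (row mean).
    Returns one value per mask atom (the Fig.-4-style heatmap column).
    """
    masks = category_masks(code)
    if category not in masks:
        raise ValueError(f"unknown category {category!r}")
    if not masks[category].any():
        raise ValueError(f"category {category} is empty under {code.name!r}")
    idx = transition_index_arrays()
    codons = sorted(profiles)
    if len(profiles) != 64:
        raise ValueError("need all 64 codon profiles")

    if metric == "dFLUX":
        per_atom = {c: np.asarray(profiles[c].flux, dtype=float) for c in profiles}
    elif metric == "dCORR":
        per_atom = {}
        for c, p in profiles.items():
            m = p.corr
            n = m.shape[0]
            if n < 2:
                per_atom[c] = np.zeros(n)
            else:
                off = m.copy()
                np.fill_diagonal(off, 0.0)
                per_atom[c] = off.sum(axis=1) / (n - 1)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    from .code_tables import ALL_CODONS

    mat = np.stack([per_atom[c] for c in ALL_CODONS])  # (64, n_atoms)
    f, t = idx["from_idx"], idx["to_idx"]
    diffs = np.abs(mat[f] - mat[t])  # (576, n_atoms)
    return diffs[masks[category]].mean(axis=0)


def results_frame(results: Sequence[EnsembleTestResult]) -> pd.DataFrame:
    """Long-form table of ensemble test results (one row per metric/category)."""
    rows = []
    for r in results:
        direction = OPTIMIZED_DIRECTION.get(r.metric, "minimized")
        outperforms = 1.0 - r.empirical_p if direction == "minimized" else r.empirical_p
        rows.append(
            {
                "metric": r.metric,
                "category": r.category,
                "mode": r.mode,
                "canonical_value": r.canonical_value,
                "empirical_p": r.empirical_p,
                "optimized_direction": direction,
                "outperforms_fraction": outperforms,
                "n_alternatives": r.n_alternatives,
            }
        )
    return pd.DataFrame(rows)


def ensemble_dump_frame(results: Sequence[EnsembleTestResult]) -> pd.DataFrame:
    """Per-alternative-code category values (code ids follow triple order)."""
    frames = []
    for r in results:
        frames.append(
            pd.DataFrame(
                {
                    "code_id": np.arange(1, r.n_alternatives + 1),
                    "metric": r.metric,
                    "category": r.category,
                    "value": r.ensemble_values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_manifest(path: str | Path, **fields) -> None:
    """Machine-readable run manifest (always records the ensemble size)."""
    manifest = {
        "n_alternative_codes": N_ALTERNATIVES,
        "transition_count": 576,
        "transition_convention": "directed; category sums double undirected totals, "
        "ECDF p-values unaffected",
        "ecdf_convention": "proportion of ensemble values <= canonical (ties included)",
    }
    manifest.update(fields)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def plot_ensemble_histogram(result: EnsembleTestResult, path: str | Path) -> None:
    """Ensemble histogram with the canonical value as a vertical line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.ensemble_values, bins=60, color="steelblue", alpha=0.8)
    ax.axvline(result.canonical_value, color="black", linestyle="--", label="canonical")
    ax.set_xlabel(f"{result.metric} {result.category} ({result.mode})")
    ax.set_ylabel("alternative codes")
    ax.set_title(f"{result.metric} {result.category}: p = {result.empirical_p:.3f}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_positional_heatmap(
    vectors: Mapping[str, np.ndarray], path: str | Path, metric: str
) -> None:
    """Category-by-atom heatmap of positional mean impacts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = list(vectors)
    mat = np.stack([vectors[c] for c in cats])
    fig, ax = plt.subplots(figsize=(6, 2 + 0.4 * len(cats)))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(cats)), cats)
    ax.set_xlabel("mask atom")
    ax.set_title(f"mean positional {metric}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
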