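"""Seeded synthetic codon MD profiles with controlled statistical structure.

Three generative models make every pipeline stage testable without MD runs:

``aa_determined``
    The base fluctuation level of a codon is a function of its canonical
    amino-acid label only (levels drawn once per label from the seeded
    stream), so with zero noise all synonymous codons have bit-identical
    profiles and the canonical synonymous impact is exactly 0.
``gc_linear``
    ``level = intercept + gc_slope * (number of G/C bases in the codon)``;
    with zero noise every transition's dFLUX equals ``|gc_slope|`` times the
    GC-count change (0 or 1), an analytic oracle.
``iid_noise``
    Levels are drawn independently per codon; the canonical code is then
    statistically exchangeable with every alternative code, so ensemble
    p-values are approximately uniform across seeds.

Correlation matrices are built from random latent-mode loadings (guaranteeing
positive semi-definiteness and a unit diagonal) keyed to the same latent
identity as the flux level, so the neutrality structure carries over to dCORR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .code_tables import ALL_CODONS, GeneticCode, gc_count, standard_code
from .impact_metrics import CodonMDProfile

MODELS = ("aa_determined", "gc_linear", "iid_noise")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic profile generator."""

    model: str = "aa_determined"
    intercept: float = 1.0
    gc_slope: float = 0.2
    noise_sd: float = 0.0
    n_atoms_per_base: int = 2
    n_replicates: int = 3
    n_latent_modes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_atoms_per_base < 1 or self.n_replicates < 1:
            raise ValueError("n_atoms_per_base and n_replicates must be >= 1")
        if self.model == "gc_linear":
            lo = min(self.intercept + self.gc_slope * g for g in range(4))
            if lo < 0:
                raise ValueError("gc_linear levels must stay non-negative over GC 0..3")


def _corr_from_loadings(w: np.ndarray) -> np.ndarray:
    # W W^T + eps I normalized to unit diagonal: PSD and symmetric by construction
    c = w @ w.T + 1e-6 * np.eye(w.shape[0])
    d = np.sqrt(np.diag(c))
    corr = c / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_profiles(
    config: GeneratorConfig, code: GeneticCode | None = None
) -> Dict[str, CodonMDProfile]:
    """Generate the 64 codon profiles for ``config`` (fully seed-determined).

    ``code`` fixes which labels define synonymy for ``aa_determined``
    (canonical by default).
    """
    code = code if code is not None else standard_code()
    rng = np.random.default_rng(config.seed)
    n_atoms = 5 * config.n_atoms_per_base

    # latent identity per codon: label for aa_determined, codon otherwise
    if config.model == "aa_determined":
        keys = {c: code.translate(c) for c in ALL_CODONS}
    else:
        keys = {c: c for c in ALL_CODONS}
    key_order = sorted(set(keys.values()))

    levels: Dict[str, float] = {}
    if config.model == "gc_linear":
        for c in ALL_CODONS:
            levels[c] = config.intercept + config.gc_slope * gc_count(c)
    else:
        # one positive level per latent key, drawn in a fixed order
        key_levels = {
            k: config.intercept * (1.0 + abs(rng.standard_normal()))
            for k in key_order
        }
        for c in ALL_CODONS:
            levels[c] = key_levels[keys[c]]

    loadings = {
        k: rng.standard_normal((n_atoms, config.n_latent_modes)) for k in key_order
    }
    if config.model == "gc_linear":
        # key by codon so corr exists, though the gc oracle only concerns flux
        loadings = {c: loadings[c] for c in ALL_CODONS}

    profiles: Dict[str, CodonMDProfile] = {}
    for c in ALL_CODONS:
        base_flux = np.full(n_atoms, levels[c])
        base_w = loadings[keys[c]] if config.model != "gc_linear" else loadings[c]
        flux_reps, corr_reps = [], []
        for _ in range(config.n_replicates):
            if config.noise_sd > 0:
                flux_reps.append(
                    base_flux + rng.normal(0.0, config.noise_sd, n_atoms)
                )
                corr_reps.append(
                    _corr_from_loadings(
                        base_w + rng.normal(0.0, config.noise_sd, base_w.shape)
                    )
                )
            else:
                flux_reps.append(base_flux)
                corr_reps.append(_corr_from_loadings(base_w))
        flux = np.maximum(np.mean(flux_reps, axis=0), 0.0)
        corr = np.mean(corr_reps, axis=0)
        np.fill_diagonal(corr, 1.0)
        profiles[c] = CodonMDProfile(
            codon=c, flux=flux, corr=corr, n_replicates=config.n_replicates
        )
    return profiles
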