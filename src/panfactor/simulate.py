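"""Matrix-level synthetic benchmark generator for strain deconvolution.

Emulates the standard validation design for strain profilers at the level of
the gene-family abundance matrix: a synthetic pangenome of K strains with a
shared core and independent accessory gene content, Dirichlet strain
compositions with a minimum frequency of 5% (one depth unit, 20 units per
sample), and count noise around the expected RPKM signal.  Read-level
artefacts (sequencing errors, real metagenomic backgrounds) are approximated
by a multiplicative lognormal efficiency per gene family and by Poisson
background counts on families absent from every strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import permutations

import numpy as np
import pandas as pd

from .datamodel import GeneFamilyMatrix, PangenomeStats, ValidationError

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "simulate_pangenome",
    "simulate_composition",
    "permutation_design",
    "simulate_dataset",
    "synthetic_membership",
]

NOISE_MODELS = ("none", "poisson", "poisson_lognormal")


@dataclass
class SimConfig:
    """Design of one synthetic strain-mixture dataset.

    A strain at the minimum frequency (5% by default) contributes one depth
    unit = ``depth_unit_rpkm`` of expected abundance to each of its gene
    families, so every sample totals ``1 / min_frequency`` (20) units.
    """

    n_families: int = 3000
    n_strains: int = 4
    core_fraction: float = 0.4
    accessory_presence_prob: float = 0.5
    min_pairwise_jaccard: float = 0.25
    n_samples: int = 20
    dirichlet_alpha: float = 1.0
    min_frequency: float = 0.05
    depth_unit_rpkm: float = 100.0
    noise_model: str = "poisson"
    overdispersion_sigma: float = 0.0
    background_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_strains < 1 or self.n_samples < 1:
            raise ValidationError("n_families, n_strains, n_samples must be >= 1")
        if not 0 < self.core_fraction < 1:
            raise ValidationError("core_fraction must lie in (0, 1)")
        if not 0 <= self.accessory_presence_prob <= 1:
            raise ValidationError("accessory_presence_prob must lie in [0, 1]")
        if not 0 < self.min_frequency <= 1 / self.n_strains:
            raise ValidationError("require 0 < min_frequency <= 1 / n_strains")
        if self.dirichlet_alpha <= 0:
            raise ValidationError("dirichlet_alpha must be > 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(f"noise_model must be one of {NOISE_MODELS}")
        if self.background_rate < 0 or self.overdispersion_sigma < 0:
            raise ValidationError("background_rate and overdispersion_sigma must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth bundle: P*, S*, per-sample depth units, config echo."""

    family_ids: list[str]
    strain_ids: list[str]
    sample_ids: list[str]
    true_content: np.ndarray       # families x K binary
    true_composition: np.ndarray   # K x samples, columns sum to 1
    depth_units: np.ndarray        # per-sample total depth in units
    seed: int
    config: dict = field(default_factory=dict)

    def content_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.true_content, index=self.family_ids, columns=self.strain_ids)

    def composition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.true_composition, index=self.strain_ids, columns=self.sample_ids)


def _pangenome(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n_core = int(cfg.core_fraction * cfg.n_families)
    max_attempts = 1000
    for _ in range(max_attempts):
        P = np.zeros((cfg.n_families, cfg.n_strains), dtype=np.int8)
        P[:n_core] = 1
        P[n_core:] = rng.random((cfg.n_families - n_core, cfg.n_strains)) < cfg.accessory_presence_prob
        if cfg.n_strains == 1:
            return P
        ok = True
        for a in range(cfg.n_strains):
            for b in range(a + 1, cfg.n_strains):
                inter = int(np.sum(P[:, a] & P[:, b]))
                union = int(np.sum(P[:, a] | P[:, b]))
                if union == 0 or 1 - inter / union < cfg.min_pairwise_jaccard:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return P
    raise ValidationError(
        "could not satisfy min_pairwise_jaccard after "
        f"{max_attempts} attempts; lower core_fraction or min_pairwise_jaccard"
    )


def simulate_pangenome(cfg: SimConfig) -> np.ndarray:
    """Binary families x strains content matrix with core/accessory structure."""
    return _pangenome(cfg, np.random.default_rng([cfg.seed, 101]))


def _composition(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.min_frequency * cfg.n_strains > 1:
        raise ValidationError("min_frequency * n_strains exceeds 1")
    cols = []
    max_attempts = 100_000
    attempts = 0
    while len(cols) < cfg.n_samples:
        draw = rng.dirichlet(np.full(cfg.n_strains, cfg.dirichlet_alpha))
        attempts += 1
        if draw.min() >= cfg.min_frequency:
            cols.append(draw)
        if attempts > max_attempts:
            raise ValidationError("Dirichlet rejection sampling failed; lower min_frequency")
    return np.column_stack(cols)


def simulate_composition(cfg: SimConfig) -> np.ndarray:
    """K x n_samples Dirichlet compositions, rejected until min entry >= min_frequency."""
    return _composition(cfg, np.random.default_rng([cfg.seed, 202]))


def permutation_design(abundances: "np.ndarray | list[float]") -> np.ndarray:
    """Fixed design: all distinct permutations of one abundance vector as columns.

    E.g. (0.05, 0.10, 0.25, 0.60) yields the 24-sample four-strain design."""
    vec = np.asarray(abundances, dtype=float)
    if not np.isclose(vec.sum(), 1.0):
        raise ValidationError("abundance vector must sum to 1")
    perms = sorted(set(permutations(vec.tolist())))
    return np.array(perms, dtype=float).T


def simulate_dataset(
    cfg: SimConfig, noise_seed: int | None = None
) -> tuple[GeneFamilyMatrix, SimulationTruth]:
    """Generate the observed abundance matrix D and its ground truth.

    Expected signal: a strain at frequency f contributes ``f / min_frequency``
    depth units, i.e. ``M = P* @ (S* / min_frequency)`` and the expected RPKM
    matrix is ``M * depth_unit_rpkm``.  Noise models: ``none`` (exact),
    ``poisson`` (draws around the expectation), ``poisson_lognormal``
    (per-family multiplicative lognormal efficiency, then Poisson).
    ``background_rate > 0`` adds Poisson counts to families absent from all
    strains.  ``noise_seed`` draws the noise from an independent stream while
    keeping the truth fixed (for replicate draws around the same mean).
    """
    rng = np.random.default_rng([cfg.seed, 303] if noise_seed is None else [noise_seed, 303])
    P = _pangenome(cfg, np.random.default_rng([cfg.seed, 101]))
    S = _composition(cfg, np.random.default_rng([cfg.seed, 202]))
    units = S / cfg.min_frequency
    mean = (P @ units) * cfg.depth_unit_rpkm

    if cfg.noise_model == "none":
        values = mean.copy()
    else:
        if cfg.noise_model == "poisson_lognormal" and cfg.overdispersion_sigma > 0:
            eff = np.exp(rng.normal(0.0, cfg.overdispersion_sigma, size=cfg.n_families))
            mean_noisy = mean * eff[:, None]
        else:
            mean_noisy = mean
        values = rng.poisson(mean_noisy).astype(float)

    if cfg.background_rate > 0:
        orphan = P.sum(axis=1) == 0
        values[orphan] += rng.poisson(cfg.background_rate, size=(int(orphan.sum()), cfg.n_samples))

    width = len(str(cfg.n_families))
    family_ids = [f"gf{i + 1:0{width}d}" for i in range(cfg.n_families)]
    strain_ids = [f"true{j + 1}" for j in range(cfg.n_strains)]
    sample_ids = [f"sample{j + 1:02d}" for j in range(cfg.n_samples)]

    D = GeneFamilyMatrix(family_ids, sample_ids, values, units="rpkm")
    truth = SimulationTruth(
        family_ids=family_ids,
        strain_ids=strain_ids,
        sample_ids=sample_ids,
        true_content=P,
        true_composition=S,
        depth_units=units.sum(axis=0),
        seed=cfg.seed,
        config=asdict(cfg),
    )
    return D, truth


def synthetic_membership(
    truth: SimulationTruth,
    n_decoys: int = 0,
    flip_fraction: float = 0.05,
    seed: int = 0,
) -> PangenomeStats:
    """Reference-genome table for a simulated pangenome: the true strains,
    optionally plus decoy genomes made by flipping a fraction of accessory bits."""
    cols = [truth.true_content[:, j] for j in range(truth.true_content.shape[1])]
    ids = [f"genome{j + 1}" for j in range(len(cols))]
    rng = np.random.default_rng([seed, 404])
    for d in range(n_decoys):
        base = cols[d % truth.true_content.shape[1]].copy()
        flip = rng.random(base.shape[0]) < flip_fraction
        base = np.where(flip, 1 - base, base)
        cols.append(base.astype(np.int8))
        ids.append(f"decoy{d + 1}")
    return PangenomeStats(
        family_ids=list(truth.family_ids),
        genome_ids=ids,
        membership=np.column_stack(cols),
    )
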