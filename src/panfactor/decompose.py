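"""Sparse NMF decomposition of a pangenome abundance matrix into strains.

The model is ``D ~ P . S`` with ``D`` the nonnegative gene-family x sample
RPKM matrix, ``P`` a binary gene-content matrix (families x strains) and
``S`` the strain x sample relative-abundance matrix.  The factorization is a
sparse NMF solved by alternating nonnegative least squares:

    min_{P', S' >= 0}  1/2 ( ||D - P'S'||_F^2
                             + eta ||P'||_F^2
                             + beta sum_j ||S'_. j||_1^2 )

The squared-L1 column penalty on the composition factor enforces sparsity
and makes the factorization essentially unique; the Frobenius ridge on the
content factor controls its scale.  Both subproblems are solved exactly by
block principal pivoting NNLS, so the objective is monotone non-increasing.

The continuous content factor is binarized per strain by locating the peak
of the kernel density of its positive weights whose right tail best matches
the expected gene-family count of a genome, thresholding at
``theta = theta_fraction * p_max`` and attaching a linear confidence score.
The number of strains (NMF rank) is chosen over a candidate range by three
plausibility criteria on abundance, profile size and pairwise profile
distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.stats import gaussian_kde

from ._nnls import nnls_blockpivot
from .datamodel import (
    DecompositionResult,
    GeneFamilyMatrix,
    PangenomeStats,
    StrainComposition,
    StrainGeneContent,
    ValidationError,
)

__all__ = [
    "FactorizeParams",
    "RankSelectConfig",
    "FactorizeResult",
    "RankDiagnostics",
    "factorize",
    "scale_composition",
    "binarize_with_confidence",
    "evaluate_rank",
    "select_rank",
    "decompose",
]


@dataclass
class FactorizeParams:
    """Hyperparameters of the sparse NMF.

    ``sparsity_weight`` is the squared-L1 penalty on each composition column;
    it is dimensionless (both terms scale with the squared data magnitude).
    ``smoothness_weight=None`` selects a weak scale-pinning ridge
    ``(1e-4 * max(D))**2`` on the content factor: the ridge only has to break
    the diagonal scale degeneracy between the factors, and a strong ridge
    (e.g. ``max(D)**2``) visibly biases the fit on RPKM-scale data.
    """

    rank: int = 1
    sparsity_weight: float = 0.01
    smoothness_weight: float | None = None
    max_iter: int = 2000
    tol: float = 1e-6
    n_restarts: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError("rank must be >= 1")
        if self.sparsity_weight < 0 or (self.smoothness_weight is not None and self.smoothness_weight < 0):
            raise ValidationError("penalty weights must be >= 0")
        if self.max_iter < 1 or self.tol <= 0 or self.n_restarts < 1:
            raise ValidationError("max_iter >= 1, tol > 0, n_restarts >= 1 required")


@dataclass
class RankSelectConfig:
    """Candidate rank range and the three strain-plausibility thresholds.

    A candidate rank is accepted only if every strain has mean relative
    abundance > ``tau2``, every strain's called profile has more than
    ``tau3 * g_min`` gene families, and every strain pair has Jaccard
    distance > ``tau1``.
    """

    rank_min: int = 1
    rank_max: int = 12
    tau1: float = 0.1
    tau2: float = 0.1
    tau3: float = 0.5
    theta_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.rank_min < 1 or self.rank_max < self.rank_min:
            raise ValidationError("require 1 <= rank_min <= rank_max")
        if not (0 < self.tau1 < 1 and 0 < self.tau2 < 1):
            raise ValidationError("tau1, tau2 must lie in (0, 1)")
        if not 0 < self.tau3 <= 1:
            raise ValidationError("tau3 must lie in (0, 1]")
        if not 0 < self.theta_fraction < 1:
            raise ValidationError("theta_fraction must lie in (0, 1)")


@dataclass
class FactorizeResult:
    content: np.ndarray        # N x K raw weights (P')
    composition: np.ndarray    # K x S raw loadings (S')
    residual: float            # penalized objective at the solution
    relative_error: float      # ||D - P'S'||_F / ||D||_F
    objective_history: list[float]
    converged: bool

    def __iter__(self):
        # allows `P, S, residual = factorize(...)`
        return iter((self.content, self.composition, self.residual))


def _objective(D: np.ndarray, P: np.ndarray, S: np.ndarray, eta: float, beta: float) -> float:
    resid = D - P @ S
    return 0.5 * (
        float(np.sum(resid * resid))
        + eta * float(np.sum(P * P))
        + beta * float(np.sum(S.sum(axis=0) ** 2))
    )


def factorize(D: GeneFamilyMatrix | np.ndarray, params: FactorizeParams) -> FactorizeResult:
    """Run the sparse NMF; best of ``n_restarts`` seeded runs by objective."""
    V = D.values if isinstance(D, GeneFamilyMatrix) else np.asarray(D, dtype=float)
    n, s = V.shape
    k = params.rank
    if k > min(n, s):
        raise ValidationError(f"rank {k} exceeds min(n_families, n_samples) = {min(n, s)}")
    eta = (
        params.smoothness_weight
        if params.smoothness_weight is not None
        else (1e-4 * float(V.max())) ** 2
    )
    beta = params.sparsity_weight
    scale = np.sqrt(V.mean() / max(k, 1)) or 1.0

    best: FactorizeResult | None = None
    for restart in range(params.n_restarts):
        rng = np.random.default_rng([params.seed, k, restart])
        # only the content factor is random-initialized; the composition factor
        # comes from its exact update, which makes every step of the algorithm
        # equivariant under sample permutations
        P = rng.uniform(0.0, 1.0, size=(n, k)) * scale
        history: list[float] = []
        converged = False
        S = None
        eye = np.eye(k)
        for _ in range(params.max_iter):
            PtP = P.T @ P
            # tiny jitter keeps the Gram matrix positive definite when the
            # factorization is over-ranked (duplicate or empty components)
            jitter = 1e-10 * max(np.trace(PtP) / k, np.finfo(float).tiny)
            S = nnls_blockpivot(PtP + beta + jitter * eye, P.T @ V)
            SSt = S @ S.T
            jitter = 1e-10 * max(np.trace(SSt) / k, np.finfo(float).tiny)
            P = nnls_blockpivot(SSt + (eta + jitter) * eye, S @ V.T).T
            obj = _objective(V, P, S, eta, beta)
            history.append(obj)
            if len(history) > 1:
                prev = history[-2]
                if abs(prev - obj) <= params.tol * max(abs(prev), 1.0):
                    converged = True
                    break
        if not converged:
            warnings.warn(
                f"NMF (rank {k}, restart {restart}) did not converge in "
                f"{params.max_iter} iterations",
                stacklevel=2,
            )
        rel = float(np.linalg.norm(V - P @ S) / max(np.linalg.norm(V), np.finfo(float).tiny))
        candidate = FactorizeResult(P, S, history[-1], rel, history, converged)
        if best is None or candidate.residual < best.residual:
            best = candidate
    assert best is not None
    return best


def scale_composition(
    raw_composition: np.ndarray,
    strain_ids: Iterable[str] | None = None,
    sample_ids: Iterable[str] | None = None,
) -> StrainComposition:
    """Normalize each sample column of the raw composition factor to sum 1."""
    S = np.asarray(raw_composition, dtype=float)
    k, s = S.shape
    strain_ids = list(strain_ids) if strain_ids is not None else [f"strain{i+1}" for i in range(k)]
    sample_ids = list(sample_ids) if sample_ids is not None else [f"sample{j+1}" for j in range(s)]
    sums = S.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValidationError(f"sample {sample_ids[zero[0]]!r} has all-zero strain loadings")
    return StrainComposition(strain_ids, sample_ids, S / sums)


def binarize_with_confidence(
    raw_content_column: np.ndarray,
    expected_count: float,
    theta_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Binarize one strain's weight vector by its density peak.

    Present families should form a tight high-weight mode of roughly
    ``expected_count`` (the mean reference-genome gene count) elements, with
    absent families spread near zero.  Among the local maxima of a Gaussian
    KDE (Silverman bandwidth, 512-point grid on [0, max]) over the strictly
    positive weights, ``p_max`` is the peak whose right-tail element count
    (weights strictly greater than the peak) matches ``expected_count`` most
    closely *from below*; if every peak has a larger right tail, the peak
    with the smallest one is used.  Ties go to the larger peak location.
    Matching from below is what makes the rule identify the present-gene
    mode: a low-lying absent-mode peak carries the whole present cluster in
    its right tail, so its count can sit close to ``expected_count`` from
    above even though cutting below that peak would call everything present.

    ``theta = theta_fraction * p_max``; weights ``>= theta`` are called
    present.  Confidence is 1 for called families and ``(theta - w) / theta``
    otherwise, so it is 1 again at weight 0.

    Returns ``(presence, confidence, p_max, theta)``.
    """
    w = np.asarray(raw_content_column, dtype=float)
    if expected_count <= 0:
        raise ValidationError("expected_count must be > 0")
    positive = w[w > 0]

    p_max = None
    degenerate = positive.size < 10 or np.ptp(positive) <= 1e-12 * max(positive.max(initial=0.0), 1.0)
    if not degenerate:
        kde = gaussian_kde(positive, bw_method="silverman")
        grid = np.linspace(0.0, float(w.max()), 512)
        density = kde(grid)
        interior = (density[1:-1] >= density[:-2]) & (density[1:-1] > density[2:])
        peak_idx = np.flatnonzero(interior) + 1
        # grid endpoints count as peaks if the curve falls away from them
        if density[0] > density[1]:
            peak_idx = np.concatenate(([0], peak_idx))
        if density[-1] > density[-2]:
            peak_idx = np.concatenate((peak_idx, [len(grid) - 1]))
        candidates = grid[peak_idx]
        if candidates.size:
            tails = np.array([(w > p).sum() for p in candidates])
            below = tails <= expected_count
            if below.any():
                pool, counts = candidates[below], tails[below]
                p_max = float(pool[counts == counts.max()].max())
            else:
                p_max = float(candidates[tails == tails.min()].max())
    if p_max is None or p_max <= 0:
        p_max = float(w.max()) if w.max() > 0 else 1.0
        warnings.warn(
            "degenerate weight distribution: falling back to theta = "
            f"{theta_fraction:g} * max weight",
            stacklevel=2,
        )

    theta = theta_fraction * p_max
    presence = (w >= theta).astype(np.int8)
    confidence = np.where(presence == 1, 1.0, (theta - w) / theta)
    return presence, np.clip(confidence, 0.0, 1.0), p_max, theta


def _binarize_content(
    raw_content: np.ndarray,
    family_ids: list[str],
    strain_ids: list[str],
    g_expected: float,
    theta_fraction: float,
) -> StrainGeneContent:
    n, k = raw_content.shape
    presence = np.zeros((n, k), dtype=np.int8)
    confidence = np.zeros((n, k))
    p_max = np.zeros(k)
    theta = np.zeros(k)
    for j in range(k):
        presence[:, j], confidence[:, j], p_max[j], theta[j] = binarize_with_confidence(
            raw_content[:, j], g_expected, theta_fraction
        )
    return StrainGeneContent(family_ids, strain_ids, raw_content, presence, confidence, theta, p_max)


def _pairwise_jaccard(presence: np.ndarray) -> np.ndarray:
    """K x K Jaccard distance matrix between binary profile columns.

    A pair of empty profiles has distance 0 (maximally redundant) so that the
    separation criterion fails instead of erroring."""
    P = presence.astype(bool)
    inter = (P.T.astype(int) @ P.astype(int)).astype(float)
    sizes = P.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    return dist


@dataclass
class RankDiagnostics:
    """Outcome of the three plausibility criteria at one candidate rank."""

    rank: int
    passed: bool
    mean_abundances: list[float]
    gene_counts: list[int]
    min_pairwise_jaccard: float | None
    relative_error: float
    converged: bool
    failures: list[str] = field(default_factory=list)


def _check_criteria(
    presence: np.ndarray,
    composition: StrainComposition,
    stats: PangenomeStats,
    cfg: RankSelectConfig,
) -> tuple[list[str], float | None]:
    failures: list[str] = []
    means = composition.mean_abundance
    for j, m in enumerate(means):
        if not m > cfg.tau2:
            failures.append(
                f"strain {j + 1}: mean relative abundance {m:.4f} <= tau2 = {cfg.tau2}"
            )
    counts = presence.sum(axis=0)
    floor = cfg.tau3 * stats.g_min
    for j, c in enumerate(counts):
        if not c > floor:
            failures.append(
                f"strain {j + 1}: {int(c)} gene families <= tau3 * g_min = {floor:.1f}"
            )
    min_jd: float | None = None
    k = presence.shape[1]
    if k > 1:
        dist = _pairwise_jaccard(presence)
        iu = np.triu_indices(k, 1)
        min_jd = float(dist[iu].min())
        for a, b in zip(*iu):
            if not dist[a, b] > cfg.tau1:
                failures.append(
                    f"strains {a + 1}/{b + 1}: Jaccard distance "
                    f"{dist[a, b]:.4f} <= tau1 = {cfg.tau1}"
                )
    return failures, min_jd


def _fit_rank(
    D: GeneFamilyMatrix,
    rank: int,
    params: FactorizeParams,
    stats: PangenomeStats,
    cfg: RankSelectConfig,
) -> tuple[FactorizeResult, StrainComposition, StrainGeneContent, RankDiagnostics]:
    with warnings.catch_warnings():
        # non-convergence and degenerate-strain warnings at over-split ranks
        # are expected; both outcomes are recorded in the diagnostics
        warnings.simplefilter("ignore")
        fit = factorize(D, replace(params, rank=rank))
    strain_ids = [f"strain{i + 1}" for i in range(rank)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        content = _binarize_content(
            fit.content, D.family_ids, strain_ids, stats.g_expected, cfg.theta_fraction
        )
    # The model is D = P.S with binary P, so once the content is called the
    # composition is re-estimated by NNLS against the binary profiles; this
    # removes the diagonal scale ambiguity of the factorization (a raw S'
    # row is only known up to its strain's weight level) and the residual
    # admixture freedom between overlapping profiles.
    Pb = content.presence.astype(float)
    raw_S = nnls_blockpivot(Pb.T @ Pb, Pb.T @ D.values)
    if (raw_S.sum(axis=0) <= 0).any():
        raw_S = fit.composition  # degenerate content (e.g. empty profiles)
    composition = scale_composition(raw_S, strain_ids, D.sample_ids)
    failures, min_jd = _check_criteria(content.presence, composition, stats, cfg)
    diag = RankDiagnostics(
        rank=rank,
        passed=not failures,
        mean_abundances=[float(x) for x in composition.mean_abundance],
        gene_counts=[int(x) for x in content.gene_counts],
        min_pairwise_jaccard=min_jd,
        relative_error=fit.relative_error,
        converged=fit.converged,
        failures=failures,
    )
    return fit, composition, content, diag


def evaluate_rank(
    D: GeneFamilyMatrix,
    rank: int,
    params: FactorizeParams,
    stats: PangenomeStats,
    cfg: RankSelectConfig | None = None,
) -> RankDiagnostics:
    """Factorize at one candidate rank and score the plausibility criteria."""
    return _fit_rank(D, rank, params, stats, cfg or RankSelectConfig())[3]


def select_rank(
    D: GeneFamilyMatrix,
    params: FactorizeParams,
    stats: PangenomeStats,
    cfg: RankSelectConfig | None = None,
) -> tuple[int, list[RankDiagnostics]]:
    """Choose the number of strains: the largest candidate rank passing all criteria.

    Rank 1 passes the criteria vacuously, so "fewest strains satisfying the
    criteria" cannot be meant literally; the criteria act as rejectors of
    over-split solutions, and the selected rank is the largest one they do
    not reject.  Falls back to 1 when no multi-strain rank passes.
    """
    cfg = cfg or RankSelectConfig()
    cap = min(cfg.rank_max, D.n_families, D.n_samples)
    diagnostics = [
        evaluate_rank(D, k, params, stats, cfg) for k in range(cfg.rank_min, cap + 1)
    ]
    passing = [d.rank for d in diagnostics if d.passed]
    selected = max(passing) if passing else 1
    return selected, diagnostics


def decompose(
    D: GeneFamilyMatrix,
    stats: PangenomeStats,
    params: FactorizeParams | None = None,
    cfg: RankSelectConfig | None = None,
    rank: int | None = None,
    preprocessing_log=None,
) -> DecompositionResult:
    """Full decomposition: rank selection (unless ``rank`` is given),
    factorization, composition scaling and gene-content binarization.

    Strains in the result are ordered by decreasing mean relative abundance
    (ties: larger called profile first, then original factor index).
    """
    params = params or FactorizeParams()
    cfg = cfg or RankSelectConfig()
    if rank is not None:
        selected, diagnostics = int(rank), []
        if selected > min(D.n_families, D.n_samples):
            raise ValidationError("requested rank exceeds matrix dimensions")
    else:
        selected, diagnostics = select_rank(D, params, stats, cfg)

    fit, composition, content, _ = _fit_rank(D, selected, params, stats, cfg)

    means = composition.mean_abundance
    order = sorted(
        range(selected),
        key=lambda j: (-means[j], -int(content.gene_counts[j]), j),
    )
    strain_ids = [f"strain{i + 1}" for i in range(selected)]
    content = StrainGeneContent(
        family_ids=list(D.family_ids),
        strain_ids=strain_ids,
        raw_weights=content.raw_weights[:, order],
        presence=content.presence[:, order],
        confidence=content.confidence[:, order],
        theta=content.theta[order],
        p_max=content.p_max[order],
    )
    composition = StrainComposition(strain_ids, list(D.sample_ids), composition.abundances[order])
    return DecompositionResult(
        gene_content=content,
        composition=composition,
        selected_rank=selected,
        rank_diagnostics=diagnostics,
        preprocessing_log=preprocessing_log,
        seed=params.seed,
    )
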