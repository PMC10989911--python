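"""Benchmark metrics for predicted strain compositions and gene contents.

Composition accuracy is scored by the Jensen-Shannon divergence (base-2 logs,
so values lie in [0, 1]) between abundance vectors sorted in decreasing order
and zero-padded to equal length.  Strain detection is scored by the Matthews
correlation coefficient over a confusion table built from nearest-reference
annotation (smallest Jaccard distance on gene profiles).  Gene-content
accuracy is scored per strain by precision/recall of the binary calls and by
the area under the precision-recall curve of confidence-ranked predictions,
against either simulation ground truth (after optimal strain matching) or a
random-profile baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import rel_entr

from .datamodel import (
    PangenomeStats,
    StrainGeneContent,
    ValidationError,
)

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "StrainAnnotation",
    "StrainMatching",
    "jsd",
    "filter_composition",
    "mcc",
    "confusion_counts",
    "jaccard_distance",
    "annotate_strains",
    "match_strains",
    "pr_auprc",
    "random_profile_baseline",
    "strain_detection_confusion",
    "align_families",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValidationError("confusion table is empty")


@dataclass
class PRCurve:
    thresholds: np.ndarray  # descending distinct scores
    precision: np.ndarray
    recall: np.ndarray      # non-decreasing
    auprc: float


@dataclass
class StrainAnnotation:
    strain_id: str
    genome_id: str    # lexicographically smallest among ties
    distance: float
    ties: list[str] = field(default_factory=list)


@dataclass
class StrainMatching:
    pairs: list[tuple[int, int, float]]  # (predicted index, true index, Jaccard distance)
    extras: list[int]                    # unmatched predicted strains ("Extras")
    missing: list[int]                   # unmatched true strains


def _as_composition(vec: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if v.ndim != 1 or (v < 0).any():
        raise ValidationError(f"{name} must be a nonnegative 1-D vector")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{name} sums to {v.sum()!r}, not 1")
    return v


def jsd(pred: np.ndarray, truth: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence of sorted, zero-padded compositions.

    0 means an exact prediction; the base-2 logarithm makes 1 the exact upper
    bound (attained by disjoint compositions).
    """
    p = np.sort(_as_composition(pred, "pred"))[::-1]
    q = np.sort(_as_composition(truth, "truth"))[::-1]
    size = max(p.size, q.size)
    p = np.pad(p, (0, size - p.size))
    q = np.pad(q, (0, size - q.size))
    m = 0.5 * (p + q)
    value = 0.5 * float(rel_entr(p, m).sum() + rel_entr(q, m).sum()) / np.log(2)
    return min(max(value, 0.0), 1.0)


def filter_composition(vec: np.ndarray, min_abundance: float = 0.01) -> np.ndarray:
    """Drop strains below ``min_abundance`` and rescale the rest to sum 1
    (the convention used before composition reporting and JSD scoring)."""
    v = _as_composition(vec, "composition")
    kept = v[v >= min_abundance]
    if kept.size == 0:
        raise ValidationError("no strain passes the abundance filter")
    return kept / kept.sum()


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Elementwise confusion table between two aligned binary vectors."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValidationError("prediction and truth must be aligned")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _as_set(x) -> frozenset:
    if isinstance(x, (set, frozenset)):
        return frozenset(x)
    arr = np.asarray(x)
    return frozenset(np.flatnonzero(arr).tolist())


def jaccard_distance(a, b) -> float:
    """``1 - |A & B| / |A | B|`` on present-family sets (binary vectors or sets)."""
    sa, sb = _as_set(a), _as_set(b)
    union = sa | sb
    if not union:
        raise ValidationError("Jaccard distance undefined for two empty sets")
    return 1.0 - len(sa & sb) / len(union)


def align_families(
    ids_a: list[str], matrix_a: np.ndarray, ids_b: list[str], matrix_b: np.ndarray
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Outer-join two families x columns matrices on the family universe;
    families absent from one side become zero rows there."""
    union = list(dict.fromkeys([*ids_a, *ids_b]))
    index = {f: i for i, f in enumerate(union)}
    out_a = np.zeros((len(union), matrix_a.shape[1]), dtype=matrix_a.dtype)
    out_b = np.zeros((len(union), matrix_b.shape[1]), dtype=matrix_b.dtype)
    out_a[[index[f] for f in ids_a]] = matrix_a
    out_b[[index[f] for f in ids_b]] = matrix_b
    return union, out_a, out_b


def annotate_strains(content: StrainGeneContent, stats: PangenomeStats) -> list[StrainAnnotation]:
    """Nearest reference genome (smallest Jaccard distance) per predicted strain."""
    _, pred, ref = align_families(
        content.family_ids, content.presence, stats.family_ids, stats.membership
    )
    annotations = []
    for j, strain in enumerate(content.strain_ids):
        profile = pred[:, j]
        if profile.sum() == 0:
            raise ValidationError(f"strain {strain!r} has an empty gene profile")
        dists = np.array(
            [jaccard_distance(profile, ref[:, g]) for g in range(len(stats.genome_ids))]
        )
        best = dists.min()
        ties = sorted(
            stats.genome_ids[g] for g in np.flatnonzero(np.isclose(dists, best, atol=1e-12))
        )
        annotations.append(StrainAnnotation(strain, ties[0], float(best), ties))
    return annotations


def match_strains(
    pred_presence: np.ndarray,
    true_presence: np.ndarray,
    pred_family_ids: list[str] | None = None,
    true_family_ids: list[str] | None = None,
) -> StrainMatching:
    """Minimum-cost bipartite assignment of predicted to true strains on
    Jaccard distance between presence profiles.  Predicted strains beyond the
    true strain count are grouped as extras; cost ties are broken toward the
    lowest predicted-strain index."""
    if pred_family_ids is not None or true_family_ids is not None:
        _, pred_presence, true_presence = align_families(
            list(pred_family_ids), pred_presence, list(true_family_ids), true_presence
        )
    kp, kt = pred_presence.shape[1], true_presence.shape[1]
    cost = np.zeros((kp, kt))
    for i in range(kp):
        for j in range(kt):
            a, b = pred_presence[:, i], true_presence[:, j]
            if a.sum() == 0 and b.sum() == 0:
                cost[i, j] = 0.0
            else:
                cost[i, j] = jaccard_distance(a, b)
    # lexicographic epsilon keeps equal-cost assignments deterministic and
    # biased toward low predicted indices
    eps = 1e-9 * (np.arange(kp)[:, None] * kt + np.arange(kt)[None, :])
    rows, cols = linear_sum_assignment(cost + eps)
    pairs = [(int(i), int(j), float(cost[i, j])) for i, j in zip(rows, cols)]
    matched_pred = {i for i, _, _ in pairs}
    matched_true = {j for _, j, _ in pairs}
    return StrainMatching(
        pairs=sorted(pairs, key=lambda t: t[1]),
        extras=[i for i in range(kp) if i not in matched_pred],
        missing=[j for j in range(kt) if j not in matched_true],
    )


def pr_auprc(
    confidence: np.ndarray, presence_calls: np.ndarray, truth: np.ndarray
) -> PRCurve:
    """Precision-recall curve of confidence-ranked gene presence predictions.

    The confidence score is 1 both for confidently present and confidently
    absent families, so ranking uses the signed score ``+confidence`` for
    called-present and ``-confidence`` for called-absent families
    (confident-present > uncertain > confident-absent).  Precision and recall
    are evaluated at every distinct score threshold; the area is trapezoidal,
    anchored at (recall 0, first precision).
    """
    conf = np.asarray(confidence, dtype=float)
    calls = np.asarray(presence_calls).astype(bool)
    t = np.asarray(truth).astype(bool)
    if not (conf.shape == calls.shape == t.shape):
        raise ValidationError("confidence, calls and truth must be aligned")
    total = int(t.sum())
    if total == 0:
        raise ValidationError("truth profile has no present family; recall undefined")

    scores = np.where(calls, conf, -conf)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = t[order]
    tp = np.cumsum(t_sorted)
    fp = np.cumsum(~t_sorted)
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    cut = np.concatenate((distinct, [s_sorted.size - 1]))

    precision = tp[cut] / (tp[cut] + fp[cut])
    recall = tp[cut] / total
    thresholds = s_sorted[cut]

    r = np.concatenate(([0.0], recall))
    p = np.concatenate(([precision[0]], precision))
    auprc = float(np.trapezoid(p, r))
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall,
                   auprc=min(max(auprc, 0.0), 1.0))


def random_profile_baseline(
    stats: PangenomeStats,
    truth: np.ndarray,
    n_draws: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """AUPRC distribution of random gene-family profiles against one truth
    profile: each draw marks ``round(g_expected)`` families (uniform, without
    replacement) as present with full confidence."""
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    n = len(stats.family_ids)
    size = int(round(stats.g_expected))
    if size > n:
        raise ValidationError("g_expected exceeds the pangenome size")
    t = np.asarray(truth).astype(bool)
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    for d in range(n_draws):
        calls = np.zeros(n, dtype=bool)
        calls[rng.choice(n, size=size, replace=False)] = True
        out[d] = pr_auprc(np.ones(n), calls, t).auprc
    return out


def strain_detection_confusion(
    content: StrainGeneContent,
    stats: PangenomeStats,
    true_genome_ids: list[str],
    distance_cutoff: float = 0.1,
) -> ConfusionCounts:
    """Strain-detection confusion table via nearest-reference annotation.

    A predicted strain annotated (within ``distance_cutoff``) to a genome in
    ``true_genome_ids`` is a true positive; reference genomes neither truly
    present nor predicted count as true negatives."""
    annotations = annotate_strains(content, stats)
    truth = set(true_genome_ids)
    universe = set(stats.genome_ids)
    detected: set[str] = set()
    fp = 0
    for a in annotations:
        if a.distance <= distance_cutoff and a.genome_id in truth and a.genome_id not in detected:
            detected.add(a.genome_id)
        else:
            fp += 1
    annotated = {a.genome_id for a in annotations}
    return ConfusionCounts(
        tp=len(detected),
        tn=len(universe - truth - annotated),
        fp=fp,
        fn=len(truth - detected),
    )
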