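"""RPKM normalization and abundance-matrix cleanup before decomposition.

Mirrors the standard pangenome-profile preprocessing: entries below an RPKM
cutoff are treated as mapping noise and zeroed, samples with too few detected
gene families (below ``sample_min_fraction * g_min``) are discarded, and gene
families left without signal in any surviving sample are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import GeneFamilyMatrix, PangenomeStats, ValidationError

__all__ = ["PreprocessConfig", "PreprocessLog", "PreprocessError", "rpkm_normalize", "trim_and_filter"]


class PreprocessError(ValueError):
    """Preprocessing removed everything (no usable samples or families)."""


@dataclass
class PreprocessConfig:
    rpkm_cutoff: float = 10.0
    sample_min_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.rpkm_cutoff < 0:
            raise ValidationError("rpkm_cutoff must be >= 0")
        if not 0 < self.sample_min_fraction <= 1:
            raise ValidationError("sample_min_fraction must lie in (0, 1]")


@dataclass
class PreprocessLog:
    rpkm_cutoff: float
    sample_threshold: float
    dropped_families: list[str] = field(default_factory=list)
    dropped_samples: list[dict] = field(default_factory=list)


def _as_series(data: Mapping[str, float] | pd.Series, ids: list[str], what: str) -> np.ndarray:
    series = pd.Series(data)
    missing = [i for i in ids if i not in series.index]
    if missing:
        raise ValidationError(f"missing {what} for: {missing[:5]}")
    values = series.reindex(ids).to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValidationError(f"{what} values must be strictly positive")
    return values


def rpkm_normalize(
    counts: GeneFamilyMatrix,
    gene_lengths: Mapping[str, float] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series,
) -> GeneFamilyMatrix:
    """Convert raw read counts to reads per kilobase per million mapped reads.

    ``rpkm = count * 1e9 / (gene_length_bp * library_size)``.
    """
    if counts.units != "counts":
        raise ValidationError("rpkm_normalize expects a matrix with units='counts'")
    lengths = _as_series(gene_lengths, counts.family_ids, "gene length")
    libsizes = _as_series(library_sizes, counts.sample_ids, "library size")
    values = counts.values * 1e9 / (lengths[:, None] * libsizes[None, :])
    return GeneFamilyMatrix(
        family_ids=list(counts.family_ids),
        sample_ids=list(counts.sample_ids),
        values=values,
        units="rpkm",
    )


def trim_and_filter(
    D: GeneFamilyMatrix,
    stats: PangenomeStats,
    cfg: PreprocessConfig | None = None,
) -> tuple[GeneFamilyMatrix, PreprocessLog]:
    """Trim sub-cutoff entries to zero, drop under-covered samples, drop empty rows.

    Thresholds are strict: an entry exactly equal to ``rpkm_cutoff`` survives,
    and a sample detecting exactly ``sample_min_fraction * g_min`` families is
    kept.  Family emptiness is re-evaluated on the surviving samples, so a
    family supported only by a discarded sample is removed too.
    """
    cfg = cfg or PreprocessConfig()
    if D.units != "rpkm":
        warnings.warn("trim_and_filter applied to a non-RPKM matrix", stacklevel=2)

    values = D.values.copy()
    values[values < cfg.rpkm_cutoff] = 0.0

    threshold = cfg.sample_min_fraction * stats.g_min
    detected = (values > 0).sum(axis=0)
    keep_samples = detected >= threshold
    log = PreprocessLog(rpkm_cutoff=cfg.rpkm_cutoff, sample_threshold=threshold)
    log.dropped_samples = [
        {"id": D.sample_ids[j], "detected": int(detected[j]), "threshold": threshold}
        for j in np.flatnonzero(~keep_samples)
    ]
    if not keep_samples.any():
        raise PreprocessError("no sample passes coverage filter")

    values = values[:, keep_samples]
    keep_families = (values > 0).any(axis=1)
    log.dropped_families = [D.family_ids[i] for i in np.flatnonzero(~keep_families)]
    if not keep_families.any():
        raise PreprocessError("all gene families removed by trimming")

    out = GeneFamilyMatrix(
        family_ids=[f for f, k in zip(D.family_ids, keep_families) if k],
        sample_ids=[s for s, k in zip(D.sample_ids, keep_samples) if k],
        values=values[keep_families],
        units=D.units,
    )
    return out, log
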