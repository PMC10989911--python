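"""Core domain types shared by every stage of the pipeline.

The central object is a nonnegative gene-family x sample abundance matrix
(``GeneFamilyMatrix``) obtained by mapping metagenomic reads against a species
pangenome.  Decomposition factorizes it into a binary gene-content matrix per
strain (``StrainGeneContent``) and a strain x sample relative-abundance matrix
(``StrainComposition``).  A pangenome membership table over reference genomes
(``PangenomeStats``) calibrates sample filtering and binarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GeneFamilyMatrix",
    "PangenomeStats",
    "StrainGeneContent",
    "StrainComposition",
    "DecompositionResult",
    "derive_pangenome_stats",
]

VALID_UNITS = ("counts", "rpkm")


class ValidationError(ValueError):
    """An input violates a structural invariant (labels, signs, shapes)."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValidationError(f"duplicate {what} IDs: {dups}")
    return ids


@dataclass
class GeneFamilyMatrix:
    """Gene-family x sample abundance matrix (raw counts or RPKM)."""

    family_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    units: str = "rpkm"

    def __post_init__(self) -> None:
        self.family_ids = _check_unique(self.family_ids, "gene-family")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.family_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.family_ids)} families x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"missing value at family {self.family_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} (missing cells are not imputed)"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at family {self.family_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.units not in VALID_UNITS:
            raise ValidationError(f"units must be one of {VALID_UNITS}, got {self.units!r}")

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.family_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, units: str = "rpkm") -> "GeneFamilyMatrix":
        return cls(
            family_ids=list(map(str, frame.index)),
            sample_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
            units=units,
        )


@dataclass
class PangenomeStats:
    """Binary gene-family membership of reference genomes plus derived scalars.

    ``g_min`` is the minimum per-genome gene-family count and ``g_expected``
    the mean; they calibrate the sample coverage filter and the expected size
    of a called gene-content profile, respectively.
    """

    family_ids: list[str]
    genome_ids: list[str]
    membership: np.ndarray
    g_min: int = field(init=False)
    g_expected: float = field(init=False)

    def __post_init__(self) -> None:
        self.family_ids = _check_unique(self.family_ids, "gene-family")
        self.genome_ids = _check_unique(self.genome_ids, "genome")
        if len(self.genome_ids) == 0:
            raise ValidationError("pangenome table must contain at least one genome")
        m = np.asarray(self.membership)
        if m.shape != (len(self.family_ids), len(self.genome_ids)):
            raise ValidationError("membership shape does not match ID lists")
        if not np.isin(m, (0, 1)).all():
            bad = m[~np.isin(m, (0, 1))][0]
            raise ValidationError(f"membership entries must be 0/1, found {bad!r}")
        self.membership = m.astype(np.int8)
        counts = self.membership.sum(axis=0)
        self.g_min = int(counts.min())
        self.g_expected = float(counts.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.membership, index=self.family_ids, columns=self.genome_ids)


def derive_pangenome_stats(membership_table: pd.DataFrame) -> PangenomeStats:
    """Build :class:`PangenomeStats` from a binary families x genomes table."""
    values = membership_table.to_numpy()
    if values.size and not np.isreal(values).all():
        raise ValidationError("membership table must be numeric 0/1")
    return PangenomeStats(
        family_ids=list(map(str, membership_table.index)),
        genome_ids=list(map(str, membership_table.columns)),
        membership=values,
    )


@dataclass
class StrainGeneContent:
    """Per-strain gene content: raw NMF weights, binary calls, confidences.

    ``presence[i, j] = 1`` iff ``raw_weights[i, j] >= theta[j]`` where
    ``theta[j] = theta_fraction * p_max[j]`` is the per-strain density-peak
    threshold.  ``confidence`` is 1 for called-present families and decays
    linearly to 1 again at weight 0 for confidently absent families.
    """

    family_ids: list[str]
    strain_ids: list[str]
    raw_weights: np.ndarray
    presence: np.ndarray
    confidence: np.ndarray
    theta: np.ndarray
    p_max: np.ndarray

    def __post_init__(self) -> None:
        self.family_ids = _check_unique(self.family_ids, "gene-family")
        self.strain_ids = _check_unique(self.strain_ids, "strain")
        n, k = len(self.family_ids), len(self.strain_ids)
        self.raw_weights = np.asarray(self.raw_weights, dtype=float)
        self.presence = np.asarray(self.presence)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.p_max = np.asarray(self.p_max, dtype=float)
        for name, arr, shape in (
            ("raw_weights", self.raw_weights, (n, k)),
            ("presence", self.presence, (n, k)),
            ("confidence", self.confidence, (n, k)),
            ("theta", self.theta, (k,)),
            ("p_max", self.p_max, (k,)),
        ):
            if arr.shape != shape:
                raise ValidationError(f"{name} shape {arr.shape} != {shape}")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValidationError("presence entries must be 0/1")
        self.presence = self.presence.astype(np.int8)
        if ((self.confidence < -1e-12) | (self.confidence > 1 + 1e-12)).any():
            raise ValidationError("confidence entries must lie in [0, 1]")
        expected = (self.raw_weights >= self.theta[None, :]).astype(np.int8)
        if not np.array_equal(expected, self.presence):
            raise ValidationError("presence must equal raw_weight >= theta elementwise")

    @property
    def gene_counts(self) -> np.ndarray:
        """Number of called-present gene families per strain."""
        return self.presence.sum(axis=0)

    def presence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.family_ids, columns=self.strain_ids)


@dataclass
class StrainComposition:
    """Strain x sample relative abundances; every column sums to one."""

    strain_ids: list[str]
    sample_ids: list[str]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.strain_ids = _check_unique(self.strain_ids, "strain")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.strain_ids), len(self.sample_ids)):
            raise ValidationError("abundance shape does not match ID lists")
        if (self.abundances < 0).any():
            raise ValidationError("relative abundances must be nonnegative")
        sums = self.abundances.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            j = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"column for sample {self.sample_ids[j]!r} sums to {sums[j]!r}, not 1"
            )

    @property
    def mean_abundance(self) -> np.ndarray:
        """Mean relative abundance of each strain across samples."""
        return self.abundances.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundances, index=self.strain_ids, columns=self.sample_ids)


@dataclass
class DecompositionResult:
    """Bundle of a full decomposition run (factors, rank diagnostics, seed)."""

    gene_content: StrainGeneContent
    composition: StrainComposition
    selected_rank: int
    rank_diagnostics: list[Any]
    preprocessing_log: Mapping[str, Any] | None
    seed: int

    def __post_init__(self) -> None:
        k = self.selected_rank
        if len(self.gene_content.strain_ids) != k or len(self.composition.strain_ids) != k:
            raise ValidationError("selected_rank does not match factor dimensions")
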