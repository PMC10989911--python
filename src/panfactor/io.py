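"""Readers and writers for the TSV/JSON interchange formats.

Gene-family matrices and pangenome membership tables are delimited text with
one header row of sample/genome IDs and a leading column of gene-family IDs.
Tab is the canonical delimiter; comma input is tolerated (auto-detected from
the header line).  Output is always tab-delimited.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datamodel import (
    DecompositionResult,
    GeneFamilyMatrix,
    PangenomeStats,
    ValidationError,
    derive_pangenome_stats,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "read_pangenome",
    "write_result",
]

_FLOAT_FORMAT = "%.6g"


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a labelled table (first column = row IDs, header = column IDs)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path}: non-numeric cell in column {col!r} "
                f"(e.g. row {bad.index[0]!r} = {bad.iloc[0]!r})"
            )
    return frame


def read_matrix(path: str | Path, units: str = "rpkm") -> GeneFamilyMatrix:
    """Read a gene-family abundance matrix; validates signs and label uniqueness."""
    return GeneFamilyMatrix.from_frame(read_table(path), units=units)


def write_matrix(matrix: GeneFamilyMatrix | pd.DataFrame, path: str | Path) -> None:
    frame = matrix.to_frame() if isinstance(matrix, GeneFamilyMatrix) else matrix
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, index_label="family")


def read_pangenome(path: str | Path) -> PangenomeStats:
    """Read a binary families x genomes membership table."""
    return derive_pangenome_stats(read_table(path))


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_result(result: DecompositionResult, outdir: str | Path) -> list[Path]:
    """Serialize a decomposition: P.tsv, P_weights.tsv, confidence.tsv, S.tsv,
    diagnostics.json.  Returns the list of files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gc = result.gene_content
    written = []

    def _save(frame: pd.DataFrame, name: str, index_label: str = "family") -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, index_label=index_label)
        written.append(path)

    strains, families = gc.strain_ids, gc.family_ids
    _save(pd.DataFrame(gc.presence, index=families, columns=strains), "P.tsv")
    _save(pd.DataFrame(gc.raw_weights, index=families, columns=strains), "P_weights.tsv")
    _save(pd.DataFrame(gc.confidence, index=families, columns=strains), "confidence.tsv")
    _save(result.composition.to_frame(), "S.tsv", index_label="strain")

    diagnostics = {
        "selected_rank": result.selected_rank,
        "seed": result.seed,
        "theta": gc.theta.tolist(),
        "p_max": gc.p_max.tolist(),
        "rank_diagnostics": _jsonable(result.rank_diagnostics),
        "preprocessing_log": _jsonable(result.preprocessing_log),
    }
    diag_path = outdir / "diagnostics.json"
    diag_path.write_text(json.dumps(diagnostics, indent=2) + "\n")
    written.append(diag_path)
    return written
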