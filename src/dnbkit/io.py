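"""Plain-text I/O: expression TSVs, sample metadata, biotype annotations.

All artifacts are UTF-8 TSV with decimal points; values round-trip exactly
at 12 significant digits.  Validation errors name the offending line.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .synthetic import ExpressionMatrix, StageSeries

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "read_annotation_tsv",
    "read_stage_series",
    "load_candidate_annotation",
]


def read_expression_tsv(path: str | Path, stage_label: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV whose first column is ``gene_id``.

    Duplicate gene ids, ragged rows and non-numeric cells raise
    :class:`ParseError` naming the 1-based file line.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "gene_id":
        raise ParseError(f"{path}: line 1: first column must be 'gene_id'")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: line 1: duplicate sample ids")
    gene_ids: list[str] = []
    seen: set[str] = set()
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: line {ln}: expected {len(header)} columns, got {len(cells)}"
            )
        gid = cells[0]
        if gid in seen:
            raise ParseError(f"{path}: line {ln}: duplicate gene id {gid!r}")
        seen.add(gid)
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as e:
            raise ParseError(f"{path}: line {ln}: non-numeric cell ({e})") from None
        gene_ids.append(gid)
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
        stage_label=stage_label if stage_label is not None else path.stem,
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV at 12 significant digits (lossless round-trip
    for values representable at that precision)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata table (``sample_id``, ``stage``,
    ``stage_order``), sorted by stage order."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    for col in ("sample_id", "stage", "stage_order"):
        if col not in meta.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    return meta.sort_values(["stage_order", "sample_id"], kind="stable")


def read_stage_series(stage_paths: dict[str, str | Path] | None = None,
                      directory: str | Path | None = None) -> StageSeries:
    """Assemble a :class:`StageSeries` from per-stage TSVs plus
    ``samples.tsv`` metadata.

    Either pass ``directory`` (the layout written by
    :func:`dnbkit.synthetic.write_stage_series`) or an explicit mapping of
    stage label to file path together with a directory holding
    ``samples.tsv``.  Samples listed in the metadata but absent from the
    matrices (or vice versa) raise :class:`ParseError` naming the orphans.
    """
    if directory is None:
        raise ParseError("directory with samples.tsv is required")
    directory = Path(directory)
    meta = read_metadata_tsv(directory / "samples.tsv")
    order = (
        meta.drop_duplicates("stage").sort_values("stage_order")["stage"].tolist()
    )
    if stage_paths is None:
        stage_paths = {lab: directory / f"{lab}.tsv" for lab in order}
    stages = []
    for lab in order:
        m = read_expression_tsv(stage_paths[lab], stage_label=lab)
        expected = set(meta.loc[meta["stage"] == lab, "sample_id"])
        got = set(m.sample_ids)
        if expected != got:
            orphans = sorted(expected ^ got)
            raise ParseError(
                f"stage {lab!r}: sample ids disagree between metadata and "
                f"matrix: {orphans}"
            )
        stages.append(m)
    return StageSeries(stages=stages, stage_order=order)


def read_annotation_tsv(path: str | Path) -> dict[str, str]:
    """Read a ``gene_id``/``biotype`` table into a dict (last entry wins on
    duplicates, with a warning)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty annotation file")
    header = lines[0].split("\t")
    if "gene_id" not in header or "biotype" not in header:
        raise ParseError(f"{path}: header must contain 'gene_id' and 'biotype'")
    gi, bi = header.index("gene_id"), header.index("biotype")
    table: dict[str, str] = {}
    for ln, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(f"{path}: line {ln}: ragged row")
        gid = cells[gi]
        if gid in table:
            warnings.warn(
                f"{path}: line {ln}: duplicate annotation for {gid!r}; "
                "last entry wins",
                stacklevel=2,
            )
        table[gid] = cells[bi]
    return table


def load_candidate_annotation() -> dict[str, str]:
    """Biotype annotation for the published TSOD top-10 candidate list
    (shipped with the package)."""
    ref = resources.files("dnbkit.data") / "tsod_top10_annotation.tsv"
    with resources.as_file(ref) as path:
        return read_annotation_tsv(path)
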