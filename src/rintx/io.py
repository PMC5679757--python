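"""Plain-text I/O for expression matrices and cohort tables.

Expression matrices are tab-separated with a ``gene_id`` first column and
sample ids as the header; values are written as shortest-round-trip
decimals so read -> write is byte-identical.  Lines starting with ``#``
(provenance headers) are ignored on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import LINEAR, LOG2, ExpressionMatrix


def read_expression(path, space: str = LINEAR) -> ExpressionMatrix:
    """Read a genes x samples TSV into an ExpressionMatrix.

    Raises on duplicated gene or sample ids (naming the offender) and on
    non-numeric cells (naming the coordinates).  A header-only file is a
    valid zero-gene matrix.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.columns[0] != "gene_id":
        raise ValueError(f"first column must be 'gene_id', got {df.columns[0]!r}")
    genes = df["gene_id"]
    dup = genes[genes.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated gene id: {dup.iloc[0]!r}")
    sample_cols = df.columns[1:]
    dup_s = sample_cols[sample_cols.duplicated()]
    if len(dup_s):
        raise ValueError(f"duplicated sample id: {dup_s[0]!r}")
    values = np.empty((len(df), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        try:
            # exact strtod parsing; pandas' fast parser can be off by 1 ulp
            values[:, j] = np.asarray(df[col], dtype=np.float64)
        except ValueError:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            gi = bad.idxmax()
            raise ValueError(
                f"non-numeric cell at gene {genes[gi]!r}, sample {col!r}: {df[col][gi]!r}"
            ) from None
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=list(sample_cols))
    return ExpressionMatrix(data, space=space)


def write_expression(matrix: ExpressionMatrix, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("gene_id\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        vals = matrix.data.to_numpy()
        for gene, row in zip(matrix.gene_ids, vals):
            fh.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int, config: dict) -> list[str]:
    from . import __version__

    return [
        f"rintx version: {__version__}",
        f"seed: {seed}",
        f"config hash: {config_hash(config)}",
    ]
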