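"""TSV and JSON interchange for matrices, results, and metadata.

Matrices travel as tab-separated tables with the taxon identifier in the
first column and one column per sample named
``<subject>_<group>_<timepoint>``. Normalized matrices get a JSON sidecar
recording the method, pseudocount, and per-sample factors.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .normalization import NormalizedMatrix

TAXON_COLUMN = "taxon"


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label=TAXON_COLUMN)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_count_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a user count table; entries must be non-negative integers."""
    df = read_matrix_tsv(path)
    values = df.to_numpy()
    if (values < 0).any():
        raise ValueError("count matrix has negative entries")
    if ((values % 1) != 0).any():
        raise ValueError("count matrix has non-integer entries")
    return df.astype(int)


def sample_metadata(columns) -> pd.DataFrame:
    """Parse ``<subject>_<group>_<timepoint>`` sample names into a table."""
    rows = []
    for name in columns:
        parts = str(name).split("_")
        if len(parts) != 3:
            raise ValueError(f"sample name {name!r} is not subject_group_timepoint")
        rows.append({"sample": name, "subject": parts[0], "group": parts[1], "timepoint": parts[2]})
    return pd.DataFrame(rows).set_index("sample")


def write_normalized(norm: NormalizedMatrix, path: str | Path) -> None:
    """Write the values TSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    write_matrix_tsv(norm.values, path)
    meta = {
        "method": norm.method,
        "pseudocount": norm.pseudocount,
        "factors": None if norm.factors is None else norm.factors.to_dict(),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_normalized(path: str | Path) -> NormalizedMatrix:
    path = Path(path)
    values = read_matrix_tsv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    factors = meta.get("factors")
    return NormalizedMatrix(
        values=values,
        method=meta["method"],
        pseudocount=meta.get("pseudocount"),
        factors=None if factors is None else pd.Series(factors).reindex(values.columns),
    )


def write_distance_tsv(d: pd.DataFrame, path: str | Path) -> None:
    d.to_csv(path, sep="\t", index_label="sample")
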