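"""Readers and writers for the plain-text formats used across the pipeline.

All tabular data are tab-separated text. Interaction networks are 3-column
edge lists (node_a, node_b, combined_score); annotation sets use the GMT
convention (set name, description, then member ids, one set per line).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .params import PARAMETERS, WELL_KEY_COLUMNS


def read_well_table(path: str | Path) -> pd.DataFrame:
    """Read a well-level screen table, validating the expected columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WELL_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table {path} lacks columns: {missing}")
    param_cols = [c for c in PARAMETERS if c in df.columns]
    if not param_cols:
        raise ValueError(f"well table {path} has no known parameter columns")
    df["is_edge"] = df["is_edge"].astype(bool)
    for col in ("shrna_id", "gene"):
        df[col] = df[col].fillna("").astype(str)
    return df


def write_well_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_protein_quant(
    quant_path: str | Path, metadata_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a protein-by-sample intensity matrix and its sample metadata.

    The quant table is indexed by protein id with an optional ``description``
    column; every other column is a sample. Metadata must carry ``sample``,
    ``group``, ``replicate`` and ``median_q`` columns.
    """
    quant = pd.read_csv(quant_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"sample", "group", "replicate", "median_q"}
    if not required.issubset(meta.columns):
        raise ValueError(f"sample metadata lacks columns: {required - set(meta.columns)}")
    sample_cols = [c for c in quant.columns if c != "description"]
    unknown = set(meta["sample"]) - set(sample_cols)
    if unknown:
        raise ValueError(f"metadata refers to samples absent from quant table: {sorted(unknown)}")
    return quant, meta


def read_network(path: str | Path) -> pd.DataFrame:
    """Read a weighted edge list with columns node_a, node_b, combined_score."""
    df = pd.read_csv(path, sep="\t")
    required = {"node_a", "node_b", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"network {path} lacks columns: {required - set(df.columns)}")
    bad = df[(df["combined_score"] < 0) | (df["combined_score"] > 1)]
    if len(bad):
        raise ValueError("combined_score outside [0, 1]")
    return df


def write_network(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_id_list(path: str | Path) -> set[str]:
    """Read a newline-delimited id file (e.g. a query protein set)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
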