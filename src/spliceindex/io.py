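"""Plain-text I/O: TSV matrices and tables, FASTA sequences.

Every table the pipeline writes starts with comment lines recording the
package version, the configuration hash and the seed, so a result file is
traceable to the run that produced it; readers skip ``#`` comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str | Path, header_meta: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_meta:
            for key, value in header_meta.items():
                fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, index_col=0)
    df.index.name = "probe_id"
    return df


def read_genotypes(path: str | Path) -> pd.Series:
    df = read_tsv(path)
    return pd.Series(df["genotype"].to_numpy(), index=pd.Index(df["sample_id"], name="sample_id"), name="genotype")


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    df["event_id"] = df["event_id"].fillna("")
    return df


def write_fasta(records: Iterable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list:
    return list(SeqIO.parse(str(path), "fasta"))
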