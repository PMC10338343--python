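"""Shared readers/writers: FASTA, TSV with schema checks, JSON reports.

TSV with a header line is the universal tabular format and JSON holds
nested results; gzip-compressed files are handled transparently by
extension.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("piwikit")

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> Dict[str, str]:
    """FASTA file -> {record id: sequence}; warns on empty input."""
    with _open_text(path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        log.warning("empty FASTA: %s", path)
    log.info("read %d FASTA records from %s", len(records), path)
    return records


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_tsv(
    path: PathLike,
    required_columns: Optional[Sequence[str]] = None,
    index_col: Optional[str] = None,
) -> pd.DataFrame:
    """Headered TSV -> DataFrame, with a schema check naming missing columns."""
    df = pd.read_csv(path, sep="\t")
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) {missing}; "
                f"found {list(df.columns)}"
            )
    if index_col is not None:
        df = df.set_index(index_col)
    log.info("read %d rows from %s", len(df), path)
    return df


def write_tsv(df: pd.DataFrame, path: PathLike, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
    log.info("wrote %d rows to %s", len(df), path)


def write_json(obj, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def read_json(path: PathLike):
    with _open_text(path) as fh:
        return json.load(fh)


def _json_default(obj):
    try:
        import numpy as np
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
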