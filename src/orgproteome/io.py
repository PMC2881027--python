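"""FASTA / TSV / JSON I/O helpers. All coordinates in output files are
1-based inclusive; every summary declares the config hash that produced it."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ProteinRecord, _AA_SET
from .signalpep import VOTE_COLUMNS

logger = logging.getLogger("orgproteome")


def read_fasta(path, tolerate_X: bool = True) -> List[ProteinRecord]:
    """Read a multi-FASTA into protein records.

    Sequences are uppercased; records containing the ambiguity symbol ``X``
    are dropped with a logged warning when *tolerate_X* is set, and any other
    non-standard residue raises an error naming the record and symbol.
    """
    path = Path(path)
    records: List[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise ValueError(f"record {entry.id!r} in {path} is empty")
        bad = sorted(set(seq) - _AA_SET)
        if bad == ["X"] and tolerate_X:
            logger.warning("dropping record %r: contains ambiguity symbol X", entry.id)
            continue
        if bad:
            raise ValueError(
                f"record {entry.id!r} contains non-standard residue {bad[0]!r}"
            )
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"no usable FASTA records in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(Path(path)), "fasta")


def write_truth_sidecar(records: Sequence[ProteinRecord], path) -> None:
    """Sidecar TSV with truth labels and 1-based cleavage indices."""
    rows = [
        {"id": r.id, "truth_label": r.truth_label or "",
         "cleavage_index": r.sp_truth if r.sp_truth is not None else ""}
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "truth_label", "cleavage_index"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth_sidecar(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    expected = ["id", "truth_label", "cleavage_index"]
    if list(df.columns) != expected:
        raise ValueError(f"sidecar TSV must have columns {expected}, got {list(df.columns)}")
    return df


def read_vote_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "predictor": str})
    if list(df.columns) != VOTE_COLUMNS:
        raise ValueError(
            f"vote table must have exactly columns {VOTE_COLUMNS}, got {list(df.columns)}"
        )
    df["cleavage_pos"] = df["cleavage_pos"].fillna("")
    return df


def write_vote_table(table: pd.DataFrame, path) -> None:
    table[VOTE_COLUMNS].to_csv(path, sep="\t", index=False)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(obj: Dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
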