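"""File formats: FASTA unigenes, one-tag-per-line libraries, TSV tables,
ground-truth JSON. All writers are deterministic given identical inputs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import GroundTruth
from .tag_filter import CleanTagTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tag_library",
    "write_tag_library",
    "read_clean_table",
    "write_clean_table",
    "write_ground_truth",
    "read_ground_truth",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Unigene FASTA -> ordered id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(unigenes: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=uid, description="") for uid, seq in unigenes.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_tag_library(path: str | Path) -> list[str]:
    """Raw tag observations: one tag per line, or FASTQ (sequence field)."""
    path = Path(path)
    if path.suffix in (".fastq", ".fq"):
        return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def write_tag_library(tags: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(t + "\n")


def write_clean_table(table: CleanTagTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_clean_table(path: str | Path, library: str) -> CleanTagTable:
    df = pd.read_csv(path, sep="\t", dtype={"tag17": str, "count": int})
    return CleanTagTable(library=library, counts=dict(zip(df["tag17"], df["count"])))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "stages": list(truth.expression_matrix.columns),
        "expression_matrix": {
            uid: [float(x) for x in row]
            for uid, row in truth.expression_matrix.iterrows()
        },
        "specificity_labels": truth.specificity_labels.to_dict(),
        "true_canonical_tags": truth.true_canonical_tags,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    mat = pd.DataFrame.from_dict(
        payload["expression_matrix"], orient="index", columns=payload["stages"]
    ).sort_index()
    return GroundTruth(
        expression_matrix=mat,
        specificity_labels=pd.Series(payload["specificity_labels"], name="label").sort_index(),
        true_canonical_tags=payload["true_canonical_tags"],
    )
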