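"""Plain-text readers and writers shared by all stages.

Every stage communicates through inspectable flat files: FASTA for
sequences (via Biopython), BED12 for exon-block structures, TSV for
per-CpG methylation and depth windows, JSON for truth sidecars and run
summaries. Emitters stamp the generating seed into headers so any file
can be traced back to its simulation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bed12",
    "read_bed12",
    "write_methyl_tsv",
    "read_methyl_tsv",
    "write_depth_tsv",
    "read_depth_tsv",
    "write_json",
]


def write_fasta(records: Iterable[tuple[str, str, str]], path, seed: int | None = None) -> None:
    """Write (id, description, sequence) triples; the seed is appended to
    each description so emitted FASTA is self-documenting."""
    stamp = f"seed={seed}" if seed is not None else ""
    seqs = [
        SeqRecord(Seq(seq), id=name, description=" ".join(x for x in (desc, stamp) if x))
        for name, desc, seq in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed12(rows: Sequence[dict], path, seed: int | None = None) -> None:
    """Write BED12. Each row dict needs chrom, start, end, name, strand and
    blocks (sorted (start, end) genomic intervals)."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for row in rows:
            blocks = row["blocks"]
            starts = ",".join(str(s - row["start"]) for s, _ in blocks)
            sizes = ",".join(str(e - s) for s, e in blocks)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        row["chrom"],
                        row["start"],
                        row["end"],
                        row["name"],
                        row.get("score", 0),
                        row["strand"],
                        row["start"],
                        row["end"],
                        "0,0,0",
                        len(blocks),
                        sizes + ",",
                        starts + ",",
                    )
                )
                + "\n"
            )


def read_bed12(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise InputError(f"BED12 line with {len(f)} fields in {path}")
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            rows.append(
                {
                    "chrom": f[0],
                    "start": start,
                    "end": int(f[2]),
                    "name": f[3],
                    "score": f[4],
                    "strand": f[5],
                    "blocks": blocks,
                }
            )
    return rows


def write_methyl_tsv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """bedMethyl-style table: chrom, start, end, coverage, percent_methylated."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_methyl_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "end" not in df.columns and {"chrom", "start", "coverage"} <= set(df.columns):
        df = df.assign(end=df["start"] + 2)  # minimal 4-column dialect
    required = {"chrom", "start", "coverage", "percent_methylated"}
    if not required <= set(df.columns):
        raise InputError(f"methylation table missing columns {required - set(df.columns)}")
    return df


def write_depth_tsv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_depth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"region", "start", "end", "count"}
    if not required <= set(df.columns):
        raise InputError(f"depth table missing columns {required - set(df.columns)}")
    return df


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
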