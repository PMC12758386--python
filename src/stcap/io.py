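"""File format helpers: FASTA, BED, bedMethyl-like TSV, PAF-like blocks."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(df: pd.DataFrame, path: str | Path,
              columns: list[str] | None = None) -> None:
    cols = columns or list(df.columns)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, columns: list[str]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=columns)


def write_bedmethyl(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", header=False, index=False,
                 columns=["chrom", "start", "end", "strand", "n_mod", "n_total"])


def read_bedmethyl(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "strand",
                              "n_mod", "n_total"])


def write_blocks(blocks, path: str | Path) -> None:
    """PAF-like TSV of alignment blocks."""
    rows = [(b.query_arm, b.q_start, b.q_end, b.target_arm,
             b.t_start, b.t_end, b.orientation, f"{b.identity:.6f}")
            for b in blocks]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
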