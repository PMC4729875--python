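"""Readers and writers for the pipeline's text formats.

Every writer emits a leading comment line beginning with ``#`` naming the
producing stage, the configuration hash and the seed, so any output file can
be traced back to its run.  Readers skip ``#`` lines.  Coordinates are
0-based half-open in all tables and BED files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def provenance_line(stage: str, config_hash: str = "-", seed: int | str = "-") -> str:
    return f"# stage={stage} config={config_hash} seed={seed}"


def write_tsv(df: pd.DataFrame, path, stage: str = "unknown",
              config_hash: str = "-", seed: int | str = "-") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(stage, config_hash, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed6(df: pd.DataFrame, path, stage: str = "unknown",
               config_hash: str = "-", seed: int | str = "-") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(stage, config_hash, seed) + "\n")
        df[BED6_COLUMNS].to_csv(fh, sep="\t", index=False, header=False)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=BED6_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_fasta(sequences: dict[str, str], path, stage: str = "unknown",
                config_hash: str = "-", seed: int | str = "-",
                width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(stage, config_hash, seed) + "\n")
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    with open(path) as fh:
        text = "".join(line for line in fh if not line.startswith("#"))
    records = SeqIO.parse(_io.StringIO(text), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in records}


def genes_to_bed(genes: pd.DataFrame) -> pd.DataFrame:
    return genes[BED6_COLUMNS]


def bed_to_genes(bed: pd.DataFrame) -> pd.DataFrame:
    genes = bed.copy()
    genes["tss"] = genes.apply(
        lambda g: g["start"] if g["strand"] == "+" else g["end"] - 1, axis=1)
    return genes


def calls_to_bed(calls: pd.DataFrame) -> pd.DataFrame:
    """BED projection of a call table for genome browsers."""
    out = pd.DataFrame({
        "chrom": calls["chrom"],
        "start": calls["position"].astype(int),
        "end": calls["position"].astype(int) + 1,
        "name": calls["family"] + ":" + calls["call_id"].astype(str),
        "score": calls["n_unique"],
        "strand": ".",
    })
    return out
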