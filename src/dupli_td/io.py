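"""Plain-text writers/readers for the pipeline's interchange formats.

All artefacts are TSV or FASTA so outputs diff cleanly and round-trip through
the standard libraries.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_counts",
    "write_design",
    "write_pairs",
    "write_cds_fasta",
    "read_cds_fasta",
    "write_od_long",
    "read_od_long",
]


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_pairs(pairs, path) -> None:
    """Two-column unordered pair list (gene_a, gene_b)."""
    if isinstance(pairs, pd.DataFrame):
        pairs[["gene_a", "gene_b"]].to_csv(path, sep="\t", index=False, header=False)
    else:
        with open(path, "w") as fh:
            for a, b in pairs:
                fh.write(f"{a}\t{b}\n")


def write_cds_fasta(records: list[tuple[str, str, str]], path) -> None:
    """Write (pair_id, cds_a, cds_b) triples as a FASTA with _a/_b suffixes."""
    seqs = []
    for pid, a, b in records:
        seqs.append(SeqRecord(Seq(a), id=f"{pid}_a", description=""))
        seqs.append(SeqRecord(Seq(b), id=f"{pid}_b", description=""))
    SeqIO.write(seqs, str(path), "fasta")


def read_cds_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_od_long(od: pd.DataFrame, path) -> None:
    od.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_od_long(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
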