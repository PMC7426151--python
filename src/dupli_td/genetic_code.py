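"""Standard genetic code tables shared by the CDS simulator and dS estimator."""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
AMINO_ACID: dict[str, str] = dict(_TABLE.forward_table)

CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(AMINO_ACID.items()):
    CODONS_BY_AA.setdefault(_aa, ())
    CODONS_BY_AA[_aa] = CODONS_BY_AA[_aa] + (_codon,)

# synonymous alternatives of each sense codon (same amino acid, different codon)
SYNONYMOUS_ALTERNATIVES: dict[str, tuple[str, ...]] = {
    c: tuple(x for x in CODONS_BY_AA[AMINO_ACID[c]] if x != c) for c in SENSE_CODONS
}

NUCLEOTIDES = ("A", "C", "G", "T")

# synonymous codons one nucleotide away (single-step substitutions)
SYNONYMOUS_NEIGHBORS: dict[str, tuple[str, ...]] = {
    c: tuple(
        x
        for x in SYNONYMOUS_ALTERNATIVES[c]
        if sum(a != b for a, b in zip(c, x)) == 1
    )
    for c in SENSE_CODONS
}


def translate_cds(seq: str) -> str:
    """Translate an in-frame CDS (no trailing stop required)."""
    return str(Seq(seq).translate())
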