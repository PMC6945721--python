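"""Small nucleotide/protein helpers shared across modules."""

from __future__ import annotations

from Bio.Seq import Seq

NT_ALPHABET = set("ACGTRYSWKMBDHVN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-.")

# IMGT hydrophobic class used for the position-89 anchor
HYDROPHOBIC = set("AVILMFWY")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(nt: str) -> str:
    """Translate frame 0, trailing partial codon dropped, stops as '*'."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
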