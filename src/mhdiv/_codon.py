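"""Genetic-code lookup tables shared across modules.

Standard nuclear code only; the locus under study is a nuclear gene.
"""

from __future__ import annotations

import itertools

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

#: codon -> one-letter amino acid, "*" for stop (standard code, table 1)
CODON_TABLE: dict[str, str] = {
    "".join(c): standard_dna_table.forward_table.get("".join(c), "*")
    for c in itertools.product(NUCLEOTIDES, repeat=3)
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if c not in STOP_CODONS))

#: purine/pyrimidine partners for transition classification
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def translate_codon(codon: str) -> str:
    """One-letter amino acid for ``codon`` ('*' for a stop)."""
    return CODON_TABLE[codon]


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; stops render as '*'."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


#: unordered base set -> IUPAC degenerate symbol
IUPAC_FROM_PAIR: dict[frozenset, str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

IUPAC_TO_BASES: dict[str, frozenset] = {v: k for k, v in IUPAC_FROM_PAIR.items()}


def degenerate_consensus(seq_a: str, seq_b: str) -> str:
    """IUPAC consensus of two equal-length unambiguous sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    return "".join(
        IUPAC_FROM_PAIR[frozenset((x, y))] for x, y in zip(seq_a, seq_b)
    )
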