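"""Polymorphism and heterozygosity summaries of a codon-frame alignment
and its accompanying diploid genotype panel."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

from ._codon import translate_codon
from .io_model import CodonAlignment, GenotypeTable, InsufficientDataError


@dataclass(frozen=True)
class DiversitySummary:
    pi: Optional[float]
    segregating_sites: int
    synonymous_substitutions: int
    variable_aa_sites: tuple[int, ...]
    observed_heterozygosity: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "pi": self.pi,
            "segregating_sites": self.segregating_sites,
            "synonymous_substitutions": self.synonymous_substitutions,
            "variable_aa_sites": list(self.variable_aa_sites),
            "observed_heterozygosity": self.observed_heterozygosity,
        }


def _pairwise_differences(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def nucleotide_diversity(
    alignment: CodonAlignment,
    weights: Optional[Sequence[float]] = None,
    n_chromosomes: Optional[int] = None,
) -> float:
    """Mean pairwise nucleotide difference per site.

    Unweighted mode (default) averages the p-distance over all unordered
    pairs of unique sequences.  Weighted mode treats ``weights`` as
    allele frequencies in a sample of ``n_chromosomes`` chromosomes and
    returns the sample estimator ``n/(n-1) * sum 2 w_i w_j d_ij / L``.
    """
    seqs = alignment.sequences
    if len(seqs) < 2:
        raise InsufficientDataError("need at least 2 sequences")
    length = alignment.length
    if weights is None:
        total = sum(
            _pairwise_differences(a, b)
            for a, b in itertools.combinations(seqs, 2)
        )
        npairs = len(seqs) * (len(seqs) - 1) // 2
        return total / (npairs * length)
    if len(weights) != len(seqs):
        raise ValueError("one weight per sequence required")
    wsum = sum(weights)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {wsum}, expected 1")
    acc = 0.0
    for (i, a), (j, b) in itertools.combinations(enumerate(seqs), 2):
        acc += 2.0 * weights[i] * weights[j] * _pairwise_differences(a, b)
    pi = acc / length
    if n_chromosomes is not None:
        if n_chromosomes < 2:
            raise InsufficientDataError("need at least 2 chromosomes")
        pi *= n_chromosomes / (n_chromosomes - 1)
    return pi


def segregating_site_columns(alignment: CodonAlignment) -> list[int]:
    """1-based nucleotide columns with more than one state."""
    cols = []
    seqs = alignment.sequences
    for c in range(alignment.length):
        if len({s[c] for s in seqs}) > 1:
            cols.append(c + 1)
    return cols


def variable_aa_columns(alignment: CodonAlignment) -> list[int]:
    """1-based codon indices whose translated column is polymorphic."""
    aas = alignment.translations()
    return [
        c + 1
        for c in range(alignment.codon_count)
        if len({a[c] for a in aas}) > 1
    ]


def synonymous_columns(alignment: CodonAlignment) -> list[int]:
    """Segregating nucleotide columns at which every observed codon pair
    (each allele keeping its own state at the other two codon positions)
    encodes the same amino acid."""
    out = []
    seqs = alignment.sequences
    for col in segregating_site_columns(alignment):
        codon_idx = (col - 1) // 3
        codons = [s[codon_idx * 3 : codon_idx * 3 + 3] for s in seqs]
        offset = (col - 1) % 3
        synonymous = True
        for ca, cb in itertools.combinations(set(codons), 2):
            if ca[offset] != cb[offset] and translate_codon(
                ca
            ) != translate_codon(cb):
                synonymous = False
                break
        if synonymous:
            out.append(col)
    return out


def polymorphism_summary(alignment: CodonAlignment) -> DiversitySummary:
    """Segregating sites, synonymous substitution columns and variable
    amino-acid sites (no pi; see :func:`nucleotide_diversity`)."""
    return DiversitySummary(
        pi=None,
        segregating_sites=len(segregating_site_columns(alignment)),
        synonymous_substitutions=len(synonymous_columns(alignment)),
        variable_aa_sites=tuple(variable_aa_columns(alignment)),
    )


def heterozygosity(genotypes: GenotypeTable) -> tuple[int, int, float]:
    """(heterozygote count, total individuals, fraction)."""
    if not len(genotypes):
        raise InsufficientDataError("empty genotype table")
    het = sum(a != b for a, b in genotypes.genotypes.values())
    total = len(genotypes)
    return het, total, het / total
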