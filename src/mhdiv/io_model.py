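"""Data model and file IO for codon-frame allele alignments, diploid
genotype panels, family pedigrees and codon-site partitions.

All downstream stages operate on the types defined here.  Codon and
nucleotide coordinates are 1-based over the trimmed frame throughout the
package.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codon import NUCLEOTIDES, translate


class MhdivError(Exception):
    """Base class for all package errors."""


class RaggedAlignmentError(MhdivError):
    """Input records are not all the same length."""


class FrameError(MhdivError):
    """Trimmed alignment length is not divisible by 3."""


class SequenceContentError(MhdivError):
    """A record contains a character outside {A, C, G, T}."""


class UnknownAlleleError(MhdivError):
    """A genotype references an allele absent from the alignment."""


class TableFormatError(MhdivError):
    """A delimited table does not follow the expected layout."""


class InsufficientDataError(MhdivError):
    """Not enough sequences/individuals for the requested statistic."""


class TranslationError(MhdivError):
    """An allele contains an internal stop codon."""


_ACGT = frozenset(NUCLEOTIDES)


@dataclass(frozen=True)
class CodonAlignment:
    """In-frame nucleotide alignment of allele sequences.

    Parameters
    ----------
    allele_ids
        Unique labels, one per sequence.
    sequences
        Equal-length uppercase DNA strings over {A, C, G, T}; no gaps.
    frame_offset
        Number of leading nucleotides removed to restore the reading
        frame (bookkeeping only; positions are relative to the trimmed
        frame).
    """

    allele_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    frame_offset: int = 0

    def __post_init__(self):
        if len(self.allele_ids) != len(self.sequences):
            raise ValueError("allele_ids and sequences differ in length")
        if len(set(self.allele_ids)) != len(self.allele_ids):
            dupes = [
                a
                for a, k in collections.Counter(self.allele_ids).items()
                if k > 1
            ]
            raise ValueError(f"duplicate allele ids: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise RaggedAlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        if self.sequences:
            (length,) = lengths
            if length % 3:
                raise FrameError(
                    f"alignment length {length} is not divisible by 3"
                )
            for aid, seq in zip(self.allele_ids, self.sequences):
                bad = next(
                    (i for i, ch in enumerate(seq) if ch not in _ACGT), None
                )
                if bad is not None:
                    raise SequenceContentError(
                        f"record {aid!r}: invalid character {seq[bad]!r} "
                        f"at column {bad + 1}"
                    )

    def __len__(self) -> int:
        return len(self.allele_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def codon_count(self) -> int:
        return self.length // 3

    def sequence(self, allele_id: str) -> str:
        return self.sequences[self.allele_ids.index(allele_id)]

    def codons(self, seq_index: int) -> list[str]:
        s = self.sequences[seq_index]
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def translations(self) -> tuple[str, ...]:
        """Amino-acid sequences; raises on internal stop codons."""
        out = []
        for aid, seq in zip(self.allele_ids, self.sequences):
            aa = translate(seq)
            if "*" in aa:
                raise TranslationError(
                    f"allele {aid!r} has a stop at codon {aa.index('*') + 1}"
                )
            out.append(aa)
        return tuple(out)

    def restrict(self, codon_indices: Iterable[int]) -> "CodonAlignment":
        """Sub-alignment over 1-based ``codon_indices`` (sorted order)."""
        idx = sorted(set(codon_indices))
        if not idx:
            raise ValueError("empty codon index set")
        if idx[0] < 1 or idx[-1] > self.codon_count:
            raise ValueError(
                f"codon indices out of range 1..{self.codon_count}"
            )
        subs = tuple(
            "".join(s[(i - 1) * 3 : i * 3] for i in idx)
            for s in self.sequences
        )
        return CodonAlignment(self.allele_ids, subs, self.frame_offset)

    def drop(self, allele_ids: Iterable[str]) -> "CodonAlignment":
        drop = set(allele_ids)
        keep = [i for i, a in enumerate(self.allele_ids) if a not in drop]
        return CodonAlignment(
            tuple(self.allele_ids[i] for i in keep),
            tuple(self.sequences[i] for i in keep),
            self.frame_offset,
        )


@dataclass(frozen=True)
class AlleleSet:
    """Allele sequences with chromosome counts and frequencies."""

    alleles: Mapping[str, tuple[str, int, float]]  # id -> (seq, count, freq)

    def __post_init__(self):
        total = sum(f for _, _, f in self.alleles.values())
        if self.alleles and abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1")

    def __len__(self) -> int:
        return len(self.alleles)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.alleles)

    def frequency(self, allele_id: str) -> float:
        return self.alleles[allele_id][2]

    def count(self, allele_id: str) -> int:
        return self.alleles[allele_id][1]

    @property
    def total_chromosomes(self) -> int:
        return sum(c for _, c, _ in self.alleles.values())


@dataclass(frozen=True)
class GenotypeTable:
    """individual -> unordered diploid allele pair (single-locus)."""

    genotypes: Mapping[str, tuple[str, str]]
    degenerate_sequences: Mapping[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genotypes)

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(self.genotypes)

    def pair(self, individual: str) -> tuple[str, str]:
        a, b = self.genotypes[individual]
        return (a, b) if a <= b else (b, a)

    def allele_counts(self) -> collections.Counter:
        counts: collections.Counter = collections.Counter()
        for a, b in self.genotypes.values():
            counts[a] += 1
            counts[b] += 1
        return counts


@dataclass(frozen=True)
class FamilyRecord:
    """One pedigree: parental allele pairs plus offspring pairs."""

    family_id: str
    father: tuple[str, str]
    mother: tuple[str, str]
    offspring: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.offspring:
            raise TableFormatError(
                f"family {self.family_id!r} has no offspring"
            )


@dataclass(frozen=True)
class SitePartition:
    """Disjoint PBS / non-PBS split of the codon frame (1-based)."""

    pbs_codons: tuple[int, ...]
    codon_count: int
    source_catalog: str = "custom"

    def __post_init__(self):
        pbs = tuple(sorted(set(self.pbs_codons)))
        object.__setattr__(self, "pbs_codons", pbs)
        if pbs and (pbs[0] < 1 or pbs[-1] > self.codon_count):
            raise ValueError(
                f"PBS codons outside 1..{self.codon_count}: {pbs}"
            )

    @property
    def non_pbs_codons(self) -> tuple[int, ...]:
        pbs = set(self.pbs_codons)
        return tuple(
            i for i in range(1, self.codon_count + 1) if i not in pbs
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_alignment(
    path: str | Path, trim_leading: int = 0, trim_trailing: int = 0
) -> CodonAlignment:
    """Read a FASTA alignment, trim exon-spanning terminal bases, and
    return an in-frame :class:`CodonAlignment`.

    ``trim_leading``/``trim_trailing`` nucleotides are removed from each
    record so that the remainder is a complete reading frame (e.g. a
    273-bp exon trimmed (2, 1) to a 270-bp / 90-codon frame).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MhdivError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = []
    for r in records:
        s = str(r.seq).upper()
        end = len(s) - trim_trailing
        seqs.append(s[trim_leading:end])
    return CodonAlignment(ids, tuple(seqs), frame_offset=trim_leading)


def write_alignment(alignment: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=a, description="")
        for a, s in zip(alignment.allele_ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Two-column TSV: individual <TAB> alleleA/alleleB ("a/a" allowed).

    An optional third column carries the individual's degenerate IUPAC
    consensus sequence.
    """
    genotypes: dict[str, tuple[str, str]] = {}
    degenerate: dict[str, str] = {}
    for lineno, line in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise TableFormatError(
                f"{path}:{lineno}: expected 'individual<TAB>a/b'"
            )
        ind, pair = parts[0], parts[1]
        alleles = pair.split("/")
        if len(alleles) != 2 or not all(alleles):
            raise TableFormatError(
                f"{path}:{lineno}: genotype {pair!r} is not 'a/b'"
            )
        genotypes[ind] = (alleles[0], alleles[1])
        if len(parts) > 2 and parts[2]:
            degenerate[ind] = parts[2].upper()
    return GenotypeTable(genotypes, degenerate)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    lines = []
    for ind in table.individuals:
        a, b = table.genotypes[ind]
        row = f"{ind}\t{a}/{b}"
        if ind in table.degenerate_sequences:
            row += f"\t{table.degenerate_sequences[ind]}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def collapse_alleles(
    genotypes: GenotypeTable, alignment: CodonAlignment
) -> AlleleSet:
    """Chromosome counts and frequencies of the alleles carried by a
    genotype panel (homozygotes count twice)."""
    counts = genotypes.allele_counts()
    known = set(alignment.allele_ids)
    missing = sorted(set(counts) - known)
    if missing:
        raise UnknownAlleleError(
            f"genotypes reference alleles absent from alignment: {missing}"
        )
    total = 2 * len(genotypes)
    alleles = {
        aid: (alignment.sequence(aid), counts[aid], counts[aid] / total)
        for aid in alignment.allele_ids
        if aid in counts
    }
    return AlleleSet(alleles)


def read_families(path: str | Path) -> list[FamilyRecord]:
    """Parse a four-column pedigree table.

    Layout (TSV, one block per family)::

        family  role      a1  a2  a3  a4
        A       father    3   4
        A       mother            4   15
        A       juvenile      4   4

    The father's pair is (a1, a2), the mother's (a3, a4); each juvenile
    row carries exactly two non-empty allele cells among a1..a4.
    """
    blocks: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        parts = (line.rstrip("\n").split("\t") + [""] * 6)[:6]
        fam, role = parts[0], parts[1].lower()
        cells = [c.strip() for c in parts[2:6]]
        if fam == "family" and role == "role":
            continue  # header
        if fam not in blocks:
            blocks[fam] = {"father": None, "mother": None, "offspring": []}
            order.append(fam)
        blk = blocks[fam]
        if role == "father":
            if not (cells[0] and cells[1]):
                raise TableFormatError(
                    f"{path}:{lineno}: father row needs a1 and a2"
                )
            blk["father"] = (cells[0], cells[1])
        elif role == "mother":
            if not (cells[2] and cells[3]):
                raise TableFormatError(
                    f"{path}:{lineno}: mother row needs a3 and a4"
                )
            blk["mother"] = (cells[2], cells[3])
        elif role in ("juvenile", "offspring"):
            present = [c for c in cells if c]
            if len(present) != 2:
                raise TableFormatError(
                    f"{path}:{lineno}: offspring row has "
                    f"{len(present)} non-empty allele cells, expected 2"
                )
            blk["offspring"].append((present[0], present[1]))
        else:
            raise TableFormatError(
                f"{path}:{lineno}: unknown role {parts[1]!r}"
            )
    families = []
    for fam in order:
        blk = blocks[fam]
        if blk["father"] is None or blk["mother"] is None:
            raise TableFormatError(f"family {fam!r}: missing parent row")
        families.append(
            FamilyRecord(
                fam, blk["father"], blk["mother"], tuple(blk["offspring"])
            )
        )
    return families


def write_families(
    families: Sequence[FamilyRecord], path: str | Path
) -> None:
    lines = ["family\trole\ta1\ta2\ta3\ta4"]
    for fam in families:
        lines.append(
            f"{fam.family_id}\tfather\t{fam.father[0]}\t{fam.father[1]}\t\t"
        )
        lines.append(
            f"{fam.family_id}\tmother\t\t\t{fam.mother[0]}\t{fam.mother[1]}"
        )
        for a, b in fam.offspring:
            lines.append(f"{fam.family_id}\tjuvenile\t{a}\t{b}\t\t")
    Path(path).write_text("\n".join(lines) + "\n")


def packaged_family_table() -> Path:
    """Path of the packaged example pedigree panel (5 families)."""
    return Path(__file__).parent / "data" / "mh_families.tsv"
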