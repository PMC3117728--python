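"""Seeded generators of allele pools, diploid panels and nuclear
families with the statistical structure the analysis pipeline assumes.

Every generator is deterministic given its seed and emits a truth
record sufficient to score planted-feature recovery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._codon import (
    NUCLEOTIDES,
    STOP_CODONS,
    degenerate_consensus,
    translate_codon,
)
from .io_model import CodonAlignment, FamilyRecord, GenotypeTable, MhdivError


@dataclass
class SimConfig:
    codon_count: int = 90
    n_alleles: int = 17
    pbs_codons: Optional[tuple[int, ...]] = None  # default: 24 spread codons
    omega_pbs: float = 5.0
    omega_nonpbs: float = 0.5
    substitutions_per_allele: float = 6.0
    n_recombinants: int = 0
    panel_size: int = 101
    mating: str = "hwe"  # or "excess_pairs"
    excess_combos: tuple[tuple[str, str], ...] = ()
    enrichment: float = 1.0
    n_families: int = 5
    offspring_per_family: tuple[int, int] = (8, 13)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.codon_count < 1 or self.n_alleles < 1:
            raise MhdivError("counts must be positive")
        if self.pbs_codons is None:
            # ~24 codons spread evenly over the frame (PBS-scale default)
            step = max(self.codon_count // 24, 1)
            self.pbs_codons = tuple(
                range(2, self.codon_count + 1, step)
            )[:24]
        if any(
            c < 1 or c > self.codon_count for c in self.pbs_codons
        ):
            raise MhdivError("pbs_codons outside codon range")
        if self.omega_pbs <= 0 or self.omega_nonpbs <= 0:
            raise MhdivError("omega values must be positive")
        if self.mating not in ("hwe", "excess_pairs"):
            raise MhdivError("mating must be 'hwe' or 'excess_pairs'")


@dataclass
class PoolTruth:
    ancestral: str
    substitutions: dict[str, list[tuple[int, str, str, bool]]] = field(
        default_factory=dict
    )  # allele -> [(nt position 1-based, from, to, is_nonsyn)]
    recombinants: dict[str, tuple[str, str, int]] = field(
        default_factory=dict
    )  # allele -> (parent_left, parent_right, 1-based crossover column)

    def to_dict(self) -> dict:
        return {
            "ancestral": self.ancestral,
            "substitutions": {
                k: [list(x) for x in v]
                for k, v in self.substitutions.items()
            },
            "recombinants": {
                k: list(v) for k, v in self.recombinants.items()
            },
        }


def _random_sense_sequence(
    codon_count: int, rng: np.random.Generator
) -> str:
    sense = [
        a + b + c
        for a in NUCLEOTIDES
        for b in NUCLEOTIDES
        for c in NUCLEOTIDES
        if (a + b + c) not in STOP_CODONS
    ]
    return "".join(
        sense[i] for i in rng.integers(0, len(sense), size=codon_count)
    )


def _mutate_codon(
    codon: str, omega: float, rng: np.random.Generator
) -> Optional[tuple[int, str, str, bool]]:
    """Sample one single-base change of ``codon``; non-synonymous
    changes weighted by ``omega`` relative to synonymous ones; changes
    to stops excluded.  Returns (offset 0-2, from, to, is_nonsyn)."""
    aa = translate_codon(codon)
    options = []
    weights = []
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            nonsyn = translate_codon(mut) != aa
            options.append((pos, codon[pos], base, nonsyn))
            weights.append(omega if nonsyn else 1.0)
    if not options:
        return None
    w = np.array(weights)
    w /= w.sum()
    return options[rng.choice(len(options), p=w)]


def gen_allele_pool(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[CodonAlignment, PoolTruth]:
    """Distinct allele sequences derived from a random ancestor.

    Substitutions land on uniformly chosen codons; their synonymous /
    non-synonymous character is tilted by the omega of the containing
    partition (PBS vs non-PBS).  Optional planted recombinants replace
    the last ``n_recombinants`` alleles with single-crossover mosaics of
    two divergent non-recombinant alleles.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_base = config.n_alleles - config.n_recombinants
    if n_base < (2 if config.n_recombinants else 1):
        raise MhdivError(
            "n_recombinants requires at least 2 non-recombinant alleles"
        )
    ancestral = _random_sense_sequence(config.codon_count, rng)
    pbs = set(config.pbs_codons)
    truth = PoolTruth(ancestral=ancestral)
    seqs: list[str] = []
    ids: list[str] = []
    attempts = 0
    while len(seqs) < n_base:
        attempts += 1
        if attempts > 200 * config.n_alleles:
            raise MhdivError(
                "cannot generate enough distinct alleles; increase "
                "substitutions_per_allele or codon_count"
            )
        k = max(1, int(rng.poisson(config.substitutions_per_allele)))
        seq = list(ancestral)
        subs = []
        for _ in range(k):
            codon_idx = int(rng.integers(0, config.codon_count))
            omega = (
                config.omega_pbs
                if (codon_idx + 1) in pbs
                else config.omega_nonpbs
            )
            codon = "".join(seq[codon_idx * 3 : codon_idx * 3 + 3])
            mut = _mutate_codon(codon, omega, rng)
            if mut is None:
                continue
            off, old, new, nonsyn = mut
            pos = codon_idx * 3 + off
            seq[pos] = new
            subs.append((pos + 1, old, new, nonsyn))
        s = "".join(seq)
        if s in seqs or s == ancestral:
            continue
        aid = f"S{len(seqs) + 1:02d}"
        seqs.append(s)
        ids.append(aid)
        truth.substitutions[aid] = subs
    for r in range(config.n_recombinants):
        # most divergent pair among the base alleles
        best = None
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
                if best is None or d > best[0]:
                    best = (d, i, j)
        _, i, j = best
        attempts = 0
        L = config.codon_count * 3
        while True:
            attempts += 1
            if attempts > 1000:
                raise MhdivError("cannot place a distinct recombinant")
            # middle-half crossover so both flanks stay informative
            cut = int(rng.integers(L // 4, 3 * L // 4))
            recomb = seqs[i][:cut] + seqs[j][cut:]
            left_signal = sum(
                a != b for a, b in zip(seqs[i][:cut], seqs[j][:cut])
            )
            right_signal = sum(
                a != b for a, b in zip(seqs[i][cut:], seqs[j][cut:])
            )
            if (
                recomb not in seqs
                and left_signal >= 2
                and right_signal >= 2
                and all(
                    "".join(recomb[c : c + 3]) not in STOP_CODONS
                    for c in range(0, len(recomb), 3)
                )
            ):
                break
        aid = f"R{r + 1:02d}"
        seqs.append(recomb)
        ids.append(aid)
        truth.recombinants[aid] = (ids[i], ids[j], cut + 1)
    return CodonAlignment(tuple(ids), tuple(seqs)), truth


def gen_panel(
    alignment: CodonAlignment,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    frequencies: Optional[Sequence[float]] = None,
) -> GenotypeTable:
    """Diploid genotype panel drawn from the allele pool.

    Allele frequencies are Dirichlet(1)-drawn unless supplied.  "hwe"
    mating draws the two alleles i.i.d.; "excess_pairs" multiplies the
    probability of the configured combos by ``enrichment`` and
    renormalises.  Degenerate IUPAC consensus sequences accompany every
    individual.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids = alignment.allele_ids
    k = len(ids)
    if k == 0:
        raise MhdivError("empty allele pool")
    if frequencies is None:
        freq = rng.dirichlet(np.ones(k))
    else:
        freq = np.asarray(frequencies, dtype=float)
        freq = freq / freq.sum()
    pair_list = [(i, j) for i in range(k) for j in range(i, k)]
    probs = np.array(
        [
            freq[i] * freq[j] * (2.0 if i != j else 1.0)
            for i, j in pair_list
        ]
    )
    if config.mating == "excess_pairs":
        index = {a: i for i, a in enumerate(ids)}
        for a, b in config.excess_combos:
            if a not in index or b not in index:
                raise MhdivError(f"enrichment on unknown combo {(a, b)!r}")
            i, j = sorted((index[a], index[b]))
            probs[pair_list.index((i, j))] *= config.enrichment
    probs = probs / probs.sum()
    draws = rng.choice(len(pair_list), size=config.panel_size, p=probs)
    genotypes = {}
    degenerate = {}
    for m, d in enumerate(draws):
        i, j = pair_list[d]
        ind = f"I{m + 1:03d}"
        genotypes[ind] = (ids[i], ids[j])
        degenerate[ind] = degenerate_consensus(
            alignment.sequences[i], alignment.sequences[j]
        )
    return GenotypeTable(genotypes, degenerate)


def gen_families(
    alignment: CodonAlignment,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    frequencies: Optional[Sequence[float]] = None,
    corrupt_offspring: int = 0,
) -> tuple[list[FamilyRecord], list[tuple[str, int]]]:
    """Nuclear families with Mendelian transmission.

    Parents are drawn like panel genotypes; each offspring receives one
    uniformly chosen allele from each parent.  ``corrupt_offspring``
    plants that many incompatibilities by replacing one allele of a
    random offspring with an allele carried by neither parent (skipped
    with a warning-free no-op when no foreign allele exists).  Returns
    the families plus [(family_id, offspring_index)] of planted errors.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids = alignment.allele_ids
    if len(ids) < 2:
        raise MhdivError("need at least 2 alleles")
    k = len(ids)
    if frequencies is None:
        freq = rng.dirichlet(np.ones(k))
    else:
        freq = np.asarray(frequencies, dtype=float)
        freq = freq / freq.sum()
    lo, hi = config.offspring_per_family
    families = []
    slots = []
    for f in range(config.n_families):
        father = tuple(ids[i] for i in rng.choice(k, size=2, p=freq))
        mother = tuple(ids[i] for i in rng.choice(k, size=2, p=freq))
        n_off = int(rng.integers(lo, hi + 1))
        offspring = []
        for _ in range(n_off):
            offspring.append(
                (
                    father[int(rng.integers(0, 2))],
                    mother[int(rng.integers(0, 2))],
                )
            )
        fam_id = f"F{f + 1}"
        families.append(
            FamilyRecord(fam_id, father, mother, tuple(offspring))
        )
        slots.extend((f, o) for o in range(n_off))
    planted: list[tuple[str, int]] = []
    if corrupt_offspring:
        chosen = rng.choice(
            len(slots), size=min(corrupt_offspring, len(slots)),
            replace=False,
        )
        for c in np.atleast_1d(chosen):
            f, o = slots[int(c)]
            fam = families[f]
            parental = set(fam.father) | set(fam.mother)
            foreign = [a for a in ids if a not in parental]
            if not foreign:
                continue
            bad = foreign[int(rng.integers(0, len(foreign)))]
            off = list(fam.offspring)
            keep = off[o][1] if off[o][1] in parental else off[o][0]
            off[o] = (bad, keep)
            families[f] = FamilyRecord(
                fam.family_id, fam.father, fam.mother, tuple(off)
            )
            planted.append((fam.family_id, o))
    return families, planted
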