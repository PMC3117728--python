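"""Hardy-Weinberg exact testing, the allelic-combination permutation
test with sequential Bonferroni correction, EM haplotype phasing of
degenerate diploid sequences, and Mendelian inheritance checking."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from ._codon import IUPAC_TO_BASES
from .io_model import (
    FamilyRecord,
    GenotypeTable,
    InsufficientDataError,
    MhdivError,
)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _log_table_probability(counts: Mapping[tuple[str, str], int]) -> float:
    """Log conditional probability of a genotype-count table given the
    allele counts (the Levene/Haldane exact distribution)."""
    n = sum(counts.values())
    allele: dict[str, int] = {}
    het = 0
    log_g = 0.0
    for (a, b), g in counts.items():
        allele[a] = allele.get(a, 0) + g
        allele[b] = allele.get(b, 0) + g
        if a != b:
            het += g
        log_g += math.lgamma(g + 1)
    return (
        math.lgamma(n + 1)
        - log_g
        + het * math.log(2)
        + sum(math.lgamma(c + 1) for c in allele.values())
        - math.lgamma(2 * n + 1)
    )


def _genotype_counts(genotypes: GenotypeTable) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for ind in genotypes.individuals:
        pair = genotypes.pair(ind)
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def _enumerate_tables(allele_counts: dict[str, int]):
    """All genotype-count tables consistent with the allele counts."""
    alleles = sorted(allele_counts)
    cells = [
        (alleles[i], alleles[j])
        for i in range(len(alleles))
        for j in range(i, len(alleles))
    ]

    def rec(idx: int, remaining: dict[str, int], acc: dict):
        if idx == len(cells):
            if all(v == 0 for v in remaining.values()):
                yield dict(acc)
            return
        a, b = cells[idx]
        if a == b:
            cap = remaining[a] // 2
        else:
            cap = min(remaining[a], remaining[b])
        for g in range(cap + 1):
            if g:
                if a == b:
                    remaining[a] -= 2 * g
                else:
                    remaining[a] -= g
                    remaining[b] -= g
                acc[(a, b)] = g
            yield from rec(idx + 1, remaining, acc)
            if g:
                if a == b:
                    remaining[a] += 2 * g
                else:
                    remaining[a] += g
                    remaining[b] += g
                acc.pop((a, b), None)

    yield from rec(0, dict(allele_counts), {})


def hwe_exact_test(
    genotypes: GenotypeTable,
    mc_steps: int = 100_000,
    seed: Optional[int] = None,
) -> float:
    """Exact Hardy-Weinberg test p-value, conditional on allele counts.

    Small problems (<= 3 alleles and <= 10 individuals) are solved by
    complete enumeration of genotype tables; larger ones by Monte Carlo
    sampling from the exact conditional null (random re-pairing of the
    2n observed allele copies, ``mc_steps`` replicates, seeded), with
    the usual +1 correction.
    """
    if len(genotypes) < 2:
        raise InsufficientDataError("need at least 2 individuals")
    counts = _genotype_counts(genotypes)
    allele_counts = dict(genotypes.allele_counts())
    if len(allele_counts) < 2:
        return 1.0
    obs_logp = _log_table_probability(counts)
    if len(allele_counts) <= 3 and len(genotypes) <= 10:
        total = 0.0
        extreme = 0.0
        for table in _enumerate_tables(allele_counts):
            lp = _log_table_probability(table)
            prob = math.exp(lp)
            total += prob
            if lp <= obs_logp + 1e-12:
                extreme += prob
        return extreme / total
    rng = np.random.default_rng(seed)
    pool = np.array(
        [a for a, c in sorted(allele_counts.items()) for _ in range(c)]
    )
    n = len(genotypes)
    hits = 0
    for _ in range(mc_steps):
        rng.shuffle(pool)
        table: dict[tuple[str, str], int] = {}
        for i in range(n):
            a, b = pool[2 * i], pool[2 * i + 1]
            key = (a, b) if a <= b else (b, a)
            table[key] = table.get(key, 0) + 1
        if _log_table_probability(table) <= obs_logp + 1e-12:
            hits += 1
    return (hits + 1) / (mc_steps + 1)


# ---------------------------------------------------------------------------
# allelic-combination permutation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComboTestResult:
    combos: tuple[tuple[str, str], ...]
    observed: np.ndarray
    simulated_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    holm_reject: np.ndarray
    reps: int
    seed: Optional[int]

    def as_rows(self) -> list[dict]:
        return [
            {
                "combo": f"{a}/{b}",
                "observed": int(self.observed[i]),
                "expected_mean": float(self.simulated_mean[i]),
                "ci_low": float(self.ci_low[i]),
                "ci_high": float(self.ci_high[i]),
                "p": float(self.p_values[i]),
                "holm_reject": bool(self.holm_reject[i]),
            }
            for i, (a, b) in enumerate(self.combos)
        ]


def allelic_combination_test(
    genotypes: GenotypeTable,
    reps: int = 10_000,
    seed: Optional[int] = None,
    two_sided: bool = False,
    frequencies: Optional[Mapping[str, float]] = None,
) -> ComboTestResult:
    """Permutation test of allele co-occurrence against random pairing.

    Each replicate draws, per individual, two alleles i.i.d. from the
    empirical allele frequencies and tallies unordered pairs.  The
    default one-sided p-value measures excess of the observed count
    (+1 Monte Carlo correction); 95% CIs are the 2.5/97.5 percentiles
    of the simulated counts.  All possible unordered combinations are
    reported (never-seen combos get p = 1 one-sided).
    """
    if not len(genotypes):
        raise MhdivError("empty genotype table")
    if frequencies is None:
        counts = genotypes.allele_counts()
        total = 2 * len(genotypes)
        frequencies = {a: c / total for a, c in counts.items()}
    alleles = sorted(frequencies)
    k = len(alleles)
    freq = np.array([frequencies[a] for a in alleles])
    freq = freq / freq.sum()
    index = {a: i for i, a in enumerate(alleles)}
    combos = [
        (alleles[i], alleles[j]) for i in range(k) for j in range(i, k)
    ]
    combo_index = {c: i for i, c in enumerate(combos)}
    n_combos = len(combos)
    observed = np.zeros(n_combos, dtype=np.int64)
    for ind in genotypes.individuals:
        a, b = sorted(genotypes.pair(ind), key=lambda x: index[x])
        observed[combo_index[(a, b)]] += 1
    n = len(genotypes)
    rng = np.random.default_rng(seed)
    # vectorised: draw (reps, n, 2), map to unordered-combo ids, bincount
    draws = rng.choice(k, size=(reps, n, 2), p=freq)
    lo = draws.min(axis=2)
    hi = draws.max(axis=2)
    # id of combo (i, j), i <= j, in the i-major enumeration above
    pair_id = lo * k - lo * (lo - 1) // 2 + (hi - lo)
    offsets = (np.arange(reps) * n_combos)[:, None]
    flat = (pair_id + offsets).ravel()
    sim = np.bincount(flat, minlength=reps * n_combos).reshape(
        reps, n_combos
    )
    p_hi = (1 + (sim >= observed[None, :]).sum(axis=0)) / (reps + 1)
    if two_sided:
        p_lo = (1 + (sim <= observed[None, :]).sum(axis=0)) / (reps + 1)
        p_values = np.minimum(1.0, 2 * np.minimum(p_hi, p_lo))
    else:
        p_values = p_hi
    reject = sequential_bonferroni(p_values)
    return ComboTestResult(
        combos=tuple(combos),
        observed=observed,
        simulated_mean=sim.mean(axis=0),
        ci_low=np.percentile(sim, 2.5, axis=0),
        ci_high=np.percentile(sim, 97.5, axis=0),
        p_values=p_values,
        holm_reject=reject,
        reps=reps,
        seed=seed,
    )


def sequential_bonferroni(
    pvals: Sequence[float], alpha: float = 0.05
) -> np.ndarray:
    """Holm step-down decisions (True = reject) at family-wise alpha."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


# ---------------------------------------------------------------------------
# EM haplotype phasing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseResult:
    haplotype_frequencies: dict[str, float]
    best_pairs: dict[str, tuple[str, str]]
    pair_posteriors: dict[str, float]
    log_likelihoods: tuple[float, ...]  # trajectory of the best start


class ComplexityError(MhdivError):
    """Too many heterozygous sites to enumerate haplotype pairs."""


def _expand_pairs(degenerate: str) -> list[tuple[str, str]]:
    """Unordered haplotype pairs compatible with an IUPAC sequence."""
    het_pos = []
    base: list[str] = []
    alt: list[str] = []
    for i, ch in enumerate(degenerate):
        bases = IUPAC_TO_BASES.get(ch)
        if bases is None:
            raise MhdivError(f"unsupported IUPAC symbol {ch!r}")
        bs = sorted(bases)
        base.append(bs[0])
        alt.append(bs[-1])
        if len(bs) == 2:
            het_pos.append(i)
    h = len(het_pos)
    if h > 20:
        raise ComplexityError(
            f"{h} heterozygous sites (> 20); prune sites before phasing"
        )
    if h == 0:
        s = "".join(base)
        return [(s, s)]
    pairs = []
    # fix the first het site's assignment to avoid double counting
    for bits in itertools.product((0, 1), repeat=h - 1):
        a = list(base)
        b = list(base)
        b[het_pos[0]] = alt[het_pos[0]]
        for bit, pos in zip(bits, het_pos[1:]):
            if bit:
                a[pos], b[pos] = alt[pos], base[pos]
            else:
                b[pos] = alt[pos]
        pairs.append(("".join(a), "".join(b)))
    return pairs


def em_phase(
    degenerate: Mapping[str, str],
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: Optional[int] = 0,
) -> PhaseResult:
    """Haplotype-frequency EM over degenerate diploid sequences.

    Multi-start (``n_starts`` seeded random initialisations plus one
    uniform start); the best-likelihood solution is kept and each
    individual is assigned its most probable compatible ordered pair.
    """
    if not degenerate:
        raise MhdivError("no individuals to phase")
    ind_pairs = {ind: _expand_pairs(s) for ind, s in degenerate.items()}
    haplotypes = sorted({h for ps in ind_pairs.values() for p in ps for h in p})
    hap_idx = {h: i for i, h in enumerate(haplotypes)}
    H = len(haplotypes)
    pair_arrays = {
        ind: np.array([[hap_idx[a], hap_idx[b]] for a, b in ps])
        for ind, ps in ind_pairs.items()
    }
    rng = np.random.default_rng(seed)
    inits = [np.full(H, 1.0 / H)]
    for _ in range(max(n_starts - 1, 0)):
        v = rng.dirichlet(np.ones(H))
        inits.append(np.maximum(v, 1e-12))
    best_f = None
    best_ll = -np.inf
    best_traj: list[float] = []
    for f0 in inits:
        f = f0 / f0.sum()
        traj = []
        prev = -np.inf
        for _ in range(max_iter):
            ll = 0.0
            expected = np.zeros(H)
            for ind, arr in pair_arrays.items():
                pa, pb = arr[:, 0], arr[:, 1]
                w = f[pa] * f[pb]
                w = np.where(pa != pb, 2.0 * w, w)
                tot = w.sum()
                if tot <= 0:
                    w = np.full(len(w), 1.0 / len(w))
                    tot = 1.0
                    ll += -745.0  # log of ~0
                else:
                    ll += math.log(tot)
                    w = w / tot
                np.add.at(expected, pa, w)
                np.add.at(expected, pb, w)
            f = expected / expected.sum()
            traj.append(ll)
            if ll - prev < tol and len(traj) > 1:
                break
            prev = ll
        if traj[-1] > best_ll:
            best_ll = traj[-1]
            best_f = f
            best_traj = traj
    best_pairs = {}
    posteriors = {}
    for ind, arr in pair_arrays.items():
        pa, pb = arr[:, 0], arr[:, 1]
        w = best_f[pa] * best_f[pb]
        w = np.where(pa != pb, 2.0 * w, w)
        tot = w.sum()
        w = w / tot if tot > 0 else np.full(len(w), 1.0 / len(w))
        k = int(np.argmax(w))
        best_pairs[ind] = (haplotypes[pa[k]], haplotypes[pb[k]])
        posteriors[ind] = float(w[k])
    freqs = {
        h: float(best_f[i]) for h, i in hap_idx.items() if best_f[i] > 1e-10
    }
    return PhaseResult(freqs, best_pairs, posteriors, tuple(best_traj))


# ---------------------------------------------------------------------------
# Mendelian inheritance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OffspringCheck:
    pair: tuple[str, str]
    compatible: bool
    paternal: Optional[str]
    maternal: Optional[str]


@dataclass(frozen=True)
class MendelReport:
    family_id: str
    checks: tuple[OffspringCheck, ...]

    @property
    def n_compatible(self) -> int:
        return sum(c.compatible for c in self.checks)

    @property
    def n_offspring(self) -> int:
        return len(self.checks)

    @property
    def all_compatible(self) -> bool:
        return self.n_compatible == self.n_offspring


def mendel_check(family: FamilyRecord) -> MendelReport:
    """Check each offspring pair for one-paternal/one-maternal
    compatibility; incompatibility is a result, not an error."""
    father = set(family.father)
    mother = set(family.mother)
    checks = []
    for x, y in family.offspring:
        assignment = None
        if x in father and y in mother:
            assignment = (x, y)
        elif y in father and x in mother:
            assignment = (y, x)
        if assignment:
            checks.append(OffspringCheck((x, y), True, *assignment))
        else:
            checks.append(OffspringCheck((x, y), False, None, None))
    return MendelReport(family.family_id, tuple(checks))
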