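"""Pathway-averaged synonymous/non-synonymous substitution analysis.

Implements the classic codon-pair counting scheme: potential synonymous
and non-synonymous sites per codon, pathway-averaged observed
differences per codon pair, multiple-hit correction, overall-mean
dN/dS across all unordered allele pairs (optionally restricted to a
codon-site partition), and a bootstrap Z-test of positive selection.

Conventions match the widespread distance-based implementation relied
on by most empirical studies: mutations to stop codons count as
non-synonymous in the site tally, mutational pathways passing through a
stop codon are excluded (averages renormalised over the remainder), the
multiple-hit correction is applied per pair, and per-pair distances are
averaged across pairs.
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import norm

from ._codon import NUCLEOTIDES, STOP_CODONS, translate_codon
from .io_model import (
    CodonAlignment,
    InsufficientDataError,
    MhdivError,
    SitePartition,
)
from .pbs_catalogs import HUMAN_BETA1_REFERENCE, catalog_positions


class SaturationError(MhdivError):
    """Observed proportion of differences too large for the correction."""


@dataclass(frozen=True)
class SubstitutionCounts:
    N: float  # potential non-synonymous sites
    S: float  # potential synonymous sites
    Nd: float  # observed non-synonymous differences (pathway-averaged)
    Sd: float  # observed synonymous differences


@dataclass(frozen=True)
class DnDsResult:
    dN: float
    dS: float
    ratio: float  # math.inf when dS == 0 and dN > 0; nan when both 0
    partition_label: str
    n_pairs: int
    z: Optional[float] = None
    p: Optional[float] = None


@functools.lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(n, s): potential non-synonymous and synonymous sites of a codon.

    Per position the synonymous fraction is the number of the three
    single-base alternatives encoding the same amino acid, divided by 3;
    changes to stop codons are non-synonymous.  Always n + s == 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r}")
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut not in STOP_CODONS and translate_codon(mut) == aa:
                syn += 1
        s += syn / 3.0
    return 3.0 - s, s


@functools.lru_cache(maxsize=None)
def ng86_pair(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Nd, Sd) between two sense codons, averaged over all mutational
    pathways; pathways passing through a stop codon are dropped and the
    average renormalised over those remaining."""
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    nd_total = sd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        nd = sd = 0.0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if translate_codon(current) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        if valid:
            nd_total += nd
            sd_total += sd
            n_paths += 1
    if n_paths == 0:
        warnings.warn(
            f"all pathways between {codon_a} and {codon_b} pass through a "
            "stop codon; pair skipped",
            stacklevel=2,
        )
        return math.nan, math.nan
    return nd_total / n_paths, sd_total / n_paths


def jc_correct(p: float) -> float:
    """Multiple-hit corrected distance d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(
            f"proportion of differences {p:.4g} >= 3/4; distance undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _pair_counts_by_codon(
    codons_a: list[str], codons_b: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon (N, S, Nd, Sd) arrays for one sequence pair."""
    k = len(codons_a)
    N = np.empty(k)
    S = np.empty(k)
    Nd = np.empty(k)
    Sd = np.empty(k)
    for i, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        na, sa = ng86_site_counts(ca)
        nb, sb = ng86_site_counts(cb)
        N[i] = (na + nb) / 2.0
        S[i] = (sa + sb) / 2.0
        Nd[i], Sd[i] = ng86_pair(ca, cb)
    return N, S, Nd, Sd


def pair_counts(
    codons_a: Iterable[str], codons_b: Iterable[str]
) -> SubstitutionCounts:
    """Aggregate :class:`SubstitutionCounts` for one codon-sequence pair."""
    N, S, Nd, Sd = _pair_counts_by_codon(list(codons_a), list(codons_b))
    good = ~np.isnan(Nd)
    return SubstitutionCounts(
        float(N[good].sum()),
        float(S[good].sum()),
        float(Nd[good].sum()),
        float(Sd[good].sum()),
    )


def _alignment_pair_arrays(
    alignment: CodonAlignment, codon_indices: Optional[Iterable[int]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stacked per-pair, per-codon count arrays, shape (pairs, codons)."""
    if len(alignment) < 2:
        raise InsufficientDataError("need at least 2 alleles")
    sub = (
        alignment
        if codon_indices is None
        else alignment.restrict(codon_indices)
    )
    codon_lists = [sub.codons(i) for i in range(len(sub))]
    rows_N, rows_S, rows_Nd, rows_Sd = [], [], [], []
    for a, b in itertools.combinations(range(len(sub)), 2):
        N, S, Nd, Sd = _pair_counts_by_codon(codon_lists[a], codon_lists[b])
        rows_N.append(N)
        rows_S.append(S)
        rows_Nd.append(Nd)
        rows_Sd.append(Sd)
    return (
        np.vstack(rows_N),
        np.vstack(rows_S),
        np.vstack(rows_Nd),
        np.vstack(rows_Sd),
    )


def _mean_distances(
    N: np.ndarray, S: np.ndarray, Nd: np.ndarray, Sd: np.ndarray
) -> tuple[float, float]:
    """Overall-mean dN and dS: per-pair correction, then pair average.

    Saturated pairs propagate as NaN and are dropped from the average.
    """
    good = ~np.isnan(Nd)
    n_tot = np.where(good, N, 0.0).sum(axis=1)
    s_tot = np.where(good, S, 0.0).sum(axis=1)
    nd_tot = np.where(good, Nd, 0.0).sum(axis=1)
    sd_tot = np.where(good, Sd, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pN = np.where(n_tot > 0, nd_tot / n_tot, 0.0)
        pS = np.where(s_tot > 0, sd_tot / s_tot, 0.0)
        dN = np.where(pN < 0.75, -0.75 * np.log1p(-4.0 * pN / 3.0), np.nan)
        dS = np.where(pS < 0.75, -0.75 * np.log1p(-4.0 * pS / 3.0), np.nan)
    return float(np.nanmean(dN)), float(np.nanmean(dS))


def mean_dn_ds(
    alignment: CodonAlignment,
    partition: Optional[Iterable[int]] = None,
    label: str = "all",
) -> DnDsResult:
    """Overall-mean corrected dN and dS over all unordered allele pairs,
    optionally restricted to the 1-based ``partition`` codon set."""
    if partition is not None:
        partition = tuple(partition)
        if not partition:
            raise ValueError("empty codon partition")
    N, S, Nd, Sd = _alignment_pair_arrays(alignment, partition)
    dN, dS = _mean_distances(N, S, Nd, Sd)
    if dS > 0:
        ratio = dN / dS
    elif dN > 0:
        ratio = math.inf
    else:
        ratio = math.nan
    return DnDsResult(
        dN=dN, dS=dS, ratio=ratio, partition_label=label, n_pairs=N.shape[0]
    )


def z_test_positive_selection(
    alignment: CodonAlignment,
    partition: Optional[Iterable[int]] = None,
    reps: int = 10000,
    seed: Optional[int] = None,
    label: str = "all",
) -> DnDsResult:
    """One-tailed test of dN > dS with bootstrap variances.

    Codon columns are resampled with replacement ``reps`` times; the
    variance of the overall-mean dN and dS over replicates feeds
    Z = (dN - dS) / sqrt(Var dN + Var dS), with the p-value from the
    standard normal upper tail.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if partition is not None:
        partition = tuple(partition)
    N, S, Nd, Sd = _alignment_pair_arrays(alignment, partition)
    dN, dS = _mean_distances(N, S, Nd, Sd)
    k = N.shape[1]
    if not np.any(Nd[~np.isnan(Nd)] > 0) and not np.any(
        Sd[~np.isnan(Sd)] > 0
    ):
        base = mean_dn_ds(alignment, partition, label)
        return DnDsResult(
            base.dN, base.dS, base.ratio, label, base.n_pairs, z=0.0, p=1.0
        )
    rng = np.random.default_rng(seed)
    boot_dN = np.empty(reps)
    boot_dS = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, k, size=k)
        boot_dN[r], boot_dS[r] = _mean_distances(
            N[:, idx], S[:, idx], Nd[:, idx], Sd[:, idx]
        )
    var = np.nanvar(boot_dN, ddof=1) + np.nanvar(boot_dS, ddof=1)
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (dN - dS) / math.sqrt(var)
        p = float(norm.sf(z))
    if dS > 0:
        ratio = dN / dS
    elif dN > 0:
        ratio = math.inf
    else:
        ratio = math.nan
    return DnDsResult(
        dN=dN,
        dS=dS,
        ratio=ratio,
        partition_label=label,
        n_pairs=N.shape[0],
        z=float(z),
        p=p,
    )


def map_pbs_sites(
    alignment: CodonAlignment,
    catalog: str = "reche",
    reference: str = HUMAN_BETA1_REFERENCE,
    positions: Optional[Sequence[int]] = None,
) -> SitePartition:
    """Map a human beta-1 PBS catalog onto the query codon frame.

    The consensus translation of ``alignment`` is pairwise-aligned to
    the human beta-1 reference; cataloged human positions covered by the
    alignment become PBS codons (1-based over the query frame).
    Positions falling outside the aligned span or opposite a gap are
    dropped with a warning.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if positions is None:
        positions = catalog_positions(catalog)
    else:
        positions = tuple(positions)
        catalog = "custom"
    if not positions:
        return SitePartition((), alignment.codon_count, catalog)
    aas = alignment.translations()
    # majority-rule consensus translation as the query
    query = "".join(
        max(set(col), key=col.count)
        for col in zip(*aas)
    )
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(query, reference)[0]
    # human position (1-based) -> query codon (1-based)
    human_to_query: dict[int, int] = {}
    for (qs, qe), (rs, re) in zip(*aln.aligned):
        for off in range(re - rs):
            human_to_query[rs + off + 1] = qs + off + 1
    pbs = []
    dropped = []
    for pos in positions:
        if pos in human_to_query:
            pbs.append(human_to_query[pos])
        else:
            dropped.append(pos)
    if dropped:
        warnings.warn(
            f"catalog positions not covered by the alignment: {dropped}",
            stacklevel=2,
        )
    return SitePartition(
        tuple(sorted(pbs)), alignment.codon_count, source_catalog=catalog
    )
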