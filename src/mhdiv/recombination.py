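"""Minimal-cost mosaic detection of intralocus recombinant alleles.

Each allele in turn is the target; the remaining alleles are candidate
sources.  A dynamic program finds the cheapest way to explain the
target column-by-column, paying 1 per mismatching column against the
current source and a switch penalty ``rho`` for changing source.  The
difference between the best single-source cost and the best mosaic cost
("savings") measures recombination signal; significance comes from
permuting column order (the same permutation applied to every
sequence), which preserves per-column mismatch structure while
destroying spatial contiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_model import CodonAlignment, MhdivError


@dataclass(frozen=True)
class MosaicPath:
    cost: float
    source_path: tuple[int, ...]  # source index per column
    breakpoints: tuple[int, ...]  # 1-based columns where the source changes


@dataclass(frozen=True)
class RecombScan:
    allele_ids: tuple[str, ...]
    single_source_cost: np.ndarray
    mosaic_cost: np.ndarray
    savings: np.ndarray
    breakpoints: tuple[tuple[int, ...], ...]  # per target, 1-based columns
    p_values: np.ndarray
    rho: float
    reps: int
    seed: Optional[int]

    def flagged(self, alpha: float = 0.05) -> tuple[str, ...]:
        return tuple(
            a
            for a, p in zip(self.allele_ids, self.p_values)
            if p < alpha
        )


def mosaic_cost(
    target: str, sources: Sequence[str], rho: float
) -> MosaicPath:
    """Minimal mosaic explanation cost of ``target`` from ``sources``.

    Ties are broken toward fewer switches, then lower source index.
    """
    if len(sources) < 2:
        raise MhdivError("need at least 2 source sequences")
    if any(len(s) != len(target) for s in sources):
        raise MhdivError("sources must match target length")
    L = len(target)
    S = len(sources)
    mism = np.array(
        [[1.0 if s[c] != target[c] else 0.0 for c in range(L)] for s in sources]
    )
    # DP on (cost, switches) lexicographic; backpointers for the path
    cost = mism[:, 0].copy()
    switches = np.zeros(S)
    back = np.zeros((L, S), dtype=np.int64)
    back[0] = np.arange(S)
    for c in range(1, L):
        # staying vs switching from the best previous state
        order = np.lexsort((np.arange(S), switches, cost))
        b = order[0]
        switch_cost = cost[b] + rho
        switch_sw = switches[b] + 1
        new_cost = np.empty(S)
        new_sw = np.empty(S)
        for s in range(S):
            stay = (cost[s], switches[s], s)
            sw = (switch_cost, switch_sw, b)
            pick = stay if stay[:2] <= sw[:2] or s == b else sw
            new_cost[s] = pick[0] + mism[s, c]
            new_sw[s] = pick[1]
            back[c, s] = pick[2]
        cost, switches = new_cost, new_sw
    order = np.lexsort((np.arange(S), switches, cost))
    end = int(order[0])
    path = [end]
    for c in range(L - 1, 0, -1):
        path.append(int(back[c, path[-1]]))
    path.reverse()
    bps = tuple(
        c + 1 for c in range(1, L) if path[c] != path[c - 1]
    )
    return MosaicPath(float(cost[end]), tuple(path), bps)


def single_source_cost(target: str, sources: Sequence[str]) -> float:
    """Mismatch count of the best single source."""
    return float(
        min(sum(a != b for a, b in zip(target, s)) for s in sources)
    )


def _variable_columns(sequences: Sequence[str]) -> list[int]:
    return [
        c
        for c in range(len(sequences[0]))
        if len({s[c] for s in sequences}) > 1
    ]


def _batched_mosaic_costs(
    mism: np.ndarray, self_mask: np.ndarray, rho: float
) -> np.ndarray:
    """Vectorised minimal mosaic costs for all targets at once.

    ``mism``: (targets, sources, columns) mismatch indicator with the
    target-as-its-own-source entries masked to +inf via ``self_mask``.
    """
    T, S, L = mism.shape
    INF = math.inf
    cost = np.where(self_mask, INF, mism[:, :, 0])
    for c in range(1, L):
        best = cost.min(axis=1, keepdims=True)
        cost = np.minimum(cost, best + rho) + mism[:, :, c]
        cost[self_mask] = INF
    return cost.min(axis=1)


def recomb_pvalues(
    alignment: CodonAlignment,
    rho: float = 1.0,
    reps: int = 10_000,
    seed: Optional[int] = None,
) -> RecombScan:
    """Mosaic-cost savings and column-permutation p-values per allele.

    Only variable columns enter the DP (invariant columns never cost
    anything); the null permutes the variable-column order, recomputing
    savings each time, with the +1 Monte Carlo correction.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    n = len(alignment)
    if n < 3:
        raise MhdivError("need at least 3 alleles (2 sources per target)")
    seqs = alignment.sequences
    var_cols = _variable_columns(seqs)
    ids = alignment.allele_ids
    if not var_cols:
        zero = np.zeros(n)
        return RecombScan(
            ids, zero, zero, zero, tuple(() for _ in ids),
            np.ones(n), rho, reps, seed,
        )
    var = [
        "".join(s[c] for c in var_cols) for s in seqs
    ]
    L = len(var_cols)
    # mismatch tensor over variable columns
    arr = np.array([[ord(ch) for ch in s] for s in var], dtype=np.int16)
    mism = (arr[:, None, :] != arr[None, :, :]).astype(np.float64)
    self_mask = np.eye(n, dtype=bool)
    single = np.where(self_mask, np.inf, mism.sum(axis=2)).min(axis=1)
    observed_mosaic = _batched_mosaic_costs(mism, self_mask, rho)
    observed_savings = single - observed_mosaic
    # exact per-target breakpoints from the scalar DP (traceback)
    breakpoints = []
    for t in range(n):
        sources = [var[s] for s in range(n) if s != t]
        mp = mosaic_cost(var[t], sources, rho)
        breakpoints.append(
            tuple(var_cols[c - 1] + 1 for c in mp.breakpoints)
        )
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n, dtype=np.int64)
    for _ in range(reps):
        perm = rng.permutation(L)
        perm_mosaic = _batched_mosaic_costs(
            mism[:, :, perm], self_mask, rho
        )
        exceed += (single - perm_mosaic) >= observed_savings - 1e-9
    p = (1 + exceed) / (reps + 1)
    return RecombScan(
        allele_ids=ids,
        single_source_cost=single,
        mosaic_cost=observed_mosaic,
        savings=observed_savings,
        breakpoints=tuple(breakpoints),
        p_values=p,
        rho=rho,
        reps=reps,
        seed=seed,
    )


def rho_sweep(
    alignment: CodonAlignment,
    rhos: Sequence[float] = (0.5, 1.0, 2.0),
    reps: int = 10_000,
    seed: Optional[int] = None,
) -> dict[float, RecombScan]:
    """Run :func:`recomb_pvalues` across a grid of switch penalties."""
    return {
        r: recomb_pvalues(alignment, rho=r, reps=reps, seed=seed)
        for r in rhos
    }
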