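"""Codon-substitution site models of positive selection.

Fits the beta-distributed-omega site-class model ("M7") and its
extension with one extra omega > 1 class ("M8") to an in-frame allele
alignment on a neighbor-joining tree, under a Goldman-Yang style codon
rate matrix with F3x4 codon frequencies, and compares them with a
df = 2 likelihood-ratio test.  Per-site empirical-Bayes posteriors
identify positively selected codons.

The likelihood machinery is self-contained: 61-state rate matrix,
eigendecomposition-based transition probabilities, Felsenstein pruning
with per-site rescaling, and bounded quasi-Newton optimization over a
fixed multi-start grid (no randomness in fitting).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import betainc
from scipy.stats import chi2

from ._codon import SENSE_CODONS, is_transition, translate_codon
from .io_model import CodonAlignment, InsufficientDataError, MhdivError
from .selection_ng86 import SaturationError, jc_correct

_NSTATES = len(SENSE_CODONS)  # 61
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_MIN_BRANCH = 1e-7
_MIN_FREQ = 1e-8


def _pair_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(single_diff, transition, nonsynonymous) boolean 61x61 masks."""
    single = np.zeros((_NSTATES, _NSTATES), dtype=bool)
    ts = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ts[i, j] = is_transition(*diffs[0])
            nonsyn[i, j] = translate_codon(a) != translate_codon(b)
    return single, ts, nonsyn


_SINGLE, _TS, _NONSYN = _pair_masks()


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class Tree:
    """Rooted-at-a-trifurcation tree in postorder arrays.

    ``children[i]`` lists child node indices of node ``i``; tips are
    nodes ``0..n_tips-1`` in ``tip_names`` order; the last node is the
    root.  ``branch_lengths[i]`` is the edge above node ``i``.
    """

    tip_names: tuple[str, ...]
    children: list[list[int]]
    branch_lengths: np.ndarray

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1  # root has no edge above it

    def newick(self) -> str:
        def fmt(i: int) -> str:
            if not self.children[i]:
                return f"{self.tip_names[i]}:{self.branch_lengths[i]:.6f}"
            inner = ",".join(fmt(c) for c in self.children[i])
            if i == self.n_nodes - 1:
                return f"({inner});"
            return f"({inner}):{self.branch_lengths[i]:.6f}"

        return fmt(self.n_nodes - 1)


def _tree_from_skbio(node, tip_names: Sequence[str]) -> Tree:
    order = {name: i for i, name in enumerate(tip_names)}
    children: list[list[int]] = [[] for _ in tip_names]
    lengths: list[float] = [0.0] * len(tip_names)
    index: dict[int, int] = {}

    def visit(n) -> int:
        if n.is_tip():
            i = order[n.name]
            lengths[i] = max(n.length or 0.0, 0.0)
            return i
        kid_idx = [visit(c) for c in n.children]
        children.append(kid_idx)
        lengths.append(max(n.length or 0.0, 0.0))
        i = len(children) - 1
        index[id(n)] = i
        return i

    visit(node)
    return Tree(tuple(tip_names), children, np.array(lengths))


def jc_distance_matrix(alignment: CodonAlignment) -> np.ndarray:
    """Pairwise JC-corrected nucleotide distances."""
    n = len(alignment)
    length = alignment.length
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diffs = sum(
                a != b
                for a, b in zip(alignment.sequences[i], alignment.sequences[j])
            )
            p = diffs / length
            try:
                d = jc_correct(p)
            except SaturationError as exc:
                raise SaturationError(
                    f"pair ({alignment.allele_ids[i]}, "
                    f"{alignment.allele_ids[j]}): {exc}"
                ) from exc
            dm[i, j] = dm[j, i] = d
    return dm


def build_nj_tree(alignment: CodonAlignment) -> Tree:
    """Neighbor-joining tree on JC-corrected nucleotide distances;
    negative branch lengths are clamped to zero."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(alignment) < 3:
        raise InsufficientDataError("need at least 3 sequences for NJ")
    dm = jc_distance_matrix(alignment)
    sk = nj(DistanceMatrix(dm, ids=list(alignment.allele_ids)))
    # root at the basal polytomy skbio returns
    return _tree_from_skbio(sk.root(), alignment.allele_ids)


# ---------------------------------------------------------------------------
# GY94 machinery
# ---------------------------------------------------------------------------


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies over the 61 sense codons."""
    pos_freq = np.full((3, 4), _MIN_FREQ)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for seq in alignment.sequences:
        for i in range(0, len(seq), 3):
            for pos in range(3):
                pos_freq[pos, base_idx[seq[i + pos]]] += 1
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, base_idx[c[0]]]
            * pos_freq[1, base_idx[c[1]]]
            * pos_freq[2, base_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    pi = np.maximum(pi, _MIN_FREQ)
    return pi / pi.sum()


def rate_matrix(omega: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalised reversible codon rate matrix (rows sum to zero)."""
    Q = np.zeros((_NSTATES, _NSTATES))
    Q[_SINGLE] = pi[np.where(_SINGLE)[1]]
    Q[_SINGLE & _TS] *= kappa
    Q[_SINGLE & _NONSYN] *= omega
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _transition_factories(
    omegas: np.ndarray, weights: np.ndarray, kappa: float, pi: np.ndarray
):
    """Eigendecompositions of each class matrix, jointly normalised so
    the mixture-average rate is one; returns P(t) factories."""
    sqrt_pi = np.sqrt(pi)
    decomps = []
    rates = np.empty(len(omegas))
    for k, w in enumerate(omegas):
        Q = rate_matrix(w, kappa, pi)
        rates[k] = -float(pi @ np.diag(Q))
        S = (sqrt_pi[:, None] / sqrt_pi[None, :]) * Q
        S = (S + S.T) / 2.0  # symmetrise numerical noise
        lam, V = np.linalg.eigh(S)
        A = V / sqrt_pi[:, None]
        B = V.T * sqrt_pi[None, :]
        decomps.append((lam, A, B))
    mean_rate = float(weights @ rates)
    if mean_rate <= 0:
        mean_rate = 1.0

    def P(k: int, t: float) -> np.ndarray:
        lam, A, B = decomps[k]
        M = (A * np.exp(lam * t / mean_rate)) @ B
        return np.clip(M, 0.0, None)

    return P


def discretize_beta(p: float, q: float, K: int) -> np.ndarray:
    """Class-mean omegas of K equal-probability beta(p, q) classes."""
    edges = np.array(
        [_beta_ppf(i / K, p, q) for i in range(K + 1)], dtype=float
    )
    upper = betainc(p + 1.0, q, edges[1:])
    lower = betainc(p + 1.0, q, edges[:-1])
    means = (upper - lower) * K * p / (p + q)
    return np.clip(means, 1e-8, 1.0)


def _beta_ppf(x: float, p: float, q: float) -> float:
    from scipy.stats import beta as beta_dist

    if x <= 0:
        return 0.0
    if x >= 1:
        return 1.0
    return float(beta_dist.ppf(x, p, q))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _encode(alignment: CodonAlignment) -> np.ndarray:
    """(n_tips, n_sites) codon state indices; stops are rejected."""
    alignment.translations()  # raises TranslationError on stops
    data = np.empty((len(alignment), alignment.codon_count), dtype=np.int64)
    for i in range(len(alignment)):
        for j, codon in enumerate(alignment.codons(i)):
            data[i, j] = _CODON_INDEX[codon]
    return data


def _class_site_likelihoods(
    data: np.ndarray,
    tree: Tree,
    omegas: np.ndarray,
    weights: np.ndarray,
    kappa: float,
    pi: np.ndarray,
    branch_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class per-site likelihoods.

    Returns (loglik_matrix with shape (K, n_sites) of log per-site
    likelihoods conditional on class, and the class weights).
    """
    n_sites = data.shape[1]
    K = len(omegas)
    Pfac = _transition_factories(omegas, weights, kappa, pi)
    lengths = np.maximum(tree.branch_lengths * branch_scale, _MIN_BRANCH)
    out = np.empty((K, n_sites))
    for k in range(K):
        Ps = [Pfac(k, lengths[i]) for i in range(tree.n_nodes)]
        logscale = np.zeros(n_sites)
        partials: dict[int, np.ndarray] = {}
        for node in range(tree.n_tips, tree.n_nodes):
            part = np.ones((_NSTATES, n_sites))
            for child in tree.children[node]:
                if child < tree.n_tips:
                    part *= Ps[child][:, data[child]]
                else:
                    part *= Ps[child] @ partials.pop(child)
            m = part.max(axis=0)
            m = np.where(m > 0, m, 1.0)
            part /= m
            logscale += np.log(m)
            partials[node] = part
        root = partials[tree.n_nodes - 1]
        site_lik = pi @ root
        out[k] = np.log(np.maximum(site_lik, 1e-300)) + logscale
    return out, weights


def _mixture_loglik(class_loglik: np.ndarray, weights: np.ndarray) -> float:
    m = class_loglik.max(axis=0)
    mix = (weights[:, None] * np.exp(class_loglik - m)).sum(axis=0)
    return float(np.sum(np.log(np.maximum(mix, 1e-300)) + m))


@dataclass
class SiteModelFit:
    model_label: str
    log_likelihood: float
    parameters: dict
    omega_classes: tuple[np.ndarray, np.ndarray]  # (omegas, weights)
    tree: Tree
    converged: bool
    n_sites: int
    class_site_loglik: np.ndarray = field(repr=False)

    @property
    def newick(self) -> str:
        return self.tree.newick()


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p: float
    selected_sites: tuple[int, ...] = ()


def _model_classes(
    model: str, params: dict, K: int
) -> tuple[np.ndarray, np.ndarray]:
    betas = discretize_beta(params["p"], params["q"], K)
    if model == "M7":
        return betas, np.full(K, 1.0 / K)
    p1 = params["p1"]
    omegas = np.append(betas, params["omega_s"])
    weights = np.append(np.full(K, (1.0 - p1) / K), p1)
    return omegas, weights


_M7_STARTS = [
    {"p": 0.5, "q": 2.0},
    {"p": 1.0, "q": 1.0},
    {"p": 2.0, "q": 0.5},
]
_M8_STARTS = [
    {"p": 0.5, "q": 2.0, "p1": 0.1, "omega_s": 2.0},
    {"p": 1.0, "q": 1.0, "p1": 0.2, "omega_s": 3.0},
    {"p": 2.0, "q": 0.5, "p1": 0.3, "omega_s": 5.0},
]


def fit_site_model(
    alignment: CodonAlignment,
    tree: Optional[Tree] = None,
    model: str = "M7",
    K: int = 10,
    n_starts: int = 3,
    max_iter: int = 200,
) -> SiteModelFit:
    """Maximum-likelihood fit of the M7 or M8 site-class model.

    Branch lengths come from the NJ tree (nucleotide substitutions per
    site) and are jointly rescaled by an optimized factor; kappa, the
    beta shape parameters and (for M8) the selection-class weight and
    omega are free.  A fixed grid of up to 3 starts makes the fit
    deterministic.
    """
    if model not in ("M7", "M8"):
        raise ValueError("model must be 'M7' or 'M8'")
    if K < 5:
        raise ValueError("K must be >= 5")
    if tree is None:
        tree = build_nj_tree(alignment)
    data = _encode(alignment)
    pi = f3x4_frequencies(alignment)
    if tree.branch_lengths[: tree.n_branches].sum() <= 0:
        tree = Tree(
            tree.tip_names,
            tree.children,
            np.full(tree.n_nodes, _MIN_BRANCH),
        )
    starts = (_M7_STARTS if model == "M7" else _M8_STARTS)[:n_starts]

    def unpack(x: np.ndarray) -> dict:
        params = {
            "scale": math.exp(x[0]),
            "kappa": math.exp(x[1]),
            "p": math.exp(x[2]),
            "q": math.exp(x[3]),
        }
        if model == "M8":
            params["p1"] = 1.0 / (1.0 + math.exp(-x[4]))
            params["omega_s"] = 1.0 + math.exp(x[5])
        return params

    def negloglik(x: np.ndarray) -> float:
        params = unpack(x)
        omegas, weights = _model_classes(model, params, K)
        cl, w = _class_site_likelihoods(
            data,
            tree,
            omegas,
            weights,
            params["kappa"],
            pi,
            params["scale"] * 3.0,  # nucleotide -> codon units
        )
        return -_mixture_loglik(cl, w)

    bounds = [(-6, 6), (-3, 4), (-4.6, 4.6), (-4.6, 4.6)]
    if model == "M8":
        bounds += [(-8, 8), (-7, 4)]
    best = None
    converged = False
    for start in starts:
        x0 = [0.0, math.log(2.0), math.log(start["p"]), math.log(start["q"])]
        if model == "M8":
            p1 = start["p1"]
            x0 += [math.log(p1 / (1 - p1)), math.log(start["omega_s"] - 1.0)]
        res = optimize.minimize(
            negloglik,
            np.array(x0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if not converged:
        warnings.warn(
            f"{model} fit did not report convergence; best lnL "
            f"{-best.fun:.4f} retained",
            stacklevel=2,
        )
    params = unpack(best.x)
    omegas, weights = _model_classes(model, params, K)
    cl, w = _class_site_likelihoods(
        data, tree, omegas, weights, params["kappa"], pi,
        params["scale"] * 3.0,
    )
    return SiteModelFit(
        model_label=model,
        log_likelihood=-float(best.fun),
        parameters=params,
        omega_classes=(omegas, weights),
        tree=tree,
        converged=converged,
        n_sites=data.shape[1],
        class_site_loglik=cl,
    )


def lrt(m7: SiteModelFit, m8: SiteModelFit) -> LrtResult:
    """Likelihood-ratio test of M8 against M7 (df = 2)."""
    if m7.model_label != "M7" or m8.model_label != "M8":
        raise ValueError("arguments must be an M7 fit and an M8 fit")
    if m7.n_sites != m8.n_sites or m7.tree.tip_names != m8.tree.tip_names:
        raise ValueError("fits are not on the same alignment/tree")
    stat = 2.0 * (m8.log_likelihood - m7.log_likelihood)
    if stat < 0:
        if stat < -0.1:
            warnings.warn(
                f"M8 worse than M7 by {-stat / 2:.4f} lnL units; "
                "statistic clamped to 0",
                stacklevel=2,
            )
        stat = 0.0
    return LrtResult(statistic=stat, df=2, p=float(chi2.sf(stat, 2)))


def site_posteriors(m8: SiteModelFit) -> np.ndarray:
    """Per-site posterior probability of membership in omega > 1 classes
    (empirical Bayes)."""
    omegas, weights = m8.omega_classes
    cl = m8.class_site_loglik
    m = cl.max(axis=0)
    lik = weights[:, None] * np.exp(cl - m)
    post = lik / lik.sum(axis=0, keepdims=True)
    return post[omegas > 1.0].sum(axis=0)


def selected_sites(
    m8: SiteModelFit, threshold: float = 0.05
) -> tuple[int, ...]:
    """1-based codon indices with posterior mass on omega > 1 classes of
    at least ``1 - threshold``."""
    post = site_posteriors(m8)
    return tuple(int(i) + 1 for i in np.where(post >= 1.0 - threshold)[0])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_gy94(
    tree: Tree,
    site_omegas: Sequence[float],
    kappa: float,
    pi: np.ndarray,
    rng: np.random.Generator,
    branch_scale: float = 1.0,
) -> CodonAlignment:
    """Simulate codon sequences on ``tree`` with per-site omegas.

    Branch lengths are interpreted (after ``branch_scale``) as expected
    substitutions per codon under the site-omega mixture, matching the
    normalisation used in fitting.
    """
    site_omegas = np.asarray(site_omegas, dtype=float)
    uniq, inv = np.unique(site_omegas, return_inverse=True)
    weights = np.bincount(inv).astype(float)
    weights /= weights.sum()
    Pfac = _transition_factories(uniq, weights, kappa, pi)
    n_sites = len(site_omegas)
    lengths = np.maximum(tree.branch_lengths * branch_scale, 0.0)
    states = {
        tree.n_nodes
        - 1: rng.choice(_NSTATES, size=n_sites, p=pi / pi.sum())
    }
    # preorder traversal
    stack = [tree.n_nodes - 1]
    while stack:
        node = stack.pop()
        for child in tree.children[node]:
            Ps = {k: Pfac(k, lengths[child]) for k in range(len(uniq))}
            parent_state = states[node]
            child_state = np.empty(n_sites, dtype=np.int64)
            for s in range(n_sites):
                probs = Ps[inv[s]][parent_state[s]]
                probs = probs / probs.sum()
                child_state[s] = rng.choice(_NSTATES, p=probs)
            states[child] = child_state
            stack.append(child)
    seqs = tuple(
        "".join(SENSE_CODONS[states[i][s]] for s in range(n_sites))
        for i in range(tree.n_tips)
    )
    return CodonAlignment(tree.tip_names, seqs)
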