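import math

import numpy as np
import pytest
from scipy.linalg import expm

from mhdiv._codon import SENSE_CODONS
from mhdiv.io_model import CodonAlignment, InsufficientDataError
from mhdiv.selection_ng86 import SaturationError
from mhdiv.site_models import (
    LrtResult,
    SiteModelFit,
    Tree,
    build_nj_tree,
    discretize_beta,
    f3x4_frequencies,
    fit_site_model,
    jc_distance_matrix,
    lrt,
    rate_matrix,
    selected_sites,
    simulate_gy94,
    site_posteriors,
    _class_site_likelihoods,
    _encode,
    _mixture_loglik,
)
from mhdiv.synthetic_data import SimConfig, gen_allele_pool


@pytest.fixture(scope="module")
def small_pool():
    cfg = SimConfig(seed=2, n_alleles=8, codon_count=50,
                    substitutions_per_allele=8.0)
    pool, _ = gen_allele_pool(cfg)
    return pool


@pytest.fixture(scope="module")
def small_tree(small_pool):
    return build_nj_tree(small_pool)


class TestNjTree:
    def test_three_equidistant_star(self):
        aln = CodonAlignment(
            ("a", "b", "c"),
            # pairwise p-distance 2/9 for every pair
            ("AAATTTGGG", "AACTTAGGG", "AACTTTGGA"),
        )
        tree = build_nj_tree(aln)
        tips = tree.branch_lengths[: tree.n_tips]
        assert np.allclose(tips, tips[0], atol=1e-12)

    def test_17_leaf_unrooted_binary_branch_count(self, default_pool):
        pool, _ = default_pool
        tree = build_nj_tree(pool)
        assert tree.n_tips == 17
        assert tree.n_branches == 2 * 17 - 3

    def test_duplicate_sequences_zero_terminal_pair(self):
        aln = CodonAlignment(
            ("a", "b", "c", "d"),
            ("AAATTTGGGCCC", "AAATTTGGGCCC",
             "AATTTTGGGCCA", "AAATTAGCGCCC"),
        )
        tree = build_nj_tree(aln)
        assert tree.branch_lengths[0] == pytest.approx(0.0, abs=1e-9)
        assert tree.branch_lengths[1] == pytest.approx(0.0, abs=1e-9)

    def test_needs_three_sequences(self):
        aln = CodonAlignment(("a", "b"), ("AAA", "AAT"))
        with pytest.raises(InsufficientDataError):
            build_nj_tree(aln)

    def test_saturated_pair_raises(self):
        aln = CodonAlignment(
            ("a", "b", "c"), ("AAAAAA", "CCCCCC", "AAAACC")
        )
        with pytest.raises(SaturationError, match="a.*b"):
            jc_distance_matrix(aln)


class TestBetaDiscretization:
    def test_equal_weight_classes_average_to_beta_mean(self):
        for p, q in [(0.5, 2.0), (1.0, 1.0), (3.0, 1.5)]:
            omegas = discretize_beta(p, q, 10)
            assert len(omegas) == 10
            assert np.all((omegas > 0) & (omegas <= 1.0))
            assert omegas.mean() == pytest.approx(p / (p + q), abs=1e-6)
            assert np.all(np.diff(omegas) >= 0)


class TestLikelihoodMachinery:
    def test_rate_matrix_rows_sum_to_zero(self):
        pi = np.full(61, 1 / 61)
        Q = rate_matrix(2.0, 3.0, pi)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_one_codon_likelihood_matches_expm_oracle(self):
        """Pruning likelihood for a single site equals direct summation
        over root states with scipy.linalg.expm transition matrices."""
        aln = CodonAlignment(("a", "b", "c"), ("ATG", "ATA", "ACG"))
        pi = np.full(61, 1 / 61)
        omegas = np.array([0.3, 1.5])
        weights = np.array([0.6, 0.4])
        kappa = 2.0
        # a 3-tip star tree with distinct branch lengths
        tree = Tree(
            ("a", "b", "c"),
            [[], [], [], [0, 1, 2]],
            np.array([0.1, 0.25, 0.4, 0.0]),
        )
        cl, w = _class_site_likelihoods(
            _encode(aln), tree, omegas, weights, kappa, pi, 1.0
        )
        got = _mixture_loglik(cl, w)
        # oracle: explicit matrix exponentials and root-state summation
        sqrt = None
        rates = []
        Qs = []
        for om in omegas:
            Q = rate_matrix(om, kappa, pi)
            rates.append(-float(pi @ np.diag(Q)))
            Qs.append(Q)
        mean_rate = float(weights @ np.array(rates))
        idx = {c: i for i, c in enumerate(SENSE_CODONS)}
        states = [idx["ATG"], idx["ATA"], idx["ACG"]]
        lengths = [0.1, 0.25, 0.4]
        total = 0.0
        for om, wgt, Q in zip(omegas, weights, Qs):
            Ps = [expm(Q * t / mean_rate) for t in lengths]
            lik = sum(
                pi[r] * Ps[0][r, states[0]] * Ps[1][r, states[1]]
                * Ps[2][r, states[2]]
                for r in range(61)
            )
            total += wgt * lik
        assert got == pytest.approx(math.log(total), abs=1e-6)


class TestFitting:
    def test_identical_sequences_lrt_zero(self):
        aln = CodonAlignment(
            ("a", "b", "c"), ("ATGGCTAAA",) * 3
        )
        m7 = fit_site_model(aln, model="M7", n_starts=1, max_iter=20)
        m8 = fit_site_model(aln, model="M8", n_starts=1, max_iter=20)
        res = lrt(m7, m8)
        assert res.statistic == pytest.approx(0.0, abs=1e-4)
        assert res.p > 0.99

    def test_k_floor(self, small_pool):
        with pytest.raises(ValueError):
            fit_site_model(small_pool, model="M7", K=3)

    def test_m8_nests_m7(self, small_pool, small_tree):
        m7 = fit_site_model(small_pool, small_tree, "M7", n_starts=1)
        m8 = fit_site_model(small_pool, small_tree, "M8", n_starts=1)
        assert m8.log_likelihood >= m7.log_likelihood - 1e-4


class TestLrt:
    def _stub(self, label, lnl):
        return SiteModelFit(
            model_label=label, log_likelihood=lnl, parameters={},
            omega_classes=(np.array([0.5]), np.array([1.0])),
            tree=Tree(("a", "b", "c"), [[], [], [], [0, 1, 2]],
                      np.zeros(4)),
            converged=True, n_sites=90,
            class_site_loglik=np.zeros((1, 90)),
        )

    def test_equal_likelihoods(self):
        res = lrt(self._stub("M7", -1000.0), self._stub("M8", -1000.0))
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_printed_value_arithmetic(self):
        res = lrt(self._stub("M7", -1000.0), self._stub("M8", -976.628))
        assert res.statistic == pytest.approx(46.744)
        assert res.df == 2
        assert res.p < 0.01

    def test_worse_m8_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = lrt(self._stub("M7", -999.0), self._stub("M8", -1000.0))
        assert res.statistic == 0.0

    def test_mismatched_inputs_rejected(self):
        a = self._stub("M7", -10.0)
        bad = self._stub("M8", -9.0)
        bad.n_sites = 50
        with pytest.raises(ValueError):
            lrt(a, bad)

    def test_wrong_labels_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._stub("M8", -10.0), self._stub("M7", -9.0))


@pytest.fixture(scope="module")
def sims():
    """Three GY94 simulations with 10 of 50 codons planted at omega 5."""
    cfg = SimConfig(seed=2, n_alleles=10, codon_count=50,
                    substitutions_per_allele=8.0)
    pool, _ = gen_allele_pool(cfg)
    base_tree = build_nj_tree(pool)
    pi = f3x4_frequencies(pool)
    rng = np.random.default_rng(17)
    out = []
    planted = set(range(1, 51, 5))
    omegas = np.where(
        np.isin(np.arange(1, 51), sorted(planted)), 5.0, 0.2
    )
    for _ in range(3):
        sim = simulate_gy94(
            base_tree, omegas, kappa=2.0, pi=pi, rng=rng,
            branch_scale=4.0,
        )
        tree = build_nj_tree(sim)
        m7 = fit_site_model(sim, tree, "M7", n_starts=1)
        m8 = fit_site_model(sim, tree, "M8", n_starts=1)
        out.append((m7, m8, planted))
    return out


class TestSimulationRecovery:
    """Planted-omega recovery on the module's own GY94 generator
    (replicate counts reduced to fit the test budget)."""

    def test_lrt_detects_planted_selection(self, sims):
        stats = [lrt(m7, m8).statistic for m7, m8, _ in sims]
        assert np.median(stats) > 9.21  # chi2(2) 1% critical value

    def test_m8_recovers_omega_above_one(self, sims):
        omega_s = [m8.parameters["omega_s"] for _, m8, _ in sims]
        assert np.median(omega_s) > 1.0

    def test_posterior_recall_of_planted_sites(self, sims):
        recalls = []
        for _, m8, planted in sims:
            sel = set(selected_sites(m8, threshold=0.05))
            recalls.append(len(sel & planted) / len(planted))
        assert np.median(recalls) >= 0.7

    def test_posterior_shape(self, sims):
        for _, m8, _ in sims:
            post = site_posteriors(m8)
            assert post.shape == (m8.n_sites,)
            assert np.all((post >= 0) & (post <= 1))

    def test_m7_null_rarely_rejects(self, small_pool, small_tree):
        """Data simulated under M7: LRT should rarely clear the 5%
        critical value (reduced replicate count; boundary-aware)."""
        pi = f3x4_frequencies(small_pool)
        rng = np.random.default_rng(23)
        omegas_pool = discretize_beta(0.8, 1.8, 10)
        exceed = 0
        n_reps = 4
        for _ in range(n_reps):
            site_omegas = rng.choice(omegas_pool, size=40)
            sim = simulate_gy94(
                small_tree, site_omegas, kappa=2.0, pi=pi, rng=rng,
                branch_scale=3.0,
            )
            tree = build_nj_tree(sim)
            m7 = fit_site_model(sim, tree, "M7", n_starts=1, max_iter=60)
            m8 = fit_site_model(sim, tree, "M8", n_starts=1, max_iter=60)
            if lrt(m7, m8).statistic > 5.99:
                exceed += 1
        assert exceed <= 1


class TestNewick:
    def test_roundtrippable_string(self, small_tree):
        nwk = small_tree.newick()
        assert nwk.endswith(";")
        import skbio

        t = skbio.TreeNode.read([nwk])
        assert {x.name for x in t.tips()} == set(small_tree.tip_names)
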