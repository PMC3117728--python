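import itertools
import math

import numpy as np
import pytest

from mhdiv._codon import NUCLEOTIDES, SENSE_CODONS, STOP_CODONS
from mhdiv.io_model import CodonAlignment, SitePartition
from mhdiv.pbs_catalogs import (
    HUMAN_BETA1_REFERENCE,
    RECHE_PBS_POSITIONS,
)
from mhdiv.selection_ng86 import (
    SaturationError,
    jc_correct,
    map_pbs_sites,
    mean_dn_ds,
    ng86_pair,
    ng86_site_counts,
    pair_counts,
    z_test_positive_selection,
)
from mhdiv.synthetic_data import SimConfig, gen_allele_pool

# --- independent oracle -----------------------------------------------------

_AA = {
    c: aa
    for c, aa in zip(
        [a + b + d for a in "TCAG" for b in "TCAG" for d in "TCAG"],
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    )
}


def oracle_pair(ca, cb):
    """Exhaustive pathway enumeration, written independently of the
    implementation (different codon table source and looping)."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(positions):
        cur, nd, sd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _AA[nxt] == "*":
                ok = False
                break
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((nd, sd))
    if not totals:
        return math.nan, math.nan
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


class TestSiteCounts:
    def test_phe(self):
        n, s = ng86_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_trp_stops_as_nonsynonymous(self):
        n, s = ng86_site_counts("TGG")
        assert s == 0.0
        assert n == 3.0

    def test_identity_n_plus_s(self):
        for codon in SENSE_CODONS:
            n, s = ng86_site_counts(codon)
            assert n + s == pytest.approx(3.0)

    def test_stop_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA")

    def test_against_oracle(self):
        for codon in SENSE_CODONS:
            syn = 0.0
            for pos in range(3):
                for b in NUCLEOTIDES:
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1 :]
                    if _AA[mut] != "*" and _AA[mut] == _AA[codon]:
                        syn += 1 / 3
            assert ng86_site_counts(codon)[1] == pytest.approx(syn)


class TestPairCounting:
    def test_identical(self):
        assert ng86_pair("ACG", "ACG") == (0.0, 0.0)

    def test_two_pathway_average(self):
        assert ng86_pair("TTT", "GTA") == (1.5, 0.5)

    def test_gly_third_position(self):
        assert ng86_pair("GGA", "GGG") == (0.0, 1.0)

    def test_stop_blocked_pathway_renormalised(self):
        # TGT->TGA (stop) blocked; only TGT->TTT->TTA remains: 2 nonsyn
        assert ng86_pair("TGT", "TTA") == (2.0, 0.0)

    def test_sampled_pairs_match_oracle(self):
        rng = np.random.default_rng(1)
        codons = rng.choice(len(SENSE_CODONS), size=(300, 2))
        for i, j in codons:
            ca, cb = SENSE_CODONS[i], SENSE_CODONS[j]
            got = ng86_pair(ca, cb)
            want = oracle_pair(ca, cb)
            assert got[0] == pytest.approx(want[0], nan_ok=True)
            assert got[1] == pytest.approx(want[1], nan_ok=True)


class TestJcCorrect:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_small_p(self):
        assert jc_correct(0.01) == pytest.approx(0.010067, abs=1e-6)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            jc_correct(0.75)


class TestMeanDnDs:
    def test_identical_alleles(self):
        aln = CodonAlignment(("a", "b"), ("ATGATG", "ATGATG"))
        r = mean_dn_ds(aln)
        assert r.dN == 0.0
        assert r.dS == 0.0
        assert math.isnan(r.ratio)

    def test_two_sequence_hand_computation(self):
        # codon 1: TTT vs GTA (Nd=1.5, Sd=0.5); codon 2: GGA vs GGG (0, 1);
        # invariant AAA tail keeps proportions off the correction boundary

        aln = CodonAlignment(
            ("a", "b"), ("TTTGGA" + "AAA" * 8, "GTAGGG" + "AAA" * 8)
        )
        counts = pair_counts(
            ["TTT", "GGA"] + ["AAA"] * 8, ["GTA", "GGG"] + ["AAA"] * 8
        )
        r = mean_dn_ds(aln)
        assert r.dN == pytest.approx(jc_correct(counts.Nd / counts.N))
        assert r.dS == pytest.approx(jc_correct(counts.Sd / counts.S))

    def test_synonymous_only_alignment_infinite_ds_is_flagged(self):
        aln = CodonAlignment(("a", "b"), ("ATGGCT", "ATGACT"))
        r = mean_dn_ds(aln)  # only a nonsyn difference
        assert r.dS == 0.0
        assert math.isinf(r.ratio)

    def test_empty_partition_rejected(self, default_pool):
        pool, _ = default_pool
        with pytest.raises(ValueError):
            mean_dn_ds(pool, partition=())

    def test_partition_bounds_full_alignment(self, default_pool):
        pool, _ = default_pool
        pbs = tuple(range(2, 91, 4))[:24]
        non = tuple(i for i in range(1, 91) if i not in set(pbs))
        full = mean_dn_ds(pool)
        a = mean_dn_ds(pool, pbs)
        b = mean_dn_ds(pool, non)
        assert min(a.dN, b.dN) - 1e-9 <= full.dN <= max(a.dN, b.dN) + 1e-9
        assert min(a.dS, b.dS) - 1e-9 <= full.dS <= max(a.dS, b.dS) + 1e-9


class TestZTest:
    def test_synonymous_variation_only(self):
        # alleles differing only by Gly/Leu third positions: dS > dN = 0
        tail = "ATGGCTAAACAT" * 5
        aln = CodonAlignment(
            ("a", "b", "c"),
            ("GGATTAGGC" + tail, "GGGTTGGGC" + tail, "GGCTTAGGT" + tail),
        )
        r = z_test_positive_selection(aln, reps=500, seed=1)
        assert r.z < 0
        assert r.p > 0.5

    def test_no_variation_degenerate(self):
        aln = CodonAlignment(("a", "b"), ("ATGATG", "ATGATG"))
        r = z_test_positive_selection(aln, reps=200, seed=1)
        assert r.z == 0.0
        assert r.p == 1.0

    def test_reps_floor(self, default_pool):
        pool, _ = default_pool
        with pytest.raises(ValueError):
            z_test_positive_selection(pool, reps=10)

    def test_positive_selection_detected_when_planted(self):
        cfg = SimConfig(
            seed=3, n_alleles=12, omega_pbs=8.0, omega_nonpbs=8.0,
            substitutions_per_allele=8.0,
        )
        pool, _ = gen_allele_pool(cfg)
        r = z_test_positive_selection(pool, reps=1000, seed=3)
        assert r.dN > r.dS
        assert r.p < 0.05

    def test_pbs_dn_exceeds_nonpbs_dn_with_planted_contrast(self):
        hits = 0
        trials = 40
        for i in range(trials):
            cfg = SimConfig(
                seed=100 + i, n_alleles=12,
                omega_pbs=10.0, omega_nonpbs=0.2,
                substitutions_per_allele=12.0,
            )
            pool, _ = gen_allele_pool(cfg)
            pbs = cfg.pbs_codons
            non = tuple(
                c for c in range(1, 91) if c not in set(pbs)
            )
            if mean_dn_ds(pool, pbs).dN > mean_dn_ds(pool, non).dN:
                hits += 1
        assert hits >= int(0.95 * trials)


class TestPbsMapping:
    def _human_backtranslated(self):
        # unambiguous back-translation of the human beta-1 reference
        table = {
            "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
            "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
            "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
            "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
        }
        nt = "".join(table[aa] for aa in HUMAN_BETA1_REFERENCE)
        return CodonAlignment(("h1", "h2"), (nt, nt))

    def test_self_mapping_is_identity(self):
        aln = self._human_backtranslated()
        part = map_pbs_sites(aln, "reche")
        assert part.pbs_codons == tuple(sorted(RECHE_PBS_POSITIONS))
        assert len(part.pbs_codons) == 24

    def test_empty_catalog(self):
        aln = self._human_backtranslated()
        part = map_pbs_sites(aln, positions=())
        assert part.pbs_codons == ()
        assert len(part.non_pbs_codons) == aln.codon_count

    def test_uncovered_positions_dropped_with_warning(self):
        aln = self._human_backtranslated().restrict(range(1, 51))
        with pytest.warns(UserWarning, match="not covered"):
            part = map_pbs_sites(aln, "reche")
        assert all(c <= 50 for c in part.pbs_codons)
        assert len(part.pbs_codons) < len(RECHE_PBS_POSITIONS)

    def test_partition_invariants(self):
        part = SitePartition((2, 5), 10)
        assert part.non_pbs_codons == (1, 3, 4, 6, 7, 8, 9, 10)
        assert set(part.pbs_codons) | set(part.non_pbs_codons) == set(
            range(1, 11)
        )
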