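"""Phase-register statistics and PHAS locus scanning.

The hypergeometric tail is checked against full enumeration of draws
(small N) and Monte-Carlo sampling (larger N); locus scanning is checked
by planted-truth recovery with register shift-equivariance and strand
symmetry.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from phasnet.config import RunConfig
from phasnet.phasing import (
    PhaseWindowStats,
    enumerate_phase_stats,
    phasing_pvalue,
    phasing_score,
    scan_phas,
    top_phasirnas,
)
from phasnet.preprocess import GenomeHit, SequenceTag
from phasnet.seqs import random_seq, revcomp


def _stats(N, m, n, k, P=0.0, U=0.0):
    return PhaseWindowStats((0, 231), 21, 0, N, m, n, k, P, U)


class TestEnumerate:
    def test_three_plus_strand_cycles(self):
        """Reads at 0, 21, 42 (register 0, window 231): k=3, n=3, m=22."""
        reads = [(0, "+", 21, 10.0), (21, "+", 21, 5.0), (42, "+", 21, 2.0)]
        st = enumerate_phase_stats(reads, 21, 0, (0, 231))
        assert (st.k, st.n, st.m, st.N) == (3, 3, 22, 462)
        assert (st.P, st.U) == (17.0, 0.0)

    def test_minus_strand_two_nt_offset(self):
        """A minus-strand read with 5' end at 19 has phase coordinate 21."""
        hit = GenomeHit("t", "chr1", 19 - 20, "-", 0, 21)  # 5' end at start+20 = 19
        from phasnet.phasing import phase_coordinate

        assert phase_coordinate(hit) == 21
        st = enumerate_phase_stats([(21, "-", 21, 4.0)], 21, 0, (0, 231))
        assert (st.k, st.n) == (1, 1)

    def test_empty_window(self):
        st = enumerate_phase_stats([], 21, 0, (0, 231))
        assert (st.n, st.k, st.P, st.U) == (0, 0, 0.0, 0.0)

    def test_window_not_multiple_of_period_rejected(self):
        with pytest.raises(ValueError):
            enumerate_phase_stats([], 21, 0, (0, 230))

    def test_grid_model_merges_strands(self):
        reads = [(0, "+", 21, 1.0), (0, "-", 21, 1.0)]
        st_all = enumerate_phase_stats(reads, 21, 0, (0, 231), "all")
        st_grid = enumerate_phase_stats(reads, 21, 0, (0, 231), "grid")
        assert (st_all.n, st_all.N, st_all.m) == (2, 462, 22)
        assert (st_grid.n, st_grid.N, st_grid.m) == (1, 231, 11)


def enumeration_pvalue(N, m, n, k):
    """Oracle: P(X >= k) by full enumeration of all C(N, n) draws."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < m) >= k:
            hits += 1
    return hits / total


class TestPvalue:
    def test_all_draws_in_register(self):
        """N=40, m=10, n=5, k=5 equals C(10,5)/C(40,5)."""
        p = phasing_pvalue(_stats(40, 10, 5, 5))
        assert p == pytest.approx(math.comb(10, 5) / math.comb(40, 5), rel=1e-12)

    def test_k_zero_is_one(self):
        assert phasing_pvalue(_stats(462, 22, 5, 0)) == 1.0

    def test_n_equals_N_degenerate(self):
        assert phasing_pvalue(_stats(20, 6, 20, 6)) == pytest.approx(1.0)

    def test_inconsistent_stats_rejected(self):
        with pytest.raises(ValueError):
            _stats(40, 10, 5, 6)

    @pytest.mark.parametrize("N,m,n,k", [
        (8, 3, 4, 2), (10, 4, 5, 3), (12, 6, 6, 4), (12, 2, 7, 1), (9, 9, 3, 3),
    ])
    def test_exhaustive_enumeration_small_N(self, N, m, n, k):
        assert phasing_pvalue(_stats(N, m, n, k)) == pytest.approx(
            enumeration_pvalue(N, m, n, k), rel=1e-12
        )

    def test_agrees_with_scipy_tail(self):
        for N, m, n, k in [(462, 22, 15, 6), (462, 22, 40, 3), (231, 11, 12, 4)]:
            assert phasing_pvalue(_stats(N, m, n, k)) == pytest.approx(
                float(sps.hypergeom.sf(k - 1, N, m, n)), rel=1e-9
            )

    def test_monte_carlo_medium_N(self, rng):
        """10^5 hypergeometric draws reproduce the tail within 3 SEs."""
        N, m, n, k = 60, 12, 20, 7
        draws = rng.hypergeometric(m, N - m, n, size=100_000)
        est = float(np.mean(draws >= k))
        se = math.sqrt(est * (1 - est) / draws.size)
        assert abs(phasing_pvalue(_stats(N, m, n, k)) - est) <= 3 * se


class TestScore:
    def test_below_three_cycles_scores_zero(self):
        assert phasing_score(_stats(462, 22, 2, 2, P=100.0, U=0.0)) == 0.0

    def test_closed_form_value(self):
        """P=100, U=0, k=5 gives 3 ln(1001)."""
        assert phasing_score(_stats(462, 22, 5, 5, P=100.0, U=0.0)) == pytest.approx(
            3 * math.log(1001), rel=1e-12
        )

    def test_monotonicity_in_P_k_and_U(self):
        base = phasing_score(_stats(462, 22, 6, 5, P=50.0, U=10.0))
        assert phasing_score(_stats(462, 22, 6, 5, P=80.0, U=10.0)) > base
        assert phasing_score(_stats(462, 22, 6, 6, P=50.0, U=10.0)) > base
        assert phasing_score(_stats(462, 22, 6, 5, P=50.0, U=20.0)) < base


def _phased_setup(rng, period=21, cycles=10, abundance=20, start=2000, genome_len=8000,
                  read_len=None, register_offset=0):
    """A clean phased run: ``cycles`` plus-strand reads, one per cycle."""
    read_len = read_len or period
    genome = random_seq(rng, genome_len, 0.5)
    tags, hits = [], []
    for j in range(cycles):
        pos = start + register_offset + j * period
        seq = genome[pos : pos + read_len]
        tag = SequenceTag(f"p{j}", seq, {"l": abundance})
        tags.append(tag)
        hits.append(GenomeHit(tag.tag_id, "chr1", pos, "+", 0, read_len))
    return genome, tags, hits


class TestScan:
    def test_planted_locus_recovered(self, rng, config):
        _, tags, hits = _phased_setup(rng)
        loci = scan_phas(hits, tags, 21, config)
        assert len(loci) == 1
        locus = loci[0]
        assert locus.register == 2000 % 21
        assert locus.p_value < 0.001 and locus.phasing_score > 10
        assert locus.phased_fraction > 0.30 and locus.dominant_length == 21
        assert locus.end - locus.start > 100

    def test_wrong_read_length_gives_no_locus(self, rng, config):
        """Reads of 20 nt at 21-nt spacing: dominant length != period."""
        _, tags, hits = _phased_setup(rng, read_len=20)
        assert scan_phas(hits, tags, 21, config) == []

    def test_short_phased_run_rejected(self, rng, config):
        """~90 bp of phased signal fails the >100 bp length filter."""
        _, tags, hits = _phased_setup(rng, cycles=4)  # span 3*21+21 = 84 bp
        assert scan_phas(hits, tags, 21, config) == []

    def test_register_shift_equivariance(self, rng, config):
        seed = int(rng.integers(2**31))
        r1 = np.random.default_rng(seed)
        r2 = np.random.default_rng(seed)
        _, tags1, hits1 = _phased_setup(r1)
        _, tags2, hits2 = _phased_setup(r2, register_offset=21)
        l1 = scan_phas(hits1, tags1, 21, config)
        l2 = scan_phas(hits2, tags2, 21, config)
        assert len(l1) == len(l2) == 1
        assert l1[0].register == l2[0].register
        assert l1[0].p_value == pytest.approx(l2[0].p_value)
        assert l1[0].phasing_score == pytest.approx(l2[0].phasing_score)
        assert l2[0].start - l1[0].start == 21

    def test_strand_symmetry(self, rng, config):
        """Reverse-complementing the genome and remapping mirrors the locus
        with identical statistics."""
        genome, tags, hits = _phased_setup(rng)
        from phasnet.preprocess import align_tags

        g = {"chr1": genome}
        g_rc = {"chr1": revcomp(genome)}
        fwd = scan_phas(align_tags(tags, g, 0), tags, 21, config)
        rev = scan_phas(align_tags(tags, g_rc, 0), tags, 21, config)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].phasing_score == pytest.approx(rev[0].phasing_score)
        assert fwd[0].p_value == pytest.approx(rev[0].p_value)
        assert fwd[0].phased_fraction == pytest.approx(rev[0].phased_fraction)
        # mirror-image span
        n = len(genome)
        assert rev[0].start == pytest.approx(n - fwd[0].end, abs=3)


class TestTopPhasirnas:
    def _locus(self, n_species):
        from phasnet.phasing import PhasLocus

        phasirnas = [(f"SEQ{i}", 21 * i, float(100 - i), "+") for i in range(n_species)]
        return PhasLocus("P", "chr1", 0, 21 * n_species, 21, 0, 1e-9, 50.0, 0.9, 21, phasirnas)

    def test_caps_at_thirty(self):
        assert len(top_phasirnas(self._locus(40), 30)) == 30

    def test_fewer_species_all_returned(self):
        assert len(top_phasirnas(self._locus(5), 30)) == 5

    def test_tie_broken_by_lower_coordinate(self):
        from phasnet.phasing import PhasLocus

        phasirnas = [("A", 210, 50.0, "+"), ("B", 42, 50.0, "+"), ("C", 0, 99.0, "+")]
        locus = PhasLocus("P", "chr1", 0, 300, 21, 0, 1e-9, 50.0, 0.9, 21, phasirnas)
        ranked = top_phasirnas(locus, 2)
        assert [r[0] for r in ranked] == ["C", "B"]
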