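"""Target-site scoring (penalty scheme, energy ratio) and trigger assignment."""

import numpy as np
import pytest

from phasnet.config import RunConfig
from phasnet.phasing import PhasLocus
from phasnet.seqs import random_seq, revcomp
from phasnet.targets import (
    DuplexAlignment,
    allen_score,
    find_candidate_sites,
    identify_triggers,
    mfe_ratio,
    predict_targets,
)

SRNA = "TGGAGCTCCCTTCAATCCAAA"  # 21 nt


def _mutate(seq, pos, base=None):
    """Force a substitution at 0-based pos."""
    old = seq[pos]
    new = base or ("A" if old != "A" else "C")
    return seq[: pos] + new + seq[pos + 1 :]


def _site_with(srna, changes):
    """Perfect complement site with per-sRNA-position substitutions.

    ``changes`` maps 1-based sRNA position -> kind ('mm' or 'gu'). A 'gu'
    makes the pair G:U by substituting the site base (sRNA G pairs site T,
    sRNA T pairs site G); the position must carry a G or T/U in the sRNA.
    """
    site = list(revcomp(srna))
    L = len(srna)
    for pos, kind in changes.items():
        i = pos - 1
        j = L - 1 - i  # site index paired with sRNA position i
        srna_base = srna[i]
        if kind == "gu":
            assert srna_base in "GT", f"position {pos} cannot form G:U"
            site[j] = "T" if srna_base == "G" else "G"
        else:
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}[srna_base]
            choices = [b for b in "ACGT" if b != comp]
            # avoid accidentally creating a wobble pair
            choices = [
                b for b in choices
                if not ((srna_base, b) in {("G", "T"), ("T", "G")})
            ]
            site[j] = choices[0]
    return "".join(site)


def _embed(site, rng, flank=60):
    left = random_seq(rng, flank, 0.5)
    right = random_seq(rng, flank, 0.5)
    return left + site + right, flank


class TestAllenScore:
    def test_perfect_complement_scores_zero(self, rng):
        tx, start = _embed(revcomp(SRNA), rng)
        sites = find_candidate_sites(SRNA, tx)
        best = min(sites, key=allen_score)
        assert allen_score(best) == 0.0
        assert best.site_start == start

    @pytest.mark.parametrize(
        "changes,expected",
        [
            ({16: "gu"}, 0.5),  # wobble outside the core
            ({5: "gu"}, 1.0),  # wobble inside positions 2-13: doubled
            ({3: "mm", 16: "gu"}, 2.5),  # doubled mismatch + plain wobble
            ({2: "mm", 13: "mm"}, 4.0),  # both core boundaries doubled
            ({1: "mm", 14: "mm"}, 2.0),  # positions outside the core
        ],
    )
    def test_penalty_scheme(self, rng, changes, expected):
        site = _site_with(SRNA, changes)
        tx, _ = _embed(site, rng)
        sites = find_candidate_sites(SRNA, tx)
        assert min(allen_score(s) for s in sites) == pytest.approx(expected)

    def test_score_invariant_under_transcript_shift(self, rng):
        site = _site_with(SRNA, {5: "mm"})
        tx1 = random_seq(rng, 30, 0.5) + site + random_seq(rng, 30, 0.5)
        tx2 = random_seq(rng, 200, 0.5) + site + random_seq(rng, 11, 0.5)
        s1 = min(find_candidate_sites(SRNA, tx1), key=allen_score)
        s2 = min(find_candidate_sites(SRNA, tx2), key=allen_score)
        assert allen_score(s1) == allen_score(s2)
        assert mfe_ratio(s1) == mfe_ratio(s2)


class TestMfeRatio:
    def test_perfect_complement_is_one(self, rng):
        tx, _ = _embed(revcomp(SRNA), rng)
        best = min(find_candidate_sites(SRNA, tx), key=allen_score)
        assert mfe_ratio(best) == pytest.approx(1.0)

    def test_losing_one_gc_pair(self):
        """A broken pair removes its energy: ratio = (E+3)/E for a GC."""
        srna = "GGGGGGGGGGCCCCCCCCCCC"  # all G/C: perfect energy -63
        site = _site_with(srna, {5: "mm"})
        duplex = find_candidate_sites(srna, site, max_equiv=7.0)
        best = min(duplex, key=allen_score)
        assert mfe_ratio(best) == pytest.approx(60 / 63)

    def test_all_positions_mismatched_is_zero(self):
        srna = "A" * 21
        site = "C" * 21  # A:C pairs nothing
        duplex = DuplexAlignment(srna, site, 0, 21, "x" * 21)
        assert mfe_ratio(duplex) == 0.0

    def test_all_n_srna_rejected(self):
        duplex = DuplexAlignment("N" * 21, "A" * 21, 0, 21, "x" * 21)
        with pytest.raises(ValueError):
            mfe_ratio(duplex)


class TestPredictTargets:
    def test_planted_site_accepted(self, rng):
        site = _site_with(SRNA, {16: "gu", 18: "mm"})  # score 1.5
        tx, start = _embed(site, rng)
        out = predict_targets([("mi1", "miRNA", SRNA)], [("tx1", tx)])
        assert len(out) == 1
        inter = out[0]
        assert inter.accepted
        assert inter.allen_score == pytest.approx(1.5)
        assert inter.site_start == start
        assert inter.cleavage_position == start + len(SRNA) - 10

    def test_score_exactly_seven_rejected(self, rng):
        """Allen score 7.0 fails the strict < 7 rule."""
        changes = {1: "gu", 16: "gu", 14: "mm", 15: "mm", 17: "mm", 18: "mm", 19: "mm", 20: "mm"}
        site = _site_with(SRNA, changes)  # 6 x 1.0 + 2 x 0.5, all outside the core
        tx, _ = _embed(site, rng)
        out = predict_targets([("mi1", "miRNA", SRNA)], [("tx1", tx)])
        assert len(out) == 1
        assert out[0].allen_score == pytest.approx(7.0)
        assert not out[0].accepted

    def test_ratio_exactly_at_threshold_rejected(self, rng):
        """MFE ratio equal to the cut-off fails the strict > rule."""
        site = _site_with(SRNA, {16: "gu"})
        tx, _ = _embed(site, rng)
        out = predict_targets([("mi1", "miRNA", SRNA)], [("tx1", tx)])
        ratio = out[0].mfe_ratio
        assert out[0].accepted  # well above 0.65 by construction
        out2 = predict_targets(
            [("mi1", "miRNA", SRNA)], [("tx1", tx)], RunConfig(mfe_ratio_min=ratio)
        )
        assert out2[0].mfe_ratio == ratio
        assert not out2[0].accepted

    def test_random_pair_typically_empty(self, rng):
        srna = random_seq(rng, 21, 0.5)
        tx = random_seq(rng, 1000, 0.5)
        out = predict_targets([("mi1", "miRNA", srna)], [("tx1", tx)])
        accepted = [o for o in out if o.accepted]
        assert accepted == []

    def test_two_planted_sites_reported_five_prime_first(self, rng):
        site = revcomp(SRNA)
        tx = random_seq(rng, 40, 0.5) + site + random_seq(rng, 40, 0.5) + site + random_seq(rng, 40, 0.5)
        sites = [s for s in find_candidate_sites(SRNA, tx) if allen_score(s) == 0.0]
        assert [s.site_start for s in sites] == [40, 40 + 21 + 40]


def brute_force_best(srna, tx, max_equiv=7.0):
    """Independent full scan: all offsets, all single-gap placements,
    scored directly from the penalty definition."""
    from phasnet.seqs import can_pair, pairs_wobble

    L = len(srna)
    w = [2.0 if 2 <= i + 1 <= 13 else 1.0 for i in range(L)]

    def pair_pen(a, b):
        if (a, b) in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}:
            return 0.0
        if (a, b) in {("G", "T"), ("T", "G")}:
            return 0.5
        return 1.0

    best = None
    for j in range(len(tx) - L + 1):  # ungapped
        site = tx[j : j + L]
        sc = sum(pair_pen(srna[i], site[L - 1 - i]) * w[i] for i in range(L))
        if best is None or sc < best[0]:
            best = (sc, j)
    for g in range(1, L - 1):  # sRNA bulge at 0-based g
        for j in range(len(tx) - (L - 1) + 1):
            site = tx[j : j + L - 1]
            sc = 2.0 * w[g]
            for i in range(L):
                if i == g:
                    continue
                idx = L - 2 - i if i < g else L - 1 - i
                sc += pair_pen(srna[i], site[idx]) * w[i]
            if best is None or sc < best[0]:
                best = (sc, j)
    for g in range(1, L):  # target bulge before 1-based position g
        for j in range(len(tx) - (L + 1) + 1):
            site = tx[j : j + L + 1]
            sc = 2.0 * w[g - 1]
            for i in range(L):
                idx = L - i if i < g - 1 else L - 1 - i
                sc += pair_pen(srna[i], site[idx]) * w[i]
            if best is None or sc < best[0]:
                best = (sc, j)
    return best[0]


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_best_score_matches_full_scan(self, seed):
        rng = np.random.default_rng(seed)
        srna = random_seq(rng, 21, 0.5)
        site = _site_with(srna, {4: "mm", 16: "mm"})
        tx = random_seq(rng, 300, 0.5) + site + random_seq(rng, 300, 0.5)
        sites = find_candidate_sites(srna, tx, max_equiv=21.0)
        got = min(allen_score(s) for s in sites)
        assert got == pytest.approx(brute_force_best(srna, tx))


class TestTriggers:
    def _phas(self, start=2000, period=21, cycles=10):
        return PhasLocus(
            "PHAS21-1", "chr1", start, start + cycles * period, period,
            start % period, 1e-9, 40.0, 0.9, period,
        )

    def _mir(self, mature):
        from phasnet.mirna import MirLocus

        return MirLocus("miR1", "chr1", "+", 100, 200, mature, 100,
                        "T" * 21, 160, "miR1", False, 0.9)

    def _genome_with_site(self, rng, mature, cleavage, changes=None, length=6000):
        """Plant the trigger's complementary site so cleavage falls at
        ``cleavage`` (site spans [cleavage-11, cleavage+10) for 21-mers)."""
        g = list(random_seq(rng, length, 0.5))
        site = _site_with(mature, changes or {})
        start = cleavage - (len(mature) - 10)
        g[start : start + len(site)] = list(site)
        return {"chr1": "".join(g)}

    def test_planted_trigger_recovered_in_register(self, rng):
        mature = random_seq(rng, 21, 0.5)
        phas = self._phas(start=2100)
        genome = self._genome_with_site(rng, mature, cleavage=2100)
        out = identify_triggers([self._mir(mature)], [phas], genome)
        assert len(out) == 1
        t = out[0]
        assert t.penalty == 0.0
        assert t.cleavage == 2100
        assert t.in_register

    def test_penalty_five_reported_six_not(self, rng):
        mature = "TGGAGCTCCCTTCAATCCAAA"
        phas = self._phas(start=2100)
        # five mismatch-points outside the core: positions 14-18 at weight 1
        changes5 = {14: "mm", 15: "mm", 16: "mm", 17: "mm", 18: "mm"}
        genome5 = self._genome_with_site(rng, mature, 2100, changes5)
        out5 = identify_triggers([self._mir(mature)], [phas], genome5)
        assert len(out5) == 1 and out5[0].penalty == pytest.approx(5.0)
        changes6 = {**changes5, 19: "mm"}
        genome6 = self._genome_with_site(rng, mature, 2100, changes6)
        out6 = identify_triggers([self._mir(mature)], [phas], genome6)
        assert out6 == []

    def test_out_of_register_site_flagged(self, rng):
        mature = random_seq(rng, 21, 0.5)
        phas = self._phas(start=2100)
        genome = self._genome_with_site(rng, mature, cleavage=2100 + 5)
        out = identify_triggers([self._mir(mature)], [phas], genome)
        assert len(out) == 1
        assert not out[0].in_register

    def test_no_site_no_assignment(self, rng):
        mature = random_seq(rng, 21, 0.5)
        genome = {"chr1": random_seq(rng, 6000, 0.5)}
        assert identify_triggers([self._mir(mature)], [self._phas()], genome) == []
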