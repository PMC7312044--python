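"""Fragmentation, step-function rejoining, and aberration scoring."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ionrbe.aberration import (
    AberrationTally,
    RejoiningParameters,
    _match_ends,
    assemble_and_score,
    cell_fate,
    fragment,
    rejoin,
)
from ionrbe.damage import CriticalLesion
from ionrbe.errors import ConfigurationError, IonRbeError

# fragment()/rejoin() need only the per-copy length/centromere arrays of a
# territory configuration, so a light stand-in keeps these tests exact
TWO_CHROM = SimpleNamespace(
    copy_length_mbp=np.array([100.0, 80.0]),
    copy_centromere_mbp=np.array([40.0, 30.0]),
)


def cl(copy, genomic, pos=(0.0, 0.0, 0.0)):
    arm = "p" if genomic < TWO_CHROM.copy_centromere_mbp[copy] else "q"
    return CriticalLesion(tuple(map(float, pos)), copy, arm, float(genomic))


class TestFragment:
    def test_no_cls_one_endless_fragment_per_copy(self):
        frags = fragment([], TWO_CHROM)
        assert len(frags) == 2
        assert all(f.end_ids == () for f in frags)
        assert all(f.centric for f in frags)

    def test_single_cl_two_fragments_one_centric(self):
        frags = fragment([cl(0, 60.0)], TWO_CHROM)
        hit = [f for f in frags if f.copy == 0]
        assert len(hit) == 2
        assert sorted((f.lo_mbp, f.hi_mbp) for f in hit) == [(0.0, 60.0), (60.0, 100.0)]
        assert sum(f.centric for f in hit) == 1
        assert all(len(f.end_ids) == 1 for f in hit)

    def test_five_cls_match_sort_and_split_oracle(self, rng):
        g = np.sort(rng.uniform(1, 99, size=5))
        shuffled = rng.permutation(g)
        frags = [f for f in fragment([cl(0, x) for x in shuffled], TWO_CHROM) if f.copy == 0]
        # independent oracle: sort genomic cuts, split intervals
        cuts = np.concatenate([[0.0], np.sort(g), [100.0]])
        expect = list(zip(cuts[:-1], cuts[1:]))
        got = sorted((f.lo_mbp, f.hi_mbp) for f in frags)
        assert np.allclose(got, expect)
        assert sum(f.centric for f in frags) == 1
        # interior fragments have 2 free ends, terminal ones have 1
        by_lo = sorted(frags, key=lambda f: f.lo_mbp)
        assert [len(f.end_ids) for f in by_lo] == [1, 2, 2, 2, 2, 1]

    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.floats(0.5, 99.0)),
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_properties(self, hits):
        hits = [(c, g if c == 0 else min(g, 79.5)) for c, g in hits]
        cls_ = [cl(c, g) for c, g in hits]
        frags = fragment(cls_, TWO_CHROM)
        # genomic conservation per copy (exact up to float summation)
        for copy in (0, 1):
            tot = sum(f.length_mbp for f in frags if f.copy == copy)
            assert tot == pytest.approx(TWO_CHROM.copy_length_mbp[copy], abs=1e-9)
        # end conservation: every CL creates exactly two free ends
        n_ends = sum(len(f.end_ids) for f in frags)
        assert n_ends == 2 * len(cls_)
        # exactly one centric fragment per copy
        for copy in (0, 1):
            assert sum(f.centric for f in frags if f.copy == copy) == 1


class TestRejoin:
    def test_f_one_no_junctions(self, rng):
        frags = fragment([cl(0, 60.0), cl(1, 50.0)], TWO_CHROM)
        out = rejoin(frags, RejoiningParameters(threshold_um=5.0, f=1.0), rng)
        assert out == []

    def test_step_function_blocks_distant_ends(self, rng):
        # two free ends 10 um apart with threshold 5 um never join
        frags = fragment(
            [cl(0, 60.0, pos=(0, 0, 0)), cl(1, 50.0, pos=(10.0, 0, 0))], TWO_CHROM
        )
        for _ in range(200):
            out = rejoin(frags, RejoiningParameters(threshold_um=5.0, f=0.0), rng)
            # each CL's own two ends are co-located and must rejoin
            # (restitution), but no cross-CL junction can form
            assert len(out) == 2
            for a, b in out:
                assert abs(a - b) == 1 and min(a, b) % 2 == 0

    def test_matching_distribution_uniform_over_perfect_matchings(self, rng):
        # 2 CLs, 4 mutually close ends, f=0: the 3 perfect matchings are
        # equally likely under the random maximal matching
        pos = np.zeros((4, 3))
        counts = {}
        n = 100_000
        for _ in range(n):
            js = _match_ends(pos, 1.0, 0.0, rng)
            key = frozenset(frozenset(p) for p in js)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for v in counts.values():
            assert abs(v / n - 1 / 3) <= 3 * se

    def test_maximal_matching_leaves_no_open_pairs(self, rng):
        # f=0 and all ends mutually within threshold: even end count => all matched
        for k in (1, 2, 3, 5):
            pos = rng.uniform(0, 0.5, size=(2 * k, 3))
            js = _match_ends(pos, 10.0, 0.0, rng)
            assert len(js) == k


class TestAssembleAndScore:
    def test_no_cls_zero_tally(self):
        frags = fragment([], TWO_CHROM)
        tally = assemble_and_score(frags, [])
        assert (tally.dicentrics, tally.centric_rings, tally.large_deletions) == (0, 0, 0)
        assert not tally.lethal
        assert cell_fate(tally) == "survives"

    def test_canonical_centric_ring(self):
        # chromosome 0 (cen at 40) cut at 20 and 60; the centric middle piece
        # closes on itself -> 1 ring; both acentric outer pieces (20 and 40
        # Mbp) exceed the visibility threshold -> 2 large deletions
        frags = fragment([cl(0, 20.0), cl(0, 60.0)], TWO_CHROM)
        middle = next(f for f in frags if f.copy == 0 and len(f.end_ids) == 2)
        tally = assemble_and_score(frags, [tuple(middle.end_ids)])
        assert tally.centric_rings == 1
        assert tally.dicentrics == 0
        assert tally.large_deletions == 2
        assert tally.lethal

    def test_truth_table_two_one_break_chromosomes(self):
        # one CL on each chromosome; exhaustive pairings of the 4 free ends.
        # Chromosome 0: centric piece 0-60 (cen 40), acentric 60-100 (40 Mbp).
        # Chromosome 1: centric piece 0-50 (cen 30), acentric 50-80 (30 Mbp).
        frags = fragment([cl(0, 60.0), cl(1, 50.0)], TWO_CHROM)

        def end_of(copy, centric):
            f = next(x for x in frags if x.copy == copy and x.centric == centric and x.end_ids)
            return f.end_ids[0]

        cA, aA = end_of(0, True), end_of(0, False)
        cB, aB = end_of(1, True), end_of(1, False)

        cases = {
            # junctions -> (dicentrics, rings, large deletions)
            (): (0, 0, 2),  # both acentric terminal pieces unrejoined
            ((cA, aA), (cB, aB)): (0, 0, 0),  # double restitution
            ((cA, cB), (aA, aB)): (1, 0, 1),  # dicentric + acentric fusion
            ((cA, aB), (cB, aA)): (0, 0, 0),  # reciprocal translocation
            ((cA, cB),): (1, 0, 2),  # dicentric, both acentric pieces open
            ((aA, aB),): (0, 0, 1),  # acentric fusion only, centrics open
            ((cA, aB),): (0, 0, 1),  # one-way translocation, aA open
        }
        for junctions, expect in cases.items():
            t = assemble_and_score(frags, list(junctions))
            assert (t.dicentrics, t.centric_rings, t.large_deletions) == expect

    def test_visibility_threshold_spares_small_deletions(self):
        # interstitial acentric piece of 2 Mbp stays below the 3-Mbp scale
        frags = fragment([cl(0, 50.0), cl(0, 52.0)], TWO_CHROM)
        tally = assemble_and_score(frags, [])
        # the 48-Mbp terminal piece scores; the 2-Mbp sliver does not
        assert tally.large_deletions == 1
        tally = assemble_and_score(frags, [], visibility_threshold_mbp=60.0)
        assert tally.large_deletions == 0
        assert not tally.lethal

    def test_reused_end_rejected(self):
        frags = fragment([cl(0, 60.0), cl(1, 50.0)], TWO_CHROM)
        e = frags[0].end_ids[0] if frags[0].end_ids else frags[1].end_ids[0]
        with pytest.raises(IonRbeError):
            assemble_and_score(frags, [(e, e + 1), (e, e + 2)])

    def test_dicentric_means_death(self):
        t = AberrationTally(dicentrics=1)
        assert t.lethal and cell_fate(t) == "dies"


class TestRejoiningParameters:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            RejoiningParameters(threshold_um=-1.0)
        with pytest.raises(ConfigurationError):
            RejoiningParameters(f=1.5)
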