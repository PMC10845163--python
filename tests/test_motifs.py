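"""Motif canonicalization, census, enrichment and gluing."""

from itertools import combinations, permutations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclesym import (SignedNetwork, canonical_form, enumerate_motif_classes,
                      glue_network, motif_enrichment, scan_network)
from cyclesym.motifs import (MotifCensus, id_to_matrix, is_connected_motif,
                             matrix_to_id, scan_population)

trit_matrix = st.lists(st.sampled_from([-1, 0, 1]), min_size=9, max_size=9) \
    .map(lambda v: np.array(v).reshape(3, 3))


class TestCanonicalForm:
    def test_all_zero_is_its_own_class(self):
        assert canonical_form(np.zeros((3, 3), dtype=int)) == "0" * 9

    @given(M=trit_matrix, perm=st.sampled_from(list(permutations(range(3)))))
    @settings(max_examples=200, derandomize=True)
    def test_relabeling_invariance(self, M, perm):
        p = list(perm)
        relabeled = M[np.ix_(p, p)]
        assert canonical_form(M) == canonical_form(relabeled)

    @given(M=trit_matrix)
    @settings(max_examples=100, derandomize=True)
    def test_idempotence(self, M):
        cid = canonical_form(M)
        assert canonical_form(id_to_matrix(cid)) == cid

    def test_canonical_is_orbit_minimum(self, rng):
        # equal ids <=> permutation-equivalent, checked by explicit orbit
        # construction; minimum taken in trit order -1 < 0 < 1
        for _ in range(50):
            M = rng.integers(-1, 2, size=(3, 3))
            orbit = [tuple(M[np.ix_(list(p), list(p))].reshape(9))
                     for p in permutations(range(3))]
            assert (id_to_matrix(canonical_form(M)).reshape(9).tolist()
                    == list(min(orbit)))

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            canonical_form(np.full((3, 3), 2))
        with pytest.raises(ValueError):
            canonical_form(np.zeros((2, 2)))

    def test_id_string_roundtrip(self):
        M = np.array([[-1, 0, 1], [1, 1, 0], [0, -1, -1]])
        assert (id_to_matrix(matrix_to_id(M)) == M).all()


class TestEnumeration:
    def test_connectivity_convention(self):
        # a lone self-loop does not connect a node to the other two
        M = np.zeros((3, 3), dtype=int)
        M[2, 2] = 1
        M[0, 1] = 1
        assert not is_connected_motif(M)
        M[1, 2] = -1
        M[2, 0] = 1
        assert is_connected_motif(M)

    def test_every_class_id_is_canonical(self):
        classes = enumerate_motif_classes()
        sample = sorted(classes)[::137]
        assert all(canonical_form(id_to_matrix(c)) == c for c in sample)


class TestScan:
    def test_zero_network(self):
        census = scan_network(SignedNetwork(np.zeros((6, 6), dtype=int)))
        assert census.counts == {}
        assert census.triples_scanned == comb(6, 3)

    def test_single_motif_network(self):
        M = np.array([[0, 1, -1], [0, 0, 1], [1, 0, 0]])
        census = scan_network(SignedNetwork(M))
        assert census.counts == {canonical_form(M): 1}
        assert census.triples_scanned == 1

    def test_scan_counts_all_triples(self, rng):
        net = SignedNetwork(rng.integers(-1, 2, size=(7, 7)))
        census = scan_network(net)
        assert census.triples_scanned == comb(7, 3)
        assert sum(census.counts.values()) <= census.triples_scanned

    def test_population_counts_relabeling_invariant(self, rng):
        nets = [SignedNetwork(rng.integers(-1, 2, size=(6, 6)))
                for _ in range(10)]
        relabeled = [net.relabel(rng.permutation(6)) for net in nets]
        assert scan_population(nets).counts == scan_population(relabeled).counts

    def test_small_network_rejected(self):
        with pytest.raises(ValueError):
            scan_network(SignedNetwork(np.zeros((2, 2), dtype=int)))


class TestEnrichment:
    def test_identical_populations_nothing_suppressed(self, rng):
        nets = [SignedNetwork(rng.integers(-1, 2, size=(6, 6)))
                for _ in range(50)]
        census = scan_population(nets)
        report, suppressed = motif_enrichment(census, census,
                                              ratio_threshold=0.99,
                                              min_support=1)
        assert suppressed == set()
        assert (report["ratio"] == 1.0).all()

    def test_absent_motif_is_suppressed(self):
        base = MotifCensus(counts={"0" * 8 + "+": 100, "0" * 8 + "-": 100},
                           triples_scanned=1000)
        target = MotifCensus(counts={"0" * 8 + "+": 120}, triples_scanned=1000)
        _, suppressed = motif_enrichment(target, base, ratio_threshold=0.05,
                                         min_support=50)
        assert suppressed == {"0" * 8 + "-"}

    def test_min_support_filters(self):
        base = MotifCensus(counts={"0" * 8 + "+": 10}, triples_scanned=100)
        target = MotifCensus(counts={}, triples_scanned=100)
        report, suppressed = motif_enrichment(target, base, min_support=50)
        assert report.empty and suppressed == set()

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment(MotifCensus(), MotifCensus())


class TestGlue:
    def test_zero_motif_never_reaches_density(self, rng):
        res = glue_network(5, {"0" * 9}, 0.3, rng, stamp_budget=20)
        assert not res.reached_density
        assert res.network.edge_count == 0
        assert res.stamps == 20

    def test_single_dense_motif_one_stamp(self, rng):
        dense = canonical_form(np.array([[1, -1, 1], [1, 1, -1], [-1, 1, 1]]))
        res = glue_network(3, {dense}, 1.0, rng)
        assert res.stamps == 1 and res.reached_density
        assert canonical_form(res.network.W) == dense

    def test_density_target_respected(self, rng):
        ids = {canonical_form(np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]]))}
        res = glue_network(8, ids, 0.2, rng)
        assert res.reached_density
        assert res.network.density >= 0.2

    def test_invalid_arguments(self, rng):
        with pytest.raises(ValueError):
            glue_network(2, {"0" * 9}, 0.5, rng)
        with pytest.raises(ValueError):
            glue_network(5, set(), 0.5, rng)
        with pytest.raises(ValueError):
            glue_network(5, {"0" * 9}, 1.5, rng)
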