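"""Association matrices, centrality and correlation screens."""

import itertools

import numpy as np
import pandas as pd
import pytest

from socdiff import (
    AssociationMatrix,
    ScanRecord,
    betweenness,
    directed_count_matrix,
    spearman_screen,
    sri_matrix,
    strength,
    symmetrize,
)
from socdiff.networks import NetworkError, scan_occasions
from socdiff.records import InteractionRecord


def _scan(sid, focal, assoc, rule="ten_m", troop="T", ts=0):
    return ScanRecord(sid, troop, ts, rule, focal, tuple(assoc))


def brute_force_sri(scans, a, b):
    """Independent SRI oracle: count occasions dyad-by-dyad."""
    x = y_ab = y_a = y_b = 0
    for occ in scan_occasions(scans):
        groups = [set(g) for g in occ]
        obs = set().union(*groups)
        in_a, in_b = a in obs, b in obs
        if in_a and in_b:
            if any(a in g and b in g for g in groups):
                x += 1
            else:
                y_ab += 1
        elif in_a:
            y_a += 1
        elif in_b:
            y_b += 1
    denom = x + y_ab + y_a + y_b
    return x / denom if denom else 0.0


class TestSRI:
    def test_direct_formula(self):
        # A,B together in 3 scans; apart-both-seen 1; A-only 2; B-only 2
        scans = (
            [_scan(f"tog{i}", "A", ["B"]) for i in range(3)]
            + [_scan("apart", "A", ["C"]), _scan("apart", "B", ["D"])]
            + [_scan(f"a{i}", "A", []) for i in range(2)]
            + [_scan(f"b{i}", "B", []) for i in range(2)]
        )
        m = sri_matrix(scans, "ten_m")
        assert m.weights[m.index_of("A"), m.index_of("B")] == pytest.approx(3 / 8)

    def test_always_together_is_one_never_is_zero(self):
        scans = [_scan(f"s{i}", "A", ["B"]) for i in range(5)]
        m = sri_matrix(scans, "ten_m")
        assert m.weights[m.index_of("A"), m.index_of("B")] == 1.0
        apart = [_scan(f"s{i}", "A", []) for i in range(3)] + [
            _scan(f"u{i}", "B", []) for i in range(3)
        ]
        m2 = sri_matrix(apart, "ten_m")
        assert m2.weights[m2.index_of("A"), m2.index_of("B")] == 0.0

    def test_never_observed_individual_is_an_error(self):
        scans = [_scan("s1", "A", ["B"])]
        with pytest.raises(NetworkError, match="C"):
            sri_matrix(scans, "ten_m", ids=["A", "B", "C"])

    def test_chain_groups_merge_within_scan_only(self):
        # two records of one occasion share member B -> one merged group
        scans = [
            _scan("occ1", "A", ["B"], rule="five_m_chain"),
            _scan("occ1", "B", ["C"], rule="five_m_chain"),
            _scan("occ2", "A", [], rule="five_m_chain"),
            _scan("occ2", "C", [], rule="five_m_chain"),
        ]
        m = sri_matrix(scans, "five_m_chain")
        a, c = m.index_of("A"), m.index_of("C")
        # occ1: A,C co-grouped via the chain; occ2: both seen apart
        assert m.weights[a, c] == pytest.approx(1 / 2)

    def test_grouping_invariant_to_listing_order(self):
        fwd = [
            _scan("occ", "A", ["B"], rule="five_m_chain"),
            _scan("occ", "B", ["C"], rule="five_m_chain"),
        ]
        rev = list(reversed(fwd))
        m1 = sri_matrix(fwd, "five_m_chain", ids=["A", "B", "C"])
        m2 = sri_matrix(rev, "five_m_chain", ids=["A", "B", "C"])
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_matches_brute_force_on_random_scan_sets(self, rng):
        ids = list("ABCDEF")
        for rep in range(20):
            scans = []
            for k in range(rng.integers(4, 15)):
                present = [i for i in ids if rng.random() < 0.7]
                rng.shuffle(present)
                # split the present individuals into 1-3 groups
                groups = np.array_split(present, rng.integers(1, 4))
                for gi, g in enumerate(groups):
                    if len(g):
                        scans.append(_scan(f"occ{k}", g[0], g[1:]))
            observed = sorted({i for s in scans for i in s.group})
            if len(observed) < 2:
                continue
            m = sri_matrix(scans, "ten_m", ids=observed)
            assert np.all(m.weights >= 0) and np.all(m.weights <= 1)
            for a, b in itertools.combinations(observed, 2):
                expected = brute_force_sri(scans, a, b)
                assert m.weights[m.index_of(a), m.index_of(b)] == pytest.approx(expected)


class TestCountMatrices:
    def test_groom_counts_directional(self):
        inter = [
            InteractionRecord("e1", "T", 1, "groom", "A", "B"),
            InteractionRecord("e2", "T", 2, "groom", "A", "B"),
            InteractionRecord("e3", "T", 3, "groom", "B", "A"),
        ]
        m = directed_count_matrix(inter, "groom_directed")
        a, b = m.index_of("A"), m.index_of("B")
        assert m.weights[a, b] == 2 and m.weights[b, a] == 1

    def test_nn_scan_one_directed_count(self):
        scans = [_scan("s1", "A", ["B"], rule="nearest_neighbour")]
        m = directed_count_matrix(scans, "nn_directed")
        a, b = m.index_of("A"), m.index_of("B")
        assert m.weights[a, b] == 1 and m.weights[b, a] == 0

    def test_symmetrize_sums_and_is_noop_on_undirected(self):
        inter = [
            InteractionRecord("e1", "T", 1, "groom", "A", "B"),
            InteractionRecord("e2", "T", 2, "groom", "A", "B"),
            InteractionRecord("e3", "T", 3, "groom", "B", "A"),
        ]
        m = directed_count_matrix(inter, "groom_directed")
        u = symmetrize(m)
        a, b = u.index_of("A"), u.index_of("B")
        assert u.weights[a, b] == u.weights[b, a] == 3
        assert not u.directed
        with pytest.warns(UserWarning, match="already undirected"):
            again = symmetrize(u)
        np.testing.assert_array_equal(again.weights, u.weights)

    def test_strength_preserved_by_symmetrization(self, small_study):
        m = small_study.networks["J"]["groom_directed"]
        pd.testing.assert_series_equal(
            strength(m), strength(symmetrize(m)), check_names=False
        )


class TestCentrality:
    def _mat(self, ids, w, directed=False):
        return AssociationMatrix("T", "ten_m" if not directed else "groom_directed",
                                 tuple(ids), np.asarray(w, float), directed)

    def test_strength_sums_edges(self):
        m = self._mat("ABC", [[0, 0.5, 0.25], [0.5, 0, 0], [0.25, 0, 0]])
        s = strength(m)
        assert s["A"] == pytest.approx(0.75)
        assert s["C"] == pytest.approx(0.25)

    def test_directed_strength_in_plus_out(self):
        m = self._mat("ABC", [[0, 2, 0], [1, 0, 0], [0, 0, 0]], directed=True)
        s = strength(m)
        assert s["A"] == 3 and s["B"] == 3 and s["C"] == 0

    def test_isolated_node_zero(self):
        m = self._mat("AB", [[0, 0], [0, 0]])
        assert strength(m)["A"] == 0
        assert betweenness(m)["A"] == 0

    def test_betweenness_path_and_triangle(self):
        path = self._mat("ABC", [[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        b = betweenness(path)
        assert b["B"] == 1 and b["A"] == 0 and b["C"] == 0
        tri = self._mat("ABC", [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        assert betweenness(tri).sum() == 0

    def test_betweenness_star_center(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        m = self._mat("SABC", w)
        b = betweenness(m)
        assert b["S"] == 3  # the three leaf pairs route through the hub

    def test_strong_edges_are_short_paths(self):
        # A-B strong, B-C strong, A-C weak: A->C routes through B
        m = self._mat("ABC", [[0, 1.0, 0.1], [1.0, 0, 1.0], [0.1, 1.0, 0]])
        assert betweenness(m)["B"] == 1

    def test_permuting_ids_permutes_centralities(self, rng):
        n = 6
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        ids = list("ABCDEF")
        m = self._mat(ids, w)
        perm = rng.permutation(n)
        m2 = self._mat([ids[i] for i in perm], w[np.ix_(perm, perm)])
        for ind in ids:
            assert strength(m)[ind] == pytest.approx(strength(m2)[ind])
            assert betweenness(m)[ind] == pytest.approx(betweenness(m2)[ind])


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "up": [2, 4, 6, 8, 10],
                           "down": [5, 4, 3, 2, 1]})
        out = spearman_screen(df).set_index(["var_a", "var_b"])
        assert out.loc[("x", "up"), "rho"] == pytest.approx(1.0)
        assert out.loc[("x", "down"), "rho"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks (1,2,3,4) vs (2,1,4,3): sum d^2 = 4, rho = 1 - 6*4/(4*15) = 0.6
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3]})
        out = spearman_screen(df)
        assert out.loc[0, "S"] == 4
        assert out.loc[0, "rho"] == pytest.approx(0.6)

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "c": [7, 7, 7, 7]})
        out = spearman_screen(df)
        assert np.isnan(out.loc[0, "rho"]) and np.isnan(out.loc[0, "p"])

    def test_requires_four_observations(self):
        with pytest.raises(ValueError, match=">= 4"):
            spearman_screen(pd.DataFrame({"x": [1, 2, 3], "y": [1, 2, 3]}))
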