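import pytest
from hypothesis import given, settings, strategies as st

from phyloregime.mk import mk_loglik
from phyloregime.painting import RegimePainting, uniform_painting
from phyloregime.simulate import random_binary_tree
from phyloregime.tree import (
    graft_tips_as_polytomy,
    make_ultrametric,
    read_newick,
    resolve_polytomies,
    root_to_tip_segments,
    write_newick,
)


class TestNewickIO:
    def test_basic_read(self):
        t = read_newick("(A:1.0,B:2.0);")
        assert t.n_tips == 2
        assert len(t.nodes[t.root].children) == 2
        d = t.depths()
        assert d[t.tip_id("A")] == 1.0 and d[t.tip_id("B")] == 2.0

    def test_polytomy_preserved(self):
        t = read_newick("(A:1,B:1,C:1);")
        assert len(t.nodes[t.root].children) == 3

    @pytest.mark.parametrize(
        "newick",
        [
            "(A:1.0,B:2.0);",
            "(A:1,B:1,C:1);",
            "((A:0.5,B:0.5)ab:0.5,C:1.0)r;",
            "('sp one':1e-3,'sp two':2.5e2);",
            "((A:0.1,B:0.2):0.0,(C:0.3,D:0.4):0.7);",
        ],
    )
    def test_round_trip(self, newick):
        t1 = read_newick(newick)
        t2 = read_newick(write_newick(t1))
        assert sorted(t1.tip_labels()) == sorted(t2.tip_labels())
        for a in t1.tip_labels():
            for b in t1.tip_labels():
                if a < b:
                    assert t1.patristic_distance(a, b) == pytest.approx(
                        t2.patristic_distance(a, b), abs=1e-12
                    )

    def test_missing_length_warns(self):
        with pytest.warns(UserWarning, match="missing"):
            t = read_newick("(A:1,B);")
        assert t.depths()[t.tip_id("B")] == 0.0

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_newick("(A:1,A:2);")

    def test_parse_error(self):
        with pytest.raises(ValueError, match="parse"):
            read_newick("(A:1,B:2;")


class TestGraft:
    def test_graft_strains(self):
        t = read_newick("(A:1.0,B:2.0);")
        g = graft_tips_as_polytomy(t, "B", ["B1", "B2"], length=0.0)
        assert sorted(g.tip_labels()) == ["A", "B", "B1", "B2"]
        parents = {g.nodes[g.tip_id(x)].parent for x in ("B", "B1", "B2")}
        assert len(parents) == 1
        hub = g.nodes[parents.pop()]
        assert len(hub.children) == 3

    def test_zero_length_graft_preserves_distances(self):
        t = random_binary_tree(6, seed=3)
        g = graft_tips_as_polytomy(t, "t1", ["s1", "s2"], length=0.0)
        for a in t.tip_labels():
            for b in t.tip_labels():
                if a < b:
                    assert g.patristic_distance(a, b) == pytest.approx(
                        t.patristic_distance(a, b), abs=0
                    )

    def test_graft_missing_data_keeps_mk_likelihood(self):
        # grafted strains with unobserved states marginalize out of the
        # pruning likelihood entirely
        t = read_newick("((A:0.4,B:0.6):0.5,(C:0.7,D:0.3):0.4);")
        states = {"A": 0, "B": 1, "C": 0, "D": 0}
        base = mk_loglik(t, states, 0.7, 0.4)
        g = graft_tips_as_polytomy(t, "D", ["D1", "D2"], length=0.2)
        grafted = mk_loglik(g, {**states, "D1": None, "D2": None}, 0.7, 0.4)
        assert grafted == pytest.approx(base, abs=1e-12)

    def test_errors(self):
        t = read_newick("(A:1.0,B:2.0);")
        with pytest.raises(KeyError):
            graft_tips_as_polytomy(t, "Z", ["x"])
        with pytest.raises(ValueError, match="duplicate"):
            graft_tips_as_polytomy(t, "B", ["A"])


class TestResolveAndUltrametric:
    def test_resolve_star(self):
        t = resolve_polytomies(read_newick("(A:1,B:1,C:1);"))
        assert t.is_binary()
        inserted = [n for n in t.nodes if n.label is None and n.parent is not None]
        assert len(inserted) == 1 and inserted[0].length == 0.0

    def test_resolve_identity_on_binary(self):
        s = "((A:0.5,B:0.5):0.5,C:1.0);"
        assert write_newick(resolve_polytomies(read_newick(s))) == write_newick(
            read_newick(s)
        )

    def test_resolution_preserves_distances(self):
        t = read_newick("(A:1,B:2,C:3,D:4,E:1.5);")
        r = resolve_polytomies(t)
        for a in t.tip_labels():
            for b in t.tip_labels():
                if a < b:
                    assert r.patristic_distance(a, b) == t.patristic_distance(a, b)

    def test_resolution_keeps_reml_sigma2(self):
        from phyloregime.ancestral import bm_sigma2_reml
        from phyloregime.traits import TraitTable

        star = read_newick("(A:1,B:1,C:1);")
        trait = TraitTable("x", {"A": 0.0, "B": 1.0, "C": 5.0})
        s_before, _ = bm_sigma2_reml(star, trait)
        s_after, _ = bm_sigma2_reml(resolve_polytomies(star), trait)
        assert s_after == pytest.approx(s_before, rel=1e-12)

    def test_extend_to_max_depth(self):
        u = make_ultrametric(read_newick("(A:1,B:2);"))
        assert u.height() == 2.0
        assert u.depths()[u.tip_id("A")] == 2.0
        assert u.is_ultrametric(1e-9)

    def test_ultrametric_identity(self):
        s = "((A:0.5,B:0.5):0.5,C:1.0);"
        assert write_newick(make_ultrametric(read_newick(s))) == write_newick(
            read_newick(s)
        )

    def test_ultrametric_rejects_polytomy(self):
        with pytest.raises(ValueError, match="binary"):
            make_ultrametric(read_newick("(A:1,B:1,C:1);"))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_extend_never_shortens(self, seed):
        t = random_binary_tree(6, seed)
        u = make_ultrametric(t)
        for n, m in zip(t.nodes, u.nodes):
            if n.children:
                assert m.length == n.length  # internal branches untouched
            else:
                assert m.length >= n.length


class TestPathSegments:
    def test_two_tip_uniform(self, two_tip_tree):
        p = uniform_painting(two_tip_tree, 0)
        segs = root_to_tip_segments(two_tip_tree, p, "A")
        assert len(segs) == 1
        assert segs[0].length == 1.0 and segs[0].state == 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_segment_lengths_sum_to_depth(self, seed):
        t = random_binary_tree(7, seed)
        p = uniform_painting(t, 1)
        d = t.depths()
        for tip in t.tip_labels():
            segs = root_to_tip_segments(t, p, tip)
            assert sum(s.length for s in segs) == pytest.approx(
                d[t.tip_id(tip)], abs=1e-12
            )
            for a, b in zip(segs, segs[1:]):
                assert a.end == b.start

    def test_regime_switch_splits_path(self):
        t = read_newick("((A:1.0,B:1.0):1.0,C:2.0);")
        states = {
            n.id: (1 if n.id in (t.tip_id("A"), t.tip_id("B")) else 0)
            for n in t.nodes
            if n.parent is not None
        }
        p = RegimePainting(states, 0)
        segs = root_to_tip_segments(t, p, "A")
        assert [s.state for s in segs] == [0, 1]

    def test_unpainted_branch_raises(self, two_tip_tree):
        p = RegimePainting({two_tip_tree.tip_id("A"): 0}, 0)
        with pytest.raises(KeyError):
            root_to_tip_segments(two_tip_tree, p, "B")
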