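"""Geometry, overlap metrics, roles and silhouette-algebra enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from replaykit import stimuli as st
from replaykit.stimuli import (
    BlockShape,
    CompositionError,
    InsufficientStimuli,
    Relation,
    RoleError,
    assign_roles,
    compose,
    conjunctions,
    conjunctive_overlap,
    enumerate_algebra_triplets,
    overlap_metrics,
)


def bar_h(bid, n=2):
    return BlockShape(bid, frozenset((0, c) for c in range(n)))


def bar_v(bid, n=2):
    return BlockShape(bid, frozenset((r, 0) for r in range(n)))


class TestCompose:
    def test_on_top_stacks_and_records_edge(self):
        s = compose(bar_h("W"), bar_v("Z"), Relation.ON_TOP)
        assert len(s.occupancy) == 4
        assert s.edges == (("W", Relation.ON_TOP, "Z"),)
        # W's cells sit in strictly smaller rows than Z's (rows grow downward)
        assert max(r for r, _ in s.block_cells("W")) < min(
            r for r, _ in s.block_cells("Z"))

    def test_same_block_twice_rejected(self):
        a = bar_h("A")
        with pytest.raises(CompositionError):
            compose(a, a, Relation.ON_TOP)

    def test_no_contact_rejected(self):
        with pytest.raises(CompositionError):
            compose(bar_h("A"), bar_h("B"), Relation.ON_TOP, contact_offset=10)

    def test_target_reference_share_blocks_but_not_edges(self, blocks):
        W, _, _, Z = blocks
        wz = compose(W, Z, Relation.ON_TOP)
        zw = compose(Z, W, Relation.ON_TOP)
        assert wz.block_ids == zw.block_ids
        assert wz.edges != zw.edges
        assert conjunctive_overlap(wz, zw) == 0

    def test_inverse_relation_same_geometry(self):
        a, b = bar_h("A"), bar_v("B")
        top = compose(a, b, Relation.ON_TOP)
        below = compose(b, a, Relation.BELOW)
        assert top.occupancy == below.occupancy

    @given(hs.sampled_from(list(Relation)))
    @settings(deadline=None)
    def test_relation_inverse_is_involution(self, r):
        assert r.inverse.inverse == r

    def test_normalisation_origin(self):
        s = compose(bar_h("A", 3), bar_h("B", 2), Relation.LEFT_OF)
        assert min(r for r, _ in s.occupancy) == 0
        assert min(c for _, c in s.occupancy) == 0

    def test_serialisation_roundtrip(self, stim12):
        for s in stim12.values():
            s2 = st.Silhouette.from_json(s.to_json())
            assert s2.occupancy == s.occupancy
            assert s2.edges == s.edges


def _brute_force_pixel_overlap(c1, c2):
    """Exhaustive translation loop (independent of the implementation)."""
    best = 0.0
    rs1 = [r for r, _ in c1]
    cs1 = [c for _, c in c1]
    rs2 = [r for r, _ in c2]
    cs2 = [c for _, c in c2]
    for dr in range(min(rs1) - max(rs2) - 1, max(rs1) - min(rs2) + 2):
        for dc in range(min(cs1) - max(cs2) - 1, max(cs1) - min(cs2) + 2):
            shifted = {(r + dr, c + dc) for r, c in c2}
            inter = len(c1 & shifted)
            union = len(c1 | shifted)
            best = max(best, inter / union)
    return best


class TestOverlapMetrics:
    def test_identity(self, stim12):
        s = next(iter(stim12.values()))
        m = overlap_metrics(s, s)
        assert m["pixel_overlap"] == 1.0
        assert m["size_nonoverlap"] == 0.0
        assert m["block_overlap"] == 1.0
        assert m["relation_same"] == 1.0

    def test_disjoint_blocks_same_bbox(self):
        s1 = compose(bar_h("A"), bar_v("B"), Relation.ON_TOP)
        s2 = compose(bar_h("C"), bar_v("D"), Relation.ON_TOP)
        m = overlap_metrics(s1, s2)
        assert m["size_nonoverlap"] == 0.0
        assert m["block_overlap"] == 0.0

    def test_pixel_overlap_matches_brute_force(self, rng, pair_set, stim12):
        sils = list(pair_set.values()) + list(stim12.values())
        idx = rng.choice(len(sils), size=(10, 2))
        for i, j in idx:
            m = overlap_metrics(sils[i], sils[j])
            expected = _brute_force_pixel_overlap(sils[i].occupancy,
                                                  sils[j].occupancy)
            assert m["pixel_overlap"] == pytest.approx(expected)

    def test_symmetry_and_bounds(self, stim12):
        sils = list(stim12.values())
        for s1, s2 in itertools.combinations(sils[:6], 2):
            m12 = overlap_metrics(s1, s2)
            m21 = overlap_metrics(s2, s1)
            for k in m12:
                assert m12[k] == pytest.approx(m21[k])
            assert 0 <= m12["pixel_overlap"] <= 1
            assert 0 <= m12["block_overlap"] <= 1

    def test_size_combination_modes(self):
        s1 = compose(bar_h("A", 3), bar_v("B", 3), Relation.ON_TOP)
        s2 = compose(bar_h("C"), bar_v("D"), Relation.ON_TOP)
        dh = abs(s1.height - s2.height)
        dw = abs(s1.width - s2.width)
        assert overlap_metrics(s1, s2)["size_nonoverlap"] == dh + dw
        assert overlap_metrics(s1, s2, size_combine="max")["size_nonoverlap"] \
            == max(dh, dw)

    def test_solution_weighted_block_overlap(self, pair_set):
        s1, s2 = pair_set["WX"], pair_set["YZ"]
        # two alternative decompositions of s1, one sharing a block with s2
        v = st.block_overlap(
            s1, s2, decompositions={1: [frozenset({"W", "X"}),
                                        frozenset({"Y", "Q"})]})
        assert v == pytest.approx(0.5 * (0 + 1 / 3))


class TestConjunctions:
    def test_self_overlap_counts_blocks(self, stim12):
        for s in stim12.values():
            assert conjunctive_overlap(s, s) == 3

    def test_shared_stable_only(self, stim12):
        # two stable-middle towers with different present pairs share only
        # the stable block in the middle position
        a = stim12["X|W|Y"]
        b = stim12["X|W|Z"]
        shared = conjunctions(a) & conjunctions(b)
        # X on top appears in both as well as W in the middle
        assert ("W", ("bottom", "top")) in shared
        c = stim12["Y|W|Z"]
        assert conjunctions(a) & conjunctions(c) == {("W", ("bottom", "top"))}

    def test_full_matrix_matches_brute_force(self, stim12):
        sils = list(stim12.values())
        for s1 in sils:
            for s2 in sils:
                expected = len([c for c in conjunctions(s1)
                                if c in conjunctions(s2)])
                assert conjunctive_overlap(s1, s2) == expected


def _brute_force_triplets(pair_set):
    """Count valid (W, X, Y, Z) quadruples by direct cancellation check."""
    labels = sorted({b for s in pair_set.values() for b in s.block_ids})

    def signed_conj(pairs):
        counts = {}
        for sign, (top, bottom) in pairs:
            for conj in ((top, ("top",)), (bottom, ("bottom",))):
                counts[conj] = counts.get(conj, 0) + sign
        return {k: v for k, v in counts.items() if v}

    count = 0
    for w, x, y, z in itertools.permutations(labels, 4):
        if all(k in pair_set for k in (w + x, y + x, y + z)):
            lhs = signed_conj([(1, (w, x)), (-1, (y, x)), (1, (y, z))])
            if lhs == signed_conj([(1, (w, z))]):
                count += 1
    return count


class TestAlgebraTriplets:
    def test_canonical_triplet_structure(self, triplets):
        assert len(triplets) == 24  # all ordered quadruples of 4 blocks
        for t in triplets:
            assert t.cancels()
            assert t.target.block_ids == t.reference.block_ids
            assert conjunctive_overlap(t.target, t.reference) == 0

    def test_count_matches_brute_force(self, pair_set):
        trips = enumerate_algebra_triplets(list(pair_set.values()))
        assert len(trips) == _brute_force_triplets(pair_set)

    def test_order_invariance(self, pair_set):
        sils = list(pair_set.values())
        a = enumerate_algebra_triplets(sils)
        b = enumerate_algebra_triplets(sils[::-1])
        key = [tuple(sorted(t.target.block_ids)) for t in a]
        assert key == [tuple(sorted(t.target.block_ids)) for t in b]
        assert [t.target.edges for t in a] == [t.target.edges for t in b]

    def test_degenerate_repeated_block_excluded(self, triplets):
        for t in triplets:
            (w, x), (y, _), (_, z) = [
                (term.edges[0][0], term.edges[0][2]) for _, term in t.terms]
            assert len({w, x, y, z}) == 4

    def test_too_few_blocks_rejected(self):
        a, b = bar_h("A"), bar_v("B")
        with pytest.raises(InsufficientStimuli):
            enumerate_algebra_triplets([compose(a, b, Relation.ON_TOP)])


class TestRoles:
    def test_stable_middle(self, blocks, stim12):
        roles = assign_roles(stim12["X|W|Y"], blocks, "W")
        assert roles.present == {"X", "Y"}
        assert roles.absent == "Z"
        assert roles.distant_present is None
        assert roles.stable_middle

    def test_stable_at_end_has_distant_present(self, blocks, stim12):
        roles = assign_roles(stim12["W|X|Y"], blocks, "W")
        assert roles.present == {"X", "Y"}
        assert roles.distant_present == "Y"
        assert not roles.stable_middle

    def test_missing_stable_rejected(self, blocks, stim12):
        with pytest.raises(RoleError):
            assign_roles(stim12["X|W|Y"], blocks, "Z")

    def test_partition_invariant_enforced(self):
        with pytest.raises(RoleError):
            st.RoleAssignment(stable="W", present=frozenset({"W", "X"}),
                              absent="Z")


def test_brick_ordering_count():
    assert st.brick_ordering_count(4) == 24
    assert st.brick_ordering_count(10) == 3_628_800


def test_stimulus_index_frame(stim12):
    df = st.stimulus_index(stim12)
    assert len(df) == 12
    assert set(df.columns) == {"stim_id", "blocks", "relation", "height", "width"}
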