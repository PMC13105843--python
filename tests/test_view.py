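"""View state: collapse/expand, aggregation, painting, palette, legend."""

from __future__ import annotations

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

import phylostack as ps
from phylostack.view import (
    active_paints,
    next_color,
    released_colors,
    replay,
    resolve_color,
    state_from_dict,
    state_to_dict,
)

from conftest import random_abundance, random_collapse_set, random_tree


def frontier_oracle(h, collapsed):
    """Per-leaf ancestor scan + maximal collapsed nodes, in leaf_order order."""
    out, emitted = [], set()
    for leaf in h.leaf_order:
        hit = None
        for anc in reversed(h.ancestors(leaf)):  # outermost first
            if anc in collapsed:
                hit = anc
                break
        unit = hit if hit is not None else leaf
        if unit not in emitted:
            emitted.add(unit)
            out.append(unit)
    return out


class TestCollapseExpand:
    def test_collapse_merges_frontier(self, ktree):
        s = ps.collapse(ktree, ps.ViewState(), "P1")
        assert ps.effective_leaves(ktree, s) == ["P1", "O3"]

    def test_collapse_is_idempotent(self, ktree):
        s1 = ps.collapse(ktree, ps.ViewState(), "P1")
        s2 = ps.collapse(ktree, s1, "P1")
        assert s1 == s2

    def test_collapsing_a_leaf_is_noop(self, ktree):
        s = ps.collapse(ktree, ps.ViewState(), "O1")
        assert s == ps.ViewState()

    def test_collapse_unknown_node_raises(self, ktree):
        with pytest.raises(ps.UnknownNodeError):
            ps.collapse(ktree, ps.ViewState(), "nope")

    def test_expand_restores_previous_composition(self, ktree, kabundance):
        s0 = ps.paint(ktree, ps.ViewState(), "O1", 3)
        before = ps.aggregate(kabundance, ktree, s0)
        s1 = ps.expand(ktree, ps.collapse(ktree, s0, "P1"), "P1")
        after = ps.aggregate(kabundance, ktree, s1)
        assert before.effective_leaf_ids == after.effective_leaf_ids
        np.testing.assert_array_equal(before.values, after.values)
        assert active_paints(ktree, s0) == active_paints(ktree, s1)

    def test_nested_collapse_survives_outer_roundtrip(self, ktree):
        s = ps.collapse(ktree, ps.ViewState(), "P1")
        s = ps.collapse(ktree, s, ktree.root)
        assert ps.effective_leaves(ktree, s) == [ktree.root]
        s = ps.expand(ktree, s, ktree.root)
        assert ps.effective_leaves(ktree, s) == ["P1", "O3"]

    def test_expand_noncollapsed_is_noop(self, ktree):
        s = ps.expand(ktree, ps.ViewState(), "P1")
        assert s == ps.ViewState()


class TestEffectiveLeaves:
    def test_no_collapse_gives_leaf_order(self, ktree):
        assert ps.effective_leaves(ktree, ps.ViewState()) == ktree.leaf_order

    def test_collapsed_root_gives_root(self, ktree):
        s = ps.collapse(ktree, ps.ViewState(), ktree.root)
        assert ps.effective_leaves(ktree, s) == [ktree.root]

    @given(seed=st.integers(0, 500))
    def test_matches_ancestor_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_tree(rng, int(rng.integers(2, 40)))
        collapsed = random_collapse_set(rng, h)
        s = ps.ViewState(collapsed=collapsed)
        assert ps.effective_leaves(h, s) == frontier_oracle(h, collapsed)


class TestAggregate:
    def test_collapsed_column_sums_leaves(self, ktree, kabundance):
        s = ps.collapse(ktree, ps.ViewState(), "P1")
        e = ps.aggregate(kabundance, ktree, s)
        assert e.effective_leaf_ids == ["P1", "O3"]
        assert e.values.tolist() == [[5.0, 5.0], [5.0, 2.0]]

    def test_no_collapse_is_identity(self, ktree, kabundance):
        e = ps.aggregate(kabundance, ktree, ps.ViewState())
        np.testing.assert_array_equal(e.values, kabundance.values)

    def test_validation_failure_raises(self, ktree):
        bad = ps.AbundanceTable.from_arrays(["s1"], ["O1", "O2"], [[1.0, 2.0]])
        with pytest.raises(ps.ViewError, match="O3"):
            ps.aggregate(bad, ktree, ps.ViewState())

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_brute_force_sums(self, seed):
        rng = np.random.default_rng(seed)
        h = random_tree(rng, 10)
        a = random_abundance(rng, h, n_samples=4, integer=True)
        s = ps.ViewState(collapsed=random_collapse_set(rng, h))
        e = ps.aggregate(a, h, s)
        np.testing.assert_array_equal(e.sample_totals(), a.values.sum(axis=1))
        label_col = {lab: j for j, lab in enumerate(h.leaf_labels)}
        for j, nid in enumerate(e.effective_leaf_ids):
            cols = [label_col[h.label(l)] for l in h.leaves_under(nid)]
            np.testing.assert_array_equal(e.values[:, j], a.values[:, cols].sum(axis=1))


class TestPaint:
    def test_paint_root_colors_every_effective_leaf(self, ktree):
        s = ps.paint(ktree, ps.ViewState(), ktree.root)
        for leaf in ps.effective_leaves(ktree, s):
            assert resolve_color(ktree, s, leaf) == 0

    def test_nearest_painted_ancestor_wins(self, ktree):
        s = ps.paint(ktree, ps.ViewState(), "P1", 2)
        s = ps.paint(ktree, s, "O1", 4)
        assert resolve_color(ktree, s, "O1") == 4
        assert resolve_color(ktree, s, "O2") == 2
        assert resolve_color(ktree, s, "O3") is None

    def test_out_of_range_color_rejected(self, ktree):
        with pytest.raises(ps.ViewError, match="out of range"):
            ps.paint(ktree, ps.ViewState(), "P1", 9)

    def test_painting_hidden_node_names_collapsed_ancestor(self, ktree):
        s = ps.collapse(ktree, ps.ViewState(), "P1")
        with pytest.raises(ps.ViewError, match="P1"):
            ps.paint(ktree, s, "O1", 0)

    def test_repaint_replaces_color_in_place(self, ktree):
        s = ps.paint(ktree, ps.ViewState(), "P1", 0)
        s = ps.paint(ktree, s, "P2", 1)
        s = ps.paint(ktree, s, "P1", 3)
        assert [(e.node_id, e.color_index) for e in ps.legend(ktree, s)] == [
            ("P1", 3),
            ("P2", 1),
        ]

    @given(seed=st.integers(0, 300))
    def test_color_resolution_matches_per_leaf_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_tree(rng, int(rng.integers(2, 30)))
        s = ps.ViewState(collapsed=random_collapse_set(rng, h, p=0.2))
        visible = [n for n in h.preorder() if all(a not in s.collapsed for a in h.ancestors(n))]
        painted = [n for n in visible if rng.random() < 0.3]
        for n in painted:
            s = ps.paint(h, s, n, int(rng.integers(0, 6)))
        paint_map = dict(s.paint_log)
        for leaf in ps.effective_leaves(h, s):
            chain = [leaf, *h.ancestors(leaf)]
            expected = next((paint_map[n] for n in chain if n in paint_map), None)
            assert resolve_color(h, s, leaf) == expected


class TestPalette:
    def test_default_palette_has_six_colors(self):
        assert len(ps.Palette()) == 6
        assert len(ps.DEFAULT_PALETTE) == 6

    def test_seven_calls_cycle_back_to_zero(self, ktree):
        s = ps.ViewState()
        seq = []
        for _ in range(7):
            s, c = next_color(ktree, s)
            seq.append(c)
        assert seq == [0, 1, 2, 3, 4, 5, 0]

    def test_single_color_palette_repeats(self, ktree):
        s = ps.ViewState(palette=ps.Palette(colors=("#000000",)))
        s, c1 = next_color(ktree, s)
        s, c2 = next_color(ktree, s)
        assert (c1, c2) == (0, 0)

    def test_thirteen_calls_end_at_zero(self, ktree):
        s = ps.ViewState()
        for _ in range(13):
            s, c = next_color(ktree, s)
        assert c == 0

    @pytest.mark.parametrize("length", [1, 2, 6])
    def test_periodicity_equals_palette_length(self, ktree, length):
        s = ps.ViewState(palette=ps.Palette(colors=tuple(f"#{i:06x}" for i in range(length))))
        seq = []
        for _ in range(3 * length):
            s, c = next_color(ktree, s)
            seq.append(c)
        assert seq == [i % length for i in range(3 * length)]

    def test_collapse_releases_color_used_only_inside(self, ktree):
        s = ps.paint(ktree, ps.ViewState(), "O1")  # takes color 0
        s = ps.collapse(ktree, s, "P1")
        assert [c for _, c in active_paints(ktree, s)] == []
        assert released_colors(ktree, s) == [0]
        s2, c = next_color(ktree, s)
        assert c == 0  # freed color re-issued before the cursor advances

    def test_expand_restores_paint_with_original_color(self, ktree):
        s = ps.paint(ktree, ps.ViewState(), "O1")  # color 0
        s = ps.expand(ktree, ps.collapse(ktree, s, "P1"), "P1")
        assert active_paints(ktree, s) == [("O1", 0)]
        assert released_colors(ktree, s) == []


class TestLegend:
    def test_entries_in_paint_insertion_order(self, ktree):
        s = ps.paint(ktree, ps.ViewState(), "P1", 0)
        s = ps.paint(ktree, s, "P2", 1)
        assert [(e.label, e.color_index) for e in ps.legend(ktree, s)] == [
            ("P1", 0),
            ("P2", 1),
        ]

    def test_empty_without_paints(self, ktree):
        assert ps.legend(ktree, ps.ViewState()) == []

    def test_suspended_paint_leaves_legend(self, ktree):
        s = ps.paint(ktree, ps.ViewState(), "O2", 1)
        s = ps.collapse(ktree, s, "P1")
        assert ps.legend(ktree, s) == []


class TestReplayAndSerialization:
    def test_replay_reproduces_manual_state(self, ktree):
        events = [
            {"op": "paint", "node": "O1"},
            {"op": "collapse", "node": "P1"},
            {"op": "expand", "node": "P1"},
            {"op": "paint", "node": "P2", "color": 3},
        ]
        s = replay(ktree, events)
        assert active_paints(ktree, s) == [("O1", 0), ("P2", 3)]

    def test_json_round_trip(self, ktree):
        s = ps.paint(ktree, ps.ViewState(), "P1", 2)
        s = ps.collapse(ktree, s, "P2")
        blob = json.dumps(state_to_dict(s))
        assert state_from_dict(json.loads(blob)) == s

    def test_unknown_event_rejected(self, ktree):
        with pytest.raises(ps.ViewError):
            replay(ktree, [{"op": "wiggle"}])
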