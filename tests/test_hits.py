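import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from macrospot.design import make_design
from macrospot.errors import ChannelMismatchError
from macrospot.hits import (CloneScore, HitList, call_hits,
                            intersect_channels, score_clones)
from macrospot.quantify import FLAG_SATURATED, SpotQuant
from macrospot.registration import SpotRef


def _quant(br, bc, pos, z, flags=frozenset()):
    return SpotQuant(SpotRef(br, bc, pos, (0.0, 0.0)), raw=z, background=0.0,
                     spread=1.0, z=z, flags=frozenset(flags))


def _score(clone_id, z1, z2, z_min=3.0):
    reps = (z1, z2)
    usable = [z for z in reps if z is not None]
    return CloneScore(
        clone_id=clone_id, replicate_z=reps,
        combined=sum(usable) / len(usable) if usable else float("nan"),
        duplicate_consistent=all(z is not None and z >= z_min for z in reps))


class TestScoreClones:
    def test_combined_is_replicate_mean(self):
        design = make_design(1, 1)
        clone = design.clone_table[(1, 1, 1)]  # positions 1 and 8
        quants = [_quant(1, 1, 1, 5.0), _quant(1, 1, 8, 7.0)]
        scores = {s.clone_id: s for s in score_clones(quants, design)}
        assert scores[clone].combined == 6.0
        assert scores[clone].replicate_z == (5.0, 7.0)

    def test_flagged_replicate_counts_as_missing(self):
        design = make_design(1, 1)
        clone = design.clone_table[(1, 1, 1)]
        quants = [_quant(1, 1, 1, 9.0),
                  _quant(1, 1, 8, 9.0, flags={FLAG_SATURATED})]
        s = {x.clone_id: x for x in score_clones(quants, design)}[clone]
        assert s.replicate_z == (9.0, None)
        assert not s.duplicate_consistent
        assert s.combined == 9.0

    def test_single_detection_in_duplex_is_inconsistent(self):
        # one bright and one dim replicate: omitted despite high intensity
        design = make_design(1, 1)
        clone = design.clone_table[(1, 1, 1)]
        quants = [_quant(1, 1, 1, 8.0), _quant(1, 1, 8, 1.2)]
        s = {x.clone_id: x for x in score_clones(quants, design, 3.0)}[clone]
        assert not s.duplicate_consistent

    def test_absent_clone_has_nan_combined(self):
        design = make_design(1, 1)
        scores = score_clones([], design)
        assert len(scores) == 4
        assert all(math.isnan(s.combined) for s in scores)


class TestCallHits:
    def test_ranked_by_mean_z(self):
        scores = [_score("A", 5.0, 6.0), _score("B", 9.0, 9.0),
                  _score("C", 4.0, 3.5)]
        hits = call_hits(scores, 3.0, channel="dAb")
        assert hits.clone_ids() == ["B", "A", "C"]

    def test_all_below_threshold_empty(self):
        hits = call_hits([_score("A", 1.0, 2.0)], 3.0)
        assert len(hits) == 0

    def test_singleton_rule_dominates_magnitude(self):
        scores = [_score("bright-once", 8.0, 1.2),
                  _score("dim-twice", 4.0, 3.5)]
        hits = call_hits(scores, 3.0)
        assert hits.clone_ids() == ["dim-twice"]

    def test_no_duplicate_filter_keeps_single_detections(self):
        scores = [_score("bright-once", 8.0, 1.2)]
        hits = call_hits(scores, 3.0, require_duplicate=False)
        assert hits.clone_ids() == ["bright-once"]
        assert not hits.entries[0].duplicate_consistent

    def test_missing_replicates_never_hit(self):
        hits = call_hits([_score("lost", None, None)], 3.0)
        assert len(hits) == 0

    def test_ties_break_on_clone_id(self):
        scores = [_score("b", 5.0, 5.0), _score("a", 5.0, 5.0)]
        assert call_hits(scores, 3.0).clone_ids() == ["a", "b"]

    def test_nonpositive_z_min_rejected(self):
        with pytest.raises(ValueError):
            call_hits([], 0.0)


class TestIntersectChannels:
    def _hl(self, channel, **clones):
        entries = tuple(sorted((_score(c, z, z) for c, z in clones.items()),
                               key=lambda e: (-e.combined, e.clone_id)))
        return HitList(channel=channel, entries=entries, z_min=3.0)

    def test_dual_format_rule(self):
        common = intersect_channels(self._hl("dAb", g1=5.0, g2=6.0),
                                    self._hl("dAb-rFc", g2=4.0, g3=7.0))
        assert common.clone_ids() == ["g2"]
        assert common.entries[0].combined == 5.0  # mean of 6 and 4

    def test_identical_lists_rerank_by_cross_channel_mean(self):
        a = self._hl("dAb", g1=5.0, g2=9.0)
        b = self._hl("dAb-rFc", g1=8.0, g2=3.0)
        common = intersect_channels(a, b)
        assert set(common.clone_ids()) == {"g1", "g2"}
        assert common.clone_ids() == ["g1", "g2"]  # 6.5 > 6.0

    def test_disjoint_lists_empty(self):
        common = intersect_channels(self._hl("dAb", g1=5.0),
                                    self._hl("dAb-rFc", g2=5.0))
        assert len(common) == 0

    def test_same_channel_is_misuse(self):
        with pytest.raises(ChannelMismatchError):
            intersect_channels(self._hl("dAb", g1=5.0),
                               self._hl("dAb", g1=5.0))


@given(st.lists(st.tuples(st.integers(0, 30),
                          st.floats(0, 12, allow_nan=False),
                          st.floats(0, 12, allow_nan=False)),
                max_size=25, unique_by=lambda t: t[0]))
def test_raising_z_min_never_adds_a_hit(entries):
    scores = [_score(f"c{i}", z1, z2) for i, z1, z2 in entries]
    low = set(call_hits(scores, 2.0).clone_ids())
    high = set(call_hits(scores, 5.0).clone_ids())
    assert high <= low


@given(st.lists(st.tuples(st.integers(0, 30),
                          st.floats(3.5, 12, allow_nan=False)),
                max_size=20, unique_by=lambda t: t[0]),
       st.lists(st.tuples(st.integers(0, 30),
                          st.floats(3.5, 12, allow_nan=False)),
                max_size=20, unique_by=lambda t: t[0]))
def test_intersection_is_subset_of_each_channel(a_entries, b_entries):
    a = call_hits([_score(f"c{i}", z, z) for i, z in a_entries], 3.0,
                  channel="dAb")
    b = call_hits([_score(f"c{i}", z, z) for i, z in b_entries], 3.0,
                  channel="dAb-rFc")
    common = intersect_channels(a, b)
    assert len(common) <= min(len(a), len(b))
    assert set(common.clone_ids()) <= set(a.clone_ids())
    assert set(common.clone_ids()) <= set(b.clone_ids())
    # ordering is strict: combined descending, id ascending on ties
    keys = [(-e.combined, e.clone_id) for e in common.entries]
    assert keys == sorted(keys)
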