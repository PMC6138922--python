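"""Consolidation: overlap matching, version choice, de-replication, refine."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from binforge.core import BinSet, QualityMetrics
from binforge.quality import count_passing, make_gold_estimator
from binforge.refine import (
    CandidateBin,
    RefinementConfig,
    bin_overlap,
    choose_version,
    consolidate,
    dereplicate,
    match_best,
    refine,
)


def q(c, x):
    return QualityMetrics(completion=c, contamination=x, n50=1, total_length=1)


def cb(name, contigs, completion, contamination, source="s", order=0):
    return CandidateBin(name, frozenset(contigs), q(completion, contamination), source, order)


# --- bin_overlap -----------------------------------------------------------


def test_bin_overlap():
    lengths = {"c1": 100, "c2": 100, "c3": 300}
    assert bin_overlap({"c1", "c2"}, {"c1", "c2"}, lengths) == 1.0
    assert bin_overlap({"c1"}, {"c3"}, lengths) == 0.0
    assert bin_overlap({"c1", "c2"}, {"c2", "c3"}, lengths) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        bin_overlap(set(), {"c1"}, lengths)


# --- match_best ------------------------------------------------------------


def test_match_best_identity_and_disjoint():
    lengths = {f"c{i}": 100 for i in range(6)}
    x = [cb("A", ["c0", "c1"], 90, 0), cb("B", ["c2", "c3"], 80, 0)]
    pairs, ux, uy = match_best(x, x, lengths, 0.8)
    assert [(a.name, b.name) for a, b in pairs] == [("A", "A"), ("B", "B")]
    assert not ux and not uy
    y = [cb("C", ["c4", "c5"], 70, 0)]
    pairs, ux, uy = match_best(x, y, lengths, 0.8)
    assert not pairs and len(ux) == 2 and len(uy) == 1


def test_match_best_at_threshold():
    # variants sharing exactly 80% of the smaller bin's bp are matched
    # both variants hold 5 equal-length contigs and share exactly 4:
    # overlap = 400 / 500 = 0.8 of the smaller bin
    lengths = {f"c{i}": 100 for i in range(12)}
    lengths.update({f"x{j}": 100 for j in range(3)})
    lengths.update({f"y{j}": 100 for j in range(3)})
    x, y = [], []
    for j in range(3):
        base = [f"c{4 * j + i}" for i in range(4)]
        x.append(cb(f"X{j}", base + [f"x{j}"], 90, 0))
        y.append(cb(f"Y{j}", base + [f"y{j}"], 90, 0))
    pairs, ux, uy = match_best(x, y, lengths, 0.8)
    assert len(pairs) == 3
    pairs, _, _ = match_best(x, y, lengths, 0.81)
    assert len(pairs) == 0


# --- choose_version --------------------------------------------------------


def test_choose_version_rank_classes():
    config = RefinementConfig(min_completion=90, max_contamination=10)
    a = cb("a", ["c1"], 92, 8)  # passes, score 52
    b = cb("b", ["c2"], 60, 1)  # fails c=90, score 55
    assert choose_version([a, b], config) is a
    config50 = RefinementConfig(min_completion=50, max_contamination=10)
    assert choose_version([a, b], config50) is b


def test_choose_version_single_and_tie():
    config = RefinementConfig()
    a = cb("a", ["c1"], 80, 2, order=0)
    assert choose_version([a], config) is a
    twin = cb("twin", ["c9"], 80, 2, order=1)
    assert choose_version([twin, a], config) is a  # earlier set wins the tie


# --- consolidate -----------------------------------------------------------


def test_consolidate_single_and_disjoint():
    lengths = {"c1": 100, "c2": 100}
    config = RefinementConfig()
    a = [cb("A", ["c1"], 90, 2)]
    assert consolidate([a], config, lengths) == a
    b = [cb("B", ["c2"], 70, 0, order=1)]
    out = consolidate([a, b], config, lengths)
    assert {x.name for x in out} == {"A", "B"}


def test_consolidate_prefers_higher_scoring_variant():
    lengths = {"c1": 100, "c2": 100, "c3": 100}
    config = RefinementConfig()
    full = [cb("A", ["c1", "c2", "c3"], 90, 2, order=0)]  # score 80
    sub = [cb("A2", ["c1", "c2", "c3"], 70, 0, order=1)]  # pure subset, score 70
    out = consolidate([full, sub], config, lengths)
    assert [x.name for x in out] == ["A"]


# --- dereplicate -----------------------------------------------------------


def test_dereplicate_keeps_highest_scoring_owner():
    bins = {"hi": {"c1", "c2"}, "lo": {"c2", "c3"}}
    out = dereplicate(bins, {"hi": 80.0, "lo": 60.0})
    assert out == {"hi": frozenset({"c1", "c2"}), "lo": frozenset({"c3"})}
    # bin emptied by removal disappears
    out = dereplicate({"hi": {"c1"}, "lo": {"c1"}}, {"hi": 80.0, "lo": 60.0})
    assert out == {"hi": frozenset({"c1"})}


@given(
    st.dictionaries(
        st.sampled_from(["A", "B", "C"]),
        st.sets(st.sampled_from([f"c{i}" for i in range(8)]), min_size=1),
        min_size=1,
    ),
    st.tuples(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100)),
)
def test_dereplicate_idempotent_and_partition(bins, scores3):
    scores = dict(zip(["A", "B", "C"], scores3))
    once = dereplicate(bins, scores)
    # partition invariant
    seen = set()
    for mem in once.values():
        assert not (mem & seen)
        seen |= mem
    assert dereplicate(once, scores) == once


# --- refine pipeline -------------------------------------------------------


def test_refine_structural_seven_candidates(community, corrupted_binnings, marker_estimator):
    res = refine(corrupted_binnings, community.lengths, marker_estimator)
    assert len(res.candidate_sets) == 7
    assert len(res.candidate_reports) == 7
    hybrid_labels = [b.label for b in res.candidate_sets if b.provenance == "hybrid"]
    assert hybrid_labels == ["hyb12", "hyb13", "hyb23", "hyb123"]


def test_refine_two_sets_three_candidates(community, corrupted_binnings, marker_estimator):
    res = refine(corrupted_binnings[:2], community.lengths, marker_estimator)
    assert len(res.candidate_sets) == 3


def test_refine_arity_errors(community, corrupted_binnings, marker_estimator):
    with pytest.raises(ValueError):
        refine(corrupted_binnings[:1], community.lengths, marker_estimator)
    with pytest.raises(ValueError):
        refine(corrupted_binnings * 2, community.lengths, marker_estimator)


def test_refine_identical_inputs_is_idempotent(community, marker_estimator):
    """Three copies of one binning come back unchanged up to (c, x)."""
    from binforge.synth import corrupt_binning

    bs = corrupt_binning(community.gold, dropout=0.1, seed=9, label="b")
    config = RefinementConfig(min_completion=50, max_contamination=10)
    res = refine([bs, bs, bs], community.lengths, marker_estimator, config)
    passing = {
        name: mem
        for name, mem in bs.bins.items()
        if config.passes(marker_estimator(mem))
    }
    assert dict(res.final.bins) == passing


def test_refine_final_bins_meet_thresholds(community, corrupted_binnings, marker_estimator):
    config = RefinementConfig(min_completion=60, max_contamination=5)
    res = refine(corrupted_binnings, community.lengths, marker_estimator, config)
    for _, row in res.report.iterrows():
        assert row.completion >= 60 and row.contamination <= 5


def test_refine_dominates_inputs_on_gold_standard(community, corrupted_binnings, marker_estimator, gold_estimator):
    """The headline behaviour in miniature: the consolidated set has at
    least as many near-complete, low-contamination bins as any input."""
    res = refine(corrupted_binnings, community.lengths, marker_estimator)
    refined = count_passing(
        [gold_estimator(m) for m in res.final.bins.values()], 90, 5
    )
    for bs in corrupted_binnings:
        inp = count_passing([gold_estimator(m) for m in bs.bins.values()], 90, 5)
        assert refined >= inp


def test_refine_threshold_responsiveness(community, corrupted_binnings, marker_estimator):
    """Asking for completion >= 90 never yields fewer >= 90 bins."""
    lengths = community.lengths
    res50 = refine(corrupted_binnings, lengths, marker_estimator, RefinementConfig(50, 10))
    res90 = refine(corrupted_binnings, lengths, marker_estimator, RefinementConfig(90, 10))
    hi50 = (res50.report.completion >= 90).sum()
    hi90 = (res90.report.completion >= 90).sum()
    assert hi90 >= hi50


def test_refine_final_set_dominance(community, corrupted_binnings, marker_estimator):
    """Every final bin scores at least as high as any (c, x)-passing
    variant that substantially overlaps it in any candidate set."""
    config = RefinementConfig()
    res = refine(corrupted_binnings, community.lengths, marker_estimator, config)
    from binforge.quality import score as qscore

    for name, members in res.final.bins.items():
        s_final = qscore(marker_estimator(members), config.score_weight)
        for cand in res.candidate_sets:
            for mem in cand.bins.values():
                if not members & mem:
                    continue
                shared = sum(community.lengths[c] for c in members & mem)
                smaller = min(
                    sum(community.lengths[c] for c in members),
                    sum(community.lengths[c] for c in mem),
                )
                if shared / smaller < config.match_overlap_threshold:
                    continue
                qv = marker_estimator(mem)
                if config.passes(qv):
                    assert s_final >= qscore(qv, config.score_weight) - 1e-9
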