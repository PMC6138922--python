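"""Bin-set consolidation: pick the best version of every bin.

The refinement pipeline takes 2-3 bin sets produced from the same
assembly, builds all hybrid (intersection-refined) sets, estimates the
completion and contamination of every bin in every candidate set (3
originals + 4 hybrids for three inputs — seven candidate sets), then
walks over the variants of each bin and keeps the best version under the
user's minimum-completion (c) / maximum-contamination (x) targets.  The
final set is filtered to (c, x), de-replicated so each contig belongs to
at most one bin, and re-scored.

"Best" ranks variants that meet (c, x) strictly above those that do
not; within a rank class the linear score completion - w*contamination
decides, with ties going to the earlier candidate set (originals before
hybrids) so the pipeline never churns without cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .core import BinSet, QualityMetrics
from .hybridize import enumerate_hybrid_sets
from .quality import BinEstimator, count_passing, score

__all__ = [
    "RefinementConfig",
    "CandidateBin",
    "RefinedResult",
    "bin_overlap",
    "match_best",
    "choose_version",
    "consolidate",
    "dereplicate",
    "refine",
]


@dataclass(frozen=True)
class RefinementConfig:
    """Tunables of the consolidation run.

    min_completion / max_contamination are the -c / -x targets in
    percent; score_weight is the contamination penalty w of the linear
    score; match_overlap_threshold is the shared-bp fraction (of the
    smaller bin) above which two bins count as versions of the same
    lineage; min_bin_size drops undersized hybrid signature groups
    (0 disables the filter — typical real assemblies use ~500 kb).
    """

    min_completion: float = 50.0
    max_contamination: float = 10.0
    score_weight: float = 5.0
    match_overlap_threshold: float = 0.8
    min_bin_size: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_completion <= 100.0:
            raise ValueError("min_completion must be in [0, 100]")
        if self.max_contamination < 0.0:
            raise ValueError("max_contamination must be >= 0")
        if self.score_weight < 0.0:
            raise ValueError("score_weight must be >= 0")
        if not 0.0 < self.match_overlap_threshold <= 1.0:
            raise ValueError("match_overlap_threshold must be in (0, 1]")

    def passes(self, q: QualityMetrics) -> bool:
        return (
            q.completion >= self.min_completion
            and q.contamination <= self.max_contamination
        )


@dataclass(frozen=True)
class CandidateBin:
    """One scored bin variant inside a candidate set."""

    name: str
    contigs: FrozenSet[str]
    quality: QualityMetrics
    source: str  # candidate-set label
    order: int  # candidate-set index (originals first, then hybrids)

    def score(self, weight: float) -> float:
        return score(self.quality, weight)


@dataclass
class RefinedResult:
    final: BinSet
    report: pd.DataFrame
    candidate_reports: Dict[str, pd.DataFrame]
    config: RefinementConfig
    n_passing: int = 0
    candidate_sets: List[BinSet] = field(default_factory=list)


def bin_overlap(
    bin_a: Iterable[str], bin_b: Iterable[str], lengths: Mapping[str, int]
) -> float:
    """Shared bp divided by the smaller bin's total bp."""
    a, b = set(bin_a), set(bin_b)
    if not a or not b:
        raise ValueError("bin_overlap of an empty bin is undefined")
    shared = sum(lengths[c] for c in a & b)
    smaller = min(sum(lengths[c] for c in a), sum(lengths[c] for c in b))
    return shared / smaller


def match_best(
    set_x: Sequence[CandidateBin],
    set_y: Sequence[CandidateBin],
    lengths: Mapping[str, int],
    threshold: float = 0.8,
) -> Tuple[List[Tuple[CandidateBin, CandidateBin]], List[CandidateBin], List[CandidateBin]]:
    """Greedy 1:1 matching of bin variants across two sets.

    Pairs are formed in descending order of :func:`bin_overlap`; only
    pairs at or above ``threshold`` are emitted; ties break on bin-name
    order for determinism.  Returns (pairs, unmatched_x, unmatched_y).
    """
    scored = []
    for bx in set_x:
        for by in set_y:
            ov = bin_overlap(bx.contigs, by.contigs, lengths)
            if ov >= threshold:
                scored.append((ov, bx.name, by.name, bx, by))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    pairs: List[Tuple[CandidateBin, CandidateBin]] = []
    used_x, used_y = set(), set()
    for _, nx, ny, bx, by in scored:
        if nx in used_x or ny in used_y:
            continue
        used_x.add(nx)
        used_y.add(ny)
        pairs.append((bx, by))
    unmatched_x = [b for b in set_x if b.name not in used_x]
    unmatched_y = [b for b in set_y if b.name not in used_y]
    return pairs, unmatched_x, unmatched_y


def choose_version(
    variants: Sequence[CandidateBin], config: RefinementConfig
) -> CandidateBin:
    """Best variant of one bin lineage.

    Variants meeting (c, x) strictly outrank those that do not; within a
    rank class the highest score wins; exact ties go to the earlier
    candidate set, then to the lexicographically smaller name.
    """
    if not variants:
        raise ValueError("choose_version needs at least one variant")
    w = config.score_weight

    def key(v: CandidateBin):
        return (config.passes(v.quality), v.score(w), -v.order, v.name)

    return max(variants, key=key)


def consolidate(
    candidates: Sequence[Sequence[CandidateBin]],
    config: RefinementConfig,
    lengths: Mapping[str, int],
) -> List[CandidateBin]:
    """Left-fold pairwise consolidation of candidate sets.

    At each step the accumulated set is matched against the next
    candidate set; matched pairs keep their :func:`choose_version`
    winner, unmatched bins from either side are carried over.  After all
    folds every distinct bin lineage is represented by one version.
    """
    if not candidates:
        raise ValueError("no candidate sets to consolidate")
    acc: List[CandidateBin] = list(candidates[0])
    for nxt in candidates[1:]:
        pairs, un_x, un_y = match_best(
            acc, list(nxt), lengths, config.match_overlap_threshold
        )
        merged = [choose_version([bx, by], config) for bx, by in pairs]
        acc = merged + un_x + un_y
    return acc


def dereplicate(
    bins: Mapping[str, Iterable[str]], scores: Mapping[str, float]
) -> Dict[str, FrozenSet[str]]:
    """Keep each contig only in its highest-scoring bin (ties by name).

    Bins emptied by the removal are dropped; the result satisfies the
    one-bin-per-contig invariant and the operation is idempotent.
    """
    owner: Dict[str, str] = {}
    # ascending name order: on score ties the lexicographically smaller
    # name is seen first and kept
    for name in sorted(bins):
        for cid in bins[name]:
            cur = owner.get(cid)
            if cur is None or scores[name] > scores[cur]:
                owner[cid] = name
    out: Dict[str, set] = {}
    for cid, name in owner.items():
        out.setdefault(name, set()).add(cid)
    return {name: frozenset(mem) for name, mem in out.items() if mem}


def _score_set(
    bs: BinSet, estimator: BinEstimator, order: int, weight: float
) -> List[CandidateBin]:
    return [
        CandidateBin(name, members, estimator(members), bs.label, order)
        for name, members in sorted(bs.bins.items())
    ]


def _candidate_report(cands: Sequence[CandidateBin], weight: float) -> pd.DataFrame:
    rows = [
        (
            c.name,
            c.quality.completion,
            c.quality.contamination,
            c.score(weight),
            c.quality.n50,
            c.quality.total_length,
            len(c.contigs),
        )
        for c in sorted(cands, key=lambda c: c.name)
    ]
    return pd.DataFrame(
        rows,
        columns=["bin", "completion", "contamination", "score", "n50", "size_bp", "n_contigs"],
    )


def refine(
    binsets: Sequence[BinSet],
    lengths: Mapping[str, int],
    estimator: BinEstimator,
    config: RefinementConfig = RefinementConfig(),
    label: str = "refined",
) -> RefinedResult:
    """Full consolidation pipeline over 2 or 3 input bin sets.

    Builds hybrids, scores all candidate sets with ``estimator``,
    consolidates, drops bins failing (c, x), de-replicates contigs, then
    re-estimates the survivors (dropping any bin the de-replication
    pushed back out of range, so the advertised thresholds always hold
    for the output).
    """
    if not 2 <= len(binsets) <= 3:
        raise ValueError("refine takes 2 or 3 input bin sets")
    hybrids = enumerate_hybrid_sets(binsets, lengths, config.min_bin_size)
    candidate_sets = list(binsets) + hybrids
    scored = [
        _score_set(bs, estimator, i, config.score_weight)
        for i, bs in enumerate(candidate_sets)
    ]
    candidate_reports = {
        bs.label: _candidate_report(cands, config.score_weight)
        for bs, cands in zip(candidate_sets, scored)
    }
    consolidated = consolidate(scored, config, lengths)
    passing = [c for c in consolidated if config.passes(c.quality)]

    # de-replicate across the surviving winners
    name_map: Dict[str, CandidateBin] = {}
    for c in passing:
        name = c.name if c.name not in name_map else f"{c.source}.{c.name}"
        name_map[name] = c
    derep = dereplicate(
        {n: c.contigs for n, c in name_map.items()},
        {n: c.score(config.score_weight) for n, c in name_map.items()},
    )

    # re-estimate after de-replication; keep only bins still in range
    final_bins: Dict[str, FrozenSet[str]] = {}
    rows = []
    for name in sorted(derep):
        members = derep[name]
        q = estimator(members)
        if not config.passes(q):
            continue
        final_bins[name] = members
        rows.append(
            (
                name,
                q.completion,
                q.contamination,
                score(q, config.score_weight),
                q.n50,
                q.total_length,
                len(members),
                name_map[name].source,
            )
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "bin",
            "completion",
            "contamination",
            "score",
            "n50",
            "size_bp",
            "n_contigs",
            "source",
        ],
    )
    final = BinSet(label, final_bins, provenance="refined")
    qualities = [estimator(m) for m in final_bins.values()]
    return RefinedResult(
        final=final,
        report=report,
        candidate_reports=candidate_reports,
        config=config,
        n_passing=count_passing(
            qualities, config.min_completion, config.max_contamination
        ),
        candidate_sets=candidate_sets,
    )
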