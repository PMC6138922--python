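"""Bin quality estimation: completion, contamination, N50, scores.

Two estimators are provided.  The *marker* estimator counts universal
single-copy marker genes within each bin — completion is the percentage
of expected markers found at least once, contamination the percentage of
extra copies.  Here markers are exact planted probe sequences (see
:mod:`binforge.synth`) or a user-supplied annotation table; real HMM-based
annotation can be plugged in through the same :class:`MarkerProfile`
shape.  The *gold* estimator scores a bin against a known contig->genome
truth: completion is the recall of the bin's majority genome,
contamination is ``100 * (1 - precision)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .core import GoldStandard, QualityMetrics, reverse_complement

__all__ = [
    "MarkerCatalog",
    "annotate_markers",
    "estimate_quality_markers",
    "estimate_quality_gold",
    "score",
    "n50",
    "count_passing",
    "make_marker_estimator",
    "make_gold_estimator",
    "make_sequence_marker_estimator",
    "quality_report",
]

#: contig-id -> multiset of marker ids detected on that contig
MarkerProfile = Dict[str, Counter]


@dataclass(frozen=True)
class MarkerCatalog:
    """Universal single-copy marker set with exact detection probes."""

    probes: Mapping[str, str]  # marker id -> probe sequence

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("marker catalog is empty")
        if len(set(self.probes.values())) != len(self.probes):
            raise ValueError("marker probes are not unique")

    @property
    def markers(self):
        return self.probes.keys()

    def __len__(self) -> int:
        return len(self.probes)


def _count_occurrences(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1  # overlap-tolerant


def annotate_markers(
    sequences: Mapping[str, str], catalog: MarkerCatalog
) -> MarkerProfile:
    """Detect catalog probes on each sequence, both strands.

    Every occurrence of a probe (forward or reverse-complement) counts as
    one marker copy; a probe and its reverse complement occurring at the
    same locus is not double-counted in practice because probes are long
    and non-palindromic.
    """
    profile: MarkerProfile = {}
    probe_pairs = [
        (mid, probe, reverse_complement(probe)) for mid, probe in catalog.probes.items()
    ]
    for cid, seq in sequences.items():
        counts: Counter = Counter()
        for mid, fwd, rev in probe_pairs:
            n = _count_occurrences(seq, fwd)
            if rev != fwd:
                n += _count_occurrences(seq, rev)
            if n:
                counts[mid] = n
        profile[cid] = counts
    return profile


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L cover half the total bp."""
    if len(lengths) == 0:
        raise ValueError("N50 of an empty length list is undefined")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[min(idx, len(arr) - 1)])


def estimate_quality_markers(
    bin_contigs: Iterable[str],
    profile: MarkerProfile,
    catalog: MarkerCatalog,
    lengths: Mapping[str, int],
    duplicate_fraction: bool = False,
) -> QualityMetrics:
    """Marker-count completion/contamination of one bin.

    completion = 100 * (#distinct markers present) / |catalog|.
    contamination = 100 * sum_m max(0, copies(m) - 1) / |catalog| by
    default (total extra copies; may exceed 100).  With
    ``duplicate_fraction=True`` the alternative reading — percentage of
    markers present more than once — is used instead.
    """
    members = list(bin_contigs)
    counts: Counter = Counter()
    for cid in members:
        counts.update(profile.get(cid, ()))
    present = len(counts)
    if duplicate_fraction:
        extra = sum(1 for v in counts.values() if v > 1)
    else:
        extra = sum(v - 1 for v in counts.values() if v > 1)
    size = len(catalog)
    member_lengths = [lengths[c] for c in members]
    return QualityMetrics(
        completion=100.0 * present / size,
        contamination=100.0 * extra / size,
        n50=n50(member_lengths),
        total_length=sum(member_lengths),
        marker_counts=dict(counts),
    )


def estimate_quality_gold(
    bin_contigs: Iterable[str],
    gold: GoldStandard,
    lengths: Mapping[str, int],
) -> QualityMetrics:
    """Truth-based quality of one bin.

    The bin is attributed to the genome contributing the most base pairs
    (ties broken by lexicographic genome id); completion = 100 * recall of
    that genome, contamination = 100 * (1 - precision of the bin).
    """
    members = list(bin_contigs)
    if not members:
        raise ValueError("cannot score an empty bin")
    unknown = sorted(c for c in members if c not in gold)
    if unknown:
        raise ValueError(f"contigs absent from gold standard: {unknown[:5]!r}")
    bp_by_genome: Dict[str, int] = {}
    for cid in members:
        g = gold.assignment[cid]
        bp_by_genome[g] = bp_by_genome.get(g, 0) + lengths[cid]
    # majority genome; lexicographic tie-break for determinism
    g_star = min(bp_by_genome, key=lambda g: (-bp_by_genome[g], g))
    member_lengths = [lengths[c] for c in members]
    total = sum(member_lengths)
    recall = bp_by_genome[g_star] / gold.genome_length[g_star]
    precision = bp_by_genome[g_star] / total
    return QualityMetrics(
        completion=100.0 * recall,
        contamination=100.0 * (1.0 - precision),
        n50=n50(member_lengths),
        total_length=total,
    )


def score(q: QualityMetrics, weight: float = 5.0) -> float:
    """Linear bin score ``completion - weight * contamination``."""
    if weight < 0:
        raise ValueError("score weight must be >= 0")
    return q.completion - weight * q.contamination


def count_passing(
    metrics: Iterable[QualityMetrics],
    min_completion: float,
    max_contamination: float,
) -> int:
    """Number of bins with completion >= c and contamination <= x (inclusive)."""
    return sum(
        1
        for q in metrics
        if q.completion >= min_completion and q.contamination <= max_contamination
    )


# ---------------------------------------------------------------------------
# estimator factories: uniform callables for refine/reassemble

BinEstimator = Callable[[Iterable[str]], QualityMetrics]


def make_marker_estimator(
    profile: MarkerProfile,
    catalog: MarkerCatalog,
    lengths: Mapping[str, int],
) -> BinEstimator:
    """Bin estimator (contig ids -> QualityMetrics) from a precomputed profile."""

    def estimator(bin_contigs: Iterable[str]) -> QualityMetrics:
        return estimate_quality_markers(bin_contigs, profile, catalog, lengths)

    return estimator


def make_gold_estimator(
    gold: GoldStandard, lengths: Mapping[str, int]
) -> BinEstimator:
    def estimator(bin_contigs: Iterable[str]) -> QualityMetrics:
        return estimate_quality_gold(bin_contigs, gold, lengths)

    return estimator


def make_sequence_marker_estimator(
    catalog: MarkerCatalog,
) -> Callable[[Mapping[str, str]], QualityMetrics]:
    """Estimator over raw sequences (id -> seq), for reassembled bins whose
    contigs are not part of the original assembly."""

    def estimator(sequences: Mapping[str, str]) -> QualityMetrics:
        profile = annotate_markers(sequences, catalog)
        lengths = {cid: len(s) for cid, s in sequences.items()}
        return estimate_quality_markers(sequences.keys(), profile, catalog, lengths)

    return estimator


def quality_report(
    bins: Mapping[str, Iterable[str]],
    estimator: BinEstimator,
    weight: float = 5.0,
) -> "pd.DataFrame":
    """Per-bin quality table: bin, completion, contamination, score, N50,
    size_bp, n_contigs — deterministic row order by bin name."""
    import pandas as pd

    rows: List[Tuple] = []
    for name in sorted(bins):
        members = list(bins[name])
        q = estimator(members)
        rows.append(
            (
                name,
                q.completion,
                q.contamination,
                score(q, weight),
                q.n50,
                q.total_length,
                len(members),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bin",
            "completion",
            "contamination",
            "score",
            "n50",
            "size_bp",
            "n_contigs",
        ],
    )
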