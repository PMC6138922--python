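"""Intersection refinement of bin sets (Binning_refiner-style hybridization).

Given two or more bin sets over the same assembly, the hybrid set splits
contigs so that no two contigs stay together if any input set placed
them in different bins: contigs binned in *every* input set are grouped
by their membership signature (the tuple of bin names across the ordered
inputs).  This trades completeness for purity — a hybrid bin is always a
subset of one bin in each contributing input, so it can never be less
pure than its parents on typical data.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Mapping, Sequence, Tuple

from .core import UNBINNED, BinSet

__all__ = ["membership_signature", "hybridize", "enumerate_hybrid_sets"]


def membership_signature(
    contig_id: str, binsets: Sequence[BinSet]
) -> Tuple[str, ...]:
    """Tuple of bin names of a contig across the ordered input sets.

    Slot ``i`` holds the contig's bin name in set ``i`` or
    :data:`~binforge.core.UNBINNED`.
    """
    return tuple(bs.bin_of(contig_id) for bs in binsets)


def hybridize(
    binsets: Sequence[BinSet],
    lengths: Mapping[str, int],
    min_bin_size: int = 0,
    label: str | None = None,
) -> BinSet:
    """Intersection-refine two or more bin sets into one hybrid set.

    Contigs unbinned in any input set are excluded (strict intersection).
    Signature groups whose total length falls below ``min_bin_size`` bp
    are dropped.  Hybrid bin names concatenate the source bin names with
    '+', prefixed by the combination label, so every hybrid bin is
    traceable to its parents.
    """
    if len(binsets) < 2:
        raise ValueError("hybridization needs at least 2 bin sets")
    if label is None:
        label = "hybrid_" + "_".join(bs.label for bs in binsets)
    # contigs binned in every input set
    common = set(binsets[0].binned_contigs)
    for bs in binsets[1:]:
        common &= bs.binned_contigs
    groups: Dict[Tuple[str, ...], List[str]] = {}
    for cid in common:
        groups.setdefault(membership_signature(cid, binsets), []).append(cid)
    bins: Dict[str, List[str]] = {}
    for sig in sorted(groups):
        members = groups[sig]
        if sum(lengths[c] for c in members) < min_bin_size:
            continue
        bins["+".join(sig)] = members
    return BinSet(label, bins, provenance="hybrid")


def enumerate_hybrid_sets(
    binsets: Sequence[BinSet],
    lengths: Mapping[str, int],
    min_bin_size: int = 0,
) -> List[BinSet]:
    """All hybrid sets over subsets of >= 2 inputs: 2^k - k - 1 of them.

    Subsets are enumerated size-ascending, lexicographic by member
    indices — for three inputs: {1,2}, {1,3}, {2,3}, {1,2,3} — so the
    "four possible combinations" feeding a three-way refinement run come
    out in a fixed, reproducible order.
    """
    k = len(binsets)
    if k < 2:
        raise ValueError("need at least 2 bin sets to enumerate hybrids")
    out: List[BinSet] = []
    for size in range(2, k + 1):
        for idxs in combinations(range(k), size):
            combo_id = "hyb" + "".join(str(i + 1) for i in idxs)
            subset = [binsets[i] for i in idxs]
            hy = hybridize(subset, lengths, min_bin_size, label=combo_id)
            # prefix bin names with the combination id for global traceability
            hy = BinSet(
                combo_id,
                {f"{combo_id}.{name}": members for name, members in hy.bins.items()},
                provenance="hybrid",
            )
            out.append(hy)
    return out
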