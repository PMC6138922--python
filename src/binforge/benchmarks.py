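"""Self-contained benchmark experiments on synthetic communities.

Each function builds its own inputs from a seed, runs one part of the
toolkit end to end, and returns the measured quantities.  These are the
experiments behind the package's reproducibility claims: consolidation
beating its input binnings on a gold standard, threshold
responsiveness, recruitment specificity, reassembly's never-worse
guarantee, and agreement of the marker estimator with the truth.

Problem sizes are deliberately small (tens of genomes of 10-100 kb)
so every experiment runs in seconds to a couple of minutes on one CPU;
the behaviours they probe are scale-free properties of the algorithms.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
import pandas as pd

from .core import UNBINNED, BinSet
from .hybridize import hybridize
from .quality import (
    annotate_markers,
    count_passing,
    estimate_quality_gold,
    estimate_quality_markers,
    make_marker_estimator,
    make_sequence_marker_estimator,
)
from .quantify import bin_abundance, standardize_table
from .reassemble import STRICT, KmerIndex, StubAssembler, reassemble_bins, recruit_reads
from .refine import RefinementConfig, refine
from .synth import (
    corrupt_binning,
    fragment,
    fragment_with_gaps,
    make_community,
    simulate_genomes,
    simulate_reads,
)

__all__ = [
    "refinement_structure",
    "hybridize_oracle_agreement",
    "consolidation_benchmark",
    "reassembly_benchmark",
    "estimator_recovery",
    "quantification_checks",
]


def _corrupted_sets(community, seed: int, n_sets: int = 3) -> List[BinSet]:
    """Three binnings with independent dropout 0.2-0.4, misassignment
    0.05-0.15, and 2 merges + 2 splits each."""
    rng = np.random.default_rng(seed)
    return [
        corrupt_binning(
            community.gold,
            dropout=rng.uniform(0.2, 0.4),
            misassignment=rng.uniform(0.05, 0.15),
            n_merges=2,
            n_splits=2,
            rng=rng,
            label=f"binner{i + 1}",
        )
        for i in range(n_sets)
    ]


def refinement_structure(seed: int = 0) -> Dict[str, int]:
    """Candidate-set bookkeeping of a three-way refinement run."""
    community = make_community(
        n_unique=4, n_common_pairs=0, genome_length=20_000, n_markers=30,
        marker_length=40, contig_median=4_000, min_contig=800, seed=seed,
    )
    profile = annotate_markers(community.assembly.sequences, community.catalog)
    estimator = make_marker_estimator(profile, community.catalog, community.lengths)
    sets = _corrupted_sets(community, seed + 1)
    res = refine(sets, community.lengths, estimator)
    n_hybrids = sum(1 for s in res.candidate_sets if s.provenance == "hybrid")
    return {
        "n_hybrid_sets": n_hybrids,
        "n_candidate_sets": len(res.candidate_sets),
    }


def _brute_force_hybrid(binsets, cids):
    """Quadratic oracle: group contigs binned everywhere so that no two
    grouped contigs were separated by any input set."""
    binned = [c for c in cids if all(bs.bin_of(c) != UNBINNED for bs in binsets)]
    groups: List[List[str]] = []
    for c in binned:
        for g in groups:
            if all(bs.bin_of(c) == bs.bin_of(g[0]) for bs in binsets):
                g.append(c)
                break
        else:
            groups.append([c])
    return {frozenset(g) for g in groups}


def hybridize_oracle_agreement(
    seed: int = 0, n_instances: int = 200, max_contigs: int = 50
) -> Dict[str, float]:
    """Fraction of random instances where hybridize equals the oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, max_contigs + 1))
        cids = [f"c{i}" for i in range(n)]
        sets = []
        for j in range(int(rng.integers(2, 4))):
            n_bins = int(rng.integers(1, 5))
            bins: Dict[str, List[str]] = {}
            for cid in cids:
                b = int(rng.integers(0, n_bins + 1))
                if b < n_bins:
                    bins.setdefault(f"s{j}b{b}", []).append(cid)
            sets.append(BinSet(f"s{j}", bins))
        hy = hybridize(sets, {c: 100 for c in cids})
        if set(hy.bins.values()) == _brute_force_hybrid(sets, cids):
            agree += 1
    return {"agreement_pct": 100.0 * agree / n_instances, "n": n_instances}


def consolidation_benchmark(seed: int = 0, n_seeds: int = 5) -> pd.DataFrame:
    """Refinement vs its input binnings on seeded 20-genome communities.

    For each replicate: a mixed community (10 unique genomes + 5 strain
    pairs at ANI 0.96), three corrupted binnings, refinement at
    (c=50, x=10) with the marker estimator, and gold-standard scoring of
    inputs and output.  Also re-runs at (c=90, x=10) for the threshold
    responsiveness comparison.
    """
    rows = []
    for i in range(n_seeds):
        community = make_community(seed=seed + i)
        profile = annotate_markers(community.assembly.sequences, community.catalog)
        lengths = community.lengths
        estimator = make_marker_estimator(profile, community.catalog, lengths)
        sets = _corrupted_sets(community, seed + 100 + i)
        res50 = refine(sets, lengths, estimator, RefinementConfig(50, 10))
        res90 = refine(sets, lengths, estimator, RefinementConfig(90, 10))

        def gold_stats(bins):
            qs = [estimate_quality_gold(m, community.gold, lengths) for m in bins.values()]
            return (
                count_passing(qs, 90, 5),
                float(np.mean([q.contamination for q in qs])) if qs else 0.0,
            )

        inputs = [gold_stats(bs.bins) for bs in sets]
        refined_count, refined_cont = gold_stats(res50.final.bins)
        best = max(inputs, key=lambda t: (t[0], -t[1]))
        rows.append(
            {
                "seed": seed + i,
                "refined_passing": refined_count,
                "input_passing_max": max(t[0] for t in inputs),
                "refined_ge_all_inputs": refined_count >= max(t[0] for t in inputs),
                "refined_mean_contamination": refined_cont,
                "best_input_mean_contamination": best[1],
                "high_completion_bins_c50": int((res50.report.completion >= 90).sum()),
                "high_completion_bins_c90": int((res90.report.completion >= 90).sum()),
            }
        )
    return pd.DataFrame(rows)


def reassembly_benchmark(seed: int = 0, n_seeds: int = 2) -> Dict[str, float]:
    """Recruitment specificity and the never-worse reassembly guarantee.

    Specificity: a 10-genome community of mutually unrelated genomes
    (far below 90% ANI), error-free reads at depth 20, bins = each
    genome's contigs; measures the strict-mode retrieval of same-genome
    pairs and cross-genome recruitment.  Reassembly: gap-fragmented bins
    of the same kind of community, reassembled with the built-in
    assembler; measures how many bins improved and whether any chosen
    version ranks below its original.
    """
    genomes, _ = simulate_genomes(
        10, genome_length=12_000, n_markers=20, marker_length=40, seed=seed
    )
    assembly, gold = fragment(genomes, 3_000, 0.5, 500, seed=seed + 1)
    bins = {
        gid: {cid: assembly[cid].sequence for cid in assembly.ids if gold.assignment[cid] == gid}
        for gid in genomes
    }
    rng = np.random.default_rng(seed + 2)
    per_genome_pairs = {
        gid: simulate_reads({gid: genomes[gid]}, depth=20, read_length=100, rng=rng)[0]
        for gid in sorted(genomes)
    }
    same_total = same_hit = cross = 0
    for gid in sorted(genomes):
        index = KmerIndex(bins[gid])
        for src, pairs in per_genome_pairs.items():
            hits = recruit_reads(pairs, bins[gid], STRICT, index=index)
            if src == gid:
                same_total += len(pairs)
                same_hit += len(hits)
            else:
                cross += len(hits)

    improved = worse = total = 0
    config = RefinementConfig()
    for i in range(n_seeds):
        g2, catalog = simulate_genomes(
            4, genome_length=8_000, n_markers=15, marker_length=40, seed=seed + 10 + i
        )
        asm2, gold2 = fragment_with_gaps(g2, 1_200, 150, seed=seed + 20 + i)
        pairs2, _ = simulate_reads(g2, depth=20, read_length=100, seed=seed + 30 + i)
        gap_bins = {
            gid: {cid: asm2[cid].sequence for cid in asm2.ids if gold2.assignment[cid] == gid}
            for gid in g2
        }
        estimator = make_sequence_marker_estimator(catalog)
        _, report = reassemble_bins(gap_bins, pairs2, StubAssembler(), estimator, config)
        total += len(report)
        improved += int(report["improved"].sum())
        for _, r in report.iterrows():
            before = (
                r.completion_before >= config.min_completion
                and r.contamination_before <= config.max_contamination,
                r.completion_before - config.score_weight * r.contamination_before,
            )
            after = (
                r.completion_after >= config.min_completion
                and r.contamination_after <= config.max_contamination,
                r.completion_after - config.score_weight * r.contamination_after,
            )
            if after < before:
                worse += 1
    return {
        "same_genome_recruitment_pct": 100.0 * same_hit / same_total,
        "cross_genome_pairs": float(cross),
        "n_pairs": same_total,
        "never_worse_pct": 100.0 * (total - worse) / total,
        "improved_pct": 100.0 * improved / total,
        "n_bins": total,
    }


def estimator_recovery(seed: int = 0, n_communities: int = 3) -> Dict[str, float]:
    """Mean absolute deviation between marker- and gold-based estimates
    over ~100 bins from corrupted binnings."""
    dc, dx = [], []
    for i in range(n_communities):
        community = make_community(seed=seed + i)
        profile = annotate_markers(community.assembly.sequences, community.catalog)
        lengths = community.lengths
        rng = np.random.default_rng(seed + 50 + i)
        for _ in range(2):
            bs = corrupt_binning(
                community.gold,
                dropout=rng.uniform(0.2, 0.4),
                misassignment=rng.uniform(0.05, 0.15),
                rng=rng,
            )
            for members in bs.bins.values():
                qm = estimate_quality_markers(members, profile, community.catalog, lengths)
                qg = estimate_quality_gold(members, community.gold, lengths)
                dc.append(qm.completion - qg.completion)
                dx.append(qm.contamination - qg.contamination)
    return {
        "completion_mad": float(np.mean(np.abs(dc))),
        "contamination_mad": float(np.mean(np.abs(dx))),
        "n_bins": len(dc),
    }


def quantification_checks(seed: int = 0) -> Dict[str, float]:
    """Hand-computable abundance example and scale equivariance."""
    cov = pd.DataFrame({"s1": [8.0, 4.0, 2.0]}, index=["c1", "c2", "c3"])
    lengths = {"c1": 100, "c2": 300, "c3": 50}
    binset = BinSet("b", {"A": ["c1", "c2"], "B": ["c3"]})
    ab = bin_abundance(binset, cov, lengths)
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(20):
        table = pd.DataFrame(
            rng.uniform(0, 100, size=(10, 3)),
            index=[f"c{i}" for i in range(10)],
            columns=["s1", "s2", "s3"],
        )
        sizes = {s: float(rng.uniform(1e8, 1e10)) for s in table.columns}
        factor = float(rng.uniform(0.1, 10))
        base = standardize_table(table, sizes)
        scaled = standardize_table(
            table * factor, {s: v * factor for s, v in sizes.items()}
        )
        max_dev = max(max_dev, float(np.abs(base - scaled).max().max()))
    return {
        "toy_bin_abundance": float(ab.loc["A", "s1"]),  # (100*8 + 300*4) / 400
        "equivariance_max_dev": max_dev,
    }
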