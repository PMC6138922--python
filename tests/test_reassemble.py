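"""Read recruitment, the stub assembler, and best-of-three selection."""

import numpy as np
import pytest

from binforge.core import reverse_complement
from binforge.quality import make_sequence_marker_estimator
from binforge.refine import RefinementConfig
from binforge.reassemble import (
    PERMISSIVE,
    STRICT,
    KmerIndex,
    ReadPair,
    StubAssembler,
    best_alignment_mismatches,
    reassemble_bin,
    reassemble_bins,
    recruit_reads,
    select_best_version,
)
from binforge.synth import simulate_genomes, simulate_reads


@pytest.fixture(scope="module")
def toy_contigs():
    genomes, _ = simulate_genomes(2, genome_length=600, n_markers=0, marker_length=0, seed=2)
    g = sorted(genomes.values())
    return {"c1": g[0][:300], "c2": g[0][300:], "other": g[1]}


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def exhaustive_mismatches(read, contigs):
    """Sliding-window Hamming oracle without seeding."""
    best = None
    for seq in (read, reverse_complement(read)):
        for contig in contigs.values():
            for start in range(len(contig) - len(seq) + 1):
                mm = sum(a != b for a, b in zip(seq, contig[start : start + len(seq)]))
                best = mm if best is None else min(best, mm)
    return best


def test_alignment_verbatim_read(toy_contigs):
    index = KmerIndex(toy_contigs)
    read = toy_contigs["c1"][50:150]
    assert best_alignment_mismatches(read, index) == 0
    assert best_alignment_mismatches(reverse_complement(read), index) == 0


def test_alignment_counts_substitutions_outside_seed(toy_contigs):
    index = KmerIndex(toy_contigs)
    read = _mutate(toy_contigs["c1"][50:150], [60, 80])  # seed intact in first 21 bp
    mm = best_alignment_mismatches(read, index, stop_at=-1)
    assert mm == 2 == exhaustive_mismatches(read, toy_contigs)


def test_alignment_no_shared_kmer_is_no_hit(toy_contigs):
    rng = np.random.default_rng(0)
    read = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
    assert best_alignment_mismatches(read, KmerIndex(toy_contigs)) is None


def test_recruitment_matches_exhaustive_oracle():
    genomes, _ = simulate_genomes(3, genome_length=400, n_markers=0, marker_length=0, seed=4)
    contigs = {f"c{i}": s for i, s in enumerate(sorted(genomes.values()))}
    rng = np.random.default_rng(8)
    pairs = []
    seqs = sorted(contigs.values())
    for i in range(20):
        src = seqs[int(rng.integers(0, len(seqs)))]
        start = int(rng.integers(0, len(src) - 100))
        mate1 = src[start : start + 100]
        n_err = int(rng.integers(0, 7))
        mate1 = _mutate(mate1, sorted(rng.choice(100, size=n_err, replace=False)))
        mate2 = "".join("ACGT"[j] for j in rng.integers(0, 4, 100))
        pairs.append(ReadPair(f"p{i}", mate1, mate2))
    bin_seqs = {"c0": contigs["c0"]}
    for mode in (STRICT, PERMISSIVE):
        got = {p.id for p in recruit_reads(pairs, bin_seqs, mode)}
        want = set()
        for p in pairs:
            mms = [exhaustive_mismatches(m, bin_seqs) for m in (p.mate1, p.mate2)]
            mms = [m for m in mms if m is not None]
            if mms and min(mms) <= mode.max_mismatches:
                want.add(p.id)
        assert got == want


def test_pair_rescue_and_mode_thresholds(toy_contigs):
    bin_seqs = {"c1": toy_contigs["c1"]}
    perfect = toy_contigs["c1"][10:110]
    random_mate = "".join("ACGT"[i] for i in np.random.default_rng(1).integers(0, 4, 100))
    rescued = ReadPair("rescued", perfect, random_mate)
    assert recruit_reads([rescued], bin_seqs, STRICT) == [rescued]
    three_mm = ReadPair("3mm", _mutate(perfect, [30, 50, 70]), random_mate)
    assert recruit_reads([three_mm], bin_seqs, STRICT) == []
    assert recruit_reads([three_mm], bin_seqs, PERMISSIVE) == [three_mm]
    neither = ReadPair("none", random_mate, random_mate)
    assert recruit_reads([neither], bin_seqs, PERMISSIVE) == []


def test_strict_subset_of_permissive(toy_contigs):
    rng = np.random.default_rng(9)
    pairs = []
    for i in range(30):
        start = int(rng.integers(0, 200))
        m1 = _mutate(
            toy_contigs["c1"][start : start + 100],
            sorted(rng.choice(100, size=int(rng.integers(0, 6)), replace=False)),
        )
        pairs.append(ReadPair(f"p{i}", m1, reverse_complement(m1)))
    strict = {p.id for p in recruit_reads(pairs, toy_contigs, STRICT)}
    permissive = {p.id for p in recruit_reads(pairs, toy_contigs, PERMISSIVE)}
    assert strict <= permissive


# --- stub assembler --------------------------------------------------------


def test_stub_assembler_reconstructs_tiling_reads():
    genomes, _ = simulate_genomes(1, genome_length=1000, n_markers=0, marker_length=0, seed=5)
    genome = next(iter(genomes.values()))
    reads = [ReadPair(f"r{i}", genome[i : i + 100], genome[i : i + 100]) for i in range(0, 901, 50)]
    contigs = StubAssembler()(reads)
    assert len(contigs) == 1
    assert contigs[0] in (genome, reverse_complement(genome))


def test_stub_assembler_empty_input():
    assert StubAssembler()([]) == []


def test_reassemble_bin_round_trip():
    genomes, _ = simulate_genomes(1, genome_length=1000, n_markers=0, marker_length=0, seed=6)
    genome = next(iter(genomes.values()))
    pairs, _ = simulate_reads({"g": genome}, depth=30, read_length=100, seed=7)
    strict_v, permissive_v = reassemble_bin({"g": genome}, pairs, StubAssembler())
    assert any(genome in c or reverse_complement(genome) in c or len(c) > 900 for c in strict_v)
    assert permissive_v  # permissive read set is a superset, so it assembles too


def test_reassemble_bin_no_reads_gives_empty_versions(toy_contigs):
    rng = np.random.default_rng(3)
    alien = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
    pairs = [ReadPair("p", alien, alien)]
    strict_v, permissive_v = reassemble_bin({"other": toy_contigs["other"]}, pairs, StubAssembler())
    assert strict_v == [] and permissive_v == []


# --- version selection -----------------------------------------------------


def _const_estimator(table):
    """Estimator returning canned metrics keyed by a sentinel contig id."""
    from binforge.core import QualityMetrics

    def est(seqs):
        key = sorted(seqs)[0].split("_")[0]
        c, x = table[key]
        return QualityMetrics(completion=c, contamination=x, n50=1, total_length=1)

    return est


def test_select_best_version_prefers_better_reassembly():
    est = _const_estimator({"orig": (70, 2), "strict": (85, 2), "permissive": (60, 2)})
    label, _, _ = select_best_version(
        {"orig_1": "ACGT"}, ["ACGT"], ["ACGT"], est, RefinementConfig()
    )
    assert label == "strict"


def test_select_best_version_rank_class_guards_contamination():
    est = _const_estimator({"orig": (80, 5), "strict": (95, 20), "permissive": (50, 0)})
    label, _, _ = select_best_version(
        {"orig_1": "ACGT"}, ["ACGT"], ["ACGT"], est, RefinementConfig(50, 10)
    )
    assert label == "original"  # reassembly inflated contamination past x


def test_select_best_version_tie_keeps_original():
    est = _const_estimator({"orig": (80, 2), "strict": (80, 2), "permissive": (80, 2)})
    label, _, _ = select_best_version(
        {"orig_1": "ACGT"}, ["ACGT"], ["ACGT"], est, RefinementConfig()
    )
    assert label == "original"


# --- whole-set reassembly --------------------------------------------------


@pytest.fixture(scope="module")
def gapped_setup():
    from binforge.synth import fragment_with_gaps

    genomes, catalog = simulate_genomes(4, genome_length=8_000, n_markers=15, marker_length=40, seed=11)
    assembly, gold = fragment_with_gaps(genomes, piece_length=1200, gap_length=150, seed=12)
    pairs, _ = simulate_reads(genomes, depth=20, read_length=100, seed=13)
    bins = {
        gid: {cid: assembly[cid].sequence for cid in assembly.ids if cid.startswith(gid + "_")}
        for gid in genomes
    }
    return bins, pairs, catalog


def test_reassemble_bins_improves_gapped_bins(gapped_setup):
    """Pairs anchored next to assembly gaps reach into them, so per-bin
    reassembly recovers markers lost in the gaps for most bins."""
    bins, pairs, catalog = gapped_setup
    est = make_sequence_marker_estimator(catalog)
    final, report = reassemble_bins(bins, pairs, StubAssembler(), est, RefinementConfig())
    assert report["improved"].sum() >= len(report) / 2
    assert (report.completion_after >= report.completion_before).all()


def test_reassemble_bins_never_worse(gapped_setup):
    bins, pairs, catalog = gapped_setup
    est = make_sequence_marker_estimator(catalog)
    config = RefinementConfig()
    _, report = reassemble_bins(bins, pairs, StubAssembler(), est, config)
    for _, r in report.iterrows():
        rank_before = (
            r.completion_before >= config.min_completion
            and r.contamination_before <= config.max_contamination,
            r.completion_before - config.score_weight * r.contamination_before,
        )
        rank_after = (
            r.completion_after >= config.min_completion
            and r.contamination_after <= config.max_contamination,
            r.completion_after - config.score_weight * r.contamination_after,
        )
        assert rank_after >= rank_before


def test_reassemble_bins_failing_assembler_keeps_original(gapped_setup):
    bins, pairs, catalog = gapped_setup
    est = make_sequence_marker_estimator(catalog)

    calls = {"n": 0}

    def flaky(read_pairs):
        calls["n"] += 1
        if calls["n"] == 1:  # the first bin's assembly fails
            raise RuntimeError("assembler crashed")
        return StubAssembler()(read_pairs)

    final, report = reassemble_bins(bins, pairs, flaky, est, RefinementConfig())
    first = report.iloc[0]
    assert first.chosen_version == "original" and not first.improved
    assert report.iloc[1:]["improved"].any()  # other bins still processed


def test_reassemble_bins_identity_when_estimator_prefers_original(gapped_setup):
    bins, pairs, catalog = gapped_setup
    from binforge.core import QualityMetrics

    def pessimist(seqs):
        # original bins contain ids with '_c'; reassembled ones do not
        original = all("_c" in k for k in seqs)
        return QualityMetrics(
            completion=90.0 if original else 10.0,
            contamination=0.0,
            n50=1,
            total_length=1,
        )

    final, report = reassemble_bins(bins, pairs, StubAssembler(), pessimist, RefinementConfig())
    assert (report.chosen_version == "original").all()
    assert set(final) == set(bins)
    for name in bins:
        assert final[name] == bins[name]


def test_cross_recruitment_rises_with_strain_similarity():
    """As two genomes approach >= 95% identity, permissive recruitment
    loses specificity — the failure mode of highly similar communities."""
    from binforge.synth import derive_strain

    genomes, _ = simulate_genomes(1, genome_length=5_000, n_markers=0, marker_length=0, seed=20)
    base = next(iter(genomes.values()))
    fractions = []
    for ani in (0.90, 0.97):
        strain = derive_strain(base, ani, seed=21)
        pairs, _ = simulate_reads({"s": strain}, depth=5, read_length=100, seed=22)
        rec = recruit_reads(pairs, {"base": base}, PERMISSIVE)
        fractions.append(len(rec) / len(pairs))
    assert fractions[1] > fractions[0]
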