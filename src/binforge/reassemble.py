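"""Per-bin read recruitment and reassembly.

Each bin recruits read pairs from the sample in two modes — *strict*
(a mate must align with 0 mismatches) and *permissive* (fewer than 5
mismatches, i.e. at most 4) — and a pair is pulled in whenever either
mate aligns, so the unaligned mate can extend the assembly into gaps.
Each recruited read set is assembled into a candidate version of the
bin, and the best of {original, strict, permissive} is kept under the
same (c, x)-then-score ranking used by bin refinement, with exact ties
resolved in favour of the original so the pipeline never replaces a bin
without a measurable gain.

Alignment is ungapped Hamming matching seeded by exact k-mer hits
(k = 21 by default) on either strand — adequate for substitution-only
reads; an external mapper can be plugged in through the same contract.
The built-in assembler is a greedy exact-overlap merger intended for
synthetic, error-free reads; real runs configure an external assembler
command template instead.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import QualityMetrics, reverse_complement
from .refine import RefinementConfig
from .quality import score

__all__ = [
    "ReadPair",
    "RecruitmentMode",
    "STRICT",
    "PERMISSIVE",
    "KmerIndex",
    "best_alignment_mismatches",
    "recruit_reads",
    "StubAssembler",
    "CommandAssembler",
    "reassemble_bin",
    "select_best_version",
    "reassemble_bins",
    "NO_HIT",
]

logger = logging.getLogger(__name__)

#: returned when no exact k-mer seed places the read anywhere on the bin
NO_HIT = None


@dataclass(frozen=True)
class ReadPair:
    """A paired read; qualities are carried but never interpreted."""

    id: str
    mate1: str
    mate2: str
    qual1: Optional[str] = None
    qual2: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.mate1 or not self.mate2:
            raise ValueError(f"read pair {self.id!r} has an empty mate")


@dataclass(frozen=True)
class RecruitmentMode:
    name: str
    max_mismatches: int


STRICT = RecruitmentMode("strict", 0)
PERMISSIVE = RecruitmentMode("permissive", 4)  # "< 5 mismatches"


class KmerIndex:
    """Exact k-mer -> (contig, position) index over a bin's contigs."""

    def __init__(self, sequences: Mapping[str, str], k: int = 21):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.sequences = dict(sequences)
        index: Dict[str, List[Tuple[str, int]]] = {}
        for cid, seq in self.sequences.items():
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((cid, pos))
        self._index = index

    def seeds(self, kmer: str) -> List[Tuple[str, int]]:
        return self._index.get(kmer, [])


def _hamming_capped(a: str, b: str, cap: int) -> int:
    """Mismatch count between equal-length strings, early-exit above cap."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def _best_for_strand(seq: str, index: KmerIndex, best: Optional[int], stop_at: int) -> Optional[int]:
    k = index.k
    n = len(seq)
    seen: set = set()
    for i in range(n - k + 1):
        for cid, pos in index.seeds(seq[i : i + k]):
            start = pos - i
            if start < 0:
                continue
            contig = index.sequences[cid]
            if start + n > len(contig):
                continue
            place = (cid, start)
            if place in seen:
                continue
            seen.add(place)
            cap = (best - 1) if best is not None else n
            mm = _hamming_capped(seq, contig[start : start + n], cap)
            if best is None or mm < best:
                best = mm
                if best <= stop_at:
                    return best
    return best


def best_alignment_mismatches(
    read: str, index: KmerIndex, stop_at: int = 0
) -> Optional[int]:
    """Minimum ungapped mismatch count of a read against indexed contigs.

    Both strands are tried; candidate placements are seeded by exact
    k-mer matches and scored by Hamming distance over the full read
    (placements running off a contig end are skipped).  Returns
    :data:`NO_HIT` when no seed exists anywhere.  ``stop_at`` allows an
    early exit once an alignment at or below that many mismatches is
    found (the returned value is then an upper bound adequate for a
    threshold decision; the default 0 always yields the exact minimum).
    """
    best = _best_for_strand(read, index, None, stop_at)
    if best is not None and best <= stop_at:
        return best
    return _best_for_strand(reverse_complement(read), index, best, stop_at)


def recruit_reads(
    pairs: Iterable[ReadPair],
    bin_sequences: Mapping[str, str],
    mode: RecruitmentMode,
    k: int = 21,
    index: Optional[KmerIndex] = None,
) -> List[ReadPair]:
    """Read pairs recruited to a bin: either mate within the mode's budget.

    Whole pairs are emitted, never single mates — a pair is pulled out
    even when only one read aligns to the bin.
    """
    if index is None:
        index = KmerIndex(bin_sequences, k)
    out: List[ReadPair] = []
    cap = mode.max_mismatches
    for pair in pairs:
        m1 = best_alignment_mismatches(pair.mate1, index, stop_at=cap)
        if m1 is not None and m1 <= cap:
            out.append(pair)
            continue
        m2 = best_alignment_mismatches(pair.mate2, index, stop_at=cap)
        if m2 is not None and m2 <= cap:
            out.append(pair)
    return out


# ---------------------------------------------------------------------------
# assemblers

Assembler = Callable[[Sequence[ReadPair]], List[str]]


class StubAssembler:
    """Greedy exact-overlap read merger (default minimum overlap 31 bp).

    Both orientations of every mate enter the pool; contigs are grown by
    repeatedly appending the read with the longest exact suffix/prefix
    overlap.  Suitable only for substitution-free synthetic reads.
    """

    def __init__(self, min_overlap: int = 31, min_contig: int = 0):
        self.min_overlap = min_overlap
        self.min_contig = min_contig

    def __call__(self, pairs: Sequence[ReadPair]) -> List[str]:
        pool = set()
        for p in pairs:
            for seq in (p.mate1, p.mate2):
                pool.add(seq)
                pool.add(reverse_complement(seq))
        reads = sorted(pool)
        if not reads:
            return []
        ov = self.min_overlap
        # index reads by their first ov-mer for O(1) extension lookup
        prefix_index: Dict[str, List[str]] = {}
        for r in reads:
            if len(r) >= ov:
                prefix_index.setdefault(r[:ov], []).append(r)
        used: set = set()
        max_len = sum(len(r) for r in reads)  # loop guard on repeats
        contigs: List[str] = []
        for seed in reads:
            if seed in used:
                continue
            used.add(seed)
            used.add(reverse_complement(seed))
            contig = seed
            # extend right, then left (via reverse complement), greedily
            for _ in range(2):
                while len(contig) < max_len:
                    ext = self._best_extension(contig, prefix_index, used)
                    if ext is None:
                        break
                    overlap, read = ext
                    used.add(read)
                    used.add(reverse_complement(read))
                    contig = contig + read[overlap:]
                contig = reverse_complement(contig)
            # absorb reads fully contained in the finished contig
            rc = reverse_complement(contig)
            for r in reads:
                if r not in used and (r in contig or r in rc):
                    used.add(r)
            if len(contig) >= self.min_contig:
                contigs.append(contig)
        contigs.sort(key=lambda s: (-len(s), s))
        return contigs

    def _best_extension(
        self, contig: str, prefix_index: Dict[str, List[str]], used: set
    ) -> Optional[Tuple[int, str]]:
        ov = self.min_overlap
        longest = max((len(r) for rs in prefix_index.values() for r in rs), default=0)
        for overlap in range(min(longest, len(contig)), ov - 1, -1):
            anchor = contig[len(contig) - overlap : len(contig) - overlap + ov]
            for r in prefix_index.get(anchor, ()):
                if r in used or len(r) <= overlap:
                    continue
                if contig.endswith(r[:overlap]):
                    return overlap, r
        return None


class CommandAssembler:
    """External assembler via a shell command template.

    The template receives ``{r1}``, ``{r2}`` (FASTQ paths of the
    recruited pairs) and ``{out}`` (path of the contig FASTA the command
    must produce), e.g. a SPAdes invocation.
    """

    def __init__(self, template: str):
        self.template = template

    def __call__(self, pairs: Sequence[ReadPair]) -> List[str]:
        from .io import read_fasta, write_fastq_pairs

        with tempfile.TemporaryDirectory() as tmp:
            r1 = Path(tmp) / "reads_1.fastq"
            r2 = Path(tmp) / "reads_2.fastq"
            out = Path(tmp) / "contigs.fasta"
            write_fastq_pairs(pairs, r1, r2)
            cmd = self.template.format(r1=r1, r2=r2, out=out)
            subprocess.run(cmd, shell=True, check=True)
            return list(read_fasta(out).values())


# ---------------------------------------------------------------------------
# per-bin reassembly and version selection


def reassemble_bin(
    bin_sequences: Mapping[str, str],
    pairs: Sequence[ReadPair],
    assembler: Assembler,
    k: int = 21,
) -> Tuple[List[str], List[str]]:
    """Strict and permissive reassembled versions of one bin.

    Reads are recruited once at the permissive budget with exact
    mismatch counts, split into the strict (0 mismatches on the better
    mate) and permissive (<= 4) pair sets, and each set is assembled.
    The strict read set is always a subset of the permissive one.
    """
    index = KmerIndex(bin_sequences, k)
    strict_pairs: List[ReadPair] = []
    permissive_pairs: List[ReadPair] = []
    cap = PERMISSIVE.max_mismatches
    for pair in pairs:
        m1 = best_alignment_mismatches(pair.mate1, index, stop_at=0)
        best = m1
        if best != 0:
            m2 = best_alignment_mismatches(pair.mate2, index, stop_at=0)
            if best is None or (m2 is not None and m2 < best):
                best = m2
        if best is None or best > cap:
            continue
        permissive_pairs.append(pair)
        if best == 0:
            strict_pairs.append(pair)
    strict_version = assembler(strict_pairs) if strict_pairs else []
    permissive_version = assembler(permissive_pairs) if permissive_pairs else []
    return strict_version, permissive_version


SequenceEstimator = Callable[[Mapping[str, str]], QualityMetrics]


def select_best_version(
    original: Mapping[str, str],
    strict_version: Sequence[str],
    permissive_version: Sequence[str],
    estimator: SequenceEstimator,
    config: RefinementConfig,
) -> Tuple[str, Dict[str, str], Dict[str, QualityMetrics]]:
    """Pick the best of the three versions of a bin.

    Ranking is identical to refinement's choose_version: versions
    meeting (c, x) outrank those that do not, then score decides; exact
    ties keep the original (order original > strict > permissive).
    Returns (label, chosen sequences, quality of each nonempty version).
    """
    versions: List[Tuple[str, Dict[str, str]]] = [("original", dict(original))]
    if strict_version:
        versions.append(
            ("strict", {f"strict_{i}": s for i, s in enumerate(strict_version)})
        )
    if permissive_version:
        versions.append(
            ("permissive", {f"permissive_{i}": s for i, s in enumerate(permissive_version)})
        )
    qualities: Dict[str, QualityMetrics] = {}
    ranked = []
    for priority, (label, seqs) in enumerate(versions):
        if not seqs:
            continue
        q = estimator(seqs)
        qualities[label] = q
        ranked.append(
            ((config.passes(q), score(q, config.score_weight), -priority), label, seqs)
        )
    if not ranked:
        raise ValueError("all versions of the bin are empty")
    key, label, seqs = max(ranked, key=lambda t: t[0])
    return label, seqs, qualities


def reassemble_bins(
    binset_sequences: Mapping[str, Mapping[str, str]],
    pairs: Sequence[ReadPair],
    assembler: Assembler,
    estimator: SequenceEstimator,
    config: RefinementConfig = RefinementConfig(),
    k: int = 21,
) -> Tuple[Dict[str, Dict[str, str]], pd.DataFrame]:
    """Reassemble every bin of a set and keep the best version of each.

    ``binset_sequences`` maps bin name -> (contig id -> sequence).  A
    failing assembler flags the bin and keeps the original; errors never
    abort the whole run.  Returns the final bins (name -> sequences) and
    a provenance report with before/after metrics and the fraction of
    bins improved.
    """
    final: Dict[str, Dict[str, str]] = {}
    rows = []
    for name in sorted(binset_sequences):
        original = dict(binset_sequences[name])
        q_orig = estimator(original)
        try:
            strict_v, permissive_v = reassemble_bin(original, pairs, assembler, k)
            label, seqs, quals = select_best_version(
                original, strict_v, permissive_v, estimator, config
            )
        except Exception as exc:  # per-bin error contract: keep the original
            logger.warning("reassembly of bin %s failed (%s); original kept", name, exc)
            label, seqs, quals = "original", original, {"original": q_orig}
        q_new = quals[label]
        final[name] = seqs
        rows.append(
            (
                name,
                label,
                q_orig.completion,
                q_new.completion,
                q_orig.contamination,
                q_new.contamination,
                q_orig.n50,
                q_new.n50,
                label != "original",
            )
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "bin",
            "chosen_version",
            "completion_before",
            "completion_after",
            "contamination_before",
            "contamination_after",
            "n50_before",
            "n50_after",
            "improved",
        ],
    )
    return final, report
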