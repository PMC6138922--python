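"""Synthetic microbial community generator.

Produces everything the rest of the toolkit consumes, with known truth:
genomes carrying one planted copy of each universal single-copy marker
tag, strain pairs at a controlled average nucleotide identity (ANI >=
0.95 makes a "common strain" pair, < 0.95 "unique" — the convention of
the CAMI benchmarks), fragmentation of genomes into contigs with an
exact gold standard, imperfect binnings with controlled dropout /
misassignment / merge / split errors, and paired short reads with
substitution errors.

Markers are exact random tags rather than real genes, which makes
completion and contamination analytically controllable; strain
mutation spares marker loci so marker-based and gold-based quality
remain comparable across strains.  All randomness flows from one
numpy Generator, so every artefact is reproducible from (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import Assembly, BinSet, Contig, GoldStandard, reverse_complement
from .quality import MarkerCatalog
from .reassemble import ReadPair

__all__ = [
    "SyntheticCommunity",
    "simulate_genomes",
    "derive_strain",
    "fragment",
    "corrupt_binning",
    "simulate_reads",
    "make_community",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, length)]).decode()


def _seq_to_idx(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _idx_to_seq(idx: np.ndarray) -> str:
    return bytes(_BASES[idx]).decode()


@dataclass
class SyntheticCommunity:
    """Genomes, marker catalog, assembly and truth of one simulation."""

    genomes: Dict[str, str]
    catalog: MarkerCatalog
    assembly: Assembly
    gold: GoldStandard
    params: Dict = field(default_factory=dict)

    @property
    def lengths(self) -> Dict[str, int]:
        return self.assembly.lengths


def simulate_genomes(
    n_genomes: int,
    genome_length: int = 100_000,
    n_markers: int = 100,
    marker_length: int = 60,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    prefix: str = "g",
) -> Tuple[Dict[str, str], MarkerCatalog]:
    """Random genomes, each carrying one copy of every marker tag.

    The backbone is i.i.d. uniform ACGT; the same set of unique random
    marker tags is written into every genome at non-overlapping,
    uniformly placed positions (positions drawn independently per
    genome).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_markers * marker_length >= genome_length:
        raise ValueError("markers cannot be packed into the genome length")
    probes: Dict[str, str] = {}
    while len(probes) < n_markers:
        tag = _random_seq(rng, marker_length)
        if tag not in probes.values():
            probes[f"m{len(probes):03d}"] = tag
    catalog = MarkerCatalog(probes) if n_markers else None  # empty -> no catalog
    genomes: Dict[str, str] = {}
    for i in range(n_genomes):
        gid = f"{prefix}{i:03d}"
        arr = rng.integers(0, 4, genome_length).astype(np.uint8)
        seq = _idx_to_seq(arr)
        if n_markers:
            # uniform non-overlapping placement: draw starts in the
            # marker-free coordinate system, then shift by slot widths
            free = genome_length - n_markers * marker_length
            offsets = np.sort(rng.choice(free, size=n_markers, replace=False))
            starts = offsets + np.arange(n_markers) * marker_length
            chars = list(seq)
            for (mid, probe), start in zip(sorted(probes.items()), starts):
                chars[start : start + marker_length] = probe
            seq = "".join(chars)
        genomes[gid] = seq
    return genomes, catalog


def _marker_mask(genome: str, catalog: Optional[MarkerCatalog]) -> np.ndarray:
    mask = np.zeros(len(genome), dtype=bool)
    if catalog is None:
        return mask
    for probe in catalog.probes.values():
        start = genome.find(probe)
        while start >= 0:
            mask[start : start + len(probe)] = True
            start = genome.find(probe, start + 1)
    return mask


def derive_strain(
    genome: str,
    ani: float,
    catalog: Optional[MarkerCatalog] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> str:
    """Mutated copy of a genome at per-base substitution rate 1 - ANI.

    Marker loci are left intact so planted tags stay detectable exactly
    once in each strain.
    """
    if not 0.0 < ani <= 1.0:
        raise ValueError("ANI must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if ani == 1.0:
        return genome
    idx = _seq_to_idx(genome)
    mutable = ~_marker_mask(genome, catalog)
    hits = (rng.random(len(genome)) < (1.0 - ani)) & mutable
    n = int(hits.sum())
    idx[hits] = (idx[hits] + rng.integers(1, 4, n).astype(np.uint8)) % 4
    return _idx_to_seq(idx)


def fragment(
    genomes: Mapping[str, str],
    median_length: int = 10_000,
    sigma: float = 0.7,
    min_length: int = 1_000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[Assembly, GoldStandard]:
    """Cut each genome sequentially into lognormal-length contigs.

    Contig lengths follow lognormal(ln median, sigma) clipped below at
    ``min_length``; a final remainder shorter than ``min_length`` is
    appended to the previous contig, so concatenating a genome's contigs
    in generation order reproduces the genome exactly.
    """
    if median_length < min_length:
        raise ValueError("median contig length must be >= min length")
    if rng is None:
        rng = np.random.default_rng(seed)
    contigs: List[Contig] = []
    assignment: Dict[str, str] = {}
    for gid in sorted(genomes):
        seq = genomes[gid]
        pieces: List[str] = []
        pos = 0
        while pos < len(seq):
            draw = int(rng.lognormal(np.log(median_length), sigma))
            draw = max(draw, min_length)
            rest = len(seq) - pos
            if rest - draw < min_length:
                draw = rest  # absorb the remainder into this piece
            pieces.append(seq[pos : pos + draw])
            pos += draw
        for k, piece in enumerate(pieces):
            cid = f"{gid}_c{k:03d}"
            contigs.append(Contig(cid, piece))
            assignment[cid] = gid
    assembly = Assembly(contigs)
    gold = GoldStandard(assignment, assembly.lengths)
    return assembly, gold


def fragment_with_gaps(
    genomes: Mapping[str, str],
    piece_length: int = 1_200,
    gap_length: int = 150,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[Assembly, GoldStandard]:
    """Fragment genomes leaving short uncovered gaps between contigs.

    Emulates assembly breakage with sequence loss: contigs are exact
    genome slices of roughly ``piece_length`` bp separated by skipped
    gaps of roughly ``gap_length`` bp.  Markers falling in a gap are
    absent from the assembly but recoverable by read recruitment (pairs
    anchored in flanking contigs reach into the gap), which is what
    per-bin reassembly exploits.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    contigs: List[Contig] = []
    assignment: Dict[str, str] = {}
    for gid in sorted(genomes):
        seq = genomes[gid]
        pos, k = 0, 0
        while pos < len(seq):
            piece = int(rng.integers(int(piece_length * 0.8), int(piece_length * 1.2) + 1))
            end = min(pos + piece, len(seq))
            if end - pos >= gap_length:  # skip trailing slivers
                cid = f"{gid}_c{k:03d}"
                contigs.append(Contig(cid, seq[pos:end]))
                assignment[cid] = gid
                k += 1
            gap = int(rng.integers(int(gap_length * 0.5), int(gap_length * 1.5) + 1))
            pos = end + gap
    assembly = Assembly(contigs)
    return assembly, GoldStandard(assignment, assembly.lengths)


def corrupt_binning(
    gold: GoldStandard,
    dropout: float = 0.0,
    misassignment: float = 0.0,
    n_merges: int = 0,
    n_splits: int = 0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    label: str = "binning",
) -> BinSet:
    """Imperfect binning derived from the perfect per-genome partition.

    Emulates the error modes of real binners: each contig is dropped
    with probability ``dropout``; each survivor moves to a uniformly
    random other bin with probability ``misassignment``; then
    ``n_merges`` random pairs of bins are unioned and ``n_splits``
    random bins are bisected.
    """
    if not 0.0 <= dropout < 1.0 or not 0.0 <= misassignment < 1.0:
        raise ValueError("rates must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    bins: Dict[str, List[str]] = {g: [] for g in sorted(gold.genomes)}
    for cid in sorted(gold.assignment):
        if rng.random() < dropout:
            continue
        bins[gold.assignment[cid]].append(cid)
    names = sorted(bins)
    if len(names) > 1 and misassignment > 0.0:
        moves: List[Tuple[str, str]] = []
        for name in names:
            kept = []
            for cid in bins[name]:
                if rng.random() < misassignment:
                    others = [n for n in names if n != name]
                    moves.append((others[rng.integers(len(others))], cid))
                else:
                    kept.append(cid)
            bins[name] = kept
        for target, cid in moves:
            bins[target].append(cid)
    bins = {n: mem for n, mem in bins.items() if mem}
    for _ in range(n_merges):
        names = sorted(bins)
        if len(names) < 2:
            break
        i, j = rng.choice(len(names), size=2, replace=False)
        a, b = names[min(i, j)], names[max(i, j)]
        bins[f"{a}+{b}"] = bins.pop(a) + bins.pop(b)
    for _ in range(n_splits):
        names = sorted(n for n in bins if len(bins[n]) >= 2)
        if not names:
            break
        name = names[rng.integers(len(names))]
        members = list(bins.pop(name))
        rng.shuffle(members)
        half = len(members) // 2
        bins[f"{name}.s1"] = members[:half]
        bins[f"{name}.s2"] = members[half:]
    return BinSet(label, {n: mem for n, mem in bins.items() if mem}, provenance="input")


def simulate_reads(
    sequences: Mapping[str, str],
    depth: float = 20.0,
    read_length: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    error_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Tuple[List[ReadPair], float]:
    """Paired reads at a requested depth with i.i.d. substitution errors.

    Fragments start uniformly within each sequence; mate 1 is the
    fragment's left end, mate 2 the reverse complement of its right end.
    Sequences shorter than the read length are rejected.  Returns the
    pairs and the total sequenced bp of the sample.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pairs: List[ReadPair] = []
    total_bp = 0.0
    qual = "I" * read_length
    for sid in sorted(sequences):
        seq = sequences[sid]
        if len(seq) < read_length:
            raise ValueError(f"sequence {sid!r} shorter than the read length")
        n_pairs = int(round(depth * len(seq) / (2 * read_length)))
        for i in range(n_pairs):
            frag = int(round(rng.normal(insert_mean, insert_sd)))
            frag = min(max(frag, read_length), len(seq))
            start = int(rng.integers(0, len(seq) - frag + 1))
            fragment_seq = seq[start : start + frag]
            m1 = fragment_seq[:read_length]
            m2 = reverse_complement(fragment_seq[-read_length:])
            if error_rate > 0.0:
                m1 = _mutate_read(m1, error_rate, rng)
                m2 = _mutate_read(m2, error_rate, rng)
            pairs.append(ReadPair(f"{sid}_r{i:05d}", m1, m2, qual, qual))
            total_bp += 2 * read_length
    return pairs, total_bp


def _mutate_read(read: str, rate: float, rng: np.random.Generator) -> str:
    idx = _seq_to_idx(read)
    hits = rng.random(len(read)) < rate
    n = int(hits.sum())
    if n:
        idx[hits] = (idx[hits] + rng.integers(1, 4, n).astype(np.uint8)) % 4
    return _idx_to_seq(idx)


def make_community(
    n_unique: int = 10,
    n_common_pairs: int = 5,
    common_ani: float = 0.96,
    genome_length: int = 100_000,
    n_markers: int = 100,
    marker_length: int = 60,
    contig_median: int = 10_000,
    contig_sigma: float = 0.7,
    min_contig: int = 1_000,
    seed: int = 0,
) -> SyntheticCommunity:
    """Community of unique genomes plus strain pairs at a common ANI.

    The default mixed layout — 10 unique genomes and 5 pairs of common
    strains at ANI 0.96 (20 genomes total) — mirrors the mixture of
    closely and distantly related organisms in benchmark communities.
    """
    rng = np.random.default_rng(seed)
    base, catalog = simulate_genomes(
        n_unique + n_common_pairs,
        genome_length,
        n_markers,
        marker_length,
        rng=rng,
    )
    genomes: Dict[str, str] = {}
    ids = sorted(base)
    for gid in ids[:n_unique]:
        genomes[gid] = base[gid]
    for gid in ids[n_unique:]:
        genomes[f"{gid}a"] = base[gid]
        genomes[f"{gid}b"] = derive_strain(base[gid], common_ani, catalog, rng=rng)
    assembly, gold = fragment(
        genomes, contig_median, contig_sigma, min_contig, rng=rng
    )
    params = dict(
        n_unique=n_unique,
        n_common_pairs=n_common_pairs,
        common_ani=common_ani,
        genome_length=genome_length,
        n_markers=n_markers,
        marker_length=marker_length,
        contig_median=contig_median,
        contig_sigma=contig_sigma,
        min_contig=min_contig,
        seed=seed,
    )
    return SyntheticCommunity(genomes, catalog, assembly, gold, params)
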