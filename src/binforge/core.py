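"""Shared domain types for metagenomic bin sets over an assembly.

An *assembly* is a collection of named contigs; a *bin set* is a partial
partition of those contigs into named bins, each bin hypothesised to be a
draft genome (MAG).  These types carry no algorithmic logic; they enforce
the structural invariants every other module relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping

__all__ = [
    "Contig",
    "Assembly",
    "BinSet",
    "QualityMetrics",
    "GoldStandard",
    "gc_content",
    "reverse_complement",
    "UNBINNED",
]

#: sentinel bin name for a contig not assigned to any bin in a set
UNBINNED = "UNBINNED"

_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def gc_content(sequence: str) -> float:
    """GC fraction of a DNA sequence over {A, C, G, T, N}.

    N bases are excluded from both numerator and denominator; a sequence
    with no unambiguous bases has GC 0 by convention.

    Raises
    ------
    ValueError
        If the sequence is empty or contains characters outside ACGTN.
    """
    if not sequence:
        raise ValueError("cannot compute GC content of an empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)!r}")
    gc = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    return gc / denom if denom else 0.0


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """A named assembly sequence.

    ``length`` and ``gc`` are derived from the sequence; construction
    validates the alphabet.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be nonempty")
        # gc_content validates alphabet and nonemptiness as a side effect
        gc_content(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)


class Assembly:
    """An id -> :class:`Contig` mapping with unique ids.

    Thin mapping wrapper; exposes ``lengths`` (id -> bp) which most
    algorithms take as their working currency.
    """

    def __init__(self, contigs: Iterable[Contig]):
        self._contigs: Dict[str, Contig] = {}
        for c in contigs:
            if c.id in self._contigs:
                raise ValueError(f"duplicate contig id in assembly: {c.id!r}")
            self._contigs[c.id] = c

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "Assembly":
        return cls(Contig(cid, seq) for cid, seq in sequences.items())

    def __getitem__(self, cid: str) -> Contig:
        return self._contigs[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self._contigs

    def __iter__(self):
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    @property
    def ids(self):
        return self._contigs.keys()

    @property
    def lengths(self) -> Dict[str, int]:
        return {cid: c.length for cid, c in self._contigs.items()}

    @property
    def sequences(self) -> Dict[str, str]:
        return {cid: c.sequence for cid, c in self._contigs.items()}


_PROVENANCES = ("input", "hybrid", "refined", "reassembled")


class BinSet:
    """A partial partition of contigs into named bins.

    Each contig id appears in at most one bin; empty bins are rejected.
    When an assembly is supplied, membership of every contig in it is
    verified (a bin referring to an unknown contig is an error, not a
    silent pass-through).
    """

    def __init__(
        self,
        label: str,
        bins: Mapping[str, Iterable[str]],
        provenance: str = "input",
        assembly: Assembly | None = None,
    ):
        if provenance not in _PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        self.label = label
        self.provenance = provenance
        frozen: Dict[str, FrozenSet[str]] = {}
        owner: Dict[str, str] = {}
        for name, members in bins.items():
            mem = frozenset(members)
            if not mem:
                raise ValueError(f"bin {name!r} in set {label!r} is empty")
            for cid in mem:
                if cid in owner:
                    raise ValueError(
                        f"contig {cid!r} appears in bins {owner[cid]!r} and "
                        f"{name!r} of set {label!r}: not a partition"
                    )
                owner[cid] = name
            frozen[name] = mem
        if assembly is not None:
            missing = sorted(cid for cid in owner if cid not in assembly)
            if missing:
                raise ValueError(
                    f"bin set {label!r} refers to contigs absent from the "
                    f"assembly: {missing[:5]!r}{'...' if len(missing) > 5 else ''}"
                )
        self.bins: Dict[str, FrozenSet[str]] = frozen
        self._owner = owner

    def bin_of(self, contig_id: str) -> str:
        """Bin name of a contig, or :data:`UNBINNED`."""
        return self._owner.get(contig_id, UNBINNED)

    @property
    def binned_contigs(self) -> FrozenSet[str]:
        return frozenset(self._owner)

    def __len__(self) -> int:
        return len(self.bins)

    def __eq__(self, other) -> bool:
        return isinstance(other, BinSet) and self.bins == other.bins

    def __repr__(self) -> str:
        return (
            f"BinSet({self.label!r}, {len(self.bins)} bins, "
            f"{len(self._owner)} contigs, provenance={self.provenance!r})"
        )

    def same_partition(self, other: "BinSet") -> bool:
        """True when both sets induce the same grouping, ignoring bin names."""
        return set(self.bins.values()) == set(other.bins.values())


@dataclass
class QualityMetrics:
    """Per-bin quality estimate.

    completion and contamination are percentages; contamination may
    exceed 100 when markers occur in many extra copies.  ``marker_counts``
    is empty for gold-standard-derived estimates.
    """

    completion: float
    contamination: float
    n50: int
    total_length: int
    marker_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.completion <= 100.0:
            raise ValueError(f"completion out of [0, 100]: {self.completion}")
        if self.contamination < 0.0:
            raise ValueError(f"negative contamination: {self.contamination}")


class GoldStandard:
    """Known contig -> source-genome truth with per-genome assembly bp."""

    def __init__(self, assignment: Mapping[str, str], lengths: Mapping[str, int]):
        self.assignment: Dict[str, str] = dict(assignment)
        missing = sorted(c for c in self.assignment if c not in lengths)
        if missing:
            raise ValueError(f"no length for contigs: {missing[:5]!r}")
        self.genome_length: Dict[str, int] = {}
        for cid, gid in self.assignment.items():
            self.genome_length[gid] = self.genome_length.get(gid, 0) + lengths[cid]

    @property
    def genomes(self):
        return self.genome_length.keys()

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.assignment

    def __len__(self) -> int:
        return len(self.assignment)
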