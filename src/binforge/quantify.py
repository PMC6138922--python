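"""Bin abundance across samples and per-contig blob tables.

Coverage is *standardized* to reads-per-base per gigabase of sample
sequencing (raw mean coverage x 1e9 / sample bp), making samples of
different depth comparable.  Bin abundance is the length-weighted mean
of its member contigs' standardized coverages.  The blob table lists
every contig with its length, GC, mean standardized abundance, bin
membership and optional taxon — the substrate of GC-vs-abundance
scatter plots used to eyeball binning success.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import UNBINNED, Assembly, BinSet
from .reassemble import KmerIndex, ReadPair, best_alignment_mismatches, PERMISSIVE

__all__ = [
    "standardize_coverage",
    "standardize_table",
    "bin_abundance",
    "blob_table",
    "coverage_from_reads",
    "log_abundance",
]


def standardize_coverage(raw, sample_total_bp: float):
    """Scale raw mean coverage to per-Gbp-of-sample units."""
    if sample_total_bp <= 0:
        raise ValueError("sample total bp must be positive")
    return np.asarray(raw, dtype=float) * 1e9 / sample_total_bp if np.ndim(raw) else float(raw) * 1e9 / sample_total_bp


def standardize_table(
    coverage: pd.DataFrame, sample_sizes: Mapping[str, float]
) -> pd.DataFrame:
    """Column-wise standardization of a contig x sample coverage matrix."""
    out = coverage.astype(float).copy()
    for sample in out.columns:
        if sample not in sample_sizes:
            raise ValueError(f"no sequencing size for sample {sample!r}")
        out[sample] = standardize_coverage(out[sample].to_numpy(), sample_sizes[sample])
    return out


def bin_abundance(
    binset: BinSet,
    coverage: pd.DataFrame,
    lengths: Mapping[str, int],
    sample_sizes: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Length-weighted mean standardized coverage per (bin, sample).

    ``coverage`` is a contig x sample matrix of raw mean coverages when
    ``sample_sizes`` is given, or of already-standardized values when it
    is None.  Every binned contig must be present.
    """
    missing = sorted(binset.binned_contigs - set(coverage.index))
    if missing:
        raise ValueError(f"coverage table lacks binned contigs: {missing[:5]!r}")
    std = (
        standardize_table(coverage, sample_sizes) if sample_sizes is not None else coverage.astype(float)
    )
    rows = {}
    for name in sorted(binset.bins):
        members = sorted(binset.bins[name])
        w = np.array([lengths[c] for c in members], dtype=float)
        sub = std.loc[members]
        rows[name] = (sub.to_numpy() * w[:, None]).sum(axis=0) / w.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=std.columns)


def blob_table(
    assembly: Assembly,
    coverage: pd.DataFrame,
    binset: Optional[BinSet] = None,
    sample_sizes: Optional[Mapping[str, float]] = None,
    taxonomy: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-contig table (id, length, gc, abundance, bin, taxon).

    Abundance is the mean standardized coverage over samples; contigs
    outside any bin are labelled UNBINNED, contigs without a taxonomy
    annotation NA.  Rows are ordered by contig id.
    """
    std = (
        standardize_table(coverage, sample_sizes) if sample_sizes is not None else coverage.astype(float)
    )
    rows = []
    for cid in sorted(assembly.ids):
        contig = assembly[cid]
        abundance = float(std.loc[cid].mean()) if cid in std.index else np.nan
        rows.append(
            (
                cid,
                contig.length,
                contig.gc,
                abundance,
                binset.bin_of(cid) if binset is not None else UNBINNED,
                taxonomy.get(cid, "NA") if taxonomy else "NA",
            )
        )
    return pd.DataFrame(
        rows, columns=["contig", "length", "gc", "abundance", "bin", "taxon"]
    )


def coverage_from_reads(
    pairs: Sequence[ReadPair],
    sequences: Mapping[str, str],
    max_mismatches: int = PERMISSIVE.max_mismatches,
    k: int = 21,
) -> tuple[pd.Series, float]:
    """Mean per-base raw coverage of each contig from read placements.

    Each mate is placed at its best ungapped alignment (permissive
    mismatch budget by default); its length is credited to the placed
    contig.  Returns (per-contig coverage, total sequenced bp) — the
    latter is the standardization denominator for this sample.
    """
    index = KmerIndex(sequences, k)
    bases: Dict[str, float] = {cid: 0.0 for cid in sequences}
    total_bp = 0.0
    for pair in pairs:
        for mate in (pair.mate1, pair.mate2):
            total_bp += len(mate)
            placement = _best_placement(mate, index, max_mismatches)
            if placement is not None:
                bases[placement] += len(mate)
    cov = pd.Series(
        {cid: bases[cid] / len(seq) for cid, seq in sequences.items()}
    ).sort_index()
    return cov, total_bp


def _best_placement(read: str, index: KmerIndex, cap: int) -> Optional[str]:
    # re-runs the aligner per contig subset is wasteful; instead scan the
    # shared index and keep the contig of the best-scoring placement
    from .core import reverse_complement

    best_mm: Optional[int] = None
    best_cid: Optional[str] = None
    for seq in (read, reverse_complement(read)):
        n = len(seq)
        seen = set()
        for i in range(n - index.k + 1):
            for cid, pos in index.seeds(seq[i : i + index.k]):
                start = pos - i
                contig = index.sequences[cid]
                if start < 0 or start + n > len(contig) or (cid, start) in seen:
                    continue
                seen.add((cid, start))
                window = contig[start : start + n]
                mm = sum(a != b for a, b in zip(seq, window))
                if best_mm is None or mm < best_mm or (mm == best_mm and cid < best_cid):
                    best_mm, best_cid = mm, cid
                    if best_mm == 0:
                        break
            if best_mm == 0:
                break
        if best_mm == 0:
            break
    if best_mm is None or best_mm > cap:
        return None
    return best_cid


def log_abundance(abundance: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log10(abundance + pseudocount), the matrix heatmaps consume."""
    return np.log10(abundance + pseudocount)
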