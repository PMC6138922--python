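"""Readers and writers for the toolkit's on-disk conventions.

Bin sets live as directories of FASTA files (one file per bin, bin name
= file basename without extension); the assembly is a single FASTA;
membership, gold-standard, coverage and quality tables are plain TSV.
FASTA/FASTQ parsing goes through Biopython and tolerates wrapped,
unwrapped and CRLF records; FASTA output is wrapped at 80 columns.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from . import __version__
from .core import Assembly, BinSet
from .reassemble import ReadPair

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_assembly",
    "read_bin_directory",
    "write_bin_directory",
    "read_membership_tsv",
    "write_membership_tsv",
    "read_gold_tsv",
    "write_gold_tsv",
    "read_coverage_tsv",
    "read_fastq_paired",
    "write_fastq_pairs",
    "write_report",
    "write_run_config",
]

logger = logging.getLogger(__name__)

_FASTA_SUFFIXES = (".fa", ".fasta", ".fna")


def read_fasta(path) -> Dict[str, str]:
    """id -> sequence; ids are the header up to the first whitespace."""
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path, records: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid in records:
            fh.write(f">{rid}\n")
            seq = records[rid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_assembly(path) -> Assembly:
    return Assembly.from_sequences(read_fasta(path))


def read_bin_directory(
    path, assembly: Optional[Assembly] = None, label: Optional[str] = None
) -> BinSet:
    """Bin set from a directory of FASTA files (one file per bin)."""
    path = Path(path)
    bins: Dict[str, list] = {}
    for fa in sorted(p for p in path.iterdir() if p.suffix in _FASTA_SUFFIXES):
        ids = list(read_fasta(fa))
        if ids:
            bins[fa.stem] = ids
    if not bins:
        warnings.warn(f"no bins found in {path}", stacklevel=2)
    return BinSet(label or path.name, bins, provenance="input", assembly=assembly)


def write_bin_directory(binset: BinSet, sequences: Mapping[str, str], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in sorted(binset.bins):
        write_fasta(
            outdir / f"{name}.fa",
            {cid: sequences[cid] for cid in sorted(binset.bins[name])},
        )


def read_membership_tsv(path, label: Optional[str] = None) -> BinSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    bins: Dict[str, list] = {}
    for cid, name in zip(df["contig_id"], df["bin_name"]):
        bins.setdefault(name, []).append(cid)
    return BinSet(label or Path(path).stem, bins)


def write_membership_tsv(binset: BinSet, path) -> None:
    rows = [
        (cid, name)
        for name in sorted(binset.bins)
        for cid in sorted(binset.bins[name])
    ]
    pd.DataFrame(rows, columns=["contig_id", "bin_name"]).to_csv(
        path, sep="\t", index=False
    )


def read_gold_tsv(path, lengths: Mapping[str, int]):
    from .core import GoldStandard

    df = pd.read_csv(path, sep="\t", dtype=str)
    return GoldStandard(dict(zip(df["contig_id"], df["genome_id"])), lengths)


def write_gold_tsv(gold, path) -> None:
    rows = sorted(gold.assignment.items())
    pd.DataFrame(rows, columns=["contig_id", "genome_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_coverage_tsv(path) -> pd.DataFrame:
    """Contig x sample coverage matrix from wide or long TSV.

    Long format has columns (contig, sample, mean_cov); anything else is
    treated as wide with contig ids in the first column.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) == ["contig", "sample", "mean_cov"]:
        return df.pivot(index="contig", columns="sample", values="mean_cov").fillna(0.0)
    return df.set_index(df.columns[0]).astype(float)


def read_fastq_paired(r1_path, r2_path) -> list:
    """Read pairs from two synchronised FASTQ files."""
    out = []
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(it1, it2):
        out.append(
            ReadPair(
                rec1.id.removesuffix("/1"),
                str(rec1.seq).upper(),
                str(rec2.seq).upper(),
                "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"]),
                "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fastq_pairs(pairs: Sequence[ReadPair], r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            q1 = p.qual1 or "I" * len(p.mate1)
            q2 = p.qual2 or "I" * len(p.mate2)
            f1.write(f"@{p.id}/1\n{p.mate1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.mate2}\n+\n{q2}\n")


def write_report(df: pd.DataFrame, path) -> None:
    """TSV with fixed column order, floats at 2 decimals, stable rows."""
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def write_run_config(outdir, params: Mapping) -> None:
    """Machine-readable copy of the resolved run configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"tool": "binforge", "version": __version__, "params": dict(params)}
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
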