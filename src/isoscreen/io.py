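"""Readers and writers for the plain-text formats used across the pipeline.

Promoters travel as BED6 with ``promoter_id;gene_id;label`` packed into the
name field, signal tracks as bedGraph, genomes as FASTA (via pyfaidx), and
tables as TSV.  Coordinates are BED-style 0-based half-open throughout; a TSS
is a single 0-based position.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pyfaidx

log = logging.getLogger(__name__)


class BedGraphParseError(ValueError):
    """Raised with the offending 1-based line number on malformed input."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an in-memory ``{name: sequence}`` dict.

    Genomes in this pipeline are small (synthetic or promoter-window scale);
    pyfaidx handles indexing and header parsing.
    """
    fa = pyfaidx.Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_promoter_bed(path: str | Path):
    """Read promoters from BED6; name packs ``promoter_id;gene_id[;label]``."""
    from isoscreen.promoters import PromoterRecord

    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6, got {len(fields)} fields")
            chrom, start, _end, name, _score, strand = fields[:6]
            parts = name.split(";")
            promoter_id = parts[0]
            gene_id = parts[1] if len(parts) > 1 else parts[0]
            label = parts[2] if len(parts) > 2 else None
            records.append(
                PromoterRecord(
                    promoter_id=promoter_id,
                    gene_id=gene_id,
                    chrom=chrom,
                    tss=int(start),
                    strand=strand,
                    label=label,
                )
            )
    return records


def write_promoter_bed(promoters: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            name = f"{p.promoter_id};{p.gene_id}" + (f";{p.label}" if p.label else "")
            fh.write(f"{p.chrom}\t{p.tss}\t{p.tss + 1}\t{name}\t0\t{p.strand}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Parse bedGraph into ``(chrom, start, end, value)`` tuples.

    Malformed lines raise :class:`BedGraphParseError` carrying the line number.
    """
    intervals: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise BedGraphParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedGraphParseError(f"{path}:{lineno}: {exc}") from exc
            if end < start:
                raise BedGraphParseError(f"{path}:{lineno}: end < start")
            intervals.append((chrom, start, end, value))
    return intervals


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes
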