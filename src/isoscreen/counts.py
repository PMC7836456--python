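"""Pooled-screen read deconvolution and per-guide depletion scores.

Reads from each screen sample (the plasmid DNA pool and the day-21
replicates) are assigned to library guides by exact — optionally
1-mismatch — matching of the extracted 20-mer spacer.  Counts are
normalized by median-ratio size factors and each day-21 sample is compared
to the DNA pool as a log2 fold change; depletion (negative lfc) marks
guides whose cells dropped out of the pool.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from isoscreen.design import GuideLibrary

log = logging.getLogger(__name__)

SPACER_LEN = 20
PREFIX_SCAN = -1  # spacer_start sentinel: scan for the constant vector prefix
VECTOR_PREFIX = "CACCG"


class FastqParseError(ValueError):
    """Raised with the 0-based record index of a truncated/malformed record."""


@dataclass
class CountMatrix:
    """Guides x samples integer counts with a designated reference sample."""

    counts: pd.DataFrame
    reference: str
    unassigned: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.reference not in self.counts.columns:
            raise KeyError(f"reference sample {self.reference!r} not in count matrix")
        vals = self.counts.values
        if (vals < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "guide_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, reference: str) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="guide_id")
        return cls(counts=df, reference=reference)


def _fastq_records(path: str | Path) -> Iterator[str]:
    """Yield read sequences; raises :class:`FastqParseError` on truncation."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            if not header.startswith("@"):
                raise FastqParseError(f"record {idx}: header does not start with '@'")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not seq or not plus or not qual:
                raise FastqParseError(f"record {idx}: truncated record")
            if not plus.startswith("+"):
                raise FastqParseError(f"record {idx}: missing '+' separator")
            yield seq.strip().upper()
            idx += 1


def _extract_spacer(read: str, spacer_start: int) -> str | None:
    if spacer_start == PREFIX_SCAN:
        i = read.find(VECTOR_PREFIX)
        if i < 0:
            return None
        start = i + len(VECTOR_PREFIX)
    else:
        start = spacer_start
    if start + SPACER_LEN > len(read):
        return None
    return read[start : start + SPACER_LEN]


def _one_mismatch_index(spacers: Sequence[str]) -> dict[str, str | None]:
    """Map every 1-mismatch variant to its guide spacer; collisions map to None."""
    index: dict[str, str | None] = {}
    for sp in spacers:
        for i in range(SPACER_LEN):
            for b in "ACGT":
                if b == sp[i]:
                    continue
                variant = sp[:i] + b + sp[i + 1 :]
                if variant in index and index[variant] != sp:
                    index[variant] = None  # ambiguous between >= 2 guides
                else:
                    index.setdefault(variant, sp)
    return index


def deconvolve(
    reads: str | Path | Iterable[str],
    library: GuideLibrary | Sequence[str] | pd.DataFrame,
    spacer_start: int = 0,
    mismatches: int = 0,
) -> tuple[pd.Series, int]:
    """Assign reads to guides; returns (per-guide counts, unassigned count).

    ``reads`` is a FASTQ path (optionally gzipped) or an iterable of read
    sequences.  The spacer is extracted at a fixed position, or located by
    scanning for the constant vector prefix when ``spacer_start`` is -1.
    At ``mismatches=1`` a read matching exactly one guide at Hamming
    distance 1 is assigned to it; variants ambiguous between guides are
    discarded as unassigned.  Exact matches always win.
    """
    if mismatches not in (0, 1):
        raise ValueError(f"mismatches must be 0 or 1, got {mismatches}")
    if spacer_start < 0 and spacer_start != PREFIX_SCAN:
        raise ValueError(f"spacer_start must be >= 0 or -1 (prefix scan), got {spacer_start}")

    if isinstance(library, GuideLibrary):
        lib_df = library.to_frame()
        spacers = list(lib_df["spacer"])
        guide_ids = list(lib_df["guide_id"])
    elif isinstance(library, pd.DataFrame):
        spacers = list(library["spacer"])
        guide_ids = list(library["guide_id"])
    else:
        spacers = list(library)
        guide_ids = list(library)
    if len(set(spacers)) != len(spacers):
        raise ValueError("library spacers are not unique")
    spacer_to_guide = dict(zip(spacers, guide_ids))
    mm_index = _one_mismatch_index(spacers) if mismatches == 1 else {}

    counts = {gid: 0 for gid in guide_ids}
    unassigned = 0
    read_iter = _fastq_records(reads) if isinstance(reads, (str, Path)) else iter(reads)
    for read in read_iter:
        extracted = _extract_spacer(read.upper(), spacer_start)
        hit = None
        if extracted is not None:
            if extracted in spacer_to_guide:
                hit = spacer_to_guide[extracted]
            elif mismatches == 1:
                sp = mm_index.get(extracted)
                hit = spacer_to_guide[sp] if sp is not None else None
        if hit is None:
            unassigned += 1
        else:
            counts[hit] += 1
    return pd.Series(counts, name="count"), unassigned


def size_factors_median_ratio(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-ratio size factors, rescaled to geometric mean 1.

    factor_s = median over guides with positive geometric mean of
    counts[g, s] / geomean_g(counts[g, .]); a sample with all-zero counts
    is an error.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = df.values.astype(float)
    zero_samples = df.columns[(vals.sum(axis=0) == 0)]
    if len(zero_samples):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero_samples)}")
    with np.errstate(divide="ignore"):
        loggeo = np.log(vals).mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError("no guide has positive counts in every sample")
    ratios = vals[usable] / np.exp(loggeo[usable])[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=df.columns, name="size_factor")


def guide_lfc(
    counts: CountMatrix,
    samples: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """log2 fold change of each sample vs the reference (DNA pool).

    lfc = log2((counts[g, s]/factor_s + pc) / (counts[g, ref]/factor_ref + pc)).
    Returns a guides x samples frame plus a ``mean`` convenience column when
    several samples are scored.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    if samples is None:
        samples = [s for s in counts.sample_ids if s != counts.reference]
    for s in samples:
        if s not in counts.counts.columns:
            raise KeyError(f"unknown sample {s!r}")
    factors = size_factors_median_ratio(counts) if size_factors is None else size_factors
    norm = counts.counts / factors
    ref = norm[counts.reference]
    out = pd.DataFrame(index=counts.guide_ids)
    for s in samples:
        out[s] = np.log2((norm[s] + pseudocount) / (ref + pseudocount))
    if len(samples) > 1:
        out["mean"] = out[list(samples)].mean(axis=1)
    return out


def guide_score_table(
    counts: CountMatrix,
    samples: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Long per-guide score table: guide_id, sample_id, lfc, rank, norm_rank.

    Ranks are ascending within a sample (most depleted = rank 1), tie-broken
    by guide_id so they form a strict permutation of 1..G; norm_rank = rank/G.
    """
    lfc = guide_lfc(counts, samples=samples, pseudocount=pseudocount)
    sample_cols = [c for c in lfc.columns if c != "mean"]
    G = len(lfc)
    rows = []
    for s in sample_cols:
        order = np.lexsort((lfc.index.values.astype(str), lfc[s].values))
        rank = np.empty(G, dtype=np.int64)
        rank[order] = np.arange(1, G + 1)
        rows.append(
            pd.DataFrame(
                {
                    "guide_id": lfc.index,
                    "sample_id": s,
                    "lfc": lfc[s].values,
                    "rank": rank,
                    "norm_rank": rank / G,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
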