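"""Calling gained and lost promoter-driven isoforms from H3K4me3 signal.

A gene may use several alternative promoters, each driving a distinct
transcript isoform.  H3K4me3 marks active promoters, so comparing its
abundance between a tumour and the patient-matched adjacent normal tissue
reads out promoter gain and loss — and hence cancer-specific isoform usage.

The caller works on per-promoter signal pairs: a per-pair log2 fold change
(with a pseudocount), a recurrence rule (a promoter is *gained* when it is
up at least 2-fold in at least ``min_pairs`` patients and gained pairs
outnumber lost pairs; *lost* symmetrically), and an expression gate
(isoform FPKM >= 5 by default) that yields the screen's target set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GAINED = "gained"
LOST = "lost"
UNALTERED = "unaltered"


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter-driven transcript isoform.

    ``tss`` is a single 0-based genomic position; ``label`` carries the
    field's customary promoter names ("P1", "P2", ...).
    """

    promoter_id: str
    gene_id: str
    chrom: str
    tss: int
    strand: str
    label: str | None = None

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError(f"{self.promoter_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.promoter_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass
class SignalPairTable:
    """Per-promoter H3K4me3 signal for paired tumour/normal samples.

    Both frames are promoters x pairs with identical index and columns;
    values are nonnegative coverage-like reals.
    """

    tumour: pd.DataFrame
    normal: pd.DataFrame

    def __post_init__(self):
        if not self.tumour.index.equals(self.normal.index):
            raise ValueError("tumour/normal promoter indexes differ")
        if list(self.tumour.columns) != list(self.normal.columns):
            raise ValueError(
                "tumour/normal sample pairs are not aligned: "
                f"{list(self.tumour.columns)} vs {list(self.normal.columns)}"
            )
        if (self.tumour.values < 0).any() or (self.normal.values < 0).any():
            raise ValueError("negative signal values")
        if not self.tumour.index.is_unique:
            raise ValueError("duplicate promoter_ids in signal table")

    @property
    def n_pairs(self) -> int:
        return self.tumour.shape[1]

    @property
    def promoter_ids(self) -> pd.Index:
        return self.tumour.index

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "SignalPairTable":
        """Build from a long table with columns promoter_id, sample_id, tumour, normal."""
        required = {"promoter_id", "sample_id", "tumour", "normal"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"signal table missing columns: {sorted(missing)}")
        tum = df.pivot(index="promoter_id", columns="sample_id", values="tumour")
        nor = df.pivot(index="promoter_id", columns="sample_id", values="normal")
        if tum.isna().any().any() or nor.isna().any().any():
            raise ValueError("signal table is not complete over promoter x sample pairs")
        return cls(tumour=tum, normal=nor)

    @classmethod
    def from_tsv(cls, path) -> "SignalPairTable":
        return cls.from_long(pd.read_csv(path, sep="\t"))


def compute_pair_log2fc(signals: SignalPairTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-pair log2((tumour + pc) / (normal + pc)), promoters x pairs.

    The pseudocount keeps the ratio finite at zero coverage and damps fold
    changes at very low signal.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    return np.log2((signals.tumour + pseudocount) / (signals.normal + pseudocount))


def call_status(
    log2fc_per_pair: Sequence[float], fc_threshold: float = 1.0, min_pairs: int = 2
) -> tuple[str, int, int]:
    """Classify one promoter from its per-pair log2 fold changes.

    A pair counts as gained when log2fc >= ``fc_threshold`` and lost when
    <= -threshold.  Status is gained when gained pairs reach ``min_pairs``
    AND outnumber lost pairs (the majority rule prevents a promoter being
    simultaneously gained and lost); lost symmetrically; else unaltered.

    Returns ``(status, n_gained_pairs, n_lost_pairs)``.
    """
    fc = np.asarray(log2fc_per_pair, dtype=float)
    if fc.size == 0:
        raise ValueError("empty log2fc vector")
    if fc_threshold <= 0:
        raise ValueError(f"fc_threshold must be > 0, got {fc_threshold}")
    if min_pairs < 1:
        raise ValueError(f"min_pairs must be >= 1, got {min_pairs}")
    n_gained = int((fc >= fc_threshold).sum())
    n_lost = int((fc <= -fc_threshold).sum())
    if n_gained >= min_pairs and n_gained > n_lost:
        return GAINED, n_gained, n_lost
    if n_lost >= min_pairs and n_lost > n_gained:
        return LOST, n_gained, n_lost
    return UNALTERED, n_gained, n_lost


def call_promoters(
    signals: SignalPairTable,
    fc_threshold: float = 1.0,
    min_pairs: int = 2,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Vectorised caller over a whole signal table.

    Returns a frame indexed by promoter_id with mean_log2fc,
    n_gained_pairs, n_lost_pairs and status.
    """
    if fc_threshold <= 0:
        raise ValueError(f"fc_threshold must be > 0, got {fc_threshold}")
    if min_pairs < 1:
        raise ValueError(f"min_pairs must be >= 1, got {min_pairs}")
    fc = compute_pair_log2fc(signals, pseudocount=pseudocount)
    n_gained = (fc.values >= fc_threshold).sum(axis=1)
    n_lost = (fc.values <= -fc_threshold).sum(axis=1)
    status = np.where(
        (n_gained >= min_pairs) & (n_gained > n_lost),
        GAINED,
        np.where((n_lost >= min_pairs) & (n_lost > n_gained), LOST, UNALTERED),
    )
    return pd.DataFrame(
        {
            "mean_log2fc": fc.values.mean(axis=1),
            "n_gained_pairs": n_gained.astype(int),
            "n_lost_pairs": n_lost.astype(int),
            "status": status,
        },
        index=fc.index,
    )


def select_screen_targets(
    calls: pd.DataFrame,
    expression: Mapping[str, float] | pd.Series | None = None,
    min_fpkm: float = 5.0,
) -> pd.DataFrame:
    """Gate called promoters by isoform expression.

    ``selected`` is True when status is gained or lost AND expression (FPKM)
    is >= ``min_fpkm`` — the boundary is inclusive.  Expression may already
    be a column of ``calls`` or supplied separately; promoters with no
    expression value are treated as unexpressed (0) and logged.
    """
    out = calls.copy()
    if expression is not None:
        expr = pd.Series(expression, dtype=float).reindex(out.index)
    elif "expression" in out.columns:
        expr = out["expression"].astype(float)
    else:
        raise ValueError("no expression column and no expression table supplied")
    n_missing = int(expr.isna().sum())
    if n_missing:
        log.warning("%d promoters have no expression value; treated as FPKM 0", n_missing)
        expr = expr.fillna(0.0)
    out["expression"] = expr
    out["selected"] = (out["status"] != UNALTERED) & (expr >= min_fpkm)
    log.info("selected %d / %d promoters", int(out["selected"].sum()), len(out))
    return out


def aggregate_track_to_promoters(
    intervals: Sequence[tuple[str, int, int, float]],
    promoters: Sequence[PromoterRecord],
    flank: int = 500,
) -> pd.Series:
    """Sum a bedGraph-style track over TSS windows.

    For each promoter the window is ``[tss - flank, tss + flank)`` (0-based
    half-open) and the summary is sum(value * overlap width).  Promoters on
    chromosomes absent from the track get 0 with a warning.  Intervals are
    assumed non-overlapping per chromosome (bedGraph contract).
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {iv[0] for iv in intervals}:
        ivs = sorted((s, e, v) for c, s, e, v in intervals if c == chrom)
        starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
        vals = np.array([v for _, _, v in ivs], dtype=float)
        by_chrom[chrom] = (starts, ends, vals)

    out = {}
    missing_chroms = set()
    for p in promoters:
        lo, hi = p.tss - flank, p.tss + flank
        if p.chrom not in by_chrom:
            missing_chroms.add(p.chrom)
            out[p.promoter_id] = 0.0
            continue
        starts, ends, vals = by_chrom[p.chrom]
        # intervals overlapping [lo, hi): start < hi and end > lo
        i = np.searchsorted(ends, lo, side="right")
        j = np.searchsorted(starts, hi, side="left")
        if i >= j:
            out[p.promoter_id] = 0.0
            continue
        ov = np.minimum(ends[i:j], hi) - np.maximum(starts[i:j], lo)
        ov = np.clip(ov, 0, None)
        out[p.promoter_id] = float((ov * vals[i:j]).sum())
    if missing_chroms:
        log.warning(
            "track has no data for chromosome(s) %s; affected promoters set to 0",
            ", ".join(sorted(missing_chroms)),
        )
    return pd.Series(out, name="signal")
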