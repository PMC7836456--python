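"""Post-score hit filtering: from per-line essentiality calls to the final
cancer-specific isoform dependency list.

Four successive filters mirror the screen's analysis cascade:

1. pan-essential exclusion — transcripts of genes lethal in >90% of DepMap
   cell lines are annotated and removed from candidate hits (they are
   housekeeping dependencies, not cancer-specific biology);
2. multi-line intersection — transcripts essential (FDR <= cutoff) in at
   least ``min_lines`` cancer lines, the normal line excluded from the
   count;
3. bidirectional-promoter off-target removal — CRISPRi at one TSS also
   silences any TSS within ~2 kb, so a hit whose nearest other TSS is
   closer than ``max_distance`` and belongs to a pan-essential gene is
   cleared (it most likely scored through the neighbour);
4. normal-line contrast — remaining hits are prioritised by breadth across
   cancer lines and selectivity against the non-transformed line.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from isoscreen.promoters import PromoterRecord

log = logging.getLogger(__name__)

UNASSESSED = "unassessed"


def flag_pan_essential(scores: pd.DataFrame, pan_list: Iterable[str]) -> pd.Series:
    """Gene-level pan-essential flags for a score table.

    Matching is exact on gene_id (DepMap dependencies are gene-level);
    case-insensitive near-misses are logged but NOT flagged, so symbol-case
    discrepancies surface in the log instead of silently changing calls.
    """
    pan = set(pan_list)
    if not pan:
        log.warning("empty pan-essential list; no transcripts flagged")
        return pd.Series(False, index=scores.index)
    flags = scores["gene_id"].isin(pan)
    lower_pan = {g.lower() for g in pan}
    near = scores.loc[~flags, "gene_id"]
    near_misses = sorted(set(near[near.str.lower().isin(lower_pan)]))
    for g in near_misses:
        log.warning("gene %r matches a pan-essential symbol only case-insensitively; not flagged", g)
    return flags


def intersect_lines(
    scores_by_line: Mapping[str, pd.DataFrame],
    fdr_cutoff: float = 0.1,
    min_lines: int = 2,
    normal_line: str | None = None,
    pan_list: Iterable[str] = (),
    include_normal: bool = False,
) -> pd.DataFrame:
    """Build the hit table by intersecting per-line essentiality calls.

    Each value of ``scores_by_line`` is a transcript score table (from
    :func:`isoscreen.rra.score_transcripts`).  A transcript's ``essential_in``
    set collects the cancer lines where fdr <= cutoff; the normal line is
    recorded separately (``normal_line_essential``) and excluded from
    ``n_lines`` unless ``include_normal``.  Promoter universes that differ
    between lines are united, absent treated as not essential (logged).

    Returns one row per promoter seen in any line, with n_lines >= 1 rows
    carrying candidate hits and ``multi_line`` marking n_lines >= min_lines.
    """
    if not scores_by_line:
        raise ValueError("at least one scored cell line is required")
    pan = set(pan_list)
    cancer_lines = [
        ln for ln in scores_by_line if include_normal or ln != normal_line
    ]

    universes = {ln: set(df["promoter_id"]) for ln, df in scores_by_line.items()}
    union = sorted(set().union(*universes.values()))
    for ln, uni in universes.items():
        absent = len(union) - len(uni)
        if absent:
            log.warning("line %s is missing %d promoters present elsewhere; treated as not essential", ln, absent)

    ess: dict[str, set[str]] = {p: set() for p in union}
    fdr_min: dict[str, float] = {p: np.inf for p in union}
    genes: dict[str, str] = {}
    normal_ess: set[str] = set()
    for ln, df in scores_by_line.items():
        for row in df.itertuples(index=False):
            pid = str(row.promoter_id)
            genes.setdefault(pid, str(row.gene_id))
            if row.fdr <= fdr_cutoff:
                if ln == normal_line:
                    normal_ess.add(pid)
                if ln in cancer_lines:
                    ess[pid].add(ln)
                    fdr_min[pid] = min(fdr_min[pid], float(row.fdr))

    out = pd.DataFrame(
        {
            "promoter_id": union,
            "gene_id": [genes.get(p, "") for p in union],
            "essential_in": [",".join(sorted(ess[p])) for p in union],
            "n_lines": [len(ess[p]) for p in union],
            "min_fdr": [fdr_min[p] for p in union],
            "normal_line_essential": [p in normal_ess for p in union],
        }
    )
    out["pan_essential"] = flag_pan_essential(out, pan)
    out["multi_line"] = out["n_lines"] >= min_lines
    out["bidirectional_partner"] = pd.Series([None] * len(out), dtype=object)
    out["partner_distance"] = np.nan
    out["partner_pan_essential"] = False
    out["final_hit"] = (out["n_lines"] >= 1) & ~out["pan_essential"]
    return out


def bidirectional_filter(
    hits: pd.DataFrame,
    all_tss: Sequence[PromoterRecord],
    max_distance: int = 2000,
    pan_list: Iterable[str] = (),
) -> pd.DataFrame:
    """Flag hits whose TSS lies within ``max_distance`` bp of another TSS.

    Distance is TSS-to-TSS, strand-agnostic, with strict inequality at
    ``max_distance``; ``max_distance=0`` disables the filter entirely.
    ``all_tss`` should be a genome-wide annotation, not just library
    promoters.  When the nearest partner's gene is pan-essential the hit is
    cleared (``final_hit`` False) — CRISPRi at the hit TSS silences the
    essential neighbour, so the depletion is off-target.  Hits whose
    promoter is absent from the annotation are retained and marked
    ``unassessed``.
    """
    if max_distance < 0:
        raise ValueError(f"max_distance must be >= 0, got {max_distance}")
    pan = set(pan_list)
    by_id = {p.promoter_id: p for p in all_tss}
    by_chrom: dict[str, list[PromoterRecord]] = {}
    for p in all_tss:
        by_chrom.setdefault(p.chrom, []).append(p)
    pos_by_chrom = {
        c: (np.array([p.tss for p in sorted(ps, key=lambda q: q.tss)]),
            [p for p in sorted(ps, key=lambda q: q.tss)])
        for c, ps in by_chrom.items()
    }
    gene_of = {p.promoter_id: p.gene_id for p in all_tss}

    out = hits.copy()
    partners: list[str | None] = []
    distances: list[float] = []
    partner_pan: list[bool] = []
    assessed: list[bool] = []
    for pid in out["promoter_id"]:
        rec = by_id.get(pid)
        if rec is None or max_distance == 0:
            partners.append(None)
            distances.append(np.nan)
            partner_pan.append(False)
            assessed.append(rec is not None)
            if rec is None:
                log.warning("promoter %s absent from the TSS annotation; bidirectional filter %s", pid, UNASSESSED)
            continue
        positions, records = pos_by_chrom[rec.chrom]
        best: tuple[int, PromoterRecord] | None = None
        i = int(np.searchsorted(positions, rec.tss))
        for j in range(max(0, i - 2), min(len(records), i + 3)):
            other = records[j]
            if other.promoter_id == pid:
                continue
            d = abs(other.tss - rec.tss)
            if best is None or d < best[0]:
                best = (d, other)
        if best is not None and best[0] < max_distance:
            partners.append(best[1].promoter_id)
            distances.append(float(best[0]))
            partner_pan.append(gene_of[best[1].promoter_id] in pan)
        else:
            partners.append(None)
            distances.append(np.nan)
            partner_pan.append(False)
        assessed.append(True)
    out["bidirectional_partner"] = pd.Series(partners, index=out.index, dtype=object)
    out["partner_distance"] = distances
    out["partner_pan_essential"] = partner_pan
    out["bidirectional_assessed"] = assessed
    out["final_hit"] = out["final_hit"] & ~out["partner_pan_essential"]
    return out


def contrast_normal(hits: pd.DataFrame, normal_scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Prioritise hits against the non-transformed line.

    Ordering: breadth across cancer lines (descending), then not-essential-
    in-normal first, then best FDR.  ``gc_selective`` marks final hits that
    do not score in the normal line.  ``normal_scores`` may refresh the
    ``normal_line_essential`` column when supplied.
    """
    out = hits.copy()
    if normal_scores is not None and len(normal_scores):
        normal_ess = set(
            normal_scores.loc[normal_scores["essential"], "promoter_id"].astype(str)
        )
        out["normal_line_essential"] = out["promoter_id"].isin(normal_ess)
    out = out.sort_values(
        by=["n_lines", "normal_line_essential", "min_fdr", "promoter_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["gc_selective"] = out["final_hit"] & ~out["normal_line_essential"]
    return out


def cascade_summary(hits: pd.DataFrame, min_lines: int = 2) -> dict[str, int]:
    """Counts at each filter stage (the screen's N -> M -> K hit cascade)."""
    candidates = hits[(hits["n_lines"] >= 1) & ~hits["pan_essential"]]
    multi = candidates[candidates["n_lines"] >= min_lines]
    flagged = candidates[candidates["bidirectional_partner"].notna()]
    removed = candidates[candidates["partner_pan_essential"]]
    final = hits[hits["final_hit"]]
    summary = {
        "scored_promoters": int(len(hits)),
        "essential_ge1_line": int(len(candidates)),
        f"essential_ge{min_lines}_lines": int(len(multi)),
        "bidirectional_flagged": int(len(flagged)),
        "removed_pan_partner": int(len(removed)),
        "final_hits": int(len(final)),
        "final_multi_line": int((final["n_lines"] >= min_lines).sum()),
    }
    if "gc_selective" in hits.columns:
        summary["gc_selective"] = int(hits["gc_selective"].sum())
    return summary
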