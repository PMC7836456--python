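"""Transcript-level essentiality by alpha-robust rank aggregation.

Each promoter-driven transcript is scored from the normalized ranks of its
guides in the depletion-ordered guide list.  The rho statistic asks how
improbable the transcript's best ranks are under uniformity, restricted to
ranks below a fraction ``alpha`` of the list: with sorted normalized ranks
r(1) <= ... <= r(n),

    rho = min over { j : r(j) <= alpha } of  Pr[ Binomial(n, r(j)) >= j ],

i.e. the smallest tail probability that at least j of n uniform ranks fall
below r(j); rho = 1 when no rank clears alpha.  Significance comes from a
permutation null (guide ranks resampled uniformly), the add-one estimator
p = (1 + #{null rho <= observed}) / (n_perm + 1), and Benjamini-Hochberg
FDR across transcripts; transcripts with FDR <= 0.1 are called essential.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DIRECTION_DEPLETION = "depletion"
DIRECTION_ENRICHMENT = "enrichment"


def rho_statistic(norm_ranks: Sequence[float], alpha: float = 0.25) -> float:
    """Alpha-restricted robust-rank-aggregation score of one guide set."""
    r = np.sort(np.asarray(norm_ranks, dtype=float))
    if r.size == 0:
        raise ValueError("empty rank vector")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("normalized ranks must lie in (0, 1]")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    n = r.size
    eligible = r <= alpha
    if not eligible.any():
        return 1.0
    j = np.arange(1, n + 1)[eligible]
    # Pr[Binomial(n, r(j)) >= j] = sf(j - 1)
    p = stats.binom.sf(j - 1, n, r[eligible])
    return float(min(p.min(), 1.0))


def _rho_matrix(ranks: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorised rho over a (draws x n) matrix of normalized ranks."""
    r = np.sort(ranks, axis=1)
    n = r.shape[1]
    j = np.arange(1, n + 1)
    p = stats.binom.sf(j - 1, n, r)
    p = np.where(r <= alpha, p, np.inf)
    rho = p.min(axis=1)
    return np.where(np.isfinite(rho), np.minimum(rho, 1.0), 1.0)


def permutation_null(
    n_guides: int,
    G: int,
    alpha: float = 0.25,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null rho distribution for a set of ``n_guides`` among ``G`` guides.

    Each draw samples ``n_guides`` ranks uniformly without replacement from
    {1..G}/G and computes rho.  Deterministic given the seed.
    """
    if n_guides > G:
        raise ValueError(f"n_guides ({n_guides}) exceeds total guides ({G})")
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_guides == G:
        full = (np.arange(1, G + 1) / G)[None, :]
        return np.full(n_perm, _rho_matrix(full, alpha)[0])
    draws = np.empty((n_perm, n_guides), dtype=float)
    for i in range(n_perm):
        draws[i] = rng.choice(G, size=n_guides, replace=False) + 1
    draws /= G
    return _rho_matrix(draws, alpha)


class _NullCache:
    """Per-``n_guides`` cache of null rho distributions within one scoring run."""

    def __init__(self, G: int, alpha: float, n_perm: int, rng: np.random.Generator):
        self.G, self.alpha, self.n_perm, self.rng = G, alpha, n_perm, rng
        self._cache: dict[int, np.ndarray] = {}

    def get(self, n_guides: int) -> np.ndarray:
        if n_guides not in self._cache:
            self._cache[n_guides] = np.sort(
                permutation_null(n_guides, self.G, self.alpha, self.n_perm, self.rng)
            )
        return self._cache[n_guides]


def normalized_ranks(lfc: pd.DataFrame, direction: str = DIRECTION_DEPLETION) -> pd.DataFrame:
    """Per-column normalized ranks of a guides x samples lfc frame.

    Depletion ranks ascend with lfc (most depleted = rank 1); enrichment
    ranks descend.  Ties take the average (mid)rank so tied guides stay
    exchangeable — a fully tied column gives every guide norm rank
    ~0.5 and no transcript can score.  Deterministic in the values alone.
    """
    cols = [c for c in lfc.columns if c != "mean"]
    G = len(lfc)
    out = pd.DataFrame(index=lfc.index)
    for c in cols:
        vals = lfc[c].values if direction == DIRECTION_DEPLETION else -lfc[c].values
        out[c] = stats.rankdata(vals, method="average") / G
    return out


def score_transcripts(
    lfc: pd.DataFrame,
    guide_map: Mapping[str, tuple[str, str]] | pd.DataFrame,
    alpha: float = 0.25,
    n_perm: int = 10_000,
    fdr_cutoff: float = 0.1,
    seed: int = 0,
    direction: str = DIRECTION_DEPLETION,
) -> pd.DataFrame:
    """Score every targeted transcript from guide-level log fold changes.

    Parameters
    ----------
    lfc
        Guides x replicate-samples frame of log2 fold changes vs the DNA
        pool (a ``mean`` column, if present, is ignored for ranking).
    guide_map
        guide_id -> (promoter_id, gene_id); a library frame with columns
        guide_id / target_promoter_id / gene_id is also accepted.  Guides
        without a promoter (negative controls) stay in the ranking universe
        but are not scored.
    direction
        ``depletion`` (negative selection, the screen's readout) or
        ``enrichment``.

    Replicate rank lists are concatenated per guide set, so a transcript
    with g guides and R replicates is scored on n = g*R normalized ranks.
    """
    if isinstance(guide_map, pd.DataFrame):
        mapping = {
            str(r.guide_id): (str(r.target_promoter_id), str(r.gene_id))
            for r in guide_map.itertuples(index=False)
            if not pd.isna(r.target_promoter_id)
        }
    else:
        mapping = dict(guide_map)

    ranks = normalized_ranks(lfc, direction=direction)
    G = len(ranks)
    by_promoter: dict[str, list[str]] = {}
    genes: dict[str, str] = {}
    for gid, (pid, gene) in mapping.items():
        if gid not in ranks.index:
            continue
        by_promoter.setdefault(pid, []).append(gid)
        genes[pid] = gene
    missing = set(mapping) - set(ranks.index)
    if missing:
        log.warning("%d mapped guides absent from the lfc table; ignored", len(missing))

    rng = np.random.default_rng(seed)
    cache = _NullCache(G, alpha, n_perm, rng)

    rows = []
    for pid in sorted(by_promoter):
        gids = sorted(by_promoter[pid])
        obs = ranks.loc[gids].values.ravel()
        rho = rho_statistic(obs, alpha=alpha)
        null = cache.get(obs.size)
        p = (1 + int(np.searchsorted(null, rho, side="right"))) / (n_perm + 1)
        rows.append((pid, genes[pid], len(gids), rho, p))
    if not rows:
        return pd.DataFrame(
            columns=["promoter_id", "gene_id", "n_guides", "rho", "p_value", "fdr", "essential", "direction"]
        )
    out = pd.DataFrame(rows, columns=["promoter_id", "gene_id", "n_guides", "rho", "p_value"])
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["essential"] = out["fdr"] <= fdr_cutoff
    out["direction"] = direction
    return out
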