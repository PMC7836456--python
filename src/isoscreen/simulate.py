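"""Seeded synthetic-data generator for the whole screening pipeline.

The generator emulates the study's statistical structure so every stage is
testable with no external data:

- a toy genome in which each gene owns one or two promoters spaced >= 5 kb
  apart, every promoter window carrying at least 10 PAM-adjacent candidate
  spacers, plus planted *bidirectional decoys* — target promoters placed
  < 2 kb from a pan-essential neighbour TSS;
- paired tumour/normal H3K4me3 matrices (17 pairs by default) with planted
  gains/losses: log-normal baselines, a 2^gain_log2fc tumour multiplier in
  a random subset of >= 2 pairs, multiplicative log-normal noise;
- isoform expression (FPKM) with planted expressed/unexpressed status;
- negative-binomial screen counts (DNA pool at ``coverage`` reads/guide,
  default 1000; two day-21 replicates per cell line) where the day-21 mean
  is scaled by 2^effect.  The central causal premise is wired in: the
  effect flows only through guides on an *expressed* planted-essential
  isoform; guides on the unexpressed isoform of the same gene, and
  negative controls, have effect 0.  Decoy-promoter guides inherit the
  essential effect of their bidirectional neighbour.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from isoscreen import counts as counts_mod
from isoscreen import design as design_mod
from isoscreen import filters as filters_mod
from isoscreen import promoters as prom_mod
from isoscreen import rra as rra_mod
from isoscreen.counts import CountMatrix
from isoscreen.promoters import PromoterRecord, SignalPairTable

log = logging.getLogger(__name__)

ROLE_TARGET = "target"
ROLE_UNALTERED = "unaltered"
ROLE_POSITIVE = "positive_control"
ROLE_DECOY_PARTNER = "decoy_partner"

DECOY_NONE = "none"
DECOY_BIDIRECTIONAL = "bidirectional_pan_essential"


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults follow the screen design: 17 tumour/normal signal pairs,
    1000x guide coverage, 6 guides/promoter in a +/-150 bp TSS window,
    two day-21 replicates, 5 cancer lines plus one normal line.  Scale
    parameters (genes, controls) default to a size that keeps a full
    pipeline run in seconds; fractions are planted as deterministic counts
    (``round(fraction * N)``).
    """

    seed: int = 0
    n_genes: int = 150
    two_promoter_fraction: float = 0.8
    n_pairs: int = 17
    gain_fraction: float = 0.3
    lost_fraction: float = 0.1
    gain_log2fc: float = 2.0
    signal_noise_sd: float = 0.25
    min_gain_pairs: int = 2
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 0.5
    fraction_expressed: float = 0.8
    unaltered_expressed_fraction: float = 0.3
    n_cell_lines: int = 5
    n_replicates: int = 2
    coverage: float = 1000.0
    nb_dispersion: float = 0.05
    essential_fraction: float = 0.15
    essential_log2fc: float = -2.0
    bidirectional_decoys: int = 1
    n_essential_genes: int = 20
    n_negative: int = 200
    guides_per_promoter: int = 6
    window: int = 150
    spacing: int = 5000
    decoy_partner_distance: int = 1500

    def __post_init__(self):
        for name in (
            "two_promoter_fraction", "gain_fraction", "lost_fraction",
            "fraction_expressed", "unaltered_expressed_fraction", "essential_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.decoy_partner_distance >= self.spacing // 2:
            raise ValueError("decoy_partner_distance must fit inside one slot")

    @property
    def cell_lines(self) -> list[str]:
        return [f"GC{i + 1}" for i in range(self.n_cell_lines)]

    @property
    def normal_line(self) -> str:
        return "NORMAL"


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _candidate_rich_slot(
    rng: np.random.Generator, spacing: int, tss_at: int, strand: str, window: int,
    min_candidates: int = 10, max_tries: int = 50,
) -> str:
    """A slot sequence whose TSS window holds >= ``min_candidates`` spacers."""
    probe = PromoterRecord("probe", "probe", "slot", tss_at, strand)
    for _ in range(max_tries):
        seq = _random_seq(rng, spacing)
        cands = design_mod.enumerate_candidates({"slot": seq}, probe, window=window)
        if len({g.spacer for g in cands}) >= min_candidates:
            return seq
    raise RuntimeError("could not seed a candidate-rich promoter window")


def plan_truth(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Plan the planted truth without touching sequence or coordinates.

    One row per promoter (indexed by promoter_id) with gene structure, the
    planted gained/lost/unaltered status (deterministic counts:
    ``round(fraction * N)``), expression and essentiality.  Essentials are
    planted only among *expressed* gained targets, encoding the premise
    that a dependency acts through the expressed isoform.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.bidirectional_decoys > config.n_genes:
        raise ValueError("more decoys than genes")

    n_two = round(config.two_promoter_fraction * config.n_genes)
    rows: list[dict] = []
    for gi in range(config.n_genes):
        gene = f"G{gi + 1:04d}"
        decoy = gi < config.bidirectional_decoys
        # decoy genes are single-promoter so the partner TSS is the only neighbour
        n_prom = 1 if decoy else (2 if gi < config.bidirectional_decoys + n_two else 1)
        rows.append(
            {"gene_id": gene, "label": "P1", "role": ROLE_TARGET,
             "decoy_role": DECOY_BIDIRECTIONAL if decoy else DECOY_NONE}
        )
        if n_prom == 2:
            rows.append({"gene_id": gene, "label": "P2", "role": ROLE_UNALTERED,
                         "decoy_role": DECOY_NONE})
    for ei in range(config.n_essential_genes):
        rows.append({"gene_id": f"ESS{ei + 1:03d}", "label": "P1", "role": ROLE_POSITIVE,
                     "decoy_role": DECOY_NONE})
    for r in rows:
        r["promoter_id"] = f"{r['gene_id']}_{r['label']}"

    truth = pd.DataFrame(rows).set_index("promoter_id")
    truth["planted_status"] = prom_mod.UNALTERED
    truth["expressed"] = False
    truth["planted_essential"] = False
    truth["planted_effect"] = 0.0

    # -- plant gains/losses, expression, essentiality -----------------------
    targets = truth.index[truth["role"] == ROLE_TARGET]
    decoys = truth.index[truth["decoy_role"] == DECOY_BIDIRECTIONAL]
    free_targets = [p for p in targets if p not in set(decoys)]
    n_gain = max(0, round(config.gain_fraction * len(targets)) - len(decoys))
    n_lost = round(config.lost_fraction * len(targets))
    if n_gain + n_lost > len(free_targets):
        raise ValueError("gain_fraction + lost_fraction exceed available target promoters")
    picked = rng.choice(len(free_targets), size=n_gain + n_lost, replace=False)
    gained = list(decoys) + [free_targets[i] for i in picked[:n_gain]]
    lost = [free_targets[i] for i in picked[n_gain:]]
    truth.loc[gained, "planted_status"] = prom_mod.GAINED
    truth.loc[lost, "planted_status"] = prom_mod.LOST

    # expression: deterministic counts of expressed promoters per group;
    # decoys forced expressed so they can reach the final-hit stage
    for group, frac in (
        (gained, config.fraction_expressed),
        (lost, config.fraction_expressed),
        (list(truth.index[truth["role"] == ROLE_UNALTERED]), config.unaltered_expressed_fraction),
    ):
        pool = [p for p in group if p not in set(decoys)]
        k = round(frac * len(group))
        k_pool = min(len(pool), max(0, k - len([p for p in group if p in set(decoys)])))
        chosen = [pool[i] for i in rng.choice(len(pool), size=k_pool, replace=False)] if k_pool else []
        truth.loc[chosen, "expressed"] = True
    truth.loc[decoys, "expressed"] = True
    truth.loc[truth["role"] == ROLE_POSITIVE, "expressed"] = True

    # essentials only among expressed gained targets (the expressed-isoform premise)
    candidates = [
        p for p in gained
        if truth.at[p, "expressed"] and truth.at[p, "decoy_role"] == DECOY_NONE
    ]
    n_ess = min(len(candidates), round(config.essential_fraction * len(candidates)))
    chosen = [candidates[i] for i in rng.choice(len(candidates), size=n_ess, replace=False)] if n_ess else []
    truth.loc[chosen, "planted_essential"] = True
    truth.loc[chosen, "planted_effect"] = config.essential_log2fc
    truth.loc[truth["role"] == ROLE_POSITIVE, "planted_essential"] = True
    truth.loc[truth["role"] == ROLE_POSITIVE, "planted_effect"] = config.essential_log2fc
    return truth


def make_genome_and_promoters(
    config: SimConfig,
) -> tuple[dict[str, str], list[PromoterRecord], pd.DataFrame, set[str]]:
    """Toy genome + promoter annotation + planted truth + pan-essential genes.

    Returns ``(genome, promoters, truth, pan_genes)``.  Each promoter sits
    mid-slot in a ``spacing``-bp slot (so same-gene promoters are
    ``spacing`` apart), every TSS window is re-rolled until it holds at
    least 10 candidate spacers, and each decoy promoter gets a
    pan-essential neighbour TSS ``decoy_partner_distance`` bp away.
    ``pan_genes`` contains the positive-control essential genes and the
    decoy neighbour genes.
    """
    rng = np.random.default_rng(config.seed)
    truth = plan_truth(config, rng)

    promoters: list[PromoterRecord] = []
    chrom = "chr1"
    chunks: list[str] = []
    offset = 0
    pan_genes: set[str] = set(truth.loc[truth["role"] == ROLE_POSITIVE, "gene_id"])
    extra_records: list[PromoterRecord] = []
    tss_col = []
    for pid, r in truth.iterrows():
        strand = "+" if rng.random() < 0.5 else "-"
        tss_in_slot = config.spacing // 2
        seq = _candidate_rich_slot(rng, config.spacing, tss_in_slot, strand, config.window)
        promoters.append(
            PromoterRecord(pid, r["gene_id"], chrom, offset + tss_in_slot, strand, r["label"])
        )
        tss_col.append(offset + tss_in_slot)
        if r["decoy_role"] == DECOY_BIDIRECTIONAL:
            partner_gene = f"NBR{r['gene_id']}"
            partner_tss = offset + tss_in_slot + config.decoy_partner_distance
            extra_records.append(
                PromoterRecord(f"{partner_gene}_P1", partner_gene, chrom, partner_tss,
                               "+" if rng.random() < 0.5 else "-", "P1")
            )
            pan_genes.add(partner_gene)
        chunks.append(seq)
        offset += config.spacing
    genome = {chrom: "".join(chunks)}
    truth = truth.copy()
    truth["tss"] = tss_col
    return genome, promoters + extra_records, truth, pan_genes


def make_h3k4me3(
    config: SimConfig, truth: pd.DataFrame, seed: int | None = None
) -> SignalPairTable:
    """Paired tumour/normal H3K4me3 signal with planted gains and losses.

    Baselines are log-normal and shared within a pair; gained promoters get
    a 2^gain_log2fc tumour multiplier in a random subset of at least
    ``min_gain_pairs`` pairs (lost promoters the reciprocal); multiplicative
    exp(N(0, signal_noise_sd)) noise is applied to both channels.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    pids = truth.index
    n, m = len(pids), config.n_pairs
    base = np.exp(rng.normal(config.baseline_meanlog, config.baseline_sdlog, (n, m)))
    tumour = base.copy()
    normal = base.copy()
    mult = 2.0 ** config.gain_log2fc
    for i, pid in enumerate(pids):
        status = truth.at[pid, "planted_status"]
        if status == prom_mod.UNALTERED:
            continue
        k = int(rng.integers(config.min_gain_pairs, m + 1))
        which = rng.choice(m, size=k, replace=False)
        if status == prom_mod.GAINED:
            tumour[i, which] *= mult
        else:
            tumour[i, which] /= mult
    tumour *= np.exp(rng.normal(0.0, config.signal_noise_sd, (n, m)))
    normal *= np.exp(rng.normal(0.0, config.signal_noise_sd, (n, m)))
    cols = [f"pair{j + 1:02d}" for j in range(m)]
    return SignalPairTable(
        tumour=pd.DataFrame(tumour, index=pids, columns=cols),
        normal=pd.DataFrame(normal, index=pids, columns=cols),
    )


def make_expression(config: SimConfig, truth: pd.DataFrame, seed: int | None = None) -> pd.Series:
    """Isoform FPKM: expressed promoters well above the FPKM>=5 gate, others below."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    expr = np.where(
        truth["expressed"].values,
        np.exp(rng.normal(3.5, 0.5, len(truth))),
        np.exp(rng.normal(0.0, 0.5, len(truth))),
    )
    return pd.Series(expr, index=truth.index, name="fpkm")


def _nb_counts(rng: np.random.Generator, mean, dispersion: float, size) -> np.ndarray:
    """Gamma-Poisson negative binomial: var = mean + dispersion * mean^2."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def guide_effects(
    library: pd.DataFrame, truth: pd.DataFrame, config: SimConfig, line: str
) -> np.ndarray:
    """Planted log2 depletion effect per library guide in one cell line.

    Effects flow only through expressed planted-essential isoforms;
    positive controls deplete in every line, decoy-promoter guides inherit
    the neighbour's essential effect, everything else (negative controls,
    unexpressed isoforms) is 0.
    """
    known = set(truth.index)
    effects = np.zeros(len(library), dtype=float)
    for i, row in enumerate(library.itertuples(index=False)):
        if row.category == design_mod.CATEGORY_NEGATIVE:
            continue
        if row.category == design_mod.CATEGORY_POSITIVE:
            effects[i] = config.essential_log2fc
            continue
        pid = row.target_promoter_id
        if pid not in known:
            raise KeyError(f"library guide {row.guide_id} targets unknown promoter {pid}")
        if truth.at[pid, "decoy_role"] == DECOY_BIDIRECTIONAL:
            effects[i] = config.essential_log2fc
        elif (
            truth.at[pid, "planted_essential"]
            and truth.at[pid, "expressed"]
            and line != config.normal_line
        ):
            effects[i] = float(truth.at[pid, "planted_effect"])
    return effects


def make_screen_counts(
    library: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
    lines: list[str] | None = None,
) -> dict[str, CountMatrix]:
    """Negative-binomial screen counts per cell line, sharing one DNA pool.

    Pool counts ~ NB(mean=coverage, dispersion); each line gets
    ``n_replicates`` day-21 samples with mean = coverage * 2^effect.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    if lines is None:
        lines = config.cell_lines + [config.normal_line]
    G = len(library)
    pool = _nb_counts(rng, config.coverage, config.nb_dispersion, (G,))
    out: dict[str, CountMatrix] = {}
    for line in lines:
        eff = guide_effects(library, truth, config, line)
        data = {"pool": pool}
        for rep in range(1, config.n_replicates + 1):
            mean = config.coverage * (2.0 ** eff)
            data[f"{line}_day21_rep{rep}"] = _nb_counts(rng, mean, config.nb_dispersion, (G,))
        out[line] = CountMatrix(
            counts=pd.DataFrame(data, index=pd.Index(library["guide_id"], name="guide_id")),
            reference="pool",
        )
    return out


def write_screen_fastq(
    counts: pd.Series, library: pd.DataFrame, path: str | Path, seed: int = 0, read_len: int = 50
) -> None:
    """Emit a FASTQ whose reads reproduce the given per-guide counts.

    Reads carry the constant vector prefix then the spacer, padded with
    random sequence — the structure the prefix-scan deconvolution mode
    expects.
    """
    rng = np.random.default_rng(seed)
    spacer_of = dict(zip(library["guide_id"], library["spacer"]))
    reads = []
    for gid, c in counts.items():
        reads.extend([spacer_of[gid]] * int(c))
    order = rng.permutation(len(reads))
    with open(path, "w") as fh:
        for ri, idx in enumerate(order):
            spacer = reads[idx]
            insert = counts_mod.VECTOR_PREFIX + spacer
            pad = _random_seq(rng, max(0, read_len - len(insert)))
            seq = (insert + pad)[:read_len]
            fh.write(f"@read{ri}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# genome-free count-level benchmarks (rra/filters statistical properties)
# ---------------------------------------------------------------------------

def make_synthetic_library(
    n_promoters: int,
    guides_per_promoter: int = 6,
    n_negative: int = 200,
    prefix: str = "P",
) -> pd.DataFrame:
    """A bare guide->promoter map (no genome) for count-level simulations."""
    rows = []
    for pi in range(n_promoters):
        pid = f"{prefix}{pi + 1:04d}"
        for g in range(guides_per_promoter):
            rows.append((f"{pid}_sg{g + 1}", pid, pid, design_mod.CATEGORY_TARGETING))
    for ni in range(n_negative):
        rows.append((f"neg_{ni + 1:04d}", None, None, design_mod.CATEGORY_NEGATIVE))
    return pd.DataFrame(rows, columns=["guide_id", "target_promoter_id", "gene_id", "category"])


def simulate_count_matrix(
    library: pd.DataFrame,
    effects: np.ndarray,
    coverage: float = 500.0,
    dispersion: float = 0.05,
    n_replicates: int = 2,
    seed: int = 0,
) -> CountMatrix:
    rng = np.random.default_rng(seed)
    G = len(library)
    data = {"pool": _nb_counts(rng, coverage, dispersion, (G,))}
    for rep in range(1, n_replicates + 1):
        data[f"day21_rep{rep}"] = _nb_counts(rng, coverage * 2.0 ** effects, dispersion, (G,))
    return CountMatrix(
        counts=pd.DataFrame(data, index=pd.Index(library["guide_id"], name="guide_id")),
        reference="pool",
    )


def spike_in_benchmark(
    seed: int = 0,
    n_promoters: int = 800,
    n_planted: int = 20,
    effect: float = -2.0,
    coverage: float = 500.0,
    dispersion: float = 0.05,
    guides_per_promoter: int = 6,
    n_negative: int = 200,
    n_perm: int = 5000,
    alpha: float = 0.25,
    fdr_cutoff: float = 0.1,
) -> dict:
    """Plant ``n_planted`` fully-depleted promoters and measure recovery.

    Returns sensitivity (planted recovered at the FDR cutoff), observed FDR
    among calls, and the call count.
    """
    rng = np.random.default_rng(seed)
    lib = make_synthetic_library(n_promoters, guides_per_promoter, n_negative)
    planted = [f"P{i + 1:04d}" for i in rng.choice(n_promoters, size=n_planted, replace=False)]
    effects = np.where(lib["target_promoter_id"].isin(planted), effect, 0.0)
    cm = simulate_count_matrix(lib, effects, coverage, dispersion, seed=seed + 1)
    lfc = counts_mod.guide_lfc(cm)
    scores = rra_mod.score_transcripts(
        lfc, lib, alpha=alpha, n_perm=n_perm, fdr_cutoff=fdr_cutoff, seed=seed + 2
    )
    called = set(scores.loc[scores["essential"], "promoter_id"])
    tp = len(called & set(planted))
    fp = len(called - set(planted))
    return {
        "sensitivity": tp / n_planted if n_planted else float("nan"),
        "observed_fdr": fp / len(called) if called else 0.0,
        "n_called": len(called),
        "n_planted": n_planted,
        "n_promoters": n_promoters,
    }


def null_essential_fraction(
    seed: int = 0,
    n_promoters: int = 300,
    coverage: float = 500.0,
    dispersion: float = 0.05,
    guides_per_promoter: int = 6,
    n_negative: int = 200,
    n_perm: int = 2000,
    alpha: float = 0.25,
    fdr_cutoff: float = 0.1,
) -> float:
    """Fraction of promoters called essential in a fully null screen."""
    lib = make_synthetic_library(n_promoters, guides_per_promoter, n_negative)
    cm = simulate_count_matrix(lib, np.zeros(len(lib)), coverage, dispersion, seed=seed)
    lfc = counts_mod.guide_lfc(cm)
    scores = rra_mod.score_transcripts(
        lfc, lib, alpha=alpha, n_perm=n_perm, fdr_cutoff=fdr_cutoff, seed=seed + 1
    )
    return float(scores["essential"].mean()) if len(scores) else 0.0


def expressed_isoform_premise_check(
    seed: int = 0,
    n_genes: int = 40,
    n_negative: int = 300,
    n_perm: int = 2000,
    fdr_cutoff: float = 0.1,
) -> dict:
    """Check the generator's causal premise on a two-promoter essential panel.

    Every gene has an expressed, essential P1 isoform and an unexpressed P2
    isoform.  Guides on P2 must behave like negative controls (KS test on
    their lfc distributions) and must not be called essential, while P1
    isoforms are recovered.
    """
    from scipy import stats as sps

    cfg = SimConfig(
        seed=seed, n_genes=n_genes, two_promoter_fraction=1.0, gain_fraction=1.0,
        lost_fraction=0.0, fraction_expressed=1.0, unaltered_expressed_fraction=0.0,
        essential_fraction=1.0, bidirectional_decoys=0, n_essential_genes=0,
        n_negative=n_negative,
    )
    truth = plan_truth(cfg)
    rows = []
    for pid in truth.index:
        category = (
            design_mod.CATEGORY_TARGETING
            if truth.at[pid, "role"] == ROLE_TARGET
            else design_mod.CATEGORY_UNALTERED
        )
        for g in range(cfg.guides_per_promoter):
            rows.append((f"{pid}_sg{g + 1}", pid, truth.at[pid, "gene_id"], category))
    for ni in range(n_negative):
        rows.append((f"neg_{ni + 1:04d}", None, None, design_mod.CATEGORY_NEGATIVE))
    lib = pd.DataFrame(rows, columns=["guide_id", "target_promoter_id", "gene_id", "category"])

    line = cfg.cell_lines[0]
    cm = make_screen_counts(lib, truth, cfg, lines=[line])[line]
    lfc = counts_mod.guide_lfc(cm)
    mean_lfc = lfc["mean"]
    unexpressed_ids = lib.loc[lib["category"] == design_mod.CATEGORY_UNALTERED, "guide_id"]
    negative_ids = lib.loc[lib["category"] == design_mod.CATEGORY_NEGATIVE, "guide_id"]
    targeting_ids = lib.loc[lib["category"] == design_mod.CATEGORY_TARGETING, "guide_id"]
    ks = sps.ks_2samp(mean_lfc[unexpressed_ids], mean_lfc[negative_ids])

    scores = rra_mod.score_transcripts(lfc, lib, n_perm=n_perm, fdr_cutoff=fdr_cutoff,
                                       seed=seed + 1)
    scores = scores.set_index("promoter_id")
    p1 = truth.index[truth["role"] == ROLE_TARGET]
    p2 = truth.index[truth["role"] == ROLE_UNALTERED]
    return {
        "ks_p": float(ks.pvalue),
        "unexpressed_mean_lfc": float(mean_lfc[unexpressed_ids].mean()),
        "targeting_mean_lfc": float(mean_lfc[targeting_ids].mean()),
        "expressed_called_fraction": float(scores.loc[p1, "essential"].mean()),
        "unexpressed_called": int(scores.loc[scores.index.intersection(p2), "essential"].sum()),
    }


# ---------------------------------------------------------------------------
# end-to-end benchmark
# ---------------------------------------------------------------------------

def end_to_end_benchmark(config: SimConfig, n_perm: int = 2000, fdr_cutoff: float = 0.1,
                         min_lines: int = 2, return_artifacts: bool = False):
    """Run promoters -> design -> counts -> rra -> filters on one simulation.

    Reports promoter-call precision/recall and false-gain rate, hit
    sensitivity over planted essentials, observed FDR among final hits, and
    decoy-removal correctness, as a JSON-serialisable dict.
    """
    genome, all_promoters, truth, pan_genes = make_genome_and_promoters(config)
    lib_promoters = {p.promoter_id: p for p in all_promoters}

    # stage 1: promoter calling + expression gate
    signals = make_h3k4me3(config, truth)
    calls = prom_mod.call_promoters(signals, fc_threshold=1.0, min_pairs=config.min_gain_pairs)
    expression = make_expression(config, truth)
    calls = prom_mod.select_screen_targets(calls, expression, min_fpkm=5.0)

    planted_gained = set(truth.index[truth["planted_status"] == prom_mod.GAINED])
    called_gained = set(calls.index[calls["status"] == prom_mod.GAINED])
    null_promoters = set(truth.index[truth["planted_status"] == prom_mod.UNALTERED])
    tp = len(called_gained & planted_gained)
    promoter_recall = tp / len(planted_gained) if planted_gained else float("nan")
    promoter_precision = tp / len(called_gained) if called_gained else float("nan")
    false_gain_rate = (
        len(called_gained & null_promoters) / len(null_promoters) if null_promoters else 0.0
    )

    # stage 2: library design on the called, expression-gated target set
    # positive controls are a fixed category; noise-called essential-gene or
    # partner promoters must not re-enter as targets
    selected_ids = [
        p for p in calls.index[calls["selected"]]
        if truth.at[p, "role"] in (ROLE_TARGET, ROLE_UNALTERED)
    ]
    selected_targets = [lib_promoters[p] for p in selected_ids]
    selected_genes = {lib_promoters[p].gene_id for p in selected_ids}
    unaltered = [
        lib_promoters[pid]
        for pid in truth.index[(truth["role"] == ROLE_UNALTERED)]
        if lib_promoters[pid].gene_id in selected_genes and pid not in set(selected_ids)
    ]
    essential_proms = [lib_promoters[pid] for pid in truth.index[truth["role"] == ROLE_POSITIVE]]
    library = design_mod.build_library(
        genome,
        selected_targets,
        unaltered_promoters=unaltered,
        essential_promoters=essential_proms,
        n_negative=config.n_negative,
        window=config.window,
        guides_per_promoter=config.guides_per_promoter,
        seed=config.seed + 10,
    )
    lib_df = library.to_frame()

    # stage 3+4: screen counts and per-line transcript scores
    matrices = make_screen_counts(lib_df, truth, config)
    scores_by_line: dict[str, pd.DataFrame] = {}
    for i, (line, cm) in enumerate(matrices.items()):
        lfc = counts_mod.guide_lfc(cm)
        scores_by_line[line] = rra_mod.score_transcripts(
            lfc, lib_df, n_perm=n_perm, fdr_cutoff=fdr_cutoff, seed=config.seed + 20 + i
        )

    # stage 5: hit filtering
    hits = filters_mod.intersect_lines(
        scores_by_line, fdr_cutoff=fdr_cutoff, min_lines=min_lines,
        normal_line=config.normal_line, pan_list=pan_genes,
    )
    hits = filters_mod.bidirectional_filter(hits, all_promoters, max_distance=2000, pan_list=pan_genes)
    hits = filters_mod.contrast_normal(hits, scores_by_line.get(config.normal_line))

    final = set(hits.loc[hits["final_hit"], "promoter_id"])
    planted_ess = set(truth.index[truth["planted_essential"] & (truth["role"] == ROLE_TARGET)])
    planted_in_lib = planted_ess & set(lib_df["target_promoter_id"].dropna())
    tp_hits = len(final & planted_in_lib)
    decoys = set(truth.index[truth["decoy_role"] == DECOY_BIDIRECTIONAL])
    decoys_removed = len(decoys - final)

    report = {
        "promoter_precision": promoter_precision,
        "promoter_recall": promoter_recall,
        "false_gain_rate": false_gain_rate,
        "n_selected": int(calls["selected"].sum()),
        "hit_sensitivity": tp_hits / len(planted_in_lib) if planted_in_lib else float("nan"),
        "observed_fdr": (len(final - planted_in_lib) / len(final)) if final else 0.0,
        "decoys_planted": len(decoys),
        "decoys_removed": decoys_removed,
        "decoy_removal_correct": decoys_removed == len(decoys),
        "library_composition": design_mod.summarise_library(library),
        "cascade": filters_mod.cascade_summary(hits, min_lines=min_lines),
    }
    if return_artifacts:
        artifacts = {
            "genome": genome, "promoters": all_promoters, "truth": truth,
            "pan_genes": pan_genes, "signals": signals, "calls": calls,
            "library": library, "matrices": matrices,
            "scores_by_line": scores_by_line, "hits": hits,
        }
        return report, artifacts
    return report


def write_simulation(config: SimConfig, outdir: str | Path, n_perm: int = 2000) -> dict:
    """Materialise a full simulated study as plain-text files under ``outdir``."""
    from isoscreen import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report, art = end_to_end_benchmark(config, n_perm=n_perm, return_artifacts=True)

    io.write_fasta(art["genome"].items(), outdir / "genome.fa")
    io.write_promoter_bed(art["promoters"], outdir / "all_tss.bed")
    signals: SignalPairTable = art["signals"]
    long = (
        signals.tumour.stack().rename("tumour").to_frame()
        .join(signals.normal.stack().rename("normal"))
        .reset_index()
    )
    long.columns = ["promoter_id", "sample_id", "tumour", "normal"]
    io.write_tsv(long, outdir / "signals.tsv")
    calls = art["calls"].reset_index(names="promoter_id")
    io.write_tsv(calls, outdir / "calls.tsv")
    io.write_tsv(art["library"].to_frame(), outdir / "library.tsv")
    for line, cm in art["matrices"].items():
        cm.to_tsv(outdir / f"counts_{line}.tsv")
    for line, sc in art["scores_by_line"].items():
        io.write_tsv(sc, outdir / f"scores_{line}.tsv")
    io.write_tsv(art["hits"], outdir / "hits.tsv")
    truth = art["truth"].reset_index()
    io.write_tsv(truth, outdir / "truth.tsv")
    (outdir / "pan_genes.txt").write_text("\n".join(sorted(art["pan_genes"])) + "\n")
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
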