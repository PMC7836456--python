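"""CRISPRi sgRNA library design in TSS windows.

CRISPRi (dCas9-KRAB) silences transcription only when targeted within a
narrow window around the TSS, which is what makes promoter-level — and
hence isoform-level — specificity possible.  The designer therefore:

1. enumerates every 20-mer protospacer immediately 5' of an NGG PAM on
   either genomic strand whose anchor lies within ±``window`` bp (default
   150) of the target TSS;
2. keeps only spacers that match the genome exactly once (exact 20/20,
   either strand; no mismatch-tolerant scoring);
3. picks up to ``guides_per_promoter`` (default 6) guides per promoter,
   closest-to-TSS first with a fully deterministic tie-break;
4. adds control classes: guides on each gene's unaltered partner isoform,
   positive controls on core-essential-gene promoters, and seeded random
   non-targeting negative controls (zero genome hits, GC in [0.4, 0.6]);
5. emits cloning oligos with the fixed BsmBI-handle flanks.

Offsets are measured from the PAM-proximal end of the protospacer (the base
dCas9 sits on) to the TSS, signed in transcript orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from isoscreen.promoters import PromoterRecord

log = logging.getLogger(__name__)

SPACER_LEN = 20
OLIGO_5P = "AGGCACTTGCTCGTACGACGCGTCTCACACCG"
OLIGO_3P = "GTTTCGAGACGTTAAGGTGCCGGGCCCACAT"

CATEGORY_TARGETING = "targeting"
CATEGORY_UNALTERED = "unaltered_control"
CATEGORY_POSITIVE = "positive_control"
CATEGORY_NEGATIVE = "negative_control"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class DesignShortfallWarning(UserWarning):
    """Fewer unique guides available than requested for a promoter."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideRecord:
    """One designed spacer.

    ``pam_site`` is the 0-based position of the N of the NGG PAM on the
    genome's forward-strand representation of the protospacer; ``offset``
    is the signed distance (transcript orientation) from the PAM-proximal
    protospacer base to the target TSS.
    """

    guide_id: str
    spacer: str
    chrom: str
    pam_site: int
    strand: str
    offset: int | None
    target_promoter_id: str | None
    gene_id: str | None
    category: str
    genome_hits: int

    def __post_init__(self):
        if len(self.spacer) != SPACER_LEN:
            raise ValueError(f"{self.guide_id}: spacer must be {SPACER_LEN} nt, got {len(self.spacer)}")
        if set(self.spacer) - set("ACGT"):
            raise ValueError(f"{self.guide_id}: spacer has non-ACGT characters")


@dataclass
class GuideLibrary:
    """A designed pooled library with per-category bookkeeping."""

    guides: list[GuideRecord]
    design_params: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [g.guide_id for g in self.guides]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate guide_ids in library")
        spacers = [g.spacer for g in self.guides]
        if len(set(spacers)) != len(spacers):
            raise ValueError("duplicate spacers in library")

    @property
    def per_promoter_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.guides:
            if g.target_promoter_id is not None:
                counts[g.target_promoter_id] = counts.get(g.target_promoter_id, 0) + 1
        return counts

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.guides:
            counts[g.category] = counts.get(g.category, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [g.guide_id for g in self.guides],
                "spacer": [g.spacer for g in self.guides],
                "chrom": [g.chrom for g in self.guides],
                "pam_site": [g.pam_site for g in self.guides],
                "strand": [g.strand for g in self.guides],
                "offset": [g.offset for g in self.guides],
                "target_promoter_id": [g.target_promoter_id for g in self.guides],
                "gene_id": [g.gene_id for g in self.guides],
                "category": [g.category for g in self.guides],
                "genome_hits": [g.genome_hits for g in self.guides],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, design_params: dict | None = None) -> "GuideLibrary":
        guides = []
        for row in df.itertuples(index=False):
            offset = None if pd.isna(row.offset) else int(row.offset)
            target = None if pd.isna(row.target_promoter_id) else str(row.target_promoter_id)
            gene = None if pd.isna(row.gene_id) else str(row.gene_id)
            guides.append(
                GuideRecord(
                    guide_id=str(row.guide_id),
                    spacer=str(row.spacer),
                    chrom=str(row.chrom),
                    pam_site=int(row.pam_site),
                    strand=str(row.strand),
                    offset=offset,
                    target_promoter_id=target,
                    gene_id=gene,
                    category=str(row.category),
                    genome_hits=int(row.genome_hits),
                )
            )
        return cls(guides=guides, design_params=design_params or {})


def emit_oligo(spacer: str) -> str:
    """Cloning oligo: fixed 32-nt 5' handle + spacer + fixed 31-nt 3' handle (83 nt)."""
    if len(spacer) != SPACER_LEN:
        raise ValueError(f"spacer must be {SPACER_LEN} nt, got {len(spacer)}")
    return OLIGO_5P + spacer + OLIGO_3P


def enumerate_candidates(
    genome: Mapping[str, str],
    promoter: PromoterRecord,
    window: int = 150,
    exclude_tttt: bool = True,
) -> list[GuideRecord]:
    """Every NGG-adjacent 20-mer whose anchor is within ±window of the TSS.

    Both genomic strands are scanned.  Spacers containing non-ACGT
    characters are excluded, as are spacers containing the Pol III
    terminator TTTT unless ``exclude_tttt`` is disabled.  ``genome_hits``
    is left at 0 (unknown) — uniqueness is a separate step.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    if promoter.chrom not in genome:
        raise KeyError(f"chromosome {promoter.chrom!r} not in genome")
    seq = genome[promoter.chrom].upper()
    tss = promoter.tss
    # anchors can lie anywhere in [tss-window, tss+window]; the protospacer
    # plus PAM extends at most 22 bases past the anchor on either side.
    lo = max(0, tss - window - SPACER_LEN - 3)
    hi = min(len(seq), tss + window + SPACER_LEN + 3)
    region = seq[lo:hi]
    sign = 1 if promoter.strand == "+" else -1

    out: list[GuideRecord] = []
    n = len(region)
    for i in range(n - 2):
        # forward-strand PAM: N G G at [i, i+3), protospacer [i-20, i)
        if region[i + 1] == "G" and region[i + 2] == "G" and i >= SPACER_LEN:
            spacer = region[i - SPACER_LEN : i]
            anchor = lo + i - 1  # PAM-proximal protospacer base
            offset = sign * (anchor - tss)
            if -window <= offset <= window and _spacer_ok(spacer, exclude_tttt):
                out.append(
                    GuideRecord(
                        guide_id=f"{promoter.promoter_id}|+|{lo + i}",
                        spacer=spacer,
                        chrom=promoter.chrom,
                        pam_site=lo + i,
                        strand="+",
                        offset=offset,
                        target_promoter_id=promoter.promoter_id,
                        gene_id=promoter.gene_id,
                        category=CATEGORY_TARGETING,
                        genome_hits=0,
                    )
                )
        # reverse-strand PAM: forward shows C C N at [i, i+3), protospacer [i+3, i+23)
        if region[i] == "C" and region[i + 1] == "C" and i + 3 + SPACER_LEN <= n:
            spacer = revcomp(region[i + 3 : i + 3 + SPACER_LEN])
            anchor = lo + i + 3  # PAM-proximal protospacer base on forward coords
            offset = sign * (anchor - tss)
            if -window <= offset <= window and _spacer_ok(spacer, exclude_tttt):
                out.append(
                    GuideRecord(
                        guide_id=f"{promoter.promoter_id}|-|{lo + i + 2}",
                        spacer=spacer,
                        chrom=promoter.chrom,
                        pam_site=lo + i + 2,
                        strand="-",
                        offset=offset,
                        target_promoter_id=promoter.promoter_id,
                        gene_id=promoter.gene_id,
                        category=CATEGORY_TARGETING,
                        genome_hits=0,
                    )
                )
    return out


def _spacer_ok(spacer: str, exclude_tttt: bool) -> bool:
    if len(spacer) != SPACER_LEN or set(spacer) - set("ACGT"):
        return False
    if exclude_tttt and "TTTT" in spacer:
        return False
    return True


def count_genome_matches(spacer: str, genome: Mapping[str, str]) -> int:
    """Exact occurrences of the spacer or its reverse complement, all sequences.

    A deliberately simple sliding scan (PAM not required); used both as the
    user-facing matcher and as the post-hoc verifier for designed guides.
    Palindromic spacers count each site once.
    """
    if len(spacer) != SPACER_LEN:
        raise ValueError(f"spacer must be {SPACER_LEN} nt, got {len(spacer)}")
    if set(spacer) - set("ACGT"):
        raise ValueError("spacer has non-ACGT characters")
    rc = revcomp(spacer)
    total = 0
    for seq in genome.values():
        seq = seq.upper()
        total += _count_overlapping(seq, spacer)
        if rc != spacer:
            total += _count_overlapping(seq, rc)
    return total


def _count_overlapping(seq: str, pattern: str) -> int:
    n = 0
    start = 0
    while True:
        i = seq.find(pattern, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def _kmer_codes(seq: str, k: int = SPACER_LEN, chunk: int = 1_000_000) -> np.ndarray:
    """Pack every valid k-mer of ``seq`` into a uint64 code (2 bits/base).

    Windows containing non-ACGT characters are dropped.
    """
    enc = _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    powers = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    codes = []
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        win = np.lib.stride_tricks.sliding_window_view(enc[lo : hi + k - 1], k)
        valid = ~(win == 255).any(axis=1)
        if valid.any():
            codes.append((win[valid].astype(np.uint64) * powers).sum(axis=1))
    if not codes:
        return np.empty(0, dtype=np.uint64)
    return np.concatenate(codes)


def _spacer_code(spacer: str) -> int:
    code = 0
    for b in spacer:
        code = code * 4 + int(_BASE_CODE[ord(b)])
    return code


def count_matches_bulk(spacers: Sequence[str], genome: Mapping[str, str]) -> np.ndarray:
    """Genome-wide exact hit counts for many spacers in one genome scan.

    Counts occurrences of each spacer or its reverse complement across all
    sequences, matching :func:`count_genome_matches` (palindromes counted
    once per site).  Uses 2-bit k-mer codes so whole-genome scans stay
    cheap.
    """
    if len(spacers) == 0:
        return np.zeros(0, dtype=np.int64)
    fwd = np.array([_spacer_code(s) for s in spacers], dtype=np.uint64)
    rev = np.array([_spacer_code(revcomp(s)) for s in spacers], dtype=np.uint64)
    counts = np.zeros(len(spacers), dtype=np.int64)
    for seq in genome.values():
        codes = _kmer_codes(seq)
        if codes.size == 0:
            continue
        uniq, cnt = np.unique(codes, return_counts=True)
        for query, skip_palindrome in ((fwd, False), (rev, True)):
            pos = np.searchsorted(uniq, query)
            ok = (pos < uniq.size) & (uniq[np.minimum(pos, uniq.size - 1)] == query)
            if skip_palindrome:
                ok &= fwd != rev  # palindromic site already counted via fwd
            counts[ok] += cnt[pos[ok]]
    return counts


def select_guides(candidates: Sequence[GuideRecord], n: int = 6) -> list[GuideRecord]:
    """Pick up to ``n`` guides, closest to the TSS first.

    Ties on |offset| break by sign (+ before −), then lexicographic spacer,
    so the selection is fully deterministic.  A shortfall (fewer unique
    candidates than requested — common in AT/GC-rich promoters) returns all
    available guides and emits :class:`DesignShortfallWarning`.
    """
    ordered = sorted(
        candidates,
        key=lambda g: (abs(g.offset), 0 if g.offset > 0 else 1, g.spacer),
    )
    if len(ordered) < n:
        target = ordered[0].target_promoter_id if ordered else "promoter"
        warnings.warn(
            f"{target}: only {len(ordered)} unique guides available (requested {n})",
            DesignShortfallWarning,
            stacklevel=2,
        )
    return ordered[:n]


def make_negative_controls(
    n: int,
    genome: Mapping[str, str],
    rng: np.random.Generator,
    gc_range: tuple[float, float] = (0.4, 0.6),
    exclude: Iterable[str] = (),
    batch: int = 512,
) -> list[str]:
    """Seeded random non-targeting 20-mers: zero genome hits, GC in range, no TTTT."""
    bases = np.array(list("ACGT"))
    lo, hi = gc_range
    chosen: list[str] = []
    taken = set(exclude)
    while len(chosen) < n:
        cand = ["".join(bases[rng.integers(0, 4, SPACER_LEN)]) for _ in range(batch)]
        cand = [
            s
            for s in cand
            if s not in taken
            and "TTTT" not in s
            and lo <= (s.count("G") + s.count("C")) / SPACER_LEN <= hi
        ]
        # dedupe within batch, keep order
        cand = list(dict.fromkeys(cand))
        if not cand:
            continue
        hits = count_matches_bulk(cand, genome)
        for s, h in zip(cand, hits):
            if h == 0 and len(chosen) < n:
                chosen.append(s)
                taken.add(s)
    return chosen


def design_promoter_guides(
    genome: Mapping[str, str],
    promoters: Sequence[PromoterRecord],
    category: str,
    window: int = 150,
    guides_per_promoter: int = 6,
    exclude_tttt: bool = True,
    taken_spacers: set[str] | None = None,
) -> list[GuideRecord]:
    """Enumerate, uniqueness-filter and select guides for a promoter set."""
    taken = taken_spacers if taken_spacers is not None else set()
    all_cands: list[list[GuideRecord]] = []
    pool: list[str] = []
    for p in promoters:
        cands = enumerate_candidates(genome, p, window=window, exclude_tttt=exclude_tttt)
        all_cands.append(cands)
        pool.extend(g.spacer for g in cands)
    # one genome scan for every candidate spacer
    uniq_spacers = list(dict.fromkeys(pool))
    hits = dict(zip(uniq_spacers, count_matches_bulk(uniq_spacers, genome)))

    selected: list[GuideRecord] = []
    for p, cands in zip(promoters, all_cands):
        unique_cands = [
            GuideRecord(
                guide_id=g.guide_id,
                spacer=g.spacer,
                chrom=g.chrom,
                pam_site=g.pam_site,
                strand=g.strand,
                offset=g.offset,
                target_promoter_id=g.target_promoter_id,
                gene_id=g.gene_id,
                category=category,
                genome_hits=1,
            )
            for g in cands
            if hits[g.spacer] == 1 and g.spacer not in taken
        ]
        # a spacer can appear twice in one window (never twice in the genome);
        # keep first by the deterministic ordering
        seen: set[str] = set()
        deduped = []
        for g in sorted(
            unique_cands, key=lambda g: (abs(g.offset), 0 if g.offset > 0 else 1, g.spacer)
        ):
            if g.spacer not in seen:
                seen.add(g.spacer)
                deduped.append(g)
        chosen = select_guides(deduped, n=guides_per_promoter)
        for rank, g in enumerate(chosen, start=1):
            taken.add(g.spacer)
            selected.append(
                GuideRecord(
                    guide_id=f"{g.target_promoter_id}_sg{rank}",
                    spacer=g.spacer,
                    chrom=g.chrom,
                    pam_site=g.pam_site,
                    strand=g.strand,
                    offset=g.offset,
                    target_promoter_id=g.target_promoter_id,
                    gene_id=g.gene_id,
                    category=category,
                    genome_hits=1,
                )
            )
    return selected


def build_library(
    genome: Mapping[str, str],
    selected_targets: Sequence[PromoterRecord],
    unaltered_promoters: Sequence[PromoterRecord] = (),
    essential_promoters: Sequence[PromoterRecord] = (),
    n_negative: int = 1064,
    window: int = 150,
    guides_per_promoter: int = 6,
    seed: int = 0,
    exclude_tttt: bool = True,
) -> GuideLibrary:
    """Assemble the full pooled library.

    Targeting guides for every selected promoter; unaltered-isoform control
    guides for each gene's unaltered partner promoter where one exists
    (genes with no unaltered partner are logged); positive controls on
    core-essential-gene promoters; ``n_negative`` seeded random
    non-targeting controls.
    """
    all_ids = [p.promoter_id for p in (*selected_targets, *unaltered_promoters, *essential_promoters)]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate promoter_ids across library categories")

    taken: set[str] = set()
    guides: list[GuideRecord] = []
    guides += design_promoter_guides(
        genome, selected_targets, CATEGORY_TARGETING, window, guides_per_promoter,
        exclude_tttt, taken,
    )
    guides += design_promoter_guides(
        genome, unaltered_promoters, CATEGORY_UNALTERED, window, guides_per_promoter,
        exclude_tttt, taken,
    )
    guides += design_promoter_guides(
        genome, essential_promoters, CATEGORY_POSITIVE, window, guides_per_promoter,
        exclude_tttt, taken,
    )

    target_genes = {p.gene_id for p in selected_targets}
    unaltered_genes = {p.gene_id for p in unaltered_promoters}
    for gene in sorted(target_genes - unaltered_genes):
        log.info("gene %s has no unaltered partner promoter; no unaltered controls", gene)

    rng = np.random.default_rng(seed)
    for i, spacer in enumerate(
        make_negative_controls(n_negative, genome, rng, exclude=taken), start=1
    ):
        guides.append(
            GuideRecord(
                guide_id=f"neg_{i:04d}",
                spacer=spacer,
                chrom="",
                pam_site=0,
                strand="+",
                offset=None,
                target_promoter_id=None,
                gene_id=None,
                category=CATEGORY_NEGATIVE,
                genome_hits=0,
            )
        )

    lib = GuideLibrary(
        guides=guides,
        design_params={
            "window": window,
            "guides_per_promoter": guides_per_promoter,
            "n_negative": n_negative,
            "seed": seed,
        },
    )
    log.info("library composition: %s", lib.category_counts())
    return lib


def summarise_library(library: GuideLibrary | pd.DataFrame) -> dict[str, int]:
    """Per-category record counts for a library (or an S2-style guide table)."""
    df = library.to_frame() if isinstance(library, GuideLibrary) else library
    counts = df["category"].value_counts().to_dict()
    counts["total"] = int(len(df))
    return {k: int(v) for k, v in counts.items()}
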