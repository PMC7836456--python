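# Methods

This note documents the models, defaults and numerical choices behind
`isoscreen`, and what the synthetic benchmarks do and do not demonstrate.

## Promoter gain/loss calling

Input is per-promoter H3K4me3 signal for paired tumour/normal samples
(17 pairs by default, matching the profiling design the pipeline targets).
For pair *i*, `log2fc_i = log2((T_i + c) / (N_i + c))` with pseudocount
`c = 1` (configurable).  The pseudocount keeps zero-coverage promoters
finite and shrinks fold changes where signal is too low to be trusted.

A pair is *gained* at `log2fc ≥ t` and *lost* at `≤ −t`, with `t = 1`
(2-fold, the conventional ChIP effect size).  The promoter is **gained**
when gained pairs number at least `min_pairs = 2` *and* exceed lost pairs;
**lost** symmetrically; otherwise unaltered.  The majority rule exists
because with 17 pairs a promoter can exceed the recurrence cutoff in both
directions; without it the two calls would not be mutually exclusive.
Screen targets are called promoters whose isoform is expressed, FPKM ≥ 5
inclusive.  Missing expression values are treated as 0 (conservative:
never select without evidence of expression) and logged.

Calls are antisymmetric under swapping tumour and normal, invariant to
joint rescaling of both channels (with the pseudocount rescaled alike),
and invariant to promoter order.

For users starting from bedGraph tracks rather than a signal table,
signal is summed as value × overlap over `[TSS − flank, TSS + flank)`
with `flank = 500` bp by default; all coordinates in the package are
BED-style 0-based half-open, a TSS being a single 0-based position.

## Guide design

Candidates are all 20-mers immediately 5′ of an NGG PAM on either genomic
strand.  The guide's *offset* is measured from the PAM-proximal end of the
protospacer — the base dCas9-KRAB effectively occupies — to the TSS,
signed in transcript orientation, and must satisfy |offset| ≤ 150 bp
(inclusive).  Spacers containing non-ACGT characters or the Pol III
terminator TTTT are excluded (the latter can be disabled).

Specificity is exact-match uniqueness: a spacer is kept only if it (or its
reverse complement) occurs exactly once across the genome, with no
mismatch-tolerant scoring.  Two matchers implement this: a simple sliding
scan used for verification and single queries, and a 2-bit-packed k-mer
scan used to screen whole candidate sets in one genome pass; they agree by
construction and are cross-checked in the tests.  Palindromic spacers
count each site once.

Per promoter, `min(6, available)` guides are chosen by |offset| ascending,
ties broken by offset sign (+ before −) then lexicographic spacer, making
the design byte-deterministic.  AT/GC-rich windows with fewer than 6
unique candidates return what exists plus a shortfall warning rather than
failing — real promoter libraries have such promoters.

Negative controls are seeded random 20-mers rejection-sampled to zero
genome hits, GC fraction in [0.40, 0.60] and no TTTT.  Cloning oligos are
the fixed 32-nt 5′ handle + spacer + 31-nt 3′ handle (83 nt total,
emitted byte-exactly).

## Count deconvolution and depletion scores

Reads assign to guides by their extracted 20-mer: either a fixed offset in
the read or, for vector-style reads, the 20-mer following the constant
`CACCG` prefix.  At `mismatches=1`, a read matching exactly one guide at
Hamming distance 1 is assigned; variants reachable from two or more guides
are discarded as unassigned, and exact matches always take precedence.
Assigned + unassigned = total reads, per sample.

Size factors are median-of-ratios (each sample's counts against the
per-guide geometric mean, over guides positive everywhere), rescaled to
geometric mean 1.  Depletion is
`lfc = log2((n_s + 1) / (n_ref + 1))` on normalized counts, each day-21
replicate scored separately against the DNA pool; replicates are kept
separate so the rank-aggregation stage sees their variance rather than an
average.

## α-robust rank aggregation

Guides are ranked per replicate by lfc ascending (most depleted first) and
normalized by the library size G.  Ties take average (mid)ranks: tied
guides must be exchangeable, otherwise a fully tied column would rank
guides by identifier and manufacture hits.  (The exported per-guide score
table, by contrast, reports strict 1..G ranks with identifier tie-break,
which is the natural bookkeeping form.)

A transcript with guides' sorted normalized ranks r(1) ≤ … ≤ r(n)
(replicate lists concatenated, so n = guides × replicates) scores

    ρ = min over {j : r(j) ≤ α} of Pr[Binomial(n, r(j)) ≥ j],

the tail probability that at least j of n uniform ranks fall below r(j);
ρ = 1 if no rank clears α.  α = 0.25 — only the top quarter of the ranked
list can contribute evidence; this is the customary default for this
statistic and is configurable.

Significance: the null resamples n ranks uniformly without replacement
from {1..G}/G (n_perm ≥ 100, cached per n; the without-replacement draw is
an approximation once replicates are concatenated, since a guide may
repeat a rank across replicates — negligible at screen scale).  The
add-one estimator `p = (1 + #{ρ0 ≤ ρ}) / (n_perm + 1)` never returns 0 and
keeps the test valid.  The null ρ distribution has an atom at 1 of mass
(1 − α)ⁿ, so null p-values are sub-uniform near 1 (conservative), which is
why calibration checks compare independent null samples rather than
testing uniformity.  FDR is Benjamini–Hochberg across scored transcripts
per cell line, hits at FDR ≤ 0.1.  Depletion is the screen's readout;
enrichment is available as the mirrored one-sided analysis.

## Hit filtering

Pan-essential annotation is gene-level (DepMap-style lists are gene-level)
and exact-match; case-insensitive near-misses are logged, not flagged.
Flagged transcripts stay in per-line score output but cannot be final
hits.  The multi-line intersection counts cancer lines with FDR ≤ 0.1,
excluding the normal line (recorded separately); differing promoter
universes are united with absent-as-not-essential.  The bidirectional
filter measures TSS-to-TSS distance, strand-agnostic, strict `<` at the
2000 bp default (`max_distance = 0` disables it exactly); a hit whose
nearest other TSS is closer and belongs to a pan-essential gene is
cleared, since CRISPRi at the hit promoter silences that neighbour.
Non-pan-essential neighbours flag the hit for review without clearing it.
Final ordering: breadth across cancer lines, then not-essential-in-normal,
then best FDR.  All filters are idempotent.

## Synthetic data generator

The generator emulates the statistical structure of a promoter-usage
screen end to end, with deterministic planted counts
(`round(fraction × N)`) so study-scale runs reproduce design numbers
exactly:

- **Genome** — one promoter per 5 kb slot (same-gene promoters ≥ 5 kb
  apart); each TSS window re-rolled until it holds ≥ 10 candidate spacers;
  each bidirectional decoy gets a pan-essential neighbour TSS 1.5 kb away.
- **Signals** — log-normal baselines (meanlog 3, sdlog 0.5) shared within
  a pair; gained promoters multiplied by 2² in a random ≥ 2-pair subset;
  multiplicative exp(N(0, 0.25)) noise per channel.  Under these
  conditions the caller's planted-gain recall is ≥ 0.95 and the false-gain
  rate ≤ 0.05 — the operating point the defaults were chosen for.
- **Expression** — expressed isoforms at lognormal FPKM ≈ 33, unexpressed
  ≈ 1, so the FPKM ≥ 5 gate separates them nearly perfectly.
- **Counts** — gamma-Poisson negative binomial, var = μ + 0.05 μ², DNA
  pool at 1000 reads/guide (500× in the spike-in benchmark), two day-21
  replicates per line; day-21 mean = pool mean × 2^effect with effect −2
  for essentials.  The central causal premise is structural: the effect
  applies only to guides on an *expressed* planted-essential isoform;
  guides on the unexpressed isoform of the same gene and negative controls
  get effect 0, and decoy-promoter guides inherit the neighbour's
  essential effect.
- Five cancer lines plus one normal line; planted cancer dependencies have
  no effect in the normal line, positive controls deplete everywhere.

Everything is byte-deterministic under a fixed seed.

**What the generator does not model:** chromatin context and guide
efficiency variation (every planted guide gets the full effect), MOI and
infection stochastics, clonal dynamics over the 21 days, sequencing error
in reads, GC/position biases, and input-normalisation artefacts in ChIP
signal.  Passing benchmarks therefore demonstrate the correctness and
calibration of the statistics under the stated noise model, not
performance on real screens, where per-guide efficacy variation in
particular will lower sensitivity.

## Benchmark problem sizes

Benchmarks are sized to make their statistical claims at modest cost:
spike-in recovery uses 800 promoters × 6 guides with 20 planted
dependencies at 4-fold depletion, 500× coverage, 5000 permutations; null
calibration pools 10–20 screens of 200 promoters at 1000 permutations;
the end-to-end pipeline default is 150 genes with one planted decoy and
2000 permutations; Monte-Carlo validation of ρ uses 10⁶ draws per
instance.  The study-scale selection benchmark plants 820 expressed gained
isoforms among 2050 and recovers exactly 820 in the noiseless limit
(>99.5% recalled under default noise).

## Known limitations

- Uniqueness filtering is exact-match only; near-match off-targets
  (1–3 mismatches) are not scored, mirroring the design rule the pipeline
  implements rather than a full off-target model.
- The permutation null treats guides as exchangeable within a line;
  guide-quality covariates (GC, position) are not modelled.
- The bidirectional filter clears a hit only on pan-essential neighbours;
  a neighbour essential in the screened lines but absent from the
  pan-essential list would not clear it.
- FASTQ deconvolution is single-end, forward-orientation, constant-prefix
  or fixed-position; UMIs and lane demultiplexing are out of scope.
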