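# Methods

This note documents the models, estimators, default parameters and design
choices behind `readerstab`, and what the synthetic-data generator does and
does not emulate.

## Decay model and estimator

Transcription shut-off (actinomycin D) turns mRNA abundance into a pure
decay process, dC/dt = −K_decay·C, hence ln(C_t/C_0) = −K_decay·t and
t½ = ln 2 / K_decay. The estimator is ordinary least squares of
ln(C_t/C_0) on t **through the origin**: the intercept is pinned at zero
because ln(C_0/C_0) = 0 holds by construction, so a free intercept would
only absorb noise in C_0 into a biased slope. Specifics:

- C_0 is the mean of the normalized t = 0 replicates; replicate values at
  later timepoints enter as separate observations (a `replicate_mean` flag
  averages abundances within each timepoint first — with balanced
  replication the two differ only through Jensen's inequality on the log).
- Zero abundances are dropped, not offset by a pseudocount; a gene keeps a
  fit only if t = 0 and at least one later timepoint carry signal,
  otherwise it is flagged `insufficient`.
- A non-positive K_decay (abundance flat or increasing) is reported as
  `increasing` with an undefined half-life. Reporting an honest NA was
  preferred to clipping to an arbitrarily long half-life, which would
  distort downstream medians and fold changes.
- The RT-qPCR-style stability fit y = exp(−A·x) on relative expression is
  the identical estimator (A = K_decay) applied to values normalized to 1
  at t = 0; a {0, 2, 4} h timepoint preset matches that assay design.

## Spike-in calibration and normalization

Per sample, a through-origin least-squares line of spike-in count against
known amount (slope = Σxy/Σx²) gives the sample's response; factors are
slopes rescaled so a designated reference sample (first WT t = 0
replicate) equals 1. "Linear fitting" is done on the linear scale because
the spike-in response is proportional and zero input must map to zero
counts; a log-log variant (geometric mean count/amount ratio) is available
behind a flag. The reference choice is inert for half-lives — only
within-gene ratios across time enter the decay fit — and a test asserts
this invariance.

Normalized expression is `count / (factor × length_kb × depth_millions)`
with the factor applied exactly once and a single run-wide depth constant
(the reference sample's raw depth in millions); all between-sample scaling
is carried by the spike-in factor alone. RPKM and FPKM are the same
formula here (single- vs paired-end naming); tables carry a units flag.
The expressed-gene filter is strict (value > 1) on the mean of the
relevant condition's t = 0/control replicates. PAC abundances use TPM
(count × 10⁶ / sample total), which sums to 10⁶ per sample by identity.

Whether the original assays calibrated spike-ins per sample or per batch
is not stated anywhere authoritative; per-sample fitting is implemented as
the safer default.

## PAC construction and the APA shift test

- **Clustering**: single linkage per chromosome and strand with an
  inclusive 25-nt rule — consecutive sites at distance ≤ 25 nt merge
  ("within 25 nt" read inclusively; both boundary cases are covered by
  tests). Clustering runs on sites pooled across samples so PAC
  identities are shared by all conditions.
- **Representative position**: the member site with the highest pooled tag
  count (5′-most on ties); a cluster-midpoint alternative sits behind a
  flag. The representative anchors gene assignment, half-splitting and
  3′UTR distances, being more robust than cluster edges.
- **High-confidence filter**: TPM ≥ 3 in **at least one** sample (the
  stricter every-sample rule is a flag).
- **Gene assignment**: a PAC belongs to the strand-matched gene whose span,
  extended 500 nt past the 3′ end, contains the representative position;
  closest stop codon breaks ties, exact ties are flagged ambiguous.
  Positions in the downstream extension are labelled 3′UTR.
- **Shift test**: genes need ≥ 2 PACs; the midpoint between the 5′-most
  and 3′-most representative positions (transcript orientation) splits
  PACs into halves, a PAC exactly at the midpoint counting as 5′
  (deterministic tie-break). Pooled **raw tag counts** per half per
  condition form the 2×2 table — Fisher's exact test requires integer
  counts, so TPM enters only the usability filter (pooled TPM > 0 in both
  halves in both conditions, applied per condition as a valid 2×2 needs)
  and the confidence filter; a `fisher_on_rounded_tpm` flag provides the
  literal-TPM alternative. Replicates are pooled by summing within
  condition: one table per gene per comparison.
- Only 3′UTR/terminal-exon PACs of a gene enter the shift analysis in the
  pipeline: a CDS-internal PAC is not an alternative 3′ end, and because
  it lies 5′ of every genuine poly(A) cluster it would drag the midpoint
  out of the 3′UTR and collapse the table into background-vs-3′UTR.
- **Fisher's exact test** is implemented by enumeration of the
  hypergeometric distribution over the observed margins: two-sided
  p = Σ P(table) over tables with probability ≤ the observed one
  (relative tolerance 1 + 1e−7 for floating-point ties, the standard
  convention). The pmf is evaluated through log-gamma, which is vectorized
  and keeps sequencing-scale tables (totals ~10⁵) fast; tests verify exact
  agreement with integer-arithmetic enumeration for all tables with total
  ≤ 40 and with an independent library implementation on random tables.
  Any zero margin returns p = 1 with an undefined odds ratio. The reported
  odds ratio is the sample ratio ad/bc; a continuity-corrected version
  exists for display only and never affects p.
- **Weighted 3′UTR length**: L = Σ dᵢ·TPMᵢ / Σ TPMᵢ with dᵢ the
  strand-aware genomic distance from the representative position to the
  stop codon. Genomic (not spliced) distance is used — the synthetic genes
  have intron-free 3′UTRs; on real annotations with 3′UTR introns this
  overestimates lengths and is flagged as a limitation. Between-genotype
  comparisons are paired-by-gene two-sided t tests within each target
  group.

## Target classification

"Overlaps an m⁶A site" is operationalized as ≥ 1-nt same-strand interval
overlap between an ECT2 peak and an m⁶A peak on the same gene. Genes with
an m⁶A peak but no ECT2 peak belong to none of the three classes (the
Non-target definition requires neither), and are reported as excluded so
the four labels always partition the gene universe. Binding-site counts
are peaks per gene, binned {1, 2, >2}. PAB target filtering consumes
precomputed enrichment tables (IP/input ≥ 1, p < 0.05, FPKM > 1, boundary
semantics as printed); peak calling itself is out of scope. Percentages
from set intersections round to 1 decimal by default with a 2-decimal
mode.

## Group comparisons

Each target group is compared to the Non-target reference (a pairwise
option exists) with a two-sided Mann–Whitney U: midrank ties, exact
enumeration for small untied samples, tie-corrected normal approximation
otherwise. No multiple-testing correction is applied across groups — the
p-values are reported raw, as is conventional for these stratified ECDF
figures — and ECDF plots are right-continuous convenience artifacts; the
U statistics are the tested surface. TE = FPKM_ribo/FPKM_RNA on the strict
FPKM > 1 intersection of both assays, with CDS-only FPKM assumed upstream.
The DE rule (fold change ≥ 2 in either direction and p < 0.05) consumes
p-values computed upstream by the caller's DE package; a Welch t-test
fallback is provided but is not the primary path.

## Synthetic-data generator

Every generator is a pure function of (config, seed) with a written truth
record. Defaults mirror the study designs the analyses expect:

- **Decay course**: two genotypes × timepoints {0, 4, 6} h × 2 replicates,
  5 × 10⁶ expected reads per sample; true half-lives log-uniform on
  1–10 h; a configurable fraction of genes destabilized in the mutant
  (half-life × 0.5), optionally pinned to a simulated target class.
  Counts are negative-binomial (dispersion 0.05) around
  depth × weight × exp(−ln2·t/t½) × sample factor, with length-scaled
  log-normal abundance weights and log-normal per-sample library
  distortions (σ = 0.25).
- **Spike-ins**: an ERCC-like series of 24 known amounts spanning four
  orders of magnitude at ~3% of library depth. Spike-in counts carry
  technical noise only (NB dispersion 0.005): they are synthetic RNAs
  added to the extract, so biological gene-level overdispersion does not
  apply to them. Giving them biological-scale dispersion would put a
  ~20% noise floor under every calibration factor regardless of depth —
  an artifact of the generator, not of the assay being emulated.
- **Poly(A) tags**: ~10⁷ tags per sample (the order of the real libraries;
  configurable). Genes carry one or two true clusters ≥ 40 nt apart in
  the 3′UTR (so the 25-nt rule can never fuse them and clustering recovery
  is exactly checkable), member sites scattered ± 10 nt, ~10% of each
  gene's tags at an internal CDS position as off-3′UTR background (tags in
  3′UTR/terminal exon ≥ 80% by design). A configured fraction of
  multi-cluster genes swaps proximal/distal usage 0.7 → 0.3 between
  conditions. Noise: the per-sample **gene total** is negative-binomial;
  given the total, tags are allocated to sites **multinomially** by usage
  fraction. This is the conditional model under which Fisher's test is
  calibrated; overdispersing the within-gene split instead would not
  represent poly(A)-site choice (which is conditional on the transcript
  being sequenced) and makes any count-based test anticonservative at
  depth.
- **Peaks**: ECT2 membership Bernoulli(0.3); m⁶A, PAB2, PAB4 conditional
  on ECT2 with probabilities 0.7/0.6/0.55; 1–4 ECT2 sites per target with
  probabilities (0.4, 0.3, 0.2, 0.1); m⁶A peaks co-located with the first
  ECT2 peak (overlap guaranteed by construction); 5% of non-ECT2 genes get
  an m⁶A-only peak to exercise the excluded class.
- **Expression pair**: ribo = TE_true × RNA × lognormal noise with
  log-TE σ = 0.5 and noise σ = 0.15 (log TE recovery correlation ≈ 0.95).

What the generator does **not** emulate: read-level artifacts (mapping
bias, PCR duplication, internal priming), intron-containing 3′UTRs,
overlapping or nested genes, antisense transcription, batch structure
beyond one scalar factor per sample, and correlated gene-gene expression.
Passing tests therefore demonstrate the estimators' correctness and
calibration under the stated sampling models, not robustness to alignment
artifacts or annotation errors in real libraries.

## Problem sizes used in checks

Recovery and calibration checks run at the design scale the analyses
assume: 500 genes × 5 × 10⁶ reads for half-life recovery (median relative
error < 20%, rank correlation > 0.9), 1000 multi-PAC genes at ~200 tags
per gene and condition for shift-test type I error (≤ 0.06 at α = 0.05)
and power (≥ 0.90 for the 0.7 → 0.3 swap), 1000 genes for the
group-comparison patterns (≥ 200 genes per compared group), and 100
simulation repeats for the TE null behaviour. Exhaustive Fisher
equivalence covers every 2×2 table with total ≤ 40.

## Numerical choices and degenerate inputs

- Through-origin slopes use closed-form sums; no iterative optimisation
  anywhere, so fits are deterministic and platform-stable.
- Coordinates are 0-based half-open internally everywhere; GFF3 converts
  at the reader/writer boundary (1-based closed). The stop codon anchor is
  the 3′-most coding base, strand-aware.
- Degenerate inputs have defined outcomes rather than exceptions wherever
  a flag is meaningful: zero-margin Fisher tables (p = 1, odds ratio NaN),
  zero-TPM weight sums (NaN, flagged), single-PAC or zero-half genes
  (skipped with reason), groups smaller than 2 (skipped with warning).
  Configuration errors (negative fractions, zero depth, missing columns)
  raise immediately with the offending field named.
- Pipeline outputs carry a provenance header (version, config hash, seed);
  identical configuration yields byte-identical artifacts.
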