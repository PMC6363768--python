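# Methods

`isomirdiff` detects **templated isomiRs** — end-shifted variants of
canonical mature miRNAs whose sequence is read verbatim off the
pre-miRNA hairpin — from plant small RNA-seq libraries, and tests them
for differential expression between stress conditions.

## Pipeline model

Reads are 3'-adapter-trimmed, collapsed to unique sequences with
per-sample counts, and purged of rRNA/tRNA/snoRNA/lncRNA matches before
any miRNA analysis.  Every comparison in the pipeline is **exact**
(zero mismatches):

* *Adapter trimming* removes the leftmost occurrence of an adapter
  prefix of length ≥ `min_overlap` (default 5) with mismatch fraction
  ≤ `max_mismatch_rate` (default 0.1, cutadapt's convention) and all
  bases 3' of it.
* *Contaminant exclusion* removes a collapsed read iff it occurs as an
  exact substring of any contaminant reference on either strand
  (equivalent to zero-mismatch alignment, matching the stringency of
  the precursor mapping step).
* *Precursor mapping* reports every exact sense-strand occurrence of a
  read on every precursor hairpin, so all retained variants are
  templated by construction; internal-SNV ("polymorphic") variants are
  excluded by construction.

Per-sample **clean-read totals** — the N1/N2 library sizes of the count
test — are computed after contaminant removal by default
(`totals_stage: post_filter`); `post_trim` is available because the
field's usage of "clean reads" is not uniform.

### Classification

A read overlapping an annotated mature interval by at least
`min_overlap_frac` (default 0.75) of the mature length, with terminal
offsets |Δ5'|, |Δ3'| ≤ `max_offset` (default 5 nt), is classified by its
offset pair: `canonical` (0, 0), `five_prime`, `three_prime`,
`three_prime_plus1` (0, +1 — a single templated 3' addition, tracked
separately because single-base 3' extension is the dominant plant
terminal-modification event), or `both_ends`.  A read hitting several
precursors yields **one** record listing the union of overlapped
matures, with its counts attributed once (sequence-centric counting, no
fractional assignment); offsets come from the best hit (smallest
|Δ5'|+|Δ3'|, ties by smaller |Δ5'|, then precursor and mature id).
Canonical-equal reads are reported but excluded from isomiR summaries.
IDs `t-<species>-isomiR-<n>` are assigned in descending total count
(ties lexicographic by sequence), so reruns are reproducible; the order
itself is a convention.

## Differential expression

### Mapping-based statistic

For a count x in a library of N1 clean reads versus y in a library of
N2, the count in the second library conditional on x follows

    p(k | x) = (N2/N1)^k (x+k)! / ( x! k! (1 + N2/N1)^(x+k+1) ),

the Audic–Claverie conditional distribution — a negative binomial
NB(x+1, q) in k with q = N2/(N1+N2), depending on the libraries only
through their ratio.  `audic_claverie_p` returns

    p_raw = min( Σ_{k≤y} p(k|x), Σ_{k≥y} p(k|x) ),

both tails including k = y.  Terms are evaluated with the multiplicative
recurrence p(k+1|x) = p(k|x) · q · (x+k+1)/(k+1) in linear space under
an explicit power-of-two scale factor, so the statistic is exact to
double precision even where the starting term underflows by hundreds of
orders of magnitude (large x, skewed ratio); the upper tail switches
from complementation to direct forward summation when cancellation
would destroy it.  Against a 40-digit direct-summation oracle the worst
absolute deviation over x, y ≤ 200 and ratios 0.2–5 is ~1e-14.

**Calibration note.**  Rejecting when the *minimum* tail is below α is
a test of size up to 2α: by exact enumeration under an iid Poisson(20)
null the min-tail form rejects 8.6% of pairs at α = 0.05.  The pipeline
therefore reports the conventional doubled two-sided p-value
(min(1, 2·p_raw); null size 4.1% in the same enumeration) as
`p_mapping` by default, and exposes `double_tails=False` for the raw
min-of-tails convention.  The raw form is kept as the statistic's
defining closed form (e.g. p(0, 0, N, N) = 1/2 exactly).

The mapping test pools replicate counts within each condition — the
statistic is defined on two libraries — and is exact under Poisson
sampling but anti-conservative under biological replicate
overdispersion; that is precisely the gap the model-based companion
covers.

### Model-based companion test

A deliberately simple negative-binomial Wald test on replicated counts
(not a DESeq2 port — no dispersion shrinkage, Cook's distances or
independent filtering):

* size factors by median-of-ratios over isomiRs with all-positive
  counts (total-count ratios as fallback);
* per-isomiR dispersion α by method of moments on normalized counts,
  α = (s² − μ̄)/μ̄², floored at 1e-8 (the Poisson limit);
* Wald statistic: difference of log group means over the delta-rule
  standard error sqrt((1/μ_a + α)/n_a + (1/μ_b + α)/n_b), referred to a
  **t distribution with n_a + n_b − 2 degrees of freedom**.

The t reference is the load-bearing small-sample choice: with 3+3
replicates the moment dispersion estimate is noisy and a normal
reference rejects visibly above its nominal level, while the t(4)
reference holds the empirical null rejection at 5.6% (2,000 NB-null
isomiRs, dispersion 0.1).  The cost is power at very small α (~70% at
p < 0.01 for a 4-fold change at mean 100), while power at α = 0.05
stays ≥ 90% under the same conditions.  The test requires ≥ 2
replicates per condition; otherwise `p_model` is absent and only the
mapping flag contributes.

### Comparisons, fold change, flags

Within each experiment with control C and stress conditions S1..Sn (in
design-table order), the comparison set is {(C, Si)} plus the
consecutive ladder {(S_{i-1}, S_i)}.  Fold change is the
reads-per-million ratio with a pseudocount,
log2(((y+c)/N2) / ((x+c)/N1)), c = 0.5 by default; positive means
higher in the stress (condition-b) library.  An isomiR is called by a
method when its p-value ≤ α (default 0.05) and |log2FC| ≥ 1 (both
thresholds configurable); the intersection requires both methods.  Raw
p-values are reported by default; Benjamini–Hochberg adjustment is a
flag.

## Target-mimic (PeTM) alignment

A plant endogenous target mimic is a transcript whose miRNA-complementary
site sequesters the miRNA.  The site is padded by 50 nt each side
(clipped at transcript ends) and the query's reverse complement is
Smith–Waterman-aligned against the window: match +1, mismatch −1,
G:U wobble +0.5, linear gap −2.  In reverse-complement string space the
duplex G:U wobbles are the aligned pairs (A, G) and (C, T) — query A
stands for miRNA U facing target G, query C for miRNA G facing target
U.  (A literal "G:T" string reading would instead reward biological
C:A/A:C mismatches; with the correct duplex set the score is *not*
invariant under reverse-complementing both sequences, because
complementation maps a wobble to a mismatch.)  Ties are broken toward
the smaller window start, then fewer gaps; the midline renders '|' for
Watson–Crick pairs and ':' for wobbles.  The scoring values are a
rendering convention, not a target-prediction model; isomiRs are joined
to PeTM entries through their overlapped canonical matures.

## Synthetic data generator

The generator emits exactly what the pipeline consumes plus a truth
table, and its defaults are the conditions under which the package's
claims are tested:

| parameter | default | meaning |
|---|---|---|
| n_precursors | 50 | uniform-random hairpins, 120 nt |
| mature_length | 21 | one mature interval per precursor |
| isomirs_per_mature | 6 | end-shift variants beside canonical and 3'+1 |
| conditions × replicates | 2 × 2 | control + one stress |
| library_size | 100,000 | exact FASTQ record count per sample |
| fraction_3p_plus1 | 0.2 | read mass given to (0, +1) variants |
| n_de / de_fold_change | 20 / 4 | planted changes, alternating up/down |
| dispersion | 0.1 | NB replicate noise (gamma-multinomial) |
| contaminant_fraction | 0.05 | reads drawn from contaminant references |
| error_rate | 0 | optional uniform substitutions |

Counts follow a gamma-multinomial scheme (gamma shape 1/dispersion, a
fixed read budget split multinomially), giving negative-binomial-like
marginals at exactly `library_size` reads per FASTQ.  Raw reads are
insert + adapter truncated to 36 nt.  Planted fold changes alternate up
and down so library totals stay balanced; one-sided planting would
shift every null's log2FC through the totals.  The catalog keeps only
variants that occur exactly once across all precursors and survive
adapter trimming intact, so each plant is unambiguously identifiable —
truth is defined by interval arithmetic, not by running the detector.

What the simulation does *not* emulate: hairpin secondary structure,
sequencing error by default (errored reads can only be dropped by an
exact-match pipeline, an optional substitution rate exists to test drop
behaviour), non-templated additions, position-dependent quality, or
ligation bias.  Recovery results on this generator therefore certify
the pipeline's bookkeeping and classification logic, not robustness to
real-library artefacts.

### Measured behaviour at the defaults

With zero error the pipeline recovers every planted variant that
receives at least one read, with exact class and offsets and no
spurious calls (4 × 100,000 reads, 50 precursors).  At the count level
(200 planted 4-fold isomiRs among 2,000 NB nulls, 3+3 replicates,
dispersion 0.1) the pooled mapping method at p ≤ 0.05, |log2FC| ≥ 1
attains sensitivity ≈ 1.0 with empirical FDR ≈ 0.11: the false calls
are almost entirely nulls whose replicate overdispersion pushes
|log2FC| past 1, i.e. a property of the Poisson-assuming statistic
under NB noise, not of its implementation.  The model-based test's
calls are nearly a subset of the mapping calls under these conditions.

## Numerical and degenerate-input conventions

* Coordinates 0-based half-open internally; U→T normalization at parse
  time; N allowed only in reads (dropped with reason), never in
  references.
* p-values clamped into (0, 1]; an extreme-imbalance tail that
  underflows double precision reports the smallest positive double.
* Empty contaminant set: pass-through with a logged warning.  A sample
  with zero surviving reads is an error (its N would be 0).
* Every discarded read carries a reason (`empty`, `no_adapter`,
  `length`, `ambiguous_base`, contaminant category), and per-sample
  accounting ties out exactly in the run manifest.
* All randomness flows through one seeded generator per simulation;
  identical config + seed reproduces every output byte for byte.

## Known limitations

* The mapping statistic assumes Poisson sampling; with biological
  replicates it is anti-conservative and should be read alongside the
  model-based test (their intersection is the conservative call set).
* The model-based test is two-group only — no covariates, no GLM
  designs, no dispersion moderation across isomiRs.
* Multi-mapping reads are counted once per sequence; arm-level
  attribution of a sequence shared by several precursors is not
  attempted.
* PeTM alignment scores rank candidate mimic sites; they are not
  calibrated binding-energy predictions.
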