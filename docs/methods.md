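# Methods

## Scope and design

`mirsplice` implements a screening cascade, not an inference engine: every
stage consumes and emits flat tables with declared schemas, all thresholds
live in one `PipelineConfig`, and the stages downstream of the
differential-expression test are deterministic set operations that can be
checked exactly against planted truth.

## Differential expression of miRNA counts

The count matrix holds integer miRNA counts for two conditions (normoxia
`Nor`, intermittent hypoxia `IH`) at each exposure week, with replicate
structure encoded in the column names (`IH_w3_r2`). Per week:

1. counts-per-million normalization per sample (library size over all
   features);
2. log₂FC = log₂((mean CPM_IH + c) / (mean CPM_Nor + c)) with pseudocount
   c = 0.5;
3. two-sided Welch t-test on log₂(CPM + c) between the groups;
4. Benjamini–Hochberg adjustment across features within the week.

This test was chosen for transparency and oracle-checkability: the screen
consumes only (log₂FC, p) and is agnostic to the producing test, so an
exact negative-binomial test, shrinkage estimation or batch correction are
deliberately out of scope. Features with all-zero counts in a week are
dropped from that week's test and logged. Zero-variance ties produce
p = 1 rather than NaN.

Screening uses strict inequalities, p < 0.05 AND |log₂FC| > 1. The miRNA
screen reads the raw p-value, the gene-level DEG screen the adjusted one;
`use_adjusted` switches between them.

### Temporal categories

Categories are defined on the set of significant weeks: category 1
requires {1, 3, 5} with week 7 tolerated (the week-1 responders may remain
changed at week 7); categories 2 and 3 are exact-set matches on {3, 5, 7}
and {5, 7}. Patterns outside the three templates are reported as `none`,
never forced to the nearest template. A categorized miRNA is
direction-consistent when every significant week shows log₂FC < 0.

## Consensus targets

Candidate targets are pairs present in ≥ 2 of exactly 3 databases;
membership only, no scores. Gene identity is exact string match after
case-folding (the first-seen spelling is reported) — no orthology or alias
mapping, since database symbols and DEG symbols are assumed to share a
namespace. Predicted targets intersect candidates with the week's
upregulated DEGs, evaluated per significant week of the miRNA and reported
per week ("upregulated at any one significant week" rather than "at every
significant week"; the per-week report lets a consumer apply the stricter
reading by intersecting across weeks).

## Splicing screen

Event tables follow an rMATS-like schema: 0-based half-open ascending
coordinate 4-tuples, per-sample inclusion/skipping junction counts, and a
length-normalized inclusion level

    psi = (I / inc_len) / (I / inc_len + S / skip_len),

undefined (missing) when both counts are zero. Overlap is computed per
event type on gene symbols with p < 0.05 on both sides; same-site matches
require identity of gene, type, chromosome, strand and the full coordinate
tuple. "Reads" is interpreted as the mean over the treatment-side samples
of (I + S); `reads_side="both"` pools the knockdown-side samples instead.
Events pass at mean reads strictly > 10, then rank by descending |ΔPSI|
(signed ranking behind a flag), ties broken lexicographically by gene then
coordinates for reproducibility. Filtering and ranking commute, so
"filter then rank" vs a composite score is a presentation choice; the
filter-then-rank reading is implemented.

## Gel densitometry and gated testing

The exon-inclusion rate divides band volume by amplicon length before the
molar ratio, making it invariant to overall exposure scaling and to
rescaling one isoform's volume and length jointly. Group comparisons use a
Shapiro–Wilk gate at α = 0.05 per group: both pass → classical
pooled-variance two-sample t-test (Welch behind `equal_var=False`);
otherwise two-sided Mann–Whitney U (SciPy's exact distribution for small
tie-free samples, normal approximation with continuity and tie correction
otherwise). Shapiro–Wilk is this package's choice of normality test; the
gate's source convention names no specific test. Constant samples are
treated as failing the gate (the normality statistic is degenerate), except
two identical constant groups, which trivially return p = 1. Stars are
strict: `**` iff p < 0.01, `*` iff 0.01 ≤ p < 0.05; p exactly at a cut
point receives the weaker annotation. Groups below 3 observations are
rejected. Reporter wells are normalized per well as Renilla/Firefly, then
divided by the control group's mean ratio, and compared with the same
gated test.

## Synthetic data generator

The generator emulates the statistical structure of the study's inputs;
its defaults are the study conditions:

- **Counts**: negative binomial with a single shared dispersion 0.1
  (variance μ + 0.1 μ²) around per-feature lognormal baselines
  (median 200 counts, σ = 0.8 on the log scale). A planted miRNA's IH
  mean is multiplied by 2^log2_effect (≤ −1, i.e. downregulation) at its
  affected weeks only. 3 replicates per group per week by default — the
  replicate count is a convention of this package (N = 3 is the typical
  validation group size in such designs), not a documented sequencing
  depth; the recovery analyses use 4.
- **DEG tables**: planted upregulations draw log₂FC ~ U(1.2, 4) and
  adjusted p ~ U(10⁻⁸, 0.04), guaranteeing passage of the strict
  thresholds; every decoy fails at least one threshold (small fold change,
  non-significant p, or significant downregulation). Raw p is drawn below
  adjusted p.
- **Target databases**: planted pairs appear in exactly their stated
  databases; each decoy pair appears in exactly one, so 2-of-3 consensus
  recovers the plant with no false positives.
- **Event tables**: each planted event's junction counts distribute a
  fixed grand total of round(mean_reads × n_samples) reads over samples
  (multinomial), so the realized mean equals the planted value whenever
  the product is integral — this makes the strict > 10 filter boundary
  exactly testable (a plant at 10.0 is excluded with certainty). The
  baseline inclusion level is drawn from the window that keeps
  psi + ΔPSI inside [0.02, 0.98], so the planted ΔPSI is realized
  exactly rather than clipped. Same-site plants share the coordinate key
  across tables; gene-only overlaps shift all four coordinates by 500 nt;
  background events use gene pools disjoint between tables.
- **Gel bands**: volume = abundance × length × LogNormal(1, cv), cv = 0.1
  by default — multiplicative because densitometry error scales with
  intensity.

All randomness flows from one seed through one independent generator
stream per artifact (fixed spawn order), so identical configs give
byte-identical bundles and adding an artifact never perturbs another. The
truth sidecar (JSON) is derived from the config by brute force and written
with every bundle; tests compare against the sidecar, never against
generator internals.

What the generator does **not** emulate: read-level data (no FASTQ,
alignment or junction calling), between-sample library-size or batch
effects, correlated miRNA co-regulation, database-specific prediction
biases, partial gels or saturated bands. Passing tests therefore show
that the screening logic is correct and calibrated under the stated noise
model — not that the upstream quantifications of any real experiment are.

## Numerical choices and edge cases

- Strict inequalities at every published threshold (p, fold change, mean
  reads, stars); boundary fixtures assert exclusion at equality.
- BH adjustment via statsmodels, validated against a brute-force
  implementation in the tests.
- Ranking uses a stable sort (mergesort) with an explicit lexicographic
  tie-break, so reruns and platform changes cannot reorder ties.
- Table readers validate the exact header, dtypes, key uniqueness,
  coordinate ordering and junction-count syntax, reporting 1-based line
  numbers of offending rows; writers emit columns in schema order so a
  write–read round trip is the identity.
- The pipeline manifest records the config hash, seed, every threshold
  and per-stage row counts; identical config + inputs reproduce outputs
  byte for byte.

## Problem sizes in the shipped analyses

The packaged analyses run at deliberately modest sizes chosen to give
stable statistics: 300 miRNAs × 4 weeks × 2 conditions for the screen,
50 seeds (tests) / 25 seeds (acceptance script) for category recovery,
2000 (tests) / 1000 (script) replicates for gated-test calibration, and
1000 gel samples for PSI recovery. All scale linearly with their size
parameters.

## Known limitations

- The DE test is a screen, not a calibrated count model; with 2–3
  replicates its power profile differs from exact NB tests, which is why
  recovery guarantees are stated at |log₂ effect| ≥ 2 and n = 4.
- Gene-symbol matching is purely lexical; cross-namespace inputs will
  silently under-intersect.
- The same-site criterion requires exact coordinate identity; events
  differing by annotation version or a 1-nt convention shift do not match.
- The luciferase module normalizes and tests ratios; it does not model
  transfection-efficiency covariates.
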