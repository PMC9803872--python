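# Methods

## Model

The unit of analysis is the *epilocus*: a window delimited by four
consecutive CpG sites on the forward strand, with interval
[first C, fourth C + 1) in 0-based half-open coordinates. Four CpGs is a
deliberate compromise — enough sites to resolve within-region
heterogeneity, few enough that short reads still span the whole window
at usable depth (spanning coverage falls off quickly with a fifth CpG).

Every read (molecule) spanning the window contributes one *epiallele*,
a 4-bit arrangement of methylation calls. The analysis is position-blind:
epialleles are collapsed by their number of methylated CpGs into five
*methylation classes*, and the *MC profile* p = (p₀,…,p₄) is the vector
of class abundances among spanning reads. The implicit sampling model is
that reads are independent draws from a locus-specific class
distribution — multinomial sampling — which is also exactly what the
calibration and the synthetic generators simulate.

Profiles are compared with the Jensen–Shannon distance (JSD): the square
root of the mean Kullback–Leibler divergence of the two profiles from
their elementwise average, base-2 logarithms. This choice gives a true
metric bounded by 1, always finite (the average covers both supports),
and symmetric — properties the test suite verifies rather than assumes.
KL terms with zero numerator contribute zero; no pseudocounts or
smoothing are applied anywhere, because the JSD is only ever evaluated
against pairwise averages where it is finite by construction.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_cpg` | 4 | sites | window definition; 5 classes. Kept as a single constant, only 4 exercised |
| `max_length` | 100 | bp | epilocus span cap; typical short-read libraries support 70–100 bp, 100 is the permissive end |
| `min_coverage` | 50 | reads | subsampling error drops sharply between 25 and 50 reads (see calibration), plateauing thereafter |
| `upper_quantile` | 0.99 | — | per-sample coverage cap against collapsed repeats/PCR stacks; nearest-rank quantile, inclusive comparison |
| `jsd_cutoff` | 0.26 | JSD | same-source 95th percentile at 50 reads; ≤ means "same", > means "different" |
| `bin_size` | 1000 | bp | neighborhood-concordance bin width |
| `min_epiloci_per_bin` | 3 | epiloci | below three members "concordance" is nearly vacuous |
| `boot_reps`, `calib_reps` | 1000 | replicates | Monte-Carlo error ≈ ±0.01 on tail probabilities at this size |
| coverage grid | 20–200 step 10 | reads | the range where accuracy transitions from poor to saturating |

All thresholds live in `RunConfig`, round-trip through JSON, and are
echoed in every output file's `#` provenance header.

## Calibration

Two simulations justify the fixed thresholds.

*Coverage–error curve.* A high-coverage reference pool (tens of
thousands of reads) is repeatedly subsampled without replacement
(multivariate hypergeometric over patterns, or equivalently over classes
— class marginals are all that matter downstream) to each coverage on
the grid; the JSD between subsample profile and reference profile is
summarized by its 50th/95th percentiles. The median error roughly halves
between 20 and 50 reads; tripling coverage past 50 buys about the same
again, which is the diminishing-returns argument for the 50-read floor.

*Same-source null.* Pairs of independent 50-read samples are drawn from
one source and the JSD within each pair recorded. The 95th percentile of
this null is the cutoff for calling two profiles different with ≤5%
false-positive risk. For sources with all classes populated the null has
a closed large-sample form — 4n·ln2·d² is asymptotically χ² with 4
degrees of freedom, giving p95 ≈ √(χ²₄(0.95)/(4·50·ln2)) ≈ 0.262 — used
as an independent oracle in the tests.

The shipped calibration panel (`data/calibration_panel.json`) holds 25
synthetic sources: five shape families (binomial, bimodal,
binomial–bimodal blend, peaked, uniform–bimodal blend) at five average
methylation levels 0.1–0.9, spanning the full methylation range and
enriched for intermediate methylation where low-coverage estimation is
hardest. Each source carries a 4% uniform error floor emulating
bisulfite non-conversion and sequencing error: in real amplicon data no
methylation class is ever exactly empty, and without the floor
degenerate-support shapes (pure bimodal) would understate the null
(their effective degrees of freedom collapse). With it, per-source 95th
percentiles at 50 reads fall in ≈0.22–0.28 — the spread a user should
expect when re-deriving the cutoff from their own high-coverage data.
The panel is a config file precisely so an in-house amplicon panel can
be dropped in.

Whether the recommended cutoff should be the pooled percentile or a
per-source summary is genuinely open; the calibrate report exposes the
uniform-source value alongside the per-source min/max so either
convention can be read off.

## Pipeline conventions

*Discovery.* CpGs are indexed case-insensitively on the forward strand
(both strands of a CpG unit collapse to the C position; Ns never match).
Candidate windows advance one CpG at a time; spans above `max_length`
are dropped. Overlap removal is greedy leftmost-first per chromosome —
deterministic, and maximal in the sense that no rejected window could be
re-added. The coverage cap uses the nearest-rank (type-1) quantile with
inclusive comparison, so "equal coverages everywhere" removes nothing.

*Extraction.* Only reads with a valid Z/z call at all four CpGs count
(full-span rule); indels across a site or non-call symbols make the read
non-spanning. Bottom-strand reads (XG tag `GA`, falling back to the
reverse flag) have their calls shifted one base left onto the
forward-strand C so both strands pool. Duplicate-marked, secondary and
supplementary records are skipped; MAPQ filtering is off by default.
Paired mates are merged into one molecule observation by default, mate 1
winning in the overlap — counting both mates would double-count
fragments. Malformed call strings are skipped and tallied, never fatal.

*Classification.* The archetype vectors are the natural instantiations
of the five described shapes: extremal (1,0,0,0,0)/(0,0,0,0,1), the
half-half bimodal, the binomial(4, ½) bell, and the uniform. They are
overridable as config in case a different parameterization is wanted.
Ties in the nearest-prototype argmin break by label order D1<…<D5.
ECD/WCD is +∞ when a profile sits exactly on a prototype.

*Multi-sample.* Stability uses ≤ cutoff on the *maximum* pairwise JSD;
difference uses > cutoff. The boundary value itself therefore counts as
stable/unchanged — declared, since either reading of "above" is
possible. Consensus averaging is unweighted across samples (coverage is
carried along but does not weight); epiloci missing eligibility in any
sample are dropped with an explicit tally. delta_meth is condition B
minus condition A, stated in the output header.

*Concordance.* Epiloci map to 1-kb bins by midpoint, so straddlers
belong to exactly one bin. The bootstrap permutes the pooled member
labels across bins (without replacement, bin sizes preserved) and uses
the add-one p-value estimator (1 + #{null ≥ obs})/(reps + 1), which is
never zero.

## Synthetic data

Generators are pure functions of (spec, seed): class counts are
multinomial in the truth profile; within a class the arrangement is
uniform over the C(4,k) patterns, which is observationally equivalent to
any other arrangement law for every class-level statistic (the analysis
never looks at positions). Replicates share one truth by default, so
between-sample variation is pure sampling noise — matching the
conditions under which the 0.26 cutoff promises ~95% stable calls; an
optional Dirichlet jitter creates deliberately variant epiloci.
Per-sample RNG streams spawn from one root seed, so cohorts are
reproducible and sample order is immaterial. The BAM writer emits one
single-end forward-strand record per molecule with a consistent XM
string over a planted reference whose only CpGs are the requested ones.

What the generators do **not** emulate: bisulfite non-conversion and
sequencing error inside cohorts (the calibration panel models their
class-level effect, the read simulator does not inject miscalls),
mapping bias, RRBS fragment-end structure, and truth correlation between
neighboring epiloci. Passing round-trip tests therefore demonstrates
correctness of the bookkeeping and the statistics under the sampling
model, not robustness to alignment artifacts in real libraries.

## Numerical choices

Profiles renormalize exactly on construction and reject vectors whose
sum strays beyond 1e-6 (serialization keeps 10 significant digits so
round-trips stay inside the tolerance). JSD clips tiny negative
radicands and caps at 1, so float noise can't push a distance out of
range. Degenerate inputs fail loudly: empty count tables, single-sample
stability calls, consensus over variant epiloci, and KL with uncovered
support all raise typed errors rather than returning NaN.

Problem sizes in the test and acceptance runs (500-epilocus cohorts,
1000 calibration replicates, 10⁴ bootstrap replicates) are chosen so
Monte-Carlo error is comfortably below the asserted tolerances while the
full suite stays interactive (~10 s).

## Limitations

- Only n = 4 CpGs is exercised end-to-end, though the class count is a
  single constant.
- The haploid/allelic path treats allele-sorted inputs as two ordinary
  samples; no SNP-aware sorting is performed.
- The concordance test treats bins as exchangeable; real CpG density
  varies, so its null is conservative where epiloci cluster.
- No annotation joins (promoters, CpG islands, chromatin states) —
  outputs are BED/TSV precisely so standard interval tools can take over.
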