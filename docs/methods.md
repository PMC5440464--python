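# Methods

## The distinguishability model

An enhancer is modelled as a run of `w` independent Bernoulli positions,
each a motif hit with probability `p` (for `m` TFs of identical
specificity, `m·p`). The point probability of exactly `k` hits,
`P(k) = C(w,k)(mp)^k(1−mp)^(w−k)`, is compared against `1/N`, the
reciprocal of the accessible genome size: a cluster rarer than one
expected background occurrence is taken as distinguishable.

`P(k)` is read as the **point mass**, not an upper tail, and the minimum
site count is the smallest `k` at or beyond the distribution mode
(`floor(w·m·p)`) with `P(k) < 1/N`. Beyond the mode the pmf is strictly
decreasing, so the answer is unique; this reading reproduces the anchor
values 13 (N = 4.1 Mb) and 15 (N = 175.5 Mb) for `w` = 1000, `p` = 2×10⁻³.
Note a degenerate branch in the definition — the mode itself already
passing — cannot occur when `N ≥ w`, because a binomial mode always has
probability ≥ 1/(w+1); the implementation still returns the mode in that
case for completeness.

Computation is in log space via log-gamma, accurate down to point
probabilities of ~10⁻³⁰⁰ and lengths up to 10⁵ (a 10⁶ guard bounds the
linear `k` search). The test oracle uses exact rational arithmetic and is
independent of this path. Accessible genome sizes ship as constants:
`dnase_conservative` 4.1 Mb, `dnase_relaxed` 19.4 Mb, `whole_genome`
175.5 Mb.

The model ignores site overlap exclusion, position dependence within
motifs, and clustering of accessible regions; it is a back-of-envelope
bound whose value is in the trends (monotone in `w`, `p`, `m`, `N`), not
in any individual count.

## PWMs, scoring and score p-values

Pseudocounts: "a total of 0.01 per column", split across bases in
proportion to the background frequency —
`p_i(b) = (c_i(b) + 0.01·q(b)) / (C_i + 0.01)`. The per-column reading
(rather than 0.01 per matrix) is the one Patser-style tools normalise;
the total is configurable. With single-observation columns the correction
is not negligible (≈0.37 bits for a deterministic column against uniform
background); with realistic count totals it is.

Scoring is the standard log-odds sum in bits (base 2), consistent with the
`I` / `p = 2^−I` relation. Score significance is the exact tail
probability of a random background window, computed by discretising the
weight matrix to a 0.01-bit grid and convolving the per-position score
pmfs (O(L·range·4)). Thresholds are reported as natural-log p-values.
Scans score windows **on the same integer grid** the distribution was
built on, so observed hit rates and theoretical tail probabilities agree
exactly up to sampling error — there is no bin-boundary drift between the
scanner and the distribution.

Both strands are scanned by default (a `forward` option exists); a
reverse-strand hit is reported at its forward-strand offset with a strand
flag. Windows containing non-ACGT characters are skipped rather than
scored worst-case: skipping never fabricates hits. A site passing on both
strands at one offset counts twice (palindrome double-counting is
possible and intentional — each strand passes independently).

## Cutoff calibration

Each motif's cutoff comes from its own provenance: the training sites the
matrix was built from are scored (best window over offsets and strands per
sequence, since training sequences may exceed the motif width), and the
cutoff is the ascending nearest-rank 75th-percentile ln(p-value), so at
least 75% of usable training sequences pass. Sequences shorter than the
motif cannot be scored and are skipped and counted. Higher percentiles
give less negative (more permissive) cutoffs, and hit counts in any fixed
sequence are non-decreasing in the percentile — the basis of the
robustness claim that relative group trends are stable across percentile
choices.

## Architecture profiles

Per enhancer: length, per-TF hit counts `n_j`, total `n_total`,
`normalized_sites = n_total / (number of motifs searched)` — the
denominator counts motifs *searched*, including those with zero hits,
which is what makes cohorts scanned with different TF repertoires
comparable — and `p_av = Σ n_j 2^−I_j / n_total` over the TFs with hits.
`p_av` is undefined (None/NaN, never silently 0) for enhancers without
hits. Overlapping hits are all counted by default (no pruning rule is
assumed); a greedy most-significant-first non-overlapping option exists.

Interval overlap between two enhancer sets reports the fraction of query
intervals overlapping ≥1 bp of the other set, plus each query's best
overlap as a fraction of the shorter interval. Coordinates are 0-based
half-open throughout; BED output is native.

## Group statistics

Two-sided Mann-Whitney rank-sum tests: exact null enumeration for
tie-free samples with min(n) ≤ 8, normal approximation with tie
correction otherwise (the method used is recorded in every result).
Bonferroni correction is applied within one metric's family of pairwise
comparisons (matching per-panel heatmaps), not across metrics. Quartiles
use linear interpolation between order statistics — the common software
default; the convention matters because a cohort median can shift one
position under other conventions, so it is fixed and documented here.
Whiskers are at quartile ± 1.5·IQR, values beyond them listed as outliers.

## Synthetic data

The generator emulates the structure of real cohorts, not their sequence
biology:

- **PWMs** with a target information content: each column is a mixture of
  a random consensus base and the background, with a single mixing weight
  tuned by bisection (realised content within 0.1 bits of target; in
  practice ~10⁻⁶). Training alignments (default 50 sites) are sampled
  column-wise from the PWM, so the 75% calibration property is exercised
  with realistic score spread, not consensus-only sites.
- **Background** is i.i.d. with specified composition — no dinucleotide
  structure, repeats, or isochores.
- **Enhancers** have log-normal lengths (parameterised by median; log-SD
  0.35 default, a realistic right skew for enhancer length
  distributions), Poisson site counts, uniform non-overlapping site
  placement (exact gap decomposition, not rejection sampling), uniform
  strand, and sites sampled from the PWM. Planted-site truth tables are
  first-class outputs; every recovery statistic is measured against them.
- **Default cohorts**: the two-group spec plants 60 enhancers at median
  1300 bp with ~47 sites over a 24-motif panel versus 39 enhancers at
  800 bp with ~9 sites over 10 motifs; the six-stage spec decreases
  median length monotonically from 1400 to 650 bp. Panels span 8–14 bits
  of information content.

What passing tests on this data do **not** show: real enhancers are not
i.i.d. background with independent planted sites — they contain homotypic
clusters, repeats, biased composition and overlapping regulatory grammar.
Calibration and hit-rate results transfer to real data only insofar as
the background model does. Scan totals on low-information motifs are
dominated by statistically expected background matches (a ~10-bit motif
hits roughly once per kb per strand at permissive cutoffs); group
*differences* are the meaningful output, which is why comparisons, not
absolute counts, are the pipeline's endpoint.

## Numerical choices and edge cases

- Score discretisation: 0.01-bit bins; the enumeration tests bound the
  induced ln(p-value) error to one bin for widths ≤ 6.
- Cutoff ties: nearest-rank (ceiling) order statistic; ties at the cutoff
  all pass (`≤` comparison).
- Degenerate inputs are explicit errors, not silent defaults: empty
  alignments, all-zero site counts for `p_av`, empty groups, single-group
  axis analysis, infeasible site packing, `m·p ≥ 1`.
- RNG: a single `numpy` Generator seeded from the spec/seed argument
  drives all sampling in generation order; identical seeds give
  byte-identical cohorts.
- Problem sizes in the test suite (background lengths of 10⁵ bp, cohorts
  of ~100 enhancers, 1000-replicate null simulations) were chosen to make
  sampling error small relative to the asserted tolerances while keeping
  the suite quick to run.

## Known limitations

- Zeroth-order background only; no higher-order or positional background
  models.
- No motif discovery or re-alignment of training sites; matrices and
  alignments are taken as given.
- The per-TF specificity comparison uses all TFs in the configured panel
  (not only TFs with hits) — the alternative reading is noted in the
  pairwise comparison docs but not implemented as an option.
- Exact Mann-Whitney enumeration is limited to small tie-free samples;
  with ties the asymptotic path is used even at small n.
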