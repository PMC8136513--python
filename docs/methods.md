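# Methods

This note documents the models and procedures implemented in `tigerscan`,
the assumptions behind them, the numerical choices that were genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## The demographic model class

All simulation-based machinery operates on one model class: a set of
demes in a *continent–island (metapopulation)* arrangement.  Each sampled
population diverged from a (possibly nested) metapopulation at time
`T_DIV` generations before present and, looking backward in time, each of
its lineages derives from the metapopulation with a constant
per-generation probability `m` (the backward migration rate).  Any deme
may pass through *bottleneck epochs* of constant reduced diploid size;
an epoch's intensity is expressed as `t/2N` (duration over twice the
bottleneck size), so a short, severe contraction and a long, mild one
with equal `t/2N` produce comparable drift.  This structure captures a
set of recently founded, weakly connected island populations, such as the
four tiger subspecies (Sumatran, Bengal, Malayan, Amur) diverging from an
ancestral Asian metapopulation within the Holocene.

Defaults: mutation rate `0.35e-8` per site per generation and a
generation time of 5 years.  Both are configurable; the mutation rate in
particular is the single assumption that most directly scales inferred
times.

The bundled example configuration (`tigerscan/data/stage1_tigers.yaml`)
encodes the four-subspecies topology with divergence times between 1,500
and 1,840 generations, a founder effect for SUM and BEN, strong recent
bottlenecks for SUM and AMU, weak immigration (below one migrant lineage
per generation), and an ancient metapopulation bottleneck around 46,800
generations.  Sizes are a desk-scale calibration chosen once to reproduce
the qualitative structure (diversity ranking BEN > MAL > AMU > SUM,
mean branch-statistic ranking SUM, AMU above BEN, MAL) — they are not
published estimates.

## Coalescent simulator

The simulator is a continuous-time structured coalescent: within each
deme lineages coalesce at rate `k(k-1)/2 · 1/(2N)`, migrate to the parent
deme at rate `m` per lineage, and are moved wholesale into the parent at
their deme's divergence time.  Waiting times are exponential within
epochs of constant size; epoch boundaries come from divergence times and
bottleneck edges.  Mutations are placed on branches as a Poisson process
with rate `μ · L · branch length` under an infinite-sites model on an
integer coordinate grid (collisions redrawn), so every site is biallelic.

There is **no intra-window recombination by default**: one window = one
genealogy.  A uniform recombination rate can be configured, in which case
a Hudson-style ancestral-recombination-graph variant of the same
algorithm is used (lineages carry ancestral-segment lists; segment pieces
that reach the sample-wide MRCA are retired).  The ARG path is exact but
roughly two orders of magnitude slower at metapopulation-scale sizes, so
it is reserved for validation rather than bulk null generation.

Per-window seeds are derived from a master seed through
`numpy.random.SeedSequence(master, spawn_key=(index,))`, a counter-based
scheme that makes replicates order-independent and bit-reproducible.

### Validation oracles

Two independent implementations check the simulator in the test suite:

* a **discrete-generation Wright–Fisher forward simulator** of the same
  model class (`forward_wf_oracle`).  It tracks per-site allele counts in
  every deme (binomial reproduction, hypergeometric sampling of diploids
  at the present, Poisson influx of new mutations, continent–island
  migration as a mixture in the binomial success probability) and refuses
  models with `N > 500` or event times beyond 5,000 generations.  Sites
  are unlinked, so only single-site summaries (segregating sites, FST)
  are compared.  Burn-in is 20N generations, long enough that the
  truncated ancestral history carries negligible probability mass
  (`P(T2 > 20N) ≈ e^-10`).
* **msprime**, used purely as a cross-check of segregating-site counts on
  a two-deme split model.

Closed forms asserted directly: `E[T2] = 2N`, Watterson's
`E[S] = θ·a_{n-1}`, the neutral unfolded SFS `ξ_i ∝ 1/i`, and FST → 1
for long-isolated demes.

## The windowed scan

**Hudson FST** per site uses the unbiased two-population estimator
(numerator `(p1-p2)² - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`, denominator
`p1(1-p2) + p2(1-p1)`); a window's FST is the **ratio of sums** of those
site components, never a mean of per-site ratios.  Sites monomorphic
across both populations contribute 0/0 and are skipped.  Windows with
fewer than `min_sites` (default 10) usable sites, or a zero denominator,
report a missing value rather than zero.

**Branch times.**  Window FST converts to a divergence time
`T = -ln(1 - FST)` in coalescent units.  Negative FST estimates (legal
for the Hudson estimator) are clamped to zero before the transform, so
`T ≥ 0` and the branch-length interpretation survives; `FST = 1` maps to
infinity and is propagated as missing.

**mPBS.**  For four populations a, b, c, d the metapopulation branch
statistic of focal `a` is

    mPBS_a = [2(T_ab + T_ac + T_ad) − (T_bc + T_bd + T_cd)] / 6,

the arithmetic mean of the three classic three-population PBS values
with focal `a`.  This form is symmetric under relabeling of the three
non-focal populations and recovers the terminal branch exactly when `T`
is additive, which is what "the length of the branch leading to the
focal lineage" requires.  An asymmetric literal variant
(`2T_ab + T_ac + T_ad` in the first group) is available behind
`literal=True` for comparison; it is *not* symmetric and is not the
default.  The statistic assumes each population diverged independently
from the metapopulation with no subsequent migration between islands;
elevated drift (or selection) in the focal lineage lengthens its terminal
branch and inflates mPBS.

**Windows** are 50 kb sliding with a 10-kb step, 0-based half-open,
starting at 0 on every scaffold.  A terminal partial window is emitted
when it is at least half a window long, or when suppressing it would
leave bases uncovered (possible only when `step > window/2`); partials
are flagged.  A scaffold shorter than one window yields a single
flagged window.

**Outliers** are the top `ceil(f · n_nonmissing)` windows per population
at `f = 0.001`; ties at the cut are all retained; missing windows count
in neither numerator nor denominator.

**The neutral null** re-simulates windows under the fitted demographic
model (default desk scale 10⁴ windows; the machinery supports 10⁶) and
scores each exactly as an observed window.  Because a simulated window is
a single genealogy, the null has somewhat heavier tails than data whose
windows recombine internally; comparisons should therefore use data
generated the same way (as the self-consistency test does) or a model
with the recombination rate configured.

## Variant filtering

Filter order is fixed: genotype level first (calls with `DP < 10` or
`GQ < 30` become missing), then site level (minor-allele frequency
≥ 0.025 computed on non-missing alleles, then missingness ≤ 5%, then the
optional complete-cases rule), then scaffold level (drop scaffolds
shorter than 1 Mb).  Missingness is compared with integer counts to
avoid float boundary artifacts at exact thresholds.  Filtering is
idempotent.  Base-quality filtering operates at the variant-calling
stage and cannot be reproduced from a VCF; it is out of scope.

PCA is the plink-style variance-standardized genotype PCA: each site is
centered by `2p` and scaled by `sqrt(2p(1-p))`; missing calls are
mean-imputed with a warning; monomorphic sites are dropped.

## SFS and composite-likelihood fitting

The joint SFS is folded to minor-allele counts by default (no outgroup
polarization is assumed): a site's count vector `c` is replaced by
`min(c, n - c)` in total-count order with a lexicographic tiebreak at
exactly half.  Monomorphic corners are retained in the totals but
excluded from likelihood cells.

The expected SFS is a Monte-Carlo estimate from the package's own
simulator.  Cells with zero simulated mass are floored at
`ε = 1/(10 · n_replicates)` and the spectrum renormalized — the standard
stabilization for simulated composite likelihoods.  The composite
log-likelihood is multinomial over polymorphic cells,
`CL = Σ m_i ln p_i`, treating sites as independent.  Singleton masking is
available as a flag for sensitivity analyses.

Fitting maximizes CL by bounded Nelder–Mead (5 restarts by default) over
at most a handful of free parameters, addressed by dotted paths into the
model (`"SUM.divergence_time"`, `"bottleneck:SUM:0.bottleneck_size"`,
`"mutation_rate"`).  Every evaluation reuses the same per-window seeds
(common random numbers), making the objective deterministic given the
master seed and the fit reproducible.  The two-stage protocol (fit a
coarse model, freeze it, fit nested parameters) is supported by freezing
fitted values into the template between calls.  This is a deliberately
desk-scale stand-in for publication-scale SFS optimizers: at the default
problem sizes (10³–10⁴ simulated windows per evaluation) it recovers a
two-deme divergence time with a median relative error around 10–25%, and
that is the resolution claimed for it, nothing more.

Time conversions (`years ↔ generations`) use exact rational arithmetic
for integer inputs, so printed figures survive round-trips unchanged.

## Runs of homozygosity

The detector is a transparent sliding-window rule, not an HMM: every
window of `window_sites = 50` consecutive non-missing sites containing
at most `max_het_per_window = 1` heterozygous calls marks its sites as
run-supporting; maximal marked stretches, trimmed to their outermost
homozygous sites, become segments; segments shorter than 10 kb are
dropped.  The union-of-qualifying-windows construction makes the
detector monotone (relaxing the heterozygote budget can only extend
segments) and non-overlapping by construction.  Absolute ROH calls are
method-dependent; only relative comparisons under a fixed rule are
meaningful.

Length-class proportions follow the subtraction-denominator convention:
`prop(>1 Mb) = L(>1 Mb)/A`;
`prop(100 kb–1 Mb) = L(100 kb–1 Mb)/(A − L(>1 Mb))`;
`prop(10–100 kb) = L(10–100 kb)/(A − L(>100 kb))`,
with `A` the autosome length.  Reporting additionally splits >2 Mb,
1–2 Mb, 100 kb–1 Mb and total >100 kb classes at output time.

## Candidate genes and enrichment

Homolog deduplication keeps one record per homolog group and collapses
same-strand overlap chains to their first record in coordinate order (a
record overlapping its predecessor is dropped even if that predecessor
was itself dropped, so a chain of three leaves one survivor).  "First"
is defined by coordinates, not file order.

A gene is a candidate when its span ±50 kb (clipped at scaffold bounds,
half-open intersection) overlaps any outlier window.  Per GO term a
one-sided Fisher's exact test (over-representation) is computed against
the full post-dedup gene list, with Benjamini–Hochberg adjustment across
tested terms at 0.05; raw p-values are reported alongside.  GO hierarchy
propagation is *not* performed — the term map is taken as given — and
term assignments transferred from model organisms remain a proxy, not a
test of function.

## Synthetic data

`generate_fixture` builds a complete, seeded dataset: VCF, scaffold
table, population map, gene BED, GO map, and a ground-truth manifest
sufficient to score recovery without re-reading simulator internals.
Defaults: the bundled four-subspecies model with its 3+3+4+3 diploid
sample layout, ten 10-Mb scaffolds (≈10,000 sliding windows), five
injected windows, injection factor 0.1, 20 genes/Mb, 30 GO terms.

Selection is emulated **demographically**: an injected 50-kb block is
simulated under the same model with the focal population's size (and its
bottleneck sizes) multiplied by the injection factor, so the block
remains a valid coalescent sample with locally elevated drift — the
footprint a sweep leaves in branch-length statistics.  One gene is
placed inside every injected block and the designated GO term is
assigned to all genes overlapping injected blocks plus ~1% of background
genes, so the enrichment stage has a scoreable true positive.

**Within-window averaging.**  Each 50-kb fixture window is composed of
50 independently simulated 1-kb chunks — free recombination between
chunks, none within ("loosely linked loci", the same independence
approximation SFS-based inference machinery makes).  This choice is what
makes the injected signal recoverable at the top-0.1% level: with one
genealogy per 50-kb window, window FST estimates from ~10 alleles per
population have a heavy noise tail that overwhelms the injected signal,
whose ceiling is `mPBS ≈ ln 2` once the focal deme is fully drifted
(a fixed deme against a source population at heterozygosity `h` caps
Hudson FST near `1 − h/2h = 1/2`).  Real genomes average over many
genealogies per 50 kb; the chunked construction emulates that averaging
honestly instead of inflating the injected effect.  The end-to-end tests
and the acceptance script quantify the resulting separation (injected
windows recovered in the top 0.1% of ~10⁴ windows).

What the fixture does **not** emulate: realistic LD decay within
windows, variable mutation/recombination rates, genotyping error and
missingness patterns, sex chromosomes, and reference biases.  Passing
the end-to-end tests therefore demonstrates the statistical machinery is
correct and powered under the stated model, not that real-data scans are
free of those artifacts.

## Problem sizes in tests and the acceptance script

Simulation scales were set to keep the full suite and the acceptance
script each within minutes on one CPU while leaving comfortable
statistical margins: 2,000 replicates for closed-form moments, 500+500
replicates for cross-simulator FST agreement, 500 windows per side for
null self-consistency, 10 master seeds × (3,000 observed + 1,000
simulated windows per likelihood evaluation) for divergence-time
recovery, and one ~10,000-window fixture for end-to-end recovery.  The
full-scale settings of the study design (10⁶ null windows, genome-sized
inputs) are supported by the same code paths.

## Known limitations

* The coalescent null at default settings ignores intra-window
  recombination; its mPBS tails are conservative relative to recombining
  data (heavier, so outlier thresholds derived from it are stringent).
* The composite-likelihood fit is desk-scale: a few free parameters,
  Monte-Carlo expected spectra, no block bootstrap for confidence
  intervals.
* The ROH rule is deliberately simple; its absolute segment boundaries
  differ from HMM callers, and no allele-frequency prior is used.
* Enrichment inherits whatever biases the supplied GO map carries; no
  term hierarchy or gene-length correction is applied.
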