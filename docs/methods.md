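# Methods

This note records the models implemented in `dieltk`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data do and do not establish about behaviour on real data.

## Expression preprocessing

Expression matrices (microarray intensity or RNA-seq FPKM) are z-scored
per gene — mean subtracted, divided by the sample standard deviation
(n−1 denominator) — so heterogeneous platforms share a scale.  The
denominator choice is cosmetic for everything downstream (all
comparisons are correlation- or rank-based) but is fixed for
reproducibility.  Genes with zero variance cannot be scaled; they are
mapped to all-zero rows, recorded in a skip list, and excluded from
rhythm testing and network construction (a constant profile would
otherwise produce division by zero or spuriously perfect correlations).

Series spanning 48–72 h are *folded* at the 24 h period: observations
at cycle 2+ act as extra replicates at `zt mod 24`.  Folded
replicate-mean profiles are linearly interpolated onto the integer-hour
grid treating the day as circular (the segment from the last observed
ZT back to the first observed ZT + 24 h fills the wrap-around gap), so
3 h- and 4 h-sampled datasets become directly comparable.  Interpolation
is exact at observed knots.  Heatmap-style gene ordering uses
average-linkage hierarchical clustering on correlation distance; the
linkage/distance choice affects only row order, never any statistic,
and constant profiles are assigned the maximal correlation distance 2.

## MBBH orthology

Alignment scores are optimal global affine-gap scores (BLOSUM62, gap
open 10, gap extend 0.5 — standard protein global-alignment defaults;
MBBH's rank-based logic is robust to the exact choice, and the scoring
config is user-replaceable).  `X` scores 0 against everything, a
neutral treatment of ambiguity codes.  Raw score is used as "sequence
similarity"; length-normalised scoring is available as a switch.

For each query, its N best hits are kept with a deterministic tie rule
(higher score first, then lexicographic target id, exactly N kept) —
determinism makes the output invariant to FASTA input order and is
testable; the choice at rank-N ties is otherwise arbitrary.  Pair
(p, q) is an MBBH orthologue when each is in the other's top-N list
(the same N in both directions) and their domain-id sets intersect.
Pairs where either member lacks any domain annotation pass the filter
by default: domain-scan coverage of real proteomes is incomplete, and
dropping unannotated proteins would silently bias the map (switchable
via `keep_unannotated=False`).

Proteins without any MBBH partner may still be matched by exact
domain-architecture identity (same domain ids, same order, same count).
Because a single widely shared domain pins down orthology only weakly,
`min_arch_len` can exclude length-1 architectures; the default keeps
them, since exact-tuple equality is already the strictest reading of
architecture identity.

With N = 1 and no domain tables, MBBH reduces exactly to classical
bidirectional best hit; the test suite verifies this, the equivalence
with a brute-force all-pairs oracle, and monotonicity of the pair set
in N.

## Rhythm detection

The rhythm test is a nonparametric phase-scanning umbrella rank test.
Observations folded at the period form k ordered circular groups.  For
a candidate peak at group p, the groups are rotated so the assumed
trough (opposite the peak) comes first, and the Mack–Wolfe umbrella
statistic

    A_p = Σ_{i<j≤p} U_ij + Σ_{p≤i<j} U_ji

sums Mann–Whitney counts concordant with a rise to the peak and a fall
after it (ties count ½; pairs spanning the peak are not compared).
Under exchangeability A_p is asymptotically normal with the standard
Mack–Wolfe mean and variance (validated against Monte-Carlo moments in
the tests).  The scan evaluates every candidate peak position; the
smallest one-sided p-value is Bonferroni-multiplied by k.  Bonferroni
over positively dependent phase statistics is conservative, which the
type-I simulations confirm (≈0.6–0.9% empirical at nominal 1% on the
4 h/48 h/3-replicate design).  This construction assumes a
single-peaked (unimodal up–down) waveform per 24 h with the trough
roughly opposite the peak; strongly asymmetric waveforms lose some
power but remain detectable because every rotation is scanned.

Replicates — and folded extra cycles — are pooled as independent
observations at their timepoint; the rank statistic needs no
longitudinal structure.  Two cross-check backends exist: an exact
permutation null of the max standardized statistic (seeded), useful for
small grids where the normal approximation is doubtful, and a
first-harmonic cosinor F-test.  No across-gene multiple-testing
correction is applied by default (the per-gene α = 1% convention);
`bh_adjust` is available if desired.

Power, as a simulation-calibrated regression test: cosine signal with
amplitude/noise-sd = 2 on 8 timepoints × 3 replicates is detected in
≥ 95% of genes at α = 1%.

Peaks and troughs are the argmax/argmin of the folded replicate-mean
profile (ties broken toward the earlier ZT), not of the raw unfolded
series: a single characteristic peak and trough per 24 h is the object
of interest.  Diel intervals are half-open, each owning its left edge
(ZT21∈Dawn, ZT3∈Day, ZT9∈Dusk, ZT15∈Night); the colloquial "from ZT21
to ZT3" phrasing overlaps at the boundaries and must be disambiguated
to partition the circle.  The 16 cluster labels are the peak-interval ×
trough-interval pairs, including equal-interval labels, which real
waveforms do populate; merging by peak interval gives the 4-way summary
clustering.

## Co-expression networks

Edges join rhythmic genes with Pearson r strictly above the threshold
(default 0.95) between hourly interpolated folded-mean profiles — the
common grid is what makes 3 h and 4 h datasets comparable.  Topology
diagnostics:

* **Scale-free check** — OLS of log10 degree frequency on log10 degree
  over k ≥ 1 with nonzero frequency, on raw (unbinned) frequencies; the
  simplest reading of a log-transformed degree distribution.
  Logarithmic binning is a known variance-reduction option but is not
  the default.  (A degree distribution with a negative *exponential*
  fit is sometimes loosely called scale-free; the implementation fits
  the log–log *power-law* regression, the standard operationalisation,
  and this divergence in terminology is noted here deliberately.)
* **Mean clustering** — average local clustering coefficient, degree<2
  nodes contributing 0.
* **Small-world test** — empirical p of the observed mean clustering
  against preferential-attachment random graphs matched in node count
  and *exactly* in edge count (the BA generator cannot hit an arbitrary
  edge count, so m = round(E/V) attachment edges are used and edges are
  randomly added/removed to match E).  p uses the +1 correction,
  (1 + #{C_rand ≥ C_obs})/(n_random + 1), standard permutation-test
  practice avoiding zero p-values.  Default n_random = 10⁴; the test is
  seeded and the seed is recorded in the pipeline manifest.

## Expresologues and Zsummary

An orthologous pair with both genes rhythmic is an expresologue when it
shares the 16-way cluster label or its hourly-profile correlation
strictly exceeds 0.98.  Setting the correlation threshold above 1
recovers the pure same-cluster criterion (tested).

Module preservation follows the permutation-Z composite design.  Of the
reference framework's ~7 component statistics, four representative ones
are implemented — density: mean intra-module correlation and mean
intra-module adjacency at the network threshold; connectivity:
correlation of intramodular connectivity vectors (row sums of the
intra-module correlation matrix) between species, and correlation of
the vectorized intra-module correlation matrices — preserving the
median-then-mean composition: Zdensity and Zconnectivity are medians of
their component Z-scores, Zsummary their mean.  The qualitative
thresholds are what matters downstream: < 2 none, 2–10 moderate
(closed interval: a score of exactly 2 or 10 reads "2–10"), > 10 high.
The permutation null redraws the test-side gene set (same size,
uniformly from the test matrix's non-constant genes) with the reference
side fixed; default 200 permutations, the conventional count for
module-preservation permutation tests; a zero permutation sd yields
Z = ±∞ with a warning.  When a reference gene maps to several test
genes, the highest-correlation partner is used (avoiding double
counting; an all-pairs mode is a documented alternative).  Directed
computation (module defined in species X, evaluated in Y) is run for
both orderings by the pipeline.

A design caveat surfaced by the simulations: a module whose members all
share *one* waveform has essentially flat intramodular connectivity, so
the connectivity Z-scores are weak and Zsummary is carried by density.
Real modules with graded membership strength would give connectivity
more discriminating power.

## Enrichment

Per-term one-sided Fisher exact tests against the whole-genome
background (classic mode — no ontology-graph decorrelation: elim/weight
algorithms require the GO DAG, which is out of scope, and classic
Fisher is the stated convention here), α = 5%; pathway enrichment uses
the hypergeometric upper tail with BH adjustment and a q < 0.05 filter.
The two tails are the same quantity and are cross-checked against an
independent binomial-coefficient enumeration on all small tables.
Redundancy among nested terms is reduced by exact collapsing: terms
whose annotated-in-set gene lists coincide are reported once, keeping
the most significant representative — an objective stand-in for manual
or semantic-similarity pruning.

## Synthetic data

`make_proteomes` grows each gene family from one uniform-random
amino-acid ancestor; every copy substitutes a configurable fraction of
positions (default 5%) with a uniformly chosen different residue, and
per-species copy numbers create the unequal family sizes (e.g. 1:1:8)
that motivate MBBH.  Uniform ancestors are adequate because the
rank-based MBBH logic is insensitive to composition realism; no
indel/codon evolution is modelled.  Domains are placed at fixed
relative coordinates, so family members share architectures exactly.

`make_diel_expression` simulates the standard diel design: default 48 h
span, 4 h sampling, 3 replicates (3 h sampling for the second species
in comparative fixtures).  Rhythmic genes follow a sign-preserving
sharpened cosine, `amplitude · sign(c)|c|^sharpness` with
`c = cos(2π(zt − phase)/24)` — sharpness > 1 emulates narrow peaks —
plus iid Gaussian replicate noise (default sd 0.5 at amplitude 1,
signal-to-noise 2, a clearly rhythmic transcript); arrhythmic genes are
iid standard Gaussian noise.  `make_preserved_module_pair` builds the
module-preservation benchmark: 50 module genes sharing one seeded
waveform (noise sd 0.2) among 450 uniform-phase background genes, with
the test-species module either repeating the waveform or replaced by
independent noise.

What the simulations do **not** capture: heteroscedastic and
platform-specific noise, temporal autocorrelation within a replicate
series, damped or asymmetric waveforms beyond the sharpness family,
unbalanced replication, and missing samples.  Passing tests therefore
establish correctness of the algorithms and calibration under the
stated model, not performance guarantees on any particular real
dataset.

## Problem sizes and numerics

The validation script and test suite run at desk scale — proteomes of
tens of proteins, expression matrices of 10²–10³ genes, 200
permutations, 50–10⁴ random graphs — sizes chosen so every quantity is
recomputed from scratch in seconds while keeping the statistics stable
across seeds (the Zsummary targets vary by ~±2 across seeds, an order
of magnitude away from their thresholds).  All generators and
permutation tests take explicit seeds; the pipeline derives per-stage
seeds from a single run seed via `numpy` seed sequences and records
them in its manifest, so a run is reproducible from one integer.
Floating-point conventions: z-score moment tolerance 1e-9; strict
inequalities at the 0.95/0.98 correlation thresholds; rank ties count
0.5 in the umbrella statistic; p-values are capped at 1 after the
Bonferroni multiplication.

## Known limitations

* The umbrella scan assumes the trough sits roughly opposite the peak;
  sawtooth-like waveforms are detected with reduced power.
* Zsummary here implements a 4-statistic subset of the full reference
  battery (no eigengene- or quality-statistics); composite values are
  comparable in interpretation, not numerically identical to the full
  implementation.
* Architecture-fallback orthology treats domain order as exact and
  ignores domain copy coordinates; tandem repeat expansions of the same
  domain count as different architectures when the repeat number
  differs.
* Enrichment takes annotation tables as given — no true-path GO
  propagation.
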