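# Methods

This note documents the models and procedures implemented in
`pioneerscope`, the default parameters and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that make runs reproducible.

## Coordinate conventions

All coordinates are 0-based half-open (`[start, end)`, the BED
convention); 1-based inputs must be converted at the I/O boundary. The
centre of an interval is `floor((start + end) / 2)` — deterministic for
odd lengths — and is the reference point for every distance: peak-pair
spacing, the ±200 bp capture radius, and the summit window. "Overlap by at
least 1 bp" means intersection length ≥ 1; abutting half-open intervals do
not overlap. Every sort breaks ties by `(chrom, start, end)` so that equal
scores or ratios order identically across runs.

## SELEX affinity mapping and peak calling

A SELEX-seq experiment yields relative binding affinities for 12-mers
(upstream estimation of that table — sequencing, Markov-model background
correction, the minimum-count filter — is out of scope; the table is an
input, and the generator fabricates one directly). Mapping finds every
exact occurrence of a table k-mer on either strand; reverse-complement
matches are reported at the forward-strand window, and a palindromic entry
matching its own reverse complement at one locus counts once (one piece of
evidence). Mismatches are not tolerated — the affinity table itself
enumerates the sequence neighbourhood of the binding site, so approximate
matching would double-count.

Peak calling: (1) the threshold is the median affinity over **all table
entries**, including k-mers that never match the genome — a literal
reading of "the median specificity of all 12-mer sequences"; (2) hits
strictly above the threshold are retained (with all affinities equal,
nothing exceeds the median and no peaks are called); (3) retained windows
are unioned and candidate regions separated by a gap < 3 bp are merged;
(4) regions with ≥ 2 contributing k-mer hits are kept, where the count is
of hit instances after palindromic deduplication; (5) the peak score is
the arithmetic mean affinity of contributing hits. Doubling every affinity
doubles scores but leaves peak coordinates unchanged (the median scales
with them).

## Spacing enrichment

The tetramer signature is an excess of peak pairs at a preferred
centre-to-centre distance inside strongly bound regions. Foreground pairs
are peak pairs in which **both** peaks lie within ±200 bp (inclusive) of
the centre of the same top-n (by score) binding site; a pair captured by
several sites counts once. The background is all same-chromosome peak
pairs with distance in (0, `max_distance`] genome-wide, foreground
included. `max_distance` defaults to 300 bp, covering the span a ±200 bp
capture window can produce while keeping windows well populated.

Distances are binned into half-open 20-bp windows `[d, d+20)` (a distance
equal to `max_distance` falls in the last window, so the windows partition
the scanned range: window counts sum to `n` and `N`). Per window,
`p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` — upper-tail, no continuity
correction, and **no multiple-testing correction across windows**: the
profile is reported as raw −log2 p against a p = 0.05 reference, matching
how such enrichment profiles are conventionally plotted. A consequence
documented here deliberately: under a uniform-spacing null the *minimum* p
over 15 unadjusted windows dips below 0.05 in a sizeable fraction of
replicates (measured ≈ 25/100 at the default geometry), which is expected
behaviour of uncorrected scans, not a defect; null calibration statements
in the test suite therefore evaluate the specific window carrying the
planted spacing, for which the hypergeometric test is valid at level α by
construction.

## Chromatin accessibility classification

Only sites with binding FDR < 0.1 are classified. Baseline accessibility
is the mean RPKM across the uninduced replicates
(`RPKM = count / (length_kb × library_size / 10⁶)`, exact). The
closed/open threshold is `(median_NFR + median_nuc) / 2`, the midpoint
between the median accessibility of signal regions overlapping (≥ 1 bp)
the nucleosome-free set and the nucleosome-containing set; on the reported
medians 30.17 and 51.79 RPKM this gives 40.98 RPKM. A site exactly at the
threshold is called closed — conservative toward the pioneer-relevant
class, and configurable in the sense that the comparison is a single `<=`.

Dynamics use the differential-accessibility fold change and p-value, all
on the **linear** FC scale (the printed "log2FC < 0.8" for the decreasing
rule is read as linear FC < 0.8, consistent with its companion rules; the
malformed "0.8 < FC > 1.2" steady rule as 0.8 ≤ FC ≤ 1.2):

| dynamics   | rule                    |
|------------|-------------------------|
| increasing | FC > 1.2 and p < 0.1    |
| decreasing | FC < 0.8 and p < 0.1    |
| steady     | 0.8 ≤ FC ≤ 1.2 and p > 0.1 |

p = 0.1 exactly satisfies none of the strict inequalities and falls
through to the residual category. Residual combinations keep their
accessibility split (`other_closed` / `other_open`); a final catch-all
`other` holds sites with no usable baseline, giving nine labels that
always partition the significant sites (closed + open = total).

Specific-site ranking adds 0.5 reads to every raw count before RPKM so
zero-count regions remain rankable, averages RPKM across replicates, and
sorts by log2(WT/mutant) — descending for WT-specific, ascending for
mutant-specific; swapping the two inputs swaps the lists exactly. Random
control regions are fixed-length (default 400 bp × 1,000) and uniform over
all valid start positions genome-wide (chromosomes weighted by their
number of valid starts). DE-gene linkage uses |log2FC| > 1 & FDR < 0.05
(activated: log2FC > 1) and the 3 kb-upstream / 1 kb-downstream vicinity
window, oriented by gene strand — the universal promoter convention; the
source analysis does not state strand handling, so this is a design
choice of this package.

The differential estimator shipped here (linear FC of pseudocounted mean
RPKM + Welch t on log2 RPKM across replicates) exists **only** to close
the loop on synthetic data; real analyses should consume an externally
computed differential table (e.g. from a negative-binomial GLM). Its null
false-positive rate at p < 0.05 measures slightly conservative
(≈ 3% on 1,000 null regions), which the calibration test pins down.

## MNase depletion ranking

The MOCK/DEX ratio uses the mean per-base coverage over the inclusive
81-bp window `[summit − 40, summit + 40]`, with 0.1 (CPM-scale) added to
both means before the ratio; windows exceeding chromosome bounds are
clipped with a warning. Mean vs sum is immaterial for a fixed window — the
ordering is identical. Groups are the top and bottom 500 by descending
ratio with coordinate tie-breaks; per-group category percentages sum to
100 so the difference vector sums to 0.

## Histone-mark contingency

Counting is site-level, not bp-level: cell (m, c) is the number of
category-c sites overlapping mark m by ≥ 1 bp, and a site may count toward
several marks (rows are non-exclusive, as such heatmaps are drawn).
Pearson residuals are `(O − E)/√E` with `E` from the margins; the
statistic is their squared sum on `(r−1)(c−1)` df, no continuity
correction, and all-zero rows or columns are dropped with a warning before
testing.

## Kd estimation

The titration series holds protein constant and dilutes labelled DNA; the
two fitted models are the ones named by their formulas: a hyperbola in
total DNA, `Bound = Bmax·Total/(Kd + Total)` by nonlinear least squares
(start: Bmax₀ = 1.1·max(bound), Kd₀ = median(total); bound is
nondimensionalised by its maximum so both parameters are fitted on
comparable scales), and the Scatchard regression of Bound/Free on Bound
with `free = total − bound`, `Kd = −1/slope`, `Bmax = −intercept/slope`.

These two are rearrangements of a single model **only in the
weak-depletion limit** (bound ≪ total); on data exactly following one
form the other is biased, which is precisely why both are reported. The
package therefore provides two generators: `simulate_series` (the
hyperbola in total, with Gaussian noise on bound, clipped into
[0, total]) and `equilibrium_series` (exact single-site mass action,
`B² − (T + Bmax + Kd)B + T·Bmax = 0`, on which Scatchard is exact).
Reactions with free = 0 (fully shifted probe, possible after noise
clipping) are excluded from the Scatchard regression with a warning. A
Michaelis–Menten estimate is flagged ill-determined when the relative
standard error of Kd exceeds 50% or when every titration point lies more
than 10× above the fitted Kd (a fully saturated series carries no
curvature information in the sampled range).

## Synthetic data: what it emulates, and what it does not

Defaults (one place, `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| genome | 2 × 350 kb, i.i.d. uniform ACGT | smallest genome that hosts 1,200 non-overlapping 400-bp sites with ≥ 100 bp gaps |
| sites | 1,200 (100 tetramer-pair, 150 uniform-pair, 250 single-box, 700 boxless) | enough sites for top/bottom-500 MNase groups; pair mix gives an informative spacing background |
| pair spacing | 50 ± 3 bp (tetramer), uniform 24–280 bp (background pairs) | the preferred tetramer looping distance sits mid-window; background spans the scanned range |
| affinity table | CArG-window 12-mers ~ lognormal(mean 10, σ 0.25); 3× as many random low entries ~ lognormal(mean 0.5, σ 0.35) | components separated so the table median falls inside the low component, below every high entry |
| ATAC counts | NB, var = μ + 0.02 μ²; closed 15 / open 70 RPKM (per-region log-σ 0.2); 3+3 replicates; libraries 20 M ± 10% | dispersion typical of deep, well-replicated ATAC; class means straddle the midpoint threshold with margin |
| dynamics | 30% increasing ×2.0, 15% decreasing ×0.5, 55% steady | a two-fold accessibility change is the magnitude the FC > 1.2 rule targets |
| MNase | gamma bins (mean 10, CV 0.1, 10-bp bins), DEX = MOCK × lognormal wobble (σ 0.05); ×0.3 over summit ± 73 bp at 500 sites | one nucleosome half-footprint of depletion over a smooth background |
| marks | base overlap 0.25; H3K27me3 odds 3.0 closed / 0.4 open; H3K4me3 0.5/3.0; H3K9ac 0.7/2.5; H3K36me3 unbiased | repressive marks toward closed chromatin, active marks toward open; one neutral control row |
| EMSA | Kd 2 nM, Bmax 1 nM, 10-point titration 0.02–12.38 nM, noise 2% of Bmax | the titration span of the in-study series around a mid-range Kd |

Every stage draws from its own child generator of the master seed
(`default_rng([stage, seed])`), so identical config + seed reproduce every
output byte-for-byte and stages can be regenerated independently. Each
generator emits a truth table (planted boxes and spacings, class and
dynamics labels, depleted-site indices, realised mark overlaps) consumed
by the recovery tests.

The generator does **not** emulate: read-level artefacts (PCR
duplication, mappability, GC bias), genome composition beyond uniform
background (so chance CArG matches are rarer than in a real genome),
fragment-size structure in MNase data, correlated replicates or batch
effects, or the upstream SELEX enrichment rounds. Passing recovery tests
therefore demonstrate that the statistics detect the structures they are
designed for under idealised noise — not that they would at the same rates
on real libraries. The `simulate_peak_geometry` helper draws sites and
peaks directly (no sequence, no mapping) and backs replicate-heavy null
experiments where only peak geometry matters.

## Problem sizes

The shipped study conditions are desk-scale by design: a 700-kb genome
with 1,200 sites stands in for a 120-Mb genome with thousands of bound
regions, the spacing null uses 100 geometry-level replicates, and the Kd
study 1,000 replicate titrations. Headline counts from the motivating
datasets (thousands of sites, specific DE-gene tallies) depend on the
deposited sequencing libraries and are not reproduced here; the package
reproduces the *procedures* and their in-text arithmetic identities
(midpoint threshold; partition of classified sites).

## Known limitations

- Exact k-mer matching only; a table that did not enumerate the binding
  site's sequence neighbourhood would under-map.
- The spacing background includes the foreground (no exclusion), and
  foreground pairs require both peaks near the *same* site — alternative
  readings exist and would change K and n.
- The stand-in differential test is a convenience for simulations, is
  slightly conservative, and bounds steady-label recovery at roughly one
  minus its size (a true-steady region with p ≤ 0.1 cannot be labelled
  steady under the rule).
- Scatchard estimates are biased under noise by construction; they are
  reported for comparability, not as the primary estimate.
- bigWig/BAM are out of scope; coverage is exchanged as bedGraph.
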