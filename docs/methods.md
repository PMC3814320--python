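# Methods

## The instability index

A fragment-analysis trace of a PCR product spanning a CAG tract is an
ordered set of peaks (integer repeat length, fluorescence height). The
index summarises a trace relative to the animal's constitutive "main
allele", called as the tallest peak of the tail trace (exact height ties
break to the smaller repeat length — a conservative choice, since calling
the longer allele would inflate apparent expansion).

Given a trace and a main allele *L₀*:

1. threshold = 0.20 × (tallest peak height *in this trace*);
2. peaks with height strictly below the threshold are excluded (a peak
   exactly at the threshold is retained — "falling below" is read
   strictly);
3. surviving heights are normalised to weights summing to 1;
4. index = Σ wᵢ (Lᵢ − L₀).

The index is therefore the signed mean repeat-length change across the
sampled cell population: contractions contribute negatively. The
normalising denominator is the post-exclusion height sum, which keeps the
weights a probability distribution over the peaks that remain "in the
analysis"; normalising by the pre-exclusion sum instead is available via
`denominator="all"` for sensitivity checks and changes the index by a
factor equal to the retained height fraction.

Base-pair sizes are converted to repeat units as
`round((size_bp − flank_bp)/3)` with a configurable flanking-amplicon
length (default 115 bp); two distinct sizes mapping to one repeat length
is an error naming the sample, since it signals a wrong flank or unit
setting. Raw electropherogram parsing and peak calling are out of scope —
input tables are assumed pre-sized.

## Synthetic somatic expansion and trace rendering

The biological generator is deliberately phenomenological: expansion is an
accumulation of +1 CAG steps, so each cell's added length is
Poisson(λ · age · tissue_factor · genotype_factor · m), with m > 1 for an
optional "fast" subpopulation (Bernoulli fraction). This reproduces the
qualitative trace shapes of the system being emulated: unimodal broadened
distributions at young ages, bimodal ones when a fast compartment is
switched on, degenerate distributions when any factor is 0 (tail, or an
expansion-null genotype). It does not model mechanism (mismatch-repair
kinetics, slip-out intermediates) and makes no claim about real per-week
rates; defaults (rate 0.30/week, age 10 weeks, striatum factor 1, tail 0,
liver 0.8) were chosen once to give striatal indices of roughly 0.5–5
repeat units, the working range of real 10-week data.

Rendering convolves the cell histogram with a PCR-stutter kernel, scales
to a maximum height of 10 000, adds truncated Gaussian noise (default SD
60 intensity units) and drops peaks under 1% of the maximum. The stutter
defaults — minus ratios (0.15, 0.04, 0.01), plus ratio 0.03 — keep every
stutter-only peak below the 20% exclusion threshold, so an expansion-free
trace scores an index of ~0 and a cohort of such traces stays inside a
|index| < 0.2 baseline band. Stronger stutter (−1 ratios above 0.20) would
survive thresholding and push the stutter-only index to about −ratio/(1 +
ratio); anyone simulating such chemistry should widen the baseline band
accordingly.

## F2 intercross simulation

Gametes are simulated per chromosome as two-state Markov chains over the
marker loci, with switch probability between adjacent loci given by the
Haldane map function r = ½(1 − e^(−2d/100)) — i.e. no crossover
interference, matching the map-function convention of classical interval
mapping and giving closed-form transition probabilities that the tests can
check exactly. The X chromosome is treated as autosomal; the default map
is 19 autosomes + X with 147 markers apportioned by genetic length and
spaced uniformly. The planted QTL is simulated jointly with the markers at
its map position (snapped to the nearest marker in the study generator so
the planted locus is fully typed), and the phenotype follows the standard
F2 decomposition y = μ + a·x_add + d·x_dom + N(0, σ), with x_add = +1/0/−1
for BB/BH/HH and x_dom = 1 for heterozygotes.

Seeding: one master seed; each animal's meioses, trace noise and genotype
failures come from a sub-generator keyed by (seed, animal index), so
growing the cohort leaves earlier animals bit-identical. All draws go
through numpy's Generator, which is platform-stable; outputs are
reproducible byte for byte for a given seed and configuration.

The default study configuration (69 animals, 147 markers, dominant
modifier on chromosome 9 with genotype factors BB = BH = 1.0, HH = 0.15,
per-animal lognormal rate multiplier with σ = 0.32, 1000 cells per trace,
2% genotype failures) is calibrated so the planted locus explains ≈60% of
striatal-index variance at n = 69. The calibration is analytic in outline —
under 3:1 dominant segregation the genetic variance is (3/16)Δ² for a
class-mean gap Δ, and the lognormal animal-level noise supplies the
residual — with the final σ fixed by a one-off simulation check. These
defaults are study conditions, not tuning knobs.

## The genome scan

At each position the 2-df model y = μ + a·x_add + d·x_dom + ε is fitted by
least squares against the null y = μ + ε, and LOD = (n/2)log₁₀(RSS₀/RSS₁).
Two routes:

* `method="marker"`: genotype-class regression at typed markers,
  individuals untyped at a marker dropped there (per-marker n enters the
  LOD);
* `method="hk"` (default): Haley–Knott regression on expected genotype
  indicators over a grid of markers plus pseudomarkers (default 1 cM).
  Expected indicators come from a forward–backward pass over the 3-state
  genotype chain (the lumped product of two independent gamete chains,
  which is exactly Markov under no interference), so missing and off-grid
  genotypes are probability-weighted rather than dropped. At a fully typed
  marker the two routes coincide.

Haley–Knott replaces EM interval mapping: at realistic marker densities
and low missingness the two are nearly identical, and the least-squares
form makes the LOD ↔ R² identity R² = 1 − 10^(−2·LOD/n) exact at typed
markers, which ties the variance-explained report directly to the LOD
engine. An EM refinement at the peak was considered and left out.

Degenerate inputs: a constant phenotype defines LOD = 0 everywhere (with a
warning); a position with an absent genotype class is fitted by
minimum-norm least squares, which reduces to the model spanned by the
observed classes; RSS₁ is floored at the smallest positive float so a
perfect fit yields a large finite LOD rather than infinity. Missing
phenotypes drop the individual; at least 8 phenotyped individuals are
required (10+ recommended for any real scan — the 8 floor exists so tiny
exact-arithmetic fixtures can run).

Significance uses the classical fixed LOD 4.3 line by default, with a
permutation alternative: phenotypes are shuffled against genotypes and the
(1 − α) quantile of the genome-wide maximum marker LOD returned. Because
the 2-df fit at a typed marker is a one-way analysis of variance, each
permutation reduces to class sums, making 1000 shuffles take seconds.

### Support intervals

The 2-LOD drop-off interval walks outward from the peak: positions with
LOD ≥ peak − drop stay inside (a dip exactly to the line with later
recovery does not terminate the walk), and each bound is the first
*marker* at or beyond the first position strictly below the line — the
interval is marker-delimited ("the markers encompassing the drop-off"),
not interpolated, and extends to the chromosome end if the drop is never
reached. Physical bounds are reported when the marker table carries bp
coordinates, as a 1-based inclusive span; no interpolation of physical
positions between markers is attempted. With drop = 0 this rule yields the
peak plus its immediately encompassing markers. Peak ties break toward the
lower-cM position with a warning.

### Dominance classification

At a marker, â = (m_BB − m_HH)/2 and d̂ = m_BH − (m_BB + m_HH)/2 from the
class means; |d̂/â| < 0.25 is reported additive, d̂/â ≥ 0.25 as
B6-dominant (heterozygote tracks the B6 homozygote), d̂/â ≤ −0.25 as
129-dominant, and any empty class as indeterminate. The 0.25 cut is a
reporting convention, not an inference.

## Variant density

Windows tile each chromosome from coordinate 0 in half-open [k·w, (k+1)·w)
bins (w = 64 kb by default); the phase of the tiling is a convention and
the summary statistics do not depend on it for uniformly scattered
variants. The terminal window is truncated at the chromosome length and
its density uses the true width (dropping truncated windows is available
behind a flag). Multiallelic VCF records are decomposed to one record per
ALT allele; structural variants count once at their POS. Region summaries
count variants per named 1-based inclusive interval, report total, span
density per kb and a nonsynonymous sub-count for exonic categories, and
route anything inside the span but outside all categories to an
"unassigned" bucket with a warning.

## Reported statistics

"Two-tailed unpaired t-test" is Student's pooled-variance test (the
classical default), with Welch behind `equal_var=False`; no
multiple-testing correction is applied across group comparisons. Pearson
correlation reports r, R² and the t-approximation p. The dose–response fit
is an ordinary least-squares line with a significant-increase flag (slope
> 0, p < 0.05). p-values print to 4 significant figures, floored as
"<0.0001" in the human-readable report only.

## What the tests show — and what they do not

The synthetic generator defines the study conditions, so green tests
demonstrate that the statistics behave correctly *under the generative
model*: the index matches its literal definition to 1e−12, meioses
segregate 1:2:1 and recombine at Haldane fractions, the scan recovers
planted effects and calibrates to its χ²₂ null, and a dominant locus of
the calibrated size yields mean peak R² ≈ 0.60 and mean peak LOD ≈ 14 over
500 replicates of n = 69. They do not validate the generator against real
electropherograms (no dye artefacts, no size-standard drift, no allele
dropout) nor the map against real marker positions (uniform spacing, no
genotyping-error model beyond random missingness).

Problem sizes in the default test run are chosen to keep the suite fast
while leaving the Monte-Carlo checks well-powered: 500 replicates for the
variance-recovery check, 40 study-level replicates for genome-wide QTL
recovery, 10 000 meioses for segregation checks, 1000 permutations for the
null threshold, and 5000 replicates for t-test/correlation type-I
calibration.

## Known limitations

* Single-QTL F2 scans only: no multiple-QTL or composite interval mapping,
  no covariates, no backcross/RIL designs, no special X-chromosome model.
* The expansion model is phenomenological; rate parameters are not
  estimates of biological step rates.
* Nonsynonymous status is an input flag, not computed from sequence.
* Physical coordinates come only from the marker annotation table; cM→bp
  conversion is never interpolated.
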