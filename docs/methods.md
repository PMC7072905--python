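# Methods

## The population model

The generator (`rilmap.simpop`) produces recombinant inbred lines by
single-seed descent: each line descends from an independent F1 whose two
haplotypes are the pure parental genomes, selfed for `n_generations − 1`
rounds (default F11).  Every meiosis draws a crossover count per
chromosome from Poisson(L/100) with uniform positions on the genetic
scale — the Haldane model, with no interference and no sex or position
effects.  Genetic coordinates are mapped linearly to physical
coordinates, i.e. recombination density is uniform within a chromosome;
real rice chromosomes suppress recombination pericentromerically, so
simulated bins are more uniformly sized than real ones.

Two analytic anchors follow from the model and are enforced by tests:
the heterozygous genome fraction at generation Ft is (1/2)^(t−1), and
the expected number of breakpoints per line per chromosome approaches 2L
Morgans as t → ∞ (map expansion factor 2 for selfed RILs).

Sequencing is emulated at the call level, not the read level: per site,
depth ~ Poisson(`mean_depth`, default 7.75), depth 0 is missing, and the
emitted call is the parental origin of the covering segment flipped with
probability `error_rate` (default 1%); heterozygous segments emit either
parent with probability ½.  Real error processes are not independent
across sites (mapping artefacts cluster), so the error model is
optimistic about local structure; the window caller is designed for
exactly such scattered errors.

The phenotype is additive: y = midparent + Σⱼ aⱼxⱼ + e with xⱼ = +1/−1/0
for BB/AA/HET at QTL j and e ~ N(0, `residual_sd`²), truncated to
[0, 100] because germination is a percentage.  The eleven published
additive effects (8.12–12.00 in germination points, signed toward the
LTH allele) sum far beyond the parental difference because they are
marginal estimates, so they are used as *relative weights* and rescaled
so that Σaⱼ equals half the parental difference — a noise-free all-LTH
genome scores exactly the LTH mean (86.5) and an all-SN265 genome the
SN265 mean (15.4).  `residual_sd` defaults to 10 germination points,
giving per-QTL variance contributions of ~5–12%, consistent in order
with the published 10–21% marginal values.  The default SNP density
(0.343/kb) reproduces the study's ~123.9k SNPs over the 361-Mb span of
the published map.  A fully penetrant single-locus trait
(`simulate_major_locus_trait`, DEP1-like panicle curvature) is the
degenerate no-noise single-QTL case.

## Window calling and breakpoints

Windows of 20 consecutive calls (step 1) are genotyped by the A-call
proportion: ≥ 0.75 homozygous-A, ≤ 0.25 homozygous-B (the 15:5 rule,
boundary inclusive), otherwise heterozygous; windows with fewer than
`min_informative` (10) informative calls are missing.  Proportions
rather than raw 15:5 counts generalise the rule to windows with missing
data.

Runs of equal window genotypes shorter than `min_run` (3) are treated as
call noise and absorbed — shortest runs first, an interior run whose
flanks agree takes their genotype, otherwise the preceding run's (a
strict left-to-right order could absorb a chromosome-start run into a
noise run).  A further step is forced by the window construction itself:
any clean homozygous junction yields a band of ~9 windows whose ratio
passes through the heterozygous zone.  HET runs shorter than 2× the
window size flanked by opposite homozygous runs are therefore read as a
single breakpoint (windows split half-and-half between the flanks);
genuine residual heterozygous segments at F11 span many windows and are
preserved.  Without this step every junction is wrapped in HET and, with
HET excluded downstream, the genetic map collapses to zero.

Each window is anchored at its central SNP and a breakpoint is placed at
the midpoint between the anchors of the adjacent runs; terminal runs
extend to the chromosome ends.  Coordinates are 1-based inclusive
everywhere; grid cells are half-open internally.

Bins: each chromosome is tiled into 15-kb cells, a line's cell genotype
is that of the segment covering the cell midpoint, and adjacent cells
with identical genotype vectors over all lines are merged.  HET bins are
kept in the bin matrix but treated as missing by map estimation and
scanning.

## Genetic map

Adjacent-bin estimation replaces multipoint EM: bins are dense, ordered
by the reference assembly, and never reordered, so pairwise estimates
are adequate and auditable.  R is the discordant fraction among lines
homozygous at both markers (capped at 0.4999 with a flag), corrected by
R = 2r/(1+2r), and converted with Kosambi (default; the rice convention)
or Haldane.  Intervals at or above a 50-cM ceiling are truncated and
flagged.  Simulation-consistency analyses (tests, acceptance script) use
Haldane because the generator is interference-free.

With error-free genotypes the total map is recovered within 5% at
n = 500 (test-enforced); with 1% call errors the window caller removes
essentially all error inflation and the map comes out slightly *short*
(−1 to −4% across seeds; tight double-crossovers merged during window
smoothing are the dominant loss).  The published map of this cross
totals 2,840 cM — roughly twice consensus rice maps — which is the
signature of residual genotyping error entering est.map-style
estimation; this artifact's own counts and lengths are reported as
computed, with the discrepancy (like the published 2,818 vs 2,828 bin
counts) documented rather than imitated.

## QTL scanning

Haley–Knott regression rather than EM mixture likelihood: at fully typed
markers the two coincide, and the regression form makes the permutation
loop cheap.  Genotype probabilities condition on the nearest informative
flanking bins through the chain P(change over d) = 2r(d)/(1+2r(d)) with
r(d) from the inverse map function; a missing flank contributes the ½/½
marginal.  LOD = (n/2)·log₁₀(RSS_reduced/RSS_full) with the reduced
model dropping only the genotype score; a perfect fit is capped at a
50-LOD ceiling and flagged; zero phenotypic variance yields an all-zero
flagged scan.

CIM adds up to `max_cov` (5) forward-selected marker covariates
(greedy RSS reduction), dropping any within 10 cM of the test position;
`max_cov = 0` reduces CIM to IM exactly.  Permutation thresholds permute
the phenotype only and re-run covariate selection inside every
permutation, keeping the null exchangeable; the threshold is the
`higher`-interpolation (1−α) quantile of the genome-wide maximum LOD.
Under the null the 5% threshold rejects at ~5% (calibration enforced
over 200 replicates at n_perm = 200).  Support intervals are the widest
contiguous region within `drop` (1.5) LOD of the peak, linearly
interpolated between grid points on the cM scale and converted to bp
along the grid.  Peaks on one chromosome are distinct when separated by
a dip below threshold − 1 — a rule that must be explicit to be testable;
the published tables report two peaks on chromosomes 7, 9 and 12.
Variance explained is 100·(1 − 10^(−2·LOD/n)), which reproduces the
published Var% column from the published LOD column within ±0.1 at
n = 144.

At the full study scale (144 lines, eleven rescaled QTLs,
residual_sd = 10) the CIM permutation threshold lands near 5.5–5.7 and
typically 2–5 of the eleven loci are declared — the honest power of
these conditions; the published eleven declared QTLs rest on marginal
effect estimates that sum beyond the parental range.

## Fine mapping

Progeny classification defaults to the t-test-vs-parents rule (class of
the parent the line does not differ from at α = 0.05; ambiguous lines
excluded with a warning); the midpoint rule serves noise-free synthetic
panels, with exact midparent ties unclassified.  The delimited interval
is the longest contiguous run of markers at which every classified
line's homozygous genotype matches its phenotype-concordant parent
(tolerant → LTH/BB), reported at the bounding markers' positions as in
graphical substitution mapping, not interpolated.  Contradictory panels
raise an error naming the offending lines; panels without an informative
recombinant return the whole region with a warning.  Gene coordinates
are normalised to start ≤ end on load (minus-strand rows in the
published table are printed reversed); overlap of ≥ 1 bp includes a
gene.

## Numerical and reproducibility choices

All randomness flows from one config seed via `numpy` SeedSequence
children; identical config ⇒ byte-identical outputs (test-enforced).
Least-squares steps use `numpy.linalg.lstsq` with residualisation
(Frisch–Waugh) so the per-position work in scans and permutations is a
vector product; degenerate predictors (zero genotype variance after
residualisation) score LOD 0.  Quantile convention, LOD ceiling, RF cap
and the interval tie-breaks (leftmost longest run) are fixed and
documented above.

## Problem sizes used by the test suite

The suites run on reduced scales chosen to exercise the same structure:
one 130-cM/30-Mb chromosome with 144 lines for calling/mapping fixtures;
500 lines for error-free map recovery; 200 null replicates at
n_perm = 200 for threshold calibration; 100 replicates of a single
8-point QTL (100 lines, 100 cM) for interval coverage and effect
unbiasedness (asserted at the true locus — the peak estimate carries
winner's-curse inflation by construction).  What passing shows about
real data is limited by the generator's idealisations listed above:
uniform recombination and SNP density, independent call errors, strictly
additive phenotypes (no dominance, epistasis, or germination-time
dynamics).
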