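# Methods

## The two-deme coalescent for a partially sex-linked locus

A locus in the pseudoautosomal region (PAR) of a ZW chromosome pair is
carried by two classes of chromosome copies: those currently on a Z and
those currently on a W. In a population of autosomal diploid effective
size `Ne` with equal sex ratio, three quarters of the copies of a
Z-linked locus reside on Z chromosomes, so the class sizes are
`N_Z = 3Ne/4` and `N_W = Ne/4`. Backward in time the classes behave as
demes of a structured coalescent: lineages coalesce only within a class,
and female recombination between the locus and the PAR boundary moves
lineages between classes.

**Migration orientation.** Every W copy sits in a female, whose meiosis
recombines the locus onto a Z with probability `r_f`; a Z copy sits in a
female with probability 1/3, so its ancestor was on a W with probability
`r_f/3`. The backward migration rates are therefore W→Z at `r_f` and
Z→W at `r_f/3` per lineage per generation. Both orientations satisfy the
same flux balance `(3/4)(r_f/3) = (1/4) r_f`; the orientation is isolated
in `scaled_rates` and can be flipped by the `orientation` argument.

**Time scale.** All internal times are in units of `2Ne` generations, so
the expected pairwise coalescence time of an autosomal locus is exactly
1. In these units the pair-coalescence rate is `4/3` within Z and `4`
within W (`2Ne / 2N_deme`), and migration rates are `2Ne·r_f` (W→Z) and
`2Ne·r_f/3` (Z→W). Conversion to diversity happens only at the end:
`π_PAR = π_auto · T̄_t`.

**Simulation.** `simulate_genealogy` is an exact Gillespie algorithm:
exponential waiting times at the summed event rate, event choice by
cumulative-rate inversion on a fixed ordering (coalescence in Z,
coalescence in W, migrations of W lineages by index, then Z lineages by
index) for reproducibility under a fixed random stream. `r_f = 0` with
lineages in both demes is rejected (`NonCoalescingError`) because the
last Z and W lineages could never meet. The sample mirrors a balanced
resequencing design: each of 5 females contributes one Z and one W
lineage, each of 5 males two Z lineages (20 lineages).

**Grouped times and observables.** Pairwise coalescence times are grouped
by starting deme (ZZ/ZW/WW) and by carrier sex (ff/fm/mm; all chromosome
pairs carried by the individuals, including the Z and W of one female).
Derived quantities: `T̄_w = (T̄_ZZ+T̄_WW)/2`,
`T̄_t = (T̄_ZZ+T̄_WW)/4 + T̄_ZW/2` (a random population pair draws Z with
probability 3/4), and the sex analogues `T̄_w^fm = (T̄_ff+T̄_mm)/2`,
`T̄_t^fm = (T̄_ff+T̄_mm+2T̄_fm)/4`. Predictions:
`π_PAR = π_auto · T̄_t` and `F_FM = 1 − T̄_w^fm/T̄_t^fm` (not clipped;
Monte-Carlo noise can make it slightly negative when the true value
is ≈ 0).

**Per-site profile.** `site_profile` builds, for each queried position,
`r_f` from the female genetic map (Kosambi on the interpolated cM
distance to the boundary) and `Ne = ρ/(4 r_f)` with ρ accumulated over
the same interval — the only unit-consistent pairing of the two
published formulas. Per replicate genealogy it evaluates `T̄_t` through
the deme-grouped formula above rather than the plain mean over sampled
pairs: the sample contains 15 Z and 5 W chromosomes, whereas the
population quantity weights classes 3/4 : 1/4, and only the formula
reading makes `π_auto · T̄_t` the correct population prediction. The
point prediction is the mean over replicates; the envelope the 2.5/97.5
percentiles. Defaults are 200 sites × 1000 replicates with the 5+5
sample.

**Branch-length π.** Per-replicate π is `π_auto · T̄_t` from branch
lengths, not from dropped mutations, so the envelopes reflect
genealogical variance only. Mutational sampling is added only when the
synthetic-data generator writes genotypes (infinite sites, Poisson at
rate θ/2 per unit branch). For 200-kb windows at θ ≈ 0.0016/site the
extra mutational noise is small relative to genealogical noise, which is
why the envelope calibration test on generated windows still covers
≈ 95%. The same is *not* true for F_FM: the Weir & Cockerham estimator
applied to 5+5 genotypes has finite-sample noise and a small-sample
centering quite different from the coalescent-time ratio, so the
time-based envelope describes the parametric F_FM, not the sampling
distribution of the W&C statistic; the calibration claim is therefore
made (and tested) for π.

## Map and rate transforms

Kosambi's map function `r = ½(e^{4x}−1)/(e^{4x}+1) = ½·tanh(2x)`
converts Morgans to recombination fraction allowing for interference;
its inverse is `x = ¼·arctanh(2r)`. ρ tracks are stored per kb (the
convention of LD-based estimators); `cumulative_rho` integrates the
piecewise-constant track, treating uncovered stretches (assembly gaps)
as zero-rate with a logged warning (configurable to error).
`linked_extent` inverts the cumulative integral to find the distance from
the boundary at which cumulative ρ reaches a threshold (default 1).
Genetic maps interpolate linearly in cM between markers and refuse to
extrapolate beyond the terminal markers. The sex-averaged map is the
arithmetic mean of the sex-specific cM columns.

## Window statistics and filtering

Coordinates: VCF positions are 1-based; all internal intervals are
0-based half-open; window grids are anchored at 0. Defaults follow
standard practice for low-sample resequencing: 200-kb non-overlapping
windows for π/θ/D/F_FM/GC/CDS, 200 kb with 50 kb overlap for LD.

**Hard filters.** Sites are removed when `QUAL < 30`, `QD < 2`,
`MQ < 40`, `MQRankSum < −12.5`, `FS > 60`, `ReadPosRankSum < −8`,
`SOR > 3`, when they overlap a repeat, or when the summed per-site depth
leaves `[depth_min, depth_max]` (bounds inclusive: 70 kept, 71 removed;
5 kept, 4 removed). A missing annotation passes that criterion (logged).
All rules are pure site predicates, so the surviving set is independent
of application order. The depth bounds follow the "5 to twice the mean"
convention; because "twice the mean" depends on the number of samples
summed, the pipeline driver derives `depth_max` as 2× the observed mean
summed depth by default (`depth_max = 0` in `RunConfig`), while the
library default `(5, 70)` matches a ~35× single-sample scale. The same
bounds define per-window accessible length `L` (the π/θ denominator)
from the depth tracks, excluding repeat-masked positions.

**SLR ploidy.** Inside the SLR, females carry one Z: homozygous diploid
female calls are haploidized (one called chromosome) and heterozygous
female calls — artifacts, typically cross-mapping from a diverged W
gametolog — are set to missing, with counts reported.

**Diversity.** Per site with `k` alternate alleles among `n` called
chromosomes, `π_site = 2k(n−k)/(n(n−1))`; window π and
`θ_W = S/(a₁L)` are per accessible site. Tajima's D uses the standard
normalization constants evaluated at the window-modal `n` (mixed ploidy
makes `n` vary between sites); D is missing when `S = 0`. The
implementation is cross-checked in the tests against tskit's
`diversity` and `Tajimas_D` on msprime-simulated data.

**F_FM.** Weir & Cockerham's (1984) two-population estimator with
females and males as the populations, accumulated as a ratio of summed
variance components across sites (the "weighted" form); negative values
are retained. Sample sizes enter in diploid-individual equivalents
(called chromosomes / 2), so haploid SLR calls contribute half an
individual and no heterozygotes.

**LD.** r² is the squared Pearson correlation of genotype dosages (the
composite genotypic measure appropriate for unphased data). Sites with
any haploid call are excluded, as are sites failing an exact
Hardy-Weinberg test (Wigginton-style enumeration, implemented here;
default threshold p < 0.01 — the HWE cutoff is not standardized, so it
is configurable and applied only to LD, never to diversity). Pairs are
formed within 200-kb windows with 50-kb overlap and de-duplicated across
windows; dense windows can be thinned (`max_snps_per_window`). Note that
under the null of linkage equilibrium the expected dosage r² is
`≈ 1/(m−1)` for `m` diploid individuals (vector length m), not `1/2m`
as for haplotype-based r². The decay curve bins mean r² per 1 kb of
pairwise distance; the decay distance is the first bin midpoint at which
the lightly smoothed curve reaches the background level (default: the
autosomal mean r²) — one of several possible operational definitions,
hence configurable.

## Landscape analysis

**Rolling mean.** Centered positional average over windows whose
midpoints fall within span/2; edge neighborhoods shrink.

**Change-points.** Broken-line regression
`y = β₀ + β₁x + Σ_k δ_k(x−ψ_k)₊` fitted by iterative linearization
(the algorithm of standard segmented regression): augment the design
with `U_k = (x−ψ_k)₊` and `V_k = −1{x>ψ_k}`, solve least squares, update
`ψ_k ← ψ_k + γ̂_k/δ̂_k`. Two robustness additions proved necessary: the
update is step-halved until the residual sum of squares does not
increase (making the objective non-increasing across accepted
iterations), and the start values come from a coarse joint scan over
breakpoint combinations (the RSS surface is multimodal and both quantile
and greedy-forward seeding find local optima on saddle-shaped
landscapes). Breakpoints collapsing within one window trigger a refit
with K−1; non-convergence returns a flagged fit, not an exception.
Breakpoint uncertainty is reported as delta-method SEs
(`SE(γ̂_k)/|δ̂_k|`); no formal significance test is attached, since none
is standardized for this model.

**Mann-Whitney.** U in the sum-of-ranks form; exact null enumeration
when there are no ties and `n_a·n_b ≤ 10⁴` (via scipy), otherwise the
normal approximation with continuity and tie corrections; completely
tied data return p = 1. The tests verify the exact path against an
independent brute-force enumeration.

**GLS with AR(1) errors.** Maximum likelihood, matching `nlme::gls`
with `corAR1` and `method="ML"`: for each candidate φ the model is
whitened by the Prais-Winsten transform (first observation retained with
its `√(1−φ²)` weight and the `½log(1−φ²)` Jacobian term), β solved by
least squares, and the concentrated log-likelihood maximized over
φ ∈ (−0.999, 0.999) by bounded Brent search. SEs use the whitened design
with the degrees-of-freedom-corrected variance; p-values are two-sided t
with n−p df. The implementation reproduces R `nlme` output to ~10⁻⁶ on
a frozen fixture (see tests). Rows with missing values must be dropped
by the caller; the series is assumed contiguous after dropping.

**Coverage boundary.** Per-sex coverage tracks (each sample normalized
to its own mean before averaging) give an F:M ratio near 1 where both
sexes are diploid, near 0.5 where females are hemizygous, and an M:F
ratio near 0 on W-specific scaffolds. The boundary is the last window
with ratio ≥ 0.75 followed by ≥ 5 consecutive informative windows with
ratio ≤ 0.6, reported as the interval between those windows;
zero-coverage windows (assembly gaps) are uninformative and are skipped,
so a gap at the transition is bracketed by the interval. The thresholds
(0.75/0.6, persistence 5, W cutoff 0.1) are configuration with these
defaults; no numeric rule is standard.

## The synthetic-data generator

`synth.generate_dataset` emulates the study design the analysis expects:
a Z chromosome with a 5-Mb PAR and a 2-Mb SLR separated by a 7.6-kb
assembly gap (a 1:10 physical scale of an ostrich-like Z, chosen so the
full pipeline runs in minutes), a saddle-shaped female recombination
landscape (ρ/kb 0.8 at the distal end, 0.02 valley mid-PAR, rising to a
0.65 peak at the boundary, collapsing to 0.01 inside the SLR; the
interior knots are the true change-points), 5 females + 5 males at ~35×,
and an optional W-linked scaffold. `Ne = 2500` with `μ = 1.6·10⁻⁷`
keeps θ = 4Neμ = 0.0016/site at a realistic avian level while making
coalescent simulation cheap; only composite parameters (θ, ρ, map
length per Mb) matter to every statistic computed downstream.

Genotypes: one genealogy per 200-kb window (independent windows — the
design the site-by-site theory assumes), with the window's `r_f` taken
from the same female map the analysis later uses and mutations dropped
on branches. SLR windows use a Z-only sample with hemizygous females,
written as the homozygous diploid calls a naive caller would emit, plus
planted female-heterozygous artifacts (default 2% of female×site SLR
calls) to exercise the ploidy filter. Site annotations are drawn from
passing ranges with a configurable fraction (default 2%) of planted
single-rule failures; variants falling in the generated repeat intervals
are dropped at generation time (as they would be absent from calls made
against a hard-masked reference), so the planted failures are exactly
the sites the hard filters remove. Depth tracks are bin means drawn as
`Poisson(mean·binlen)/binlen` — read sampling averaged over the bin —
with female depth halved in the SLR, zero across the gap, and trace male
coverage on the W scaffold. An optional `linked_selection_strength`
scales each window's θ by `(ρ_local/ρ̄)^strength`, creating the positive
diversity–recombination correlation of linked selection for regression
tests; the default (0) is the plain neutral model.

The truth tables record, per window, the model (Ne, r_f) and the
*realized* `T̄_t` and F_FM of the simulated genealogy, so recovery tests
isolate exactly the noise the generator adds (mutational sampling); the
scalar truth JSON records boundary, gap, landscape knots, repeat
intervals and every planted failure.

**What the generator does not emulate.** Cross-window linkage (each
window is an independent genealogy; within-window LD is real because all
SNPs share one tree, and `ld_fixture` provides block-structured panels
for LD unit tests); sequencing error and genotype-calling error beyond
the planted artifact classes; missing genotypes; multi-allelic sites and
indels; GC-biased gene conversion; selection (beyond the optional θ–ρ
coupling); and population structure or demographic change. Passing
tests therefore validate the estimators and the pipeline logic, not
robustness to real-data artifacts outside these classes.

## Numerical choices and degenerate inputs

* Event choice in the simulator uses cumulative-rate inversion on a
  fixed ordering; genealogies are bit-reproducible for a given seed.
* `site_profile` rejects sites with `r_f = 0` (at or beyond the
  boundary) unless an explicit floor (`clamp_rf`) is requested.
* `Ne = ρ/(4r)` raises at `r = 0` rather than returning infinity.
* Tajima's D is missing at `S = 0`; F_FM is missing for monomorphic
  windows; GC is missing for all-N windows (CDS fraction still
  computed).
* Mean depth bounds are inclusive on both sides.
* The envelope test interpolates bounds linearly at window midpoints and
  drops windows outside the profile's site range (erroring only when no
  window overlaps).
* The segmented fit's breakpoint SEs are `∞` when a segment's slope
  change is numerically zero (no identifiable break).

## Known limitations

* The Gillespie simulator is exact but event-by-event: cost grows with
  `2Ne·r_f`, so profiles over effectively autosomal sites (migration
  rate ≫ 1) are slow at large Ne. The analyses here keep scaled sizes
  (or boundary-adjacent sites, where structure actually matters), and an
  external coalescent engine could be slotted in behind the same
  interface if chromosome-scale profiles at large Ne were needed.
* The F_FM envelope characterizes the parametric quantity, not the W&C
  estimator's sampling distribution (see above).
* W&C F_ST with 5+5 individuals has a visible small-sample centering
  (≈ −1/(2n−1) for identical allele frequencies); window estimates
  should be interpreted relative to a permutation or autosomal baseline,
  which the pipeline's group tests provide.
* `boundary_from_coverage` assumes a single high→low transition per
  scaffold; scaffolds with multiple rearranged segments would need
  per-segment scans.
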