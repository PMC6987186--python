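# Methods

`admixscan` detects adaptive introgression in an admixed population from
phased SNP-array haplotypes. The chain is: marker QC → windowed-PCA local
ancestry inference (LAI) against two reference ancestry classes → consensus
introgression-window calling over a grid of reference-population pairs →
an nSL haplotype-homozygosity scan for co-located selective sweeps →
per-population diversity statistics. A synthetic study generator with known
ground truth drives all recovery tests. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Windowed-PCA local ancestry inference

Markers are cut into consecutive, non-overlapping blocks of `window_snps`
(default 20, the marker density at which ~60 kb blocks on a bovine HD array
carry enough signal without spanning many recombination events). A trailing
remainder shorter than half a window is merged into the previous block.

Per window, the pooled reference haplotypes of the two classes (A =
majority/taurine-like, B = minority/indicine-like) are column-centred and
decomposed by SVD. Among the five leading principal axes, those along which
the class centroids are at least one pooled within-class standard deviation
apart are retained (always at least the best axis; 20-SNP windows cannot
support more than ~5 axes without fitting noise). A window whose pooled
references are constant, or whose centroids coincide, is flagged
uninformative and contributes a neutral score.

A target haplotype's window is scored by the distance ratio
`r = d_A / (d_A + d_B)` to the class centroids in the retained subspace
(`r -> 1` means B-like). Scores are smoothed along each chromosome by a
two-state HMM: between adjacent window midpoints separated by `Δ` Morgans the
ancestry process is redrawn with probability `t = 1 − exp(−g·Δ)`, where `g`
(default 100 generations) is the assumed age of admixture; the redrawn state
is uniform over the two classes, so the effective switch probability is
`t/2`. The uniform redraw keeps the painter exactly symmetric under exchange
of the reference roles (confidence maps to its complement), which the
consensus layer relies on. `r` enters the HMM as a Bernoulli-like evidence
weight (`P(obs|B) ∝ r`); the posterior probability of class B is the
reported confidence, and the hard label is B iff confidence exceeds 0.5,
with exact ties resolved to A (conservative toward the majority background).
The real admixture age of the motivating system is uncertain, so `g` is a
parameter, not an inference.

Per-window class-B frequencies and marker-count-weighted global fractions
summarise a run; window-level accuracy against simulated truth uses the
majority ancestry of the window's markers as the true label.

## Consensus introgression windows

LAI output depends on the reference populations chosen. The consensus layer
runs the painter for every pairwise combination of class-A and class-B
references (3×3 = 9 by default), with identical windowing, and pools the
per-window B-frequencies `f[w,c]`:

* consensus score `S[w]` = mean of `f[w,c]` over combinations;
* consistency `C[w]` = number of combinations in which `f[w,c]` reaches that
  combination's own genome-wide 95th percentile. A combination whose 95th
  percentile is zero flags nothing (an all-background run carries no
  evidence, and a zero cutoff would otherwise flag every window).

A window is called at stringency `top_pct` iff `S[w]` reaches the genome-wide
`100 − top_pct` percentile (5% for the broad set, 1% for the strict set) and
`C[w]` equals the number of combinations (a `min_consistency` and a
k-of-n intersection mode are configurable). Qualifying windows separated by
at most one non-qualifying window are merged into regions — single-window
dropouts from uninformative windows should not split one signal. Regions are
annotated with overlapping genes (1 bp suffices) and intersected across
target populations by interval algebra. Because the 1% score cutoff is never
below the 5% cutoff and the consistency condition is shared, strict regions
always nest inside broad ones.

## nSL selection scan

For a focal marker, `SL` of an allele class is the mean over haplotype pairs
carrying that allele of the number of consecutive markers in the maximal
interval containing the focal marker over which the pair is identical.
Intervals are truncated (and flagged) at chromosome ends rather than the
site being dropped — synthetic chromosomes are short and the flag lets
analyses exclude edge effects explicitly. The statistic is

    nSL = ln(SL_ancestral / SL_derived)

computed per marker with known ancestral allele and derived frequency in
`[0.05, 0.95]` (below that, an allele class has too few carriers for a
meaningful pair average). Negative values mean excess homozygosity around
the derived allele — a sweep on the derived allele; the sign convention is
fixed here because conventions differ between implementations. Flipping a
marker's ancestral/derived polarity negates the raw value exactly.

Raw scores are z-normalised within 20 equal-width derived-frequency bins
(frequency confounds the statistic's null distribution); bins with fewer
than 10 scored markers are merged with the nearest populated bin.

The normalised scores are smoothed along the chromosome with a cubic
smoothing spline whose penalty is chosen by generalized cross-validation
(a fixed penalty can be supplied). The spline is fitted to the *magnitude*
of the normalised score by default. The reason is structural: around a
favoured haplotype, linked sites carry that haplotype's allele, which is
ancestral at roughly half the sites and derived at the rest, so the signed
scores inside a swept region are large in both directions and a signed fit
cancels toward zero; the magnitude accumulates instead. A signed fit remains
available (`signed=True`). Maximal spans where the smoothed curve reaches
`call_threshold` (default 2, i.e. two null standard deviations) over at
least 3 consecutive scored markers are reported as sweep intervals — a
genuine sweep extends over many markers, and the marker minimum suppresses
single-point excursions the spline tracks under GCV. Each consensus region
is reported with the fraction of its span covered by sweep intervals.

## Diversity statistics

* **Observed heterozygosity**: per locus, the share of called genotypes that
  are heterozygous; per population, the mean over loci. The spread is
  reported along both axes (across loci and across individuals) since either
  convention appears in study tables.
* **Runs of homozygosity / F_ROH**: greedy left-to-right maximal stretches
  with at most `max_het` (1) heterozygous and `max_missing` (5) missing
  calls, inter-marker gaps ≤ 1 Mb, ≥ 50 markers spanning ≥ 1 Mb at an
  average density of ≤ 50 kb per marker — the published defaults of the
  standard array-data ROH tool, all exposed. F_ROH is the summed run length
  over the genome length (by default the marker-covered span).
* **Ne from LD**: pairwise haplotype r² binned by genetic distance `c`; the
  phased-sample sampling bias `1/n` (n haplotypes) is subtracted and each bin
  converted with `Ne = (4 f(c))⁻¹ (1/E[r²_adj] − α)` at `t = 1/(2 f(c))`
  generations, with Sved & Feldman's mutation-rate modifier `α = 2`. The
  distance mapping `f` is linear by default (`f(c) = c`; a Haldane-type
  mapping is available) — the tool this reimplements does not publish its
  constants, so all are configurable. Bins with non-positive mean adjusted
  r² report Ne as missing; estimates are clamped below at 1.
* **Reynolds' distance**: the uncorrected biallelic coancestry estimator
  `θ = Σ(p₁−p₂)² / Σ(p₁+p₂−2p₁p₂)` over loci with a positive denominator
  term, with an optional `−ln(1−θ)` transform; written in PHYLIP and NEXUS
  for external Neighbour-Net viewers. The sample-size-corrected estimator is
  deliberately out of scope.

## Synthetic study generator

The generator emulates a two-lineage livestock design: ancestral allele
frequencies Uniform(0.05, 0.95) (array-ascertained common variants; rare
alleles would make 20-SNP windows degenerate), two ancestry classes drifted
from them under the Balding–Nichols model with `F_class = 0.3` (the
taurine/indicine separation scale), and three reference populations per
class drifted a further `F_div = 0.15` (within-lineage breed divergence).
Allele 0 is declared ancestral at every site — a pure coding convention that
fixes polarity for the sweep scan.

Target haplotypes are recombination mosaics: crossover breakpoints follow a
Poisson process of `g_admix = 100` per Morgan (inter-breakpoint distances
Exponential with mean 1 cM), each segment is independently of class B with
probability `alpha = 0.12` (the "pool" approximation to g-generation
admixture; tract lengths then match the theory LAI assumes) and is copied
from a uniformly chosen founder haplotype of that class. The default
chromosome carries 5,000 evenly spaced markers on 100 cM at 1 cM/Mb, and the
default target population holds 50 samples (100 haplotypes).

Adaptive introgression is *injected*, not evolved: one donor template
haplotype is drawn from the class-B class-level frequencies — a haplotype of
the donor lineage's common ancestral pool, recognisable as class B under any
class-B reference panel, as an introgressed tract that rose to high
frequency before breed formation would be — and copied over the tract
(default 1.2 cM centred at 50.2 cM, i.e. mid-window, so the tract tiles
three full 20-SNP windows) into a `carrier_fraction` (default 0.9) share of
target haplotypes. This creates the joint signature
the pipeline looks for: near-fixed local minor ancestry plus extended
haplotype homozygosity.

Founder haplotypes carry **independent sites** (no background LD). The
windowed-frequency painter and the injected-identical-tract sweep signal do
not require background LD, and independence keeps every expectation in the
recovery tests analytic. Consequences: LD pruning on simulated references
removes almost nothing, and the background level of |nSL| is milder than in
real data — so passing tests demonstrate recovery of the modelled signals,
not performance under realistic background haplotype structure. A coalescent
backend would be the natural extension point. For the LD-based Ne estimator,
which *needs* linkage, a separate forward Wright–Fisher simulator with
recombination at constant size is provided (monoecious random mating,
Poisson crossovers; founders at Uniform(0.1, 0.9) frequencies; 50
generations is enough for LD at c ≥ 0.01 M to equilibrate, so the
recent-generation bins are informative about the simulated size).

Multi-chromosome studies are concatenations of independent replicates;
recombination hotspots, post-admixture mutation and three-way admixture are
out of scope.

## Numerical and degenerate-input choices

* QC removal order is fixed (unmapped → call rate → MAF) so report counts
  are deterministic; thresholds are strict (`MAF < 0.01` removed, a marker
  at exactly 0.01 retained). MAF uses called genotypes only.
* LD pruning removes the later-positioned member of an offending pair
  (keep-first convention) and re-scans windows of 50 retained markers,
  advanced by 5, to a fixpoint. Monomorphic columns yield undefined r² and
  are treated as unlinked.
* Genetic positions default to 1 cM/Mb when no map is supplied.
* BED is 0-based half-open, GFF3 1-based closed; internal coordinates are
  1-based closed with conversion at the boundary only.
* The 95th/5th/1st percentiles use linear interpolation (numpy default).
* Spline fitting with a constant input short-circuits to that constant
  (GCV is undefined on zero-variance residuals).
* Normalisation raises on a zero-variance bin rather than emitting zeros.

## Problem sizes used in the checks

The recovery suite runs the full default scenario (5,000 markers, 100 target
haplotypes, 9-combination grids) over 5–10 seeds per property, and the
brute-force cross-checks (pair-enumeration nSL, exhaustive-fixpoint LD
pruning) on 200 panels of up to 8 × 30 and 20 panels of 60 × 200
respectively — sizes at which the oracles are exact and the whole suite
stays desk-scale.

## Known limitations

* No background LD in the generator's founders (see above); accuracy numbers
  on real data will be lower and reference-pair disagreement higher.
* The painter is strictly two-way; three-way ancestry is handled pairwise,
  as the consensus design intends.
* Consensus scores are empirical-percentile ranked; no formal significance.
* The HMM is a declared replacement for the original PCAdmix internals —
  same information per window, fully specified here, but not bit-compatible
  with that tool.
* Genotype call-rate handling exists for completeness; phased haplotype
  panels are complete by construction.
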