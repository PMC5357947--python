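# Methods

## The analysis model

The pipeline treats chromatin accessibility as a per-region read count
over an 8-sample design: four T-cell states (NS, ST, SW, RS) crossed
with two pre-treatments (DMSO vehicle, rottlerin). Differential
accessibility is *not* modelled with a count GLM: the caller is a
deliberate thresholded fold change — a region changes between two
samples when its normalised fold change reaches 1.75 and the larger of
the two normalised counts reaches 30 — because the study design has one
library per condition and no replicates from which to estimate
dispersion. Statistical control comes instead from an *empirical*
calibration: NS-DMSO vs NS-rottlerin is biologically null, so the number
of regions the caller fires on that pair estimates the false positives
carried by every real comparison; dividing it by each comparison's call
count gives a per-comparison false-positive rate, reported as a
(min, max) range.

The three state-vs-NS directions define the memory taxonomy. Writing
the (ST, SW, RS) up-pattern as a binary triple: a = (1,0,0),
b = (1,0,1), c = (0,0,1), d = (1,1,0), e = (1,1,1), f = (0,1,1),
g = (0,1,0); h–n mirror a–g for decreases. Sets b, e, i, l subdivide by
the RS/ST normalised ratio (suffix 2 when RS/ST ≥ 1.75, suffix 1 when
ST/RS ≥ 1.75, suffix 0 otherwise — the ratio rule leaves a genuine gap,
and we keep the residual rather than forcing a side). Meta-groups:
primary-enriched {a, b1, e1}, secondary-enriched {b2, c, e2},
SW-enriched {f, g}; all decreased sets report as `decreased`, and
{b0, e0, d} as `other_increased`. Regions with both up and down calls
across the three comparisons take the majority direction (ties toward
up) and carry an `ambiguous` flag rather than being dropped.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `extension` | 200 bp | 3′ extension of each read before counting (any-overlap rule) |
| `fc_cutoff` | 1.75 | fold-change threshold of the caller |
| `min_reads` | 30 | floor on the max of the two compared normalised counts |
| `ratio_cutoff` | 1.75 | ST/RS subdivision threshold for b, e, i, l |
| `attenuation_cutoff` | 1.75 | DMSO/rottlerin ratio that flags a call rottlerin-sensitive |
| `window` | 50 kb | TSS-to-region-edge distance for gene-set association |
| `expression_threshold` | 0.5 log2 | PRG/MRG margin rule |
| `motif_width` | 300 bp (500 for co-occupancy) | standardised region width for scanning |
| `relative_threshold` | 0.8 | PWM hit = score ≥ 80 % of the motif's maximum log2-odds |
| `n_perm` | 1000 | region permutations for GSEA significance |

`min_reads` applies to the **max** of the two compared samples: requiring
both would make it impossible to call a region that opens from zero.
Fold changes use a +0.5 pseudocount on both counts. The rottlerin
sensitivity threshold re-uses 1.75 since nothing in the design motivates
a second constant; it is configurable.

## Normalisation

MA normalisation puts every sample on the scale of a common reference
(NS-DMSO by default): with M = log2 s − log2 ref and
A = (log2 s + log2 ref)/2 over regions, the correction is median(M)
(default) or a lowess fit of M on A (`method="loess"`, span 0.4), and
counts are back-transformed by s·2^(−correction). The pseudocount pads
**only zero counts** (0.5), so a sample that is an exact k-fold rescaling
of the reference normalises back to the reference exactly; a global
pseudocount would break that identity at low counts. A degenerate
(constant) sample falls back from loess to median with a warning.
Spearman correlations are computed on the normalised matrix over all
retained regions (configurable to raw).

## Statistics

* Wilcoxon comparisons (`compare_profiles`, RS/ST ratio contrasts) use
  the two-sided rank-sum normal approximation with continuity
  correction — the convention of R's `wilcox.test(correct=TRUE)` — via
  `scipy.stats.mannwhitneyu`; fully tied inputs return p = 1 with a
  warning.
* Gene-class proximity enrichment reports background counts against all
  genes on the array, but the Fisher 2×2 itself contrasts the class with
  its complement so the table margins are disjoint (a column that
  includes the class double-counts it and is not a valid exact-test
  design). The odds ratio uses the cross-product with a 0.5 Haldane
  correction applied only when a cell is zero. Two-sided by default;
  direction is read from the odds ratio.
* Motif enrichment against a background region collection is a
  two-sided Fisher test on presence/absence; presence defaults to ≥ 1
  occurrence for composition tables and ≥ 2 for GSEA membership.
* Region-GSEA: walking the fold-change-ranked region list, hits add
  |score|^w / Σ|score in set|^w (w = 1) and misses subtract 1/(N − n);
  ES is the signed maximum deviation, p = (1 + #{|ES*| ≥ |ES|})/(1 + n_perm)
  over random memberships of the same size (exhaustive enumeration
  available for small N), and NES divides ES by the mean |ES*| of the
  same sign. ES is invariant under positive rescaling of the scores and
  bounded in [−1, 1].

## The synthetic generator

The generator emulates the structure the analysis consumes, with ground
truth recorded for every plant.

**Counts.** Each region draws an accessibility propensity
g ~ Gamma(mean 1) shared by all 8 samples; sample counts are negative
binomial around baseline_mean × library_factor × fold × g. The planted
fold is `effect_fold` (default 3) in exactly the state-vs-NS comparisons
that define the region's set label (1/effect_fold for decreases), and
rottlerin samples of flagged "sensitive" regions attenuate the fold on
the log scale (fold^(1−attenuation)). Total overdispersion
(`nb_dispersion`, default 0.05) splits 80/20 between the shared region
propensity and the per-sample technical component
(`sample_dispersion_fraction`): marginally each count is negative
binomial at the stated dispersion, while between-sample fold changes
carry only the technical part — which is what makes a threshold caller
viable at one library per condition, and keeps the null pair's
false-positive rate small but non-zero and monotone in the cutoff.
`nb_dispersion = 0` disables noise entirely (counts are rounded means).
Default set proportions: 50 % unchanged, 25 % increases split across a–g
in the study's observed composition (a 832 : b 1013 : c 1430 : d 92 :
e 579 : f 492 : g 899), 25 % mirrored decreases; the changed fraction is
deliberately higher than a real experiment's so every set is populated
at desk scale.

**Reads.** Regions are laid out with inter-region gaps of at least the
read extension, and each counted event becomes one 50-bp read whose
200-bp extension overlaps its region; background reads fall entirely
inside gaps. Re-counting the emitted reads therefore reproduces the
count matrix *exactly* — the round trip is a test oracle, not an
approximation.

**Expression.** Planted MRG genes get RS = max(NS, ST) + effect (+ the
condition's own measurement noise), anchoring the memory response to the
realised baseline levels; PRG mirror for ST. A plant can still be missed
when its own noise draw dips below the 0.5 rule, which is why recovery
at noise sd 0.2 is ~99 %, not 100 %. A configurable fraction of MRG TSSs
(default 0.8) lands within 50 kb of regions in designated memory sets.

**Sequences.** Backgrounds are i.i.d. uniform ACGT; for each
(motif, set) plant probability, a Bernoulli subset of that set's regions
receives the motif's consensus at a uniform offset. The bundled PWM
library is consensus-derived (0.94 on the consensus base), which makes
closed-form background hit rates computable for tests.

What the generator does **not** emulate: GC/mappability bias, fragment-
size distributions, sequencing error, replicate structure, correlated
gene expression programs, or real motif information content. Passing
tests therefore demonstrate the correctness of the analysis logic under
a controlled generative model, not performance on real libraries.

## Problem sizes

The test-suite and acceptance runs use 200–5000 regions, 500–1000 genes
and 300–600 sequences; the 5000-region fixture (effect 3, dispersion
0.05, baseline 200) is the standard recovery condition, and the
read-level round trip runs at 200–1000 regions (~0.5–2 M reads). These
sizes give stable Monte-Carlo margins while keeping any single check in
seconds.

## Known limitations

* The printed study-scale numbers (40 731 merged regions, 5337
  increases, 242 expected false positives, ρ = 0.93/0.70) derive from
  the deposited sequencing data and require realignment and broad-peak
  calling to reproduce; the package consumes peak/read-level inputs and
  does not re-implement that upstream.
* The false-positive-rate denominator ("rate per comparison") is one
  reading of an under-specified quantity; the calibration object exposes
  the raw counts so alternatives are easy to derive.
* Nearest-transcript annotation uses TSS distance only; ties break
  lexicographically for determinism. Chromatin state is read at the
  region midpoint (configurable conceptually, midpoint implemented).
* The PWM scan threshold (80 % of max score) stands in for external
  scanners whose thresholds are tool-internal; motif lists are
  user-supplied rather than re-derived.
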