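# Methods

## Model and procedure

diffedit scores differential A-to-I editing between two sample sets on
non-overlapping genomic windows. The chain of statistics is deliberately
simple: a per-site editing ratio (mismatch reads over coverage), summed
over the window into a per-sample editing signal, averaged within each
set, and differenced between sets into the window score δ. Positive δ
means more editing in the second ("condition") set.

Significance is empirical. The eleven mismatch classes other than the
focal one (A→G by default) are subject to the same sequencing and PCR
error processes and the same pipeline, but carry no A-to-I editing signal;
their δ distributions therefore estimate how many focal windows of a given
extremity arise without editing. The per-decoy estimate is the ratio of
decoy to focal tail counts at δ (lower tail for δ < 0, upper for δ > 0);
the median over available decoys, capped at 1, is the raw q, and a running
minimum within each sign tail makes q non-increasing in |δ|. The estimator
rests on one assumption — exchangeability of focal-null and decoy window
deltas — discussed under *Limitations*.

Mismatch classes are defined in reference-genome orientation and never
folded by strand: with unstranded libraries, minus-strand A→G editing
surfaces as the T→C class, which can itself be scored by setting
`focal_mismatch="TC"`. Any of the twelve classes may be focal; the decoys
are always the remaining eleven.

## Eligibility rules and their rationale

* **All-sample coverage.** A position counts only when *every* sample of
  both sets reaches `min_coverage` (default 10 reads). This keeps each
  sample's window signal a sum over the identical site set; otherwise
  coverage differences alone would move δ. The price is sensitivity loss
  in the weakest sample.
* **Window tiling.** Windows (default 51 nt) are anchored at each merged
  region's start and never span region boundaries; the final remainder
  window of a region is kept so short exons still contribute. Anchoring at
  region rather than chromosome coordinates changes window identities but
  not the statistics.
* **Minimum sites per window.** Default 1, the weakest choice; raising it
  trades coverage of sparse regions for more stable signals.
* **SNP filter (optional, default off).** A site is dropped for a class
  when any single sample with `min_coverage` shows a mismatch frequency at
  or above `snp_freq_threshold` (default 0.80, inclusive). Only covered
  samples are consulted — a 1-of-1 read must not veto a site — and the
  check spans all samples of both sets, the conservative reading. A
  variant shared by both sets does not bias δ even unfiltered (it shifts
  both set means equally, a property the tests assert to 1e-12); the
  filter matters when genotypes differ between the groups, e.g. when
  comparing distinct cell lines.
* **Pileup.** Bases contribute when aligned as match/mismatch with base
  quality ≥ 20 and mapping quality ≥ 0 (both configurable); deletions,
  reference skips and N calls never count. Duplicate-flagged reads are
  counted by default (configurable), and overlapping mate pairs count
  independently; users wanting single-counting of overlaps should
  pre-collapse pairs. The base-quality default mirrors the common q20
  trimming convention; mapping quality 0 keeps aligner-accepted
  multimappers.

## q-value conventions

* The focal tail count always includes δ itself, so the denominator is at
  least 1.
* The ratio can exceed 1 when a decoy set is larger or noisier; q is a
  proportion, so estimates are capped at 1 after the median.
* A window with δ exactly 0 is maximally non-significant (q = 1) and does
  not participate in either sign tail.
* Ties at identical δ receive identical q (the running minimum is taken
  over all windows with |δ′| ≤ |δ|).
* Decoy classes with zero windows are skipped; if none remains, the run
  aborts with an explanatory error rather than inventing a null.
* `normalize_decoy_size` (default off) additionally scales each decoy tail
  count by the focal/decoy set-size ratio. The default follows the raw
  count-ratio definition; the normalized variant exists for analyses whose
  classes have very different window counts.

## Synthetic data generator

`diffedit.simulate` produces count tables (and, on demand, FASTA +
indexed micro-BAM fixtures whose pileup reproduces the counts
integer-exactly) with fully recorded ground truth. Its data model mirrors
the detector's assumptions: a uniform-random reference; per-site,
per-sample coverage from a negative binomial (defaults: mean 50,
dispersion 10); every base mis-read as each other base with probability
`error_rate/3` (default total 0.002, the scale of Illumina substitution
errors), symmetric across the twelve classes; and A-to-I editing as an
excess of observed G at edited reference-A sites, with levels drawn
Beta(2, 8) (mean 0.2) shared by all samples of a set. Planted windows
shift the second set's levels additively (clipped to [0, 1]), so each
window's true expected δ is the sum of per-site level differences, which
the generator records.

By default, edited sites exist only inside planted windows. This is a
considered choice, not a simplification: background editing with identical
levels in both sets still contributes sampling variance p(1−p)/c to
focal-class windows only, making the focal null heavier-tailed than every
decoy; any focal δ beyond a decoy's observed range then gets a zero tail
count and hence q̂ = 0, and calibration collapses. The default regime is
the one in which the estimator's exchangeability assumption holds;
`background_editing=True` and the per-class `error_skew` knob exist
precisely to violate it and observe the consequences. What passing tests
on this generator do *not* show: robustness to focal-specific biological
variance, strand-bleed artifacts, alignment errors around splice sites, or
transcript-structure effects — none of which the generator emulates.

One-set SNP sites (genuine genotype differences between groups) produce
extreme deltas in whatever class matches their substitution; the generator
supports them for exercising the SNP filter.

## Numerical choices

* Window signals are summed per window (`np.add.reduceat`), not as
  prefix-sum differences, so rounding is independent of chromosome-scale
  accumulations.
* The exactness tests exploit dyadic arithmetic: with power-of-two
  coverages every editing ratio and every sum is an exact binary fraction,
  so the vectorized pipeline must agree *bitwise* with a plain-loop
  reference implementation regardless of summation order. Arbitrary
  coverages are checked to 1e-12.
* Medians over an even number of decoy estimates take the midpoint of the
  central pair.
* Degenerate inputs: empty decoy classes are skipped, an empty focal class
  yields an empty (warned) result, a window with no eligible site is
  absent from that class's table rather than zero-filled.

## Problem sizes in the shipped checks

The test and acceptance runs use 2 + 2 samples, 2,000 windows of 51 nt
(40 regions × 2,550 nt), coverage mean 50, ten replicates for null
calibration, and planted shifts of +0.2 in 5% of windows — small enough to
run in seconds per replicate while leaving ≥ 1,900 null windows per class
for the tail estimates.

## Known limitations

* **Extreme-window decoy artifact.** Under a perfectly exchangeable null,
  the most extreme focal window in each sign tail exceeds the minima of at
  least six of the eleven decoy classes with probability exactly 1/2 (a
  rank argument over the twelve class extrema), receiving q̂ median 0. The
  method therefore emits on the order of one spurious zero-q window per
  tail per run; this is intrinsic to tail-count ratios against finitely
  many decoys and is why sign-consistency of detections should be judged
  against the FDR allowance rather than expected to be absolute.
* The realized FDR at q ≤ 0.1 on planted data hovers around the nominal
  level (the q ≤ t set trades planted and borderline-null windows); q is
  an FDR estimate, not a per-window error probability.
* Focal-specific variance not shared by decoys (e.g. biologically variable
  but non-differential editing) makes q anticonservative, as the generator
  section explains.
* Unstranded data fold antisense editing into T→C; no attempt is made to
  reassign it.
* The SNP heuristic cannot see variants below the frequency threshold;
  comparisons across genetically distinct samples should treat residual
  decoy-class signal as a warning sign.
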