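# Methods

## Overview

`fastseqs` models an aneuploidy screen in which a single primer pair
amplifies a dispersed subset of LINE-1 (L1) repeat loci, 37-base tags are
sequenced and counted per locus, per-position counts are quantile-normalized
within an experimental group, and per-chromosome totals are standardized
against a euploid reference group. This note records the generative model,
the parameters that matter, the numerical choices, and what the synthetic
data does and does not capture.

## The count model

A *position panel* of `n` loci carries, per locus: chromosome, coordinate,
strand, one of seven L1 subfamily labels, an expected amplicon length drawn
from a two-component normal mixture, and a reproducible amplification
efficiency.

Per-position expected counts for a sample of depth `D` are

```
mu_i = D * w_i / sum(w),   w_i = bias_i * eff_i * copy_i
```

* `bias_i` — the small-fragment amplification advantage: positions in the
  124 bp mode get `size_bias` (default 2.0), positions in the 142 bp mode
  get 1. Membership is by nearest mode peak. This reproduces the observed
  preferential amplification of the smaller size class and makes the
  log-count density bimodal with mode separation log(2) ≈ 0.69.
* `eff_i` — per-position amplification efficiency, lognormal with log-scale
  SD 0.25 (default), drawn **once with the panel** and shared by all
  samples. Real amplicon data shows a broad but highly reproducible spread
  of per-locus yields; modeling it matters because quantile normalization
  maps each count to the group-mean value at its rank — if all positions in
  a mode had identical expectations, a copy-number shift would push the
  affected chromosome's positions *en bloc* to the extreme ranks and the
  rank→value map would clip the signal (in development this saturated a 25%
  admixture at an apparent 10%). With a realistic across-position spread
  the map is locally smooth and a (1 + f/2) mean shift survives
  normalization essentially undistorted. The value 0.25 keeps the two size
  modes clearly separated (0.69 apart) while giving each mode a realistic
  width.
* `copy_i` — 1 + f/2 on the trisomic chromosome of a mixture with trisomic
  DNA fraction f, 1 elsewhere. Totals are renormalized to `D`, matching the
  fixed-depth reality of a sequencer (the trisomic chromosome gains share;
  all others dip by a factor 1/(1 + w·f/2), which is negligible at
  physiologic f).

Counts are negative binomial with variance `mu + mu^2/r`; the dispersion
`r` defaults to 20 (visibly overdispersed sequencing counts) and is the
calibration knob for reference-group tightness.

### Dispersion calibration

Experiments that pin the reference group's chromosome-total relative SD to
a target `t` solve for `r` in closed form. For a sum `T` of independent
NB(mu_i, r) over the retained positions of the chromosome, with
`M = sum(mu_i)` and `S2 = sum(mu_i^2)`,

```
relvar(T) = 1/M + S2 / (r M^2)   =>   r = S2 / (t^2 M^2 − M)
```

The retained set is predicted by applying the left-tail valley cutoff
(below) to the noiseless log-mean distribution. The target is unreachable
when the Poisson floor `1/sqrt(M)` exceeds `t`; the calibration then raises
an error so the caller increases depth. Achieved relative SDs land within a
few percent of the target; the residual excess comes from rank-assignment
noise added by normalization and is absorbed by the empirical SD used in
the z denominator.

## Read-level simulation

Reads are 37 bases: the last 3 bases of the forward primer followed by
34 locus-specific bases (the reference 37-mers are generated with the
panel; a minimum pairwise Hamming distance can be enforced for small
panels). Substitution errors hit bases independently at `error_rate`; a
configurable fraction of bases (default 5%) receives a Phred quality below
20, the rest 30–40. UIDs, sample barcodes and a chastity flag travel in
FASTQ header fields. With `reads_per_template > 1` the NB draw is
interpreted as template molecules, each with a distinct UID and a perfectly
even PCR — adequate for testing template counting, not for modeling PCR
stochasticity.

All randomness flows from one integer seed per sample through a
counter-based Philox generator with fixed stream offsets per purpose
(panel, counts, tags, reads), so adding samples or stages never perturbs
existing draws and equal seeds give byte-identical outputs.

## Tag processing

Per sample: drop chastity failures; keep reads whose first three bases
equal the primer's last three; mask bases with quality < 20 to N; collapse
to distinct sequences; align each distinct sequence against the panel's
reference 37-mers, accepting only a **unique** hit within one mismatch
(two or more qualifying references suppress the read; N matches nothing,
including another N — the conservative reading of mismatch-counting
alignment); map multiplicities back to positions. An accounting object
proves conservation: reads in = chastity-failed + primer-dropped +
unaligned + multi-suppressed + counted. With UIDs, the per-position count
is the number of distinct UIDs among its aligned reads.

## Normalization

Within an experimental group (≥2 samples):

1. keep only positions with ≥1 tag in every sample;
2. quantile-normalize: stable-sort each sample's counts (position order
   breaks ties), take the across-sample mean at each rank, substitute, and
   unsort. Afterwards every sample has the same sorted vector and the same
   total. Ties in raw counts may map to different means when their ranks
   differ — standard quantile-normalization behavior without tie-averaging;
3. estimate a Gaussian KDE of the natural-log per-position means
   (Silverman bandwidth, 512-point grid spanning the data ± 3 bandwidths).
   Modes are strict local maxima with density ≥ 1% of the global maximum —
   the floor keeps sampling wiggles in the tails from counting as peaks
   while still detecting genuinely small secondary modes;
4. the left-tail cutoff is the grid point of minimum density strictly
   between the two highest modes ("the valley"); positions whose log mean
   falls below it are discarded and the quantile normalization is repeated.
   A unimodal density skips exclusion with a logged warning.

Zeros cannot reach the log transform because step 1 guarantees counts ≥ 1
everywhere. The density is estimated on per-position means across samples
so the exclusion list is group-level — one shared retained set, which the
identical-distribution property requires. Full normalization of
8 × 25,000 runs in well under a second.

## z-scores and calls

Chromosome totals (sex chromosomes excluded by default; a flag includes
them) are standardized against the reference group's per-chromosome mean
and **sample SD (n−1 denominator)** — the appropriate choice for reference
groups of ~8 samples. Calls are strict: gain iff z > cutoff (default 3.0),
loss iff z < −cutoff; exactly 3.0 is euploid. Reference members are scored
leave-in by default (matching the reproducibility experiments, where
plotted samples belong to their own reference group; the internal bound
|z| ≤ (n−1)/√n makes this safe); a leave-one-out mode exists but is off by
default. The trisomic fraction estimate f̂ = 2(chrN/µ − 1) is clipped to
[−2, 2].

The subfamily summary compares, per subfamily, the observed percentage of
positions per chromosome (mean across samples, a position counting as
observed when its count is nonzero) with the panel-predicted percentage,
via a paired two-tailed t-test across chromosomes. Because both vectors
sum to 100%, the mean paired difference is zero whenever the subfamily is
present at all, so the null yields p ≈ 1 (exactly 1 for perfect agreement,
reported by convention when all differences vanish); a subfamily missing
from the observations gives a strongly negative mean difference and a
small p.

## Canonical experiments

`experiments.py` fixes the study designs used for validation: panel of
21,676 positions; an 8-sample euploid group at depth 4×10⁶ and r = 20 for
the reproducibility bound; quadruplicate 4% and 8% trisomy-21 admixtures
at depth 2×10⁷ with r calibrated to a chr21 relative SD of 0.003; and a
six-sample 0/0/5/5/10/25% mixing series at depth 7×10⁷ calibrated to
0.0015. The admixture depths are set by the calibration itself: the Poisson
floor must sit below the target relative SD, which 4×10⁶ cannot reach for
a ~1.2%-weight chromosome. Per-sample seeds derive from one experiment
seed plus fixed role keys via `numpy.random.SeedSequence`.

## Primer-design module

The similarity search is k-mer-seeded (default k = 20) ungapped alignment:
every shared exact k-mer proposes a diagonal, each diagonal is scored once
over the full query length (clipped at contig ends), and "variant bases"
are substitutions only. Indel-tolerant alignment is out of scope; the
downstream filters consume variant-base counts and spans, which ungapped
matching supplies. Uniqueness under e read errors uses the radius-2e rule:
a sequence is distinct iff no other sequence lies within Hamming distance
2e, guaranteeing any read with ≤ e errors stays strictly closer to its
source than to any other candidate. In-silico PCR is IUPAC-aware, requires
an exactly compatible 3'-terminal base regardless of the mismatch budget,
and reports both orientations; it is meant for synthetic genomes up to a
few megabases. Sliding windows over a region of length L number
`floor((L − 150)/50) + 1`; reports use 1-based inclusive coordinates, BED
output 0-based half-open.

## What the simulation does not capture

* PCR stochasticity and polymerase errors shared across reads of one
  template (UID families are error-free copies unless read errors are
  added independently).
* Indels, optical duplicates, flow-cell chemistry, GC-dependent bias
  (the assay's design makes GC correction unnecessary; none is applied).
* Real L1 sequence content: reference 37-mers are random, so alignment
  ambiguity is rarer than among true repeat copies. The multi-hit
  suppression path is exercised by construction in tests instead.
* Biological covariance between positions (e.g. batch effects); positions
  are conditionally independent given the panel.

Passing tests therefore demonstrate the correctness and statistical
behavior of the pipeline under its stated model, not clinical performance
on plasma DNA.
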