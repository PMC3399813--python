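# fastseqs

Amplicon tag counting and z-score aneuploidy detection for repeat-primed
massively parallel sequencing assays.

## The problem

Counting sequencing reads per chromosome detects aneuploidies (e.g. trisomy
21) because one extra chromosome copy in a fraction *f* of a DNA mixture
raises that chromosome's share of reads by *f*/2. Whole-genome approaches
need expensive library preparation and genome-scale alignment. An
alternative assay amplifies ~20,000 dispersed LINE-1 (L1) retrotransposon
loci with a **single primer pair**, sequences 37-base tags, and counts tags
per amplified locus ("position") — a small, highly reproducible target set
that makes both the wet-lab and the analysis radically simpler.

`fastseqs` implements the full computational side of that assay for
bioinformaticians who want to study, extend or stress-test it:

* **simulator** — synthetic position panels (bimodal 124/142 bp amplicon
  mixture, seven L1 subfamilies, 22 autosomes + X/Y), negative-binomial tag
  counts with reproducible per-position amplification efficiencies, trisomy
  admixture at fraction *f* (count factor 1 + *f*/2), and 37-base FASTQ
  reads with optional unique molecular identifiers (UIDs);
* **primer_design** — the in-silico selection workflow: 150 bp sliding
  windows (step 50), k-mer-seeded ungapped similarity search, the
  11–30-variant-base / ≤180 bp / ≥3-sibling filters, distinctness of
  candidate amplicons under 1–3 read errors, and IUPAC-aware in-silico PCR;
* **tagproc** — chastity gating, the 3-terminal-primer-base filter, masking
  of bases with Phred quality < 20 to N, distinct-sequence collapse, unique
  alignment with at most one mismatch (multi-hits suppressed), count
  back-mapping, and UID-based template counting;
* **normalize** — quantile normalization across an experimental group with
  left-tail position exclusion at the density valley between the two modes
  of the log-count distribution;
* **aneuploidy** — per-chromosome z-scores against a euploid reference
  group, gain/loss calls at |z| > 3.0, and trisomic-fraction estimation
  f̂ = 2(chrN/µ<sub>chrN</sub> − 1).

## The statistic

For sample *i* and chromosome *N*, with µ<sub>chrN</sub> and
sd<sub>chrN</sub> the mean and sample standard deviation of normalized
chromosome totals in a euploid reference group,

```
z_i = (chrN_i − µ_chrN) / sd_chrN
```

z > 3.0 calls a chromosomal gain. Members of a reference group of size *n*
scored against their own group satisfy |z| ≤ (n−1)/√n (≈ 2.475 for n = 8),
so a euploid reference can never self-flag at the 3.0 cutoff.

## Worked example

Create `config.yaml`:

```yaml
n_positions: 600
depth: 12000
seed: 5
q20_fail_frac: 0.0
samples:
  - {sample_id: ref0, seed: 50}
  - {sample_id: ref1, seed: 51}
  - {sample_id: ref2, seed: 52}
  - {sample_id: ref3, seed: 53}
  - {sample_id: ref4, seed: 54}
  - {sample_id: ref5, seed: 55}
  - {sample_id: tri21, trisomic_chrom: chr21, f: 1.0, seed: 99}
reference_samples: [ref0, ref1, ref2, ref3, ref4, ref5]
```

then

```sh
fastseqs run --config config.yaml --outdir run/
fastseqs figures --manifest run/manifest.json
```

This simulates FASTQ for six euploid references and one pure trisomy-21
sample, processes tags, normalizes, and calls. `run/summary.json` reads:

```json
{
  "max_abs_z": 5.70779131175936,
  "calls": [
    {"sample": "tri21", "chrom": "chr1",  "z": -5.145, "call": "aneuploid-loss"},
    {"sample": "tri21", "chrom": "chr10", "z": 3.099,  "call": "aneuploid-gain"},
    {"sample": "tri21", "chrom": "chr21", "z": 5.708,  "call": "aneuploid-gain"}
  ]
}
```

The trisomic sample's chr21 total sits 5.7 reference SDs above the euploid
mean — an unambiguous gain — while every reference sample stays within
±2.5 (the structural in-group bound). The weaker chr1/chr10 calls are the
flip side of fixed sequencing depth: a pure-trisomy sample spends ~1% more
of its reads on chr21, so every other chromosome's share dips slightly, and
at this toy scale some of those dips cross the cutoff. At realistic
admixture fractions (f ≤ 0.25) the effect is negligible.

Each stage is also exposed separately (`fastseqs simulate`, `design scan`,
`design filter`, `design distinct`, `design ispcr`, `tags`, `normalize`,
`call`) and as plain library functions.

## Layout

```
src/fastseqs/
  simulator.py      synthetic panels, counts, reads; dispersion calibration
  primer_design.py  window scan, similarity search, filters, in-silico PCR
  tagproc.py        read filtering, masking, unique alignment, counting
  normalize.py      quantile normalization + left-tail exclusion
  aneuploidy.py     z-scores, calls, fraction estimates, subfamily summary
  experiments.py    canonical simulation study designs
  pipeline.py       end-to-end orchestration with hashed manifests
  cli.py            command-line interface
docs/methods.md     model, parameters, numerical choices, limitations
```
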