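# rigstruct

Structural-genomics analysis toolkit for tumor cohorts, built around five
pipeline stages plus a ground-truthed synthetic cohort generator:

- **`rigstruct.cnv`** — copy-number segment classification (gain/loss at
  inclusive ±0.2 log2, with a ±0.25 sequencing preset), focal vs broad
  calls (≤25 %-of-arm or ≤3 Mb modes), arm-level alteration frequencies,
  gene-level calls (gain / amplification / loss / neutral), and CNV
  counts per sample. Centromere-spanning segments are split per arm.
- **`rigstruct.chromothripsis`** — per-chromosome evaluation of four
  statistical hallmarks: C1 copy-number oscillation (two dominant states,
  ≥6 switches), C2 breakpoint clustering (seeded Monte-Carlo one-sided
  KS test on inter-breakpoint spacings vs uniform placement), C3 join
  orientation randomness (4-class goodness of fit, exact multinomial at
  small n), and C4 fragment-order randomness (rank correlation). A
  chromosome is called positive when ≥2 criteria are satisfied; exactly
  2 sets a machine-readable borderline flag. **Note the inverted logic
  of C3/C4:** shattering predicts *randomness*, so those criteria are
  satisfied when their tests do **not** reject (p ≥ α).
- **`rigstruct.eccdna`** — circular extrachromosomal DNA reconstruction:
  highly amplified segments (default ≥2.0 log2) become two-ended graph
  nodes, SV joins attach to segment boundaries within a tolerance
  (default 10 kb), and all simple traverse-through cycles are enumerated
  exhaustively, deduplicated under rotation/reversal, and ranked by
  amplified mass. An independent verifier re-walks each reported cycle
  against the raw join list.
- **`rigstruct.mutload`** — germline load (QUAL ≥ 50), somatic load
  (≥4 supporting reads, QUAL ignored), exome reporting filter (≥5 reads,
  ≥30 % VAF, curated-database pass-through), variants/Mb, 6-class
  purine-reference substitution spectra, and the two-group burden
  comparison (fold change + Student's t-test) with hypermutator
  exclusion.
- **`rigstruct.stats`** — medians/ranges with missing-value handling,
  Fisher exact tests (two-sided by the probability-≤-observed rule, and
  one-sided), odds ratios with Haldane–Anscombe-corrected CIs,
  Kaplan–Meier estimation with Greenwood log(−log) bands and a
  Brookmeyer–Crowley-style median CI, and the two-group log-rank test.
- **`rigstruct.synthetic`** — seeded generator that plants every signal
  the callers look for: shattered chromosomes (clustered breakpoints,
  two-state oscillation, shuffled random-orientation joins),
  progressive-rearrangement negative controls, circular amplicons, two
  tumor groups with a configurable (default 9×) somatic burden ratio and
  a shared germline rate, and a clinical table. One RNG stream per
  sample keeps outputs independent of generation order.
- **`rigstruct.experiments`** — planted-truth recovery and
  null-calibration experiments used by the validation suite.

File formats (`rigstruct.io`): IGV-dialect SEG (1-based inclusive on
disk, 0-based half-open in memory), 10-column BEDPE, VCF v4.2 (read via
cyvcf2; allele depth from a FORMAT AD field or INFO counts), clinical
TSV (en-dash/empty = missing), JSON ground truth and run manifests.
SEG and BEDPE round-trip bit-exactly.

## CLI

```bash
rigstruct simulate --seed 7 --n-group-a 3 --n-group-b 6 --outdir out/
rigstruct cnv --seg out/cohort.seg [--focal-mode arm25|3mb] [--preset methylation|wgs]
rigstruct chromothripsis --seg out/cohort.seg --sv out/S1.bedpe --alpha 0.05 --mc-seed 0
rigstruct eccdna --seg out/cohort.seg --sv out/S1.bedpe --amp-threshold 2.0 --tol 10000
rigstruct mutload --vcf-dir out/ --groups out/groups.tsv --coding-mb 34
rigstruct cohort --clinical out/clinical.tsv
rigstruct all --seed 7 --outdir out/     # full pipeline + manifest
```

`rigstruct all` is deterministic: re-running with the same seed yields
byte-identical outputs and manifest.

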