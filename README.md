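# cutrun

Analysis toolkit for studying how V(D)J recombination by-products destabilize
lymphocyte genomes. During deletional recombination the excised DNA circle
(the excised signal circle, ESC) retains both recombination signal sequences
(RSSs) ligated head-to-head; re-bound by the RAG recombinase, it can cleave
single genomic RSSs and cryptic RSSs, leaving orphan double-strand breaks
that feed chromosome translocations (for example in *ETV6*/*RUNX1*-positive
acute lymphoblastic leukemia). This package implements the downstream
computational analyses such studies need, end to end and with a
synthetic-data generator that plants recoverable ground truth for every
stage:

* **RSS motif detection** around translocation junctions: position weight
  matrix (PWM) heptamer scans with FIMO-style *exact* p-values (dynamic
  programming over the achievable-score distribution), and a composite
  12/23-RSS scorer — per-position log10 probabilities for the heptamer
  (consensus `CACAGTG`) and nonamer (`ACAAAAACC`) across allowed spacer
  lengths (12 ± 1 / 23 ± 1 bp), rescaled so the consensus scores 0 and floored
  at −1000, with pass thresholds −38.81 (12-RSS) and −58.45 (23-RSS).
* **Exclusion-region filtering** of junction catalogs (the EF1-alpha promoter
  capture artifact on chr6, and the 12-RSS vector-origin region on chr7,
  scoped to 12-RSS datasets only).
* **Co-localization statistics**: patient-breakpoint overlap counting within
  a 100-bp window against a Poisson null with λ = kM/N (k patient
  breakpoints, N genome size, M the merged union of junctions extended by
  the window on both sides), cross-checked by Monte-Carlo simulation;
  upper-tail hypergeometric gene-list overlap; one-tailed chi-square tests
  of association with Yates' continuity correction for dataset comparisons.
* **ESC repertoire enumeration**: all head-to-head 12×23 RSS pairs per
  locus, classified against the consensus criteria (each heptamer keeps
  `CAC` with at most one mismatch over `AGTG`; nonamer positions 5–6 are
  `AA` in both), usage-weighted per segment and aggregated per locus.

## Worked example

The shipped demo config simulates a 1-Mb genome with 20 planted consensus
RSSs, an RSS-proximal-enriched junction arm (`sj`, 30% within 100 bp of a
planted RSS) against a background control arm (5%), 60 patient breakpoints
with 12 planted co-localizations, and a 30-segment repertoire:

```sh
cutrun run-all --config examples/demo.toml
cat scratch/demo_run/summary.txt
```

```
cutrun run (seed 7)

dataset sj: 78/150 junctions with a passing RSS within the scan window
dataset control: 44/150 junctions with a passing RSS within the scan window
co-localization [sj]: k_obs=12, M=25668, lambda=1.54, p=9.03e-08
co-localization [control]: k_obs=0, M=29260, lambda=1.756, p=1
dataset comparison ['sj', 'control']: chi2=15.04, one-tailed p=5.25e-05
ESC usage-weighted consensus fraction: 0.772958 (125 pairs)
```

Reading the output: the enriched arm recovers all 12 planted
co-localizations (`k_obs=12` against an expectation of λ ≈ 1.5 under the
random-placement null, p ≈ 9×10⁻⁸), the control arm none; the 2×2
dataset-by-RSS-presence comparison rejects at p ≈ 5×10⁻⁵; and the
usage-weighted consensus fraction equals the generator's exhaustively
enumerated ground truth for this repertoire (0.772958). The JSON report in
`scratch/demo_run/report.json` carries the same numbers machine-readably,
and `manifest.json` records the config hash and seed; reruns are
byte-identical.

Individual stages are also available as `cutrun
simulate|filter|scan|colocalize|esc-fraction|chrom-dist|compare`, and the
same operations can be called directly from Python (`cutrun.motifs`,
`cutrun.stats`, `cutrun.esc`, `cutrun.junctions`, `cutrun.synthetic`).

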