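# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the package. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## RSS scoring model

A recombination signal sequence (RSS) is modeled as heptamer(7 bp) +
spacer(12 or 23 bp, non-conserved) + nonamer(9 bp). The composite scorer
(`cutrun.motifs.RssModel`) assumes per-position independence: for a
candidate window and spacer length L,

    score = Σ_i log10 p_hept(b_i, i) + Σ_j log10 p_non(b_j, j) − score(consensus)

so the model's consensus sequence scores exactly 0, every other sequence is
negative, and the total is floored at `score_floor = −1000`. Among the
allowed spacer lengths (defaults 12 ± 1 and 23 ± 1) the best-scoring one is
reported; ties prefer the shortest. A site passes when its score is
*strictly* greater than the threshold for its type, −38.81 (12-RSS) or
−58.45 (23-RSS) by default. `N` bases contribute a zero log-ratio.

The published scoring scheme that motivated these thresholds uses
position-correlation statistics whose parameters are not public, so the
matrices behind the default model are the package's own synthetic profile:
every non-modal base has probability 1e-10, i.e. each mismatch at the 16
informative positions costs ≈ 10 log10 units. Under that scale the default
thresholds become small mismatch budgets — a 12-RSS passes with ≤ 3
mismatches, a 23-RSS with ≤ 5 — which keeps exact consensus sites at score
0 (always passing) while random background passes rarely (the binomial
mismatch count of a random 16-mer, mean 12, reaches ≤ 5 with probability
≈ 3×10⁻⁴ per window/strand/spacer). Real conservation matrices can be
supplied as TOML (`RssModel.from_toml`) or TSV tables and the thresholds
recalibrated against an empirical score distribution.

Strand handling: minus-strand candidates are scored on the
reverse-complemented window. Scoring a fixed window is exactly
strand-consistent; when the spacer set is flexible, best-spacer selection
anchors at the left edge of the scanned orientation, so the per-window
property is the invariant, not best-over-spacers at mirrored offsets.

### Windowed junction scans

`find_rss_near_junctions` extracts the junction's ±window slice (default
100 bp; 1000 bp for patient-overlap context scans) extended by one full site
length each side, scans every offset, both strands, both RSS types, and
keeps hits whose nearest base lies within the window of the junction point
(inclusive distance rule). Slices overhanging chromosome ends are clipped,
never padded.

## PWM scans with exact p-values

`build_pwm` uses the count-to-probability rule p(b,i) = (count(b,i) +
pc·bg(b)) / (total(i) + pc) — the pseudocount (default 1) allocated
proportionally to the background (default 30% A/T, 20% C/G) — and log2
log-odds. `pwm_exact_pvalue` computes P(score ≥ s) for a random background
window by dynamic programming over the achievable-score distribution. For
widths ≤ 12 the distribution is exact: scores are accumulated position by
position in the same order the scorer adds them, so DP support values agree
bit-for-bit with directly computed window scores. Wider models drop to a
discretized lattice (default bin 1e-3 bits). Scanning reports every window
with p ≤ 0.001 (both strands; minus-strand p-values use the same null,
which is exact for complement-symmetric backgrounds such as the default).
Because the score distribution is discrete, the attained size at the
p ≤ 0.001 cut is generally below 0.001; null-calibration checks use the
attained size.

## Co-localization statistics

An overlap is a patient breakpoint within ≤ 100 bp (inclusive) of a
junction; each breakpoint counts at most once. The null models patient
breakpoints as uniform points over the genome, so the overlap count is
approximately Poisson with λ = kM/N, where M is the *merged union* of
junction ± window extensions (union semantics avoid inflating λ when
extensions overlap), clipped to chromosome bounds, and N defaults to the
sum of the supplied chromosome sizes. `mc_overlap_null` provides the exact
finite-k null by simulation (add-one smoothed tail, (successes+1)/(n+1));
the Poisson form is its sparse-coverage (M/N ≪ 1) approximation, the regime
of real genome-scale data, and the acceptance check compares the two at
M/N ≤ 2.5×10⁻³.

Gene-list overlap uses the upper-tail hypergeometric distribution with a
configurable universe (default 20,000 protein-coding genes; the choice only
shifts absolute p-values, not orderings). Dataset comparisons use the
chi-square test of association on the 2×2 dataset × RSS-present table with
Yates' continuity correction, flooring each cell's correction at zero
(max(|O−E|−0.5, 0)) so near-null tables cannot acquire a negative
correction. "One-tailed" means: half the two-tailed chi-square(1) tail when
the observed direction matches the stated alternative, else 1 − p_two/2;
a zero statistic yields 0.5 regardless of direction.

## ESC repertoire criteria

Candidate ESCs are all head-to-head 12×23 RSS pairs within a locus
(Cartesian product; a pairing-rules table can restrict to, e.g., V–J).
The "single mismatch" allowance is read per heptamer — each heptamer must
keep `CAC` and deviate from `AGTG` at no more than one position — not as
one mismatch shared across the pair; nonamer positions 5–6 must be `AA` in
both. Non-ACGT characters fail classification rather than raising. Pair
weight is the product of the two segments' usage frequencies (independence
assumption), renormalized within each (locus, segment_type) class; the
overall fraction is the equal-weight mean of per-locus fractions unless
locus weights are supplied. D segments carrying two RSSs are represented as
two rows.

## Synthetic data generator

The generator emulates the pipeline's inputs with planted structure. Its
defaults are the study conditions used throughout: a 10-Mb two-chromosome
genome at GC 0.41 (a typical human breakpoint-neighborhood composition; the
value is this package's choice), 25+25 planted consensus RSSs, 500
junctions with 30% placed within 100 bp of a planted RSS, and 140 patient
breakpoints of which 28 are placed within 100 bp of distinct junctions
while the remainder explicitly avoid all junction neighborhoods — so the
planted overlap count is recovered exactly, not approximately. Repertoire
simulation draws each segment "good" with probability sqrt(target) and
stores the exact usage-weighted fraction by exhaustive enumeration (an
independent re-statement of the criteria, usable as an oracle).

One seeded `numpy` generator drives a run; operations draw in the
documented order (see `cutrun.synthetic`), and counts derived from
fractions use round-half-to-even. Identical configs therefore produce
byte-identical FASTA/BED/TSV outputs.

What the generator does *not* emulate: sequencing reads and PCR artifacts,
junction-caller behavior, chromatin accessibility or RAG expression
dynamics, realistic chromosome counts, inter-position correlations in real
RSSs, or the real patient-breakpoint catalog. Passing planted-truth tests
therefore demonstrates correctness of the analysis logic under the stated
model, not performance on real libraries.

## Pipeline orchestration

A TOML config drives `run-all`; all stage randomness derives from the one
config seed via per-stage child seeds (`SeedSequence([seed, crc32(stage)])`).
Reports contain no timestamps, so reruns are byte-identical; the manifest
records the config hash, seed, versions and per-stage record counts.
Patient breakpoints are planted against the first configured dataset and
avoid all datasets' junctions.

## Problem sizes

The default test and acceptance runs use a 10-Mb genome, 2×500 junctions,
140 breakpoints, 10⁵ Monte-Carlo iterations with ~2000 random points per
iteration, and full 4^w enumerations up to w = 8 — sizes chosen so the
whole suite completes in well under a minute per component while keeping
every statistical check at ≥ 3-standard-error resolution.

## Known limitations

* The independence RSS scorer is not the published correlated-position
  model; the printed thresholds are kept as decision rules, but absolute
  scores are not comparable to the published tool's output.
* The Poisson null ignores chromosome-boundary effects beyond clipping and
  assumes breakpoints are independent and uniform; real breakpoint
  catalogs cluster.
* Repertoire enumeration does not model nucleotide-level signal-joint
  reconstruction or recombination frequencies beyond segment usage.
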