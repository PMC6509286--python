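# Demo run: a 1-Mb two-chromosome toy genome with planted RSSs, two junction
# datasets (RSS-proximal enrichment vs background control), patient
# breakpoints with planted co-localizations, and a synthetic repertoire.
seed = 7
outdir = "scratch/demo_run"

[simulate]
gc_content = 0.41
n_rss12 = 10
n_rss23 = 10
rss_mutation_rate = 0.0
proximity_window = 100
n_patient_bps = 60
n_planted_overlaps = 12
overlap_window = 100

[simulate.chrom_sizes]
chr1 = 500000
chr2 = 500000

[[simulate.datasets]]
name = "sj"
n_junctions = 150
rss_proximal_fraction = 0.3

[[simulate.datasets]]
name = "control"
n_junctions = 150
rss_proximal_fraction = 0.05

[simulate.repertoire]
n_v = 25
n_j = 5
consensus_pair_fraction = 0.72
usage_model = "dirichlet"

[scan]
window = 100

[colocalize]
window = 100
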