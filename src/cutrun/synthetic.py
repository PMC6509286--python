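"""Synthetic genomes, planted RSS sites, junctions, patient breakpoints and
repertoires with recoverable ground truth.

Every quantity the downstream analyses estimate is planted here with a known
value: RSS motifs at recorded coordinates, a controlled fraction of
translocation junctions near those motifs, a fixed number of patient
breakpoints co-localizing with junctions, and a repertoire whose
usage-weighted consensus-pair fraction is computed exactly by enumeration at
generation time.

Reproducibility contract: one seeded generator per run, and the operations
draw from it in a documented order.  Within each operation the draw order is
part of the API (reordering draws is a breaking change):

* :func:`make_genome` — one multinomial base draw per chromosome, in
  ``chrom_sizes`` insertion order;
* :func:`plant_rss_sites` — per site (12-type sites first, then 23-type):
  repeated (chromosome, start) proposals until non-overlapping, then strand,
  spacer bases, mutation mask over the 16 conserved positions, substitution
  offsets for mutated positions;
* :func:`simulate_junctions` — proximal junctions first (planted-site index,
  position, strand per junction), then background junctions (global position,
  strand), then one shuffling permutation;
* :func:`simulate_patient_breakpoints` — junction subset choice, one position
  per planted overlap, rejection-sampled background positions, one shuffling
  permutation.

Counts derived from fractions use Python's ``round`` (round-half-to-even).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pyfaidx

from .core import (
    COMPLEMENT_CODES,
    Breakpoint,
    GenomicInterval,
    Junction,
    decode,
    encode,
    merge_intervals,
)
from .esc import CONSENSUS_HEPTAMER, CONSENSUS_NONAMER, SegmentRss

_GOOD_HEPTAMERS = [CONSENSUS_HEPTAMER] + [
    CONSENSUS_HEPTAMER[:3] + "AGTG"[:i] + b + "AGTG"[i + 1 :]
    for i in range(4)
    for b in "ACGT"
    if b != "AGTG"[i]
]  # consensus + the 12 single-mismatch CAC-retaining variants


class ParameterError(ValueError):
    """A simulation parameter violates its contract."""


class PlacementError(RuntimeError):
    """The genome is too small/crowded to satisfy a placement request."""


@dataclass
class SimConfig:
    """Study conditions for a synthetic run.

    Defaults mirror the shape of the real study: a 10-Mb genome, 50 planted
    consensus RSSs, 500 junctions with 30% placed within 100 bp of a planted
    RSS, and 140 patient breakpoints of which 28 co-localize (<=100 bp) with
    junctions.  ``gc_content`` defaults to 0.41, a typical human breakpoint
    neighborhood composition.
    """

    seed: int = 0
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    gc_content: float = 0.41
    n_rss12: int = 25
    n_rss23: int = 25
    rss_mutation_rate: float = 0.0
    n_junctions: int = 500
    rss_proximal_fraction: float = 0.3
    proximity_window: int = 100
    n_patient_bps: int = 140
    n_planted_overlaps: int = 28
    overlap_window: int = 100

    def validate(self) -> None:
        if not self.chrom_sizes:
            raise ParameterError("chrom_sizes must be non-empty")
        for name, size in self.chrom_sizes.items():
            if size < 1000:
                raise ParameterError(f"chromosome {name} must be >= 1000 bp")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ParameterError(f"gc_content must be in [0, 1], got {self.gc_content}")
        for fname in ("rss_mutation_rate", "rss_proximal_fraction"):
            v = getattr(self, fname)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{fname} must be in [0, 1], got {v}")
        for fname in (
            "n_rss12", "n_rss23", "n_junctions", "proximity_window",
            "n_patient_bps", "n_planted_overlaps", "overlap_window",
        ):
            if getattr(self, fname) < 0:
                raise ParameterError(f"{fname} must be >= 0")
        if self.n_planted_overlaps > min(self.n_patient_bps, self.n_junctions):
            raise ParameterError(
                "n_planted_overlaps must be <= min(n_patient_bps, n_junctions)"
            )

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True)
class PlantedRss:
    interval: GenomicInterval
    rss_type: int
    strand: str
    sequence: str  # final heptamer+spacer+nonamer in RSS orientation


@dataclass
class SimTruth:
    planted_rss: list[PlantedRss] = field(default_factory=list)
    junction_labels: dict = field(default_factory=dict)  # dataset -> bool array
    overlap_labels: Optional[np.ndarray] = None
    repertoire_expected_fraction: Optional[float] = None


def default_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def make_genome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, np.ndarray]:
    """Random genome as uint8 code arrays with expected G+C = ``gc_content``."""
    config.validate()
    rng = rng if rng is not None else default_rng(config.seed)
    probs = _base_probs(config.gc_content)
    return {
        name: rng.choice(4, size=size, p=probs).astype(np.uint8)
        for name, size in config.chrom_sizes.items()
    }


def _global_to_local(
    g: int, names: list[str], cum: np.ndarray
) -> tuple[str, int]:
    ci = int(np.searchsorted(cum, g, side="right"))
    prev = int(cum[ci - 1]) if ci > 0 else 0
    return names[ci], g - prev


def _chrom_index(chrom_sizes: dict) -> tuple[list[str], np.ndarray]:
    names = list(chrom_sizes)
    cum = np.cumsum([chrom_sizes[n] for n in names])
    return names, cum


def plant_rss_sites(
    genome: dict[str, np.ndarray],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 1000,
) -> list[PlantedRss]:
    """Write non-overlapping consensus-derived RSS motifs into the genome.

    Each site is heptamer(7) + spacer(12 or 23, background-composition
    sequence) + nonamer(9), on a uniformly chosen strand; substitutions at
    ``rss_mutation_rate`` hit heptamer/nonamer bases only.  The truth record
    keeps the final motif sequence in RSS orientation.
    """
    config.validate()
    rng = rng if rng is not None else default_rng(config.seed)
    sizes = {name: len(arr) for name, arr in genome.items()}
    names, cum = _chrom_index(sizes)
    total = int(cum[-1])
    probs = _base_probs(config.gc_content)
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    planted: list[PlantedRss] = []
    hept = encode(CONSENSUS_HEPTAMER)
    nona = encode(CONSENSUS_NONAMER)
    for rss_type in (12, 23):
        n_sites = config.n_rss12 if rss_type == 12 else config.n_rss23
        site_len = 16 + rss_type
        for _ in range(n_sites):
            for attempt in range(max_attempts):
                g = int(rng.integers(0, total))
                chrom, start = _global_to_local(g, names, cum)
                if start + site_len > sizes[chrom]:
                    continue
                end = start + site_len
                if any(s < end and start < e for s, e in placed[chrom]):
                    continue
                break
            else:
                raise PlacementError(
                    f"could not place a {rss_type}-RSS without overlap after "
                    f"{max_attempts} attempts"
                )
            strand = "+" if rng.integers(2) == 0 else "-"
            spacer = rng.choice(4, size=rss_type, p=probs).astype(np.uint8)
            site = np.concatenate([hept, spacer, nona])
            conserved_idx = np.concatenate(
                [np.arange(7), np.arange(7 + rss_type, site_len)]
            )
            mask = rng.random(16) < config.rss_mutation_rate
            n_mut = int(mask.sum())
            if n_mut:
                shifts = rng.integers(1, 4, size=n_mut).astype(np.uint8)
                pos = conserved_idx[mask]
                site[pos] = (site[pos] + shifts) % 4
            written = site if strand == "+" else COMPLEMENT_CODES[site[::-1]]
            genome[chrom][start:end] = written
            placed[chrom].append((start, end))
            planted.append(
                PlantedRss(
                    interval=GenomicInterval(chrom, start, end, strand),
                    rss_type=rss_type,
                    strand=strand,
                    sequence=decode(site),
                )
            )
    return planted


def simulate_junctions(
    truth: Sequence[PlantedRss],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    dataset: str = "sim",
    n_junctions: Optional[int] = None,
    rss_proximal_fraction: Optional[float] = None,
) -> tuple[list[Junction], np.ndarray]:
    """Junction list with exactly round(n * fraction) RSS-proximal members.

    A proximal junction lies within ``proximity_window`` bp (inclusive,
    nearest-base distance) of a uniformly chosen planted RSS; the rest fall
    uniformly over the genome.  Returns (junctions, proximal-labels), both
    shuffled by one permutation.
    """
    config.validate()
    rng = rng if rng is not None else default_rng(config.seed)
    n = config.n_junctions if n_junctions is None else n_junctions
    frac = (
        config.rss_proximal_fraction
        if rss_proximal_fraction is None
        else rss_proximal_fraction
    )
    if not (0.0 <= frac <= 1.0):
        raise ParameterError(f"rss_proximal_fraction must be in [0, 1], got {frac}")
    n_prox = round(n * frac)
    if n_prox and not truth:
        raise ParameterError("cannot place proximal junctions without planted RSSs")
    names, cum = _chrom_index(config.chrom_sizes)
    total = int(cum[-1])
    w = config.proximity_window
    junctions: list[Junction] = []
    for _ in range(n_prox):
        site = truth[int(rng.integers(len(truth)))]
        size = config.chrom_sizes[site.interval.chrom]
        lo = max(0, site.interval.start - w)
        hi = min(size - 1, site.interval.end - 1 + w)
        pos = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.integers(2) == 0 else "-"
        junctions.append(Junction(site.interval.chrom, pos, strand, dataset))
    for _ in range(n - n_prox):
        g = int(rng.integers(0, total))
        chrom, pos = _global_to_local(g, names, cum)
        strand = "+" if rng.integers(2) == 0 else "-"
        junctions.append(Junction(chrom, pos, strand, dataset))
    labels = np.zeros(n, dtype=bool)
    labels[:n_prox] = True
    perm = rng.permutation(n)
    junctions = [junctions[i] for i in perm]
    return junctions, labels[perm]


def simulate_patient_breakpoints(
    junctions: Sequence[Junction],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    avoid_junctions: Optional[Sequence[Junction]] = None,
    max_attempts_per_bp: int = 1000,
) -> tuple[list[Breakpoint], np.ndarray]:
    """Patient breakpoints with exactly ``n_planted_overlaps`` co-localizers.

    Planted overlaps sit within ``overlap_window`` bp of distinct junctions;
    the remainder are uniform over the genome but rejected out of every
    (junction ± window) neighborhood (``avoid_junctions`` defaults to the
    planting set; pass the union of all datasets to rule out chance overlaps
    genome-wide).  Returns (breakpoints, planted-labels), shuffled together.
    """
    config.validate()
    rng = rng if rng is not None else default_rng(config.seed)
    if config.n_planted_overlaps > len(junctions):
        raise ParameterError("n_planted_overlaps exceeds the junction count")
    avoid = list(avoid_junctions) if avoid_junctions is not None else list(junctions)
    names, cum = _chrom_index(config.chrom_sizes)
    total = int(cum[-1])
    w = config.overlap_window
    bounds: dict[str, np.ndarray] = {}
    for name in names:
        size = config.chrom_sizes[name]
        ivs = [
            (max(0, j.pos - w), min(size, j.pos + w + 1))
            for j in avoid
            if j.chrom == name
        ]
        bounds[name] = np.array(merge_intervals(ivs), dtype=np.int64).reshape(-1)
    chosen = rng.choice(len(junctions), size=config.n_planted_overlaps, replace=False)
    bps: list[Breakpoint] = []
    for idx in chosen:
        j = junctions[int(idx)]
        size = config.chrom_sizes[j.chrom]
        lo = max(0, j.pos - w)
        hi = min(size - 1, j.pos + w)
        bps.append(Breakpoint(j.chrom, int(rng.integers(lo, hi + 1)), "planted"))
    n_rest = config.n_patient_bps - config.n_planted_overlaps
    for _ in range(n_rest):
        for attempt in range(max_attempts_per_bp):
            g = int(rng.integers(0, total))
            chrom, pos = _global_to_local(g, names, cum)
            inside = int(np.searchsorted(bounds[chrom], pos, side="right")) % 2 == 1
            if not inside:
                bps.append(Breakpoint(chrom, pos, "background"))
                break
        else:
            raise PlacementError(
                "could not place a background breakpoint outside junction "
                f"neighborhoods after {max_attempts_per_bp} attempts"
            )
    labels = np.zeros(config.n_patient_bps, dtype=bool)
    labels[: config.n_planted_overlaps] = True
    perm = rng.permutation(config.n_patient_bps)
    bps = [bps[i] for i in perm]
    return bps, labels[perm]


def simulate_repertoire(
    n_v: int,
    n_j: int,
    consensus_pair_fraction: float,
    usage_model: str = "uniform",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    locus: str = "SYNLOC",
) -> tuple[list[SegmentRss], float]:
    """Repertoire with an analytically known usage-weighted consensus fraction.

    V segments carry 23-RSSs and J segments 12-RSSs.  Each segment is drawn
    "good" (criteria-passing heptamer and nonamer) with probability
    sqrt(target), so pair passes land near the target fraction; the exact
    usage-weighted fraction of the generated repertoire is then computed by
    exhaustive enumeration and returned as ground truth.  ``usage_model`` is
    ``uniform`` or ``dirichlet`` (flat Dirichlet weights).
    """
    if n_v < 1 or n_j < 1:
        raise ParameterError("n_v and n_j must be >= 1")
    if not (0.0 <= consensus_pair_fraction <= 1.0):
        raise ParameterError("consensus_pair_fraction must be in [0, 1]")
    if usage_model not in ("uniform", "dirichlet"):
        raise ParameterError(f"unknown usage_model {usage_model!r}")
    rng = rng if rng is not None else default_rng(0 if seed is None else seed)
    q = math.sqrt(consensus_pair_fraction)

    def random_seq(k: int) -> str:
        return decode(rng.integers(0, 4, size=k).astype(np.uint8))

    def draw_segment(name: str, seg_type: str, rss_type: int) -> SegmentRss:
        good = rng.random() < q
        if good:
            heptamer = _GOOD_HEPTAMERS[int(rng.integers(len(_GOOD_HEPTAMERS)))]
            n = list(random_seq(9))
            n[4] = "A"
            n[5] = "A"
            nonamer = "".join(n)
        else:
            # breaking the invariant CAC guarantees the pair fails
            heptamer = "AGT"[int(rng.integers(3))] + random_seq(6)
            nonamer = random_seq(9)
        return SegmentRss(
            locus=locus,
            segment=name,
            segment_type=seg_type,
            rss_type=rss_type,
            heptamer=heptamer,
            spacer=random_seq(rss_type),
            nonamer=nonamer,
            usage_freq=1.0,
        )

    segments = [draw_segment(f"V{i+1}", "V", 23) for i in range(n_v)]
    segments += [draw_segment(f"J{i+1}", "J", 12) for i in range(n_j)]
    if usage_model == "uniform":
        usage_v = np.full(n_v, 1.0 / n_v)
        usage_j = np.full(n_j, 1.0 / n_j)
    else:
        usage_v = rng.dirichlet(np.ones(n_v))
        usage_j = rng.dirichlet(np.ones(n_j))
    usage = np.concatenate([usage_v, usage_j])
    segments = [
        SegmentRss(
            locus=s.locus,
            segment=s.segment,
            segment_type=s.segment_type,
            rss_type=s.rss_type,
            heptamer=s.heptamer,
            spacer=s.spacer,
            nonamer=s.nonamer,
            usage_freq=float(u),
        )
        for s, u in zip(segments, usage)
    ]
    expected = _brute_force_fraction(segments)
    return segments, expected


def _brute_force_fraction(segments: Sequence[SegmentRss]) -> float:
    """Independent exhaustive enumeration of the usage-weighted pass fraction.

    Deliberately re-states the criteria with plain string operations so the
    value can serve as an oracle for the analysis-side computation.
    """

    def hept_ok(h: str) -> bool:
        return h[:3] == "CAC" and sum(a != b for a, b in zip(h[3:], "AGTG")) <= 1

    def nona_ok(n: str) -> bool:
        return n[4] == "A" and n[5] == "A"

    twelves = [s for s in segments if s.rss_type == 12]
    twothrees = [s for s in segments if s.rss_type == 23]
    num = 0.0
    den = 0.0
    for a in twelves:
        for b in twothrees:
            wgt = a.usage_freq * b.usage_freq
            den += wgt
            if (
                hept_ok(a.heptamer)
                and hept_ok(b.heptamer)
                and nona_ok(a.nonamer)
                and nona_ok(b.nonamer)
            ):
                num += wgt
    return num / den if den > 0 else float("nan")


# --------------------------------------------------------------------------
# file output
# --------------------------------------------------------------------------


def write_genome_fasta(genome: dict[str, np.ndarray], path, width: int = 60) -> None:
    """Write the genome as FASTA and build a pyfaidx sidecar index."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, codes in genome.items():
            fh.write(f">{name}\n")
            seq = decode(codes)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    pyfaidx.Faidx(str(path))


def load_genome_fasta(path) -> dict[str, np.ndarray]:
    fa = pyfaidx.Fasta(str(path))
    return {name: encode(str(fa[name][:])) for name in fa.keys()}


def write_truth_bed(planted: Sequence[PlantedRss], path) -> None:
    with open(path, "w") as fh:
        for p in planted:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"RSS{p.rss_type}\t0\t{p.strand}\n"
            )


def write_junctions_tsv(junctions: Sequence[Junction], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tdataset\n")
        for j in junctions:
            fh.write(f"{j.chrom}\t{j.pos}\t{j.strand}\t{j.dataset}\n")


def write_breakpoints_bed(
    bps: Sequence[Breakpoint], path, labels: Optional[np.ndarray] = None
) -> None:
    with open(path, "w") as fh:
        for i, bp in enumerate(bps):
            name = bp.label if labels is None else (
                "planted" if labels[i] else "background"
            )
            fh.write(f"{bp.chrom}\t{bp.pos}\t{bp.pos + 1}\t{name}\t0\t+\n")


def write_repertoire_tsv(segments: Sequence[SegmentRss], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "locus\tsegment\tsegment_type\trss_type\theptamer\tspacer\t"
            "nonamer\tusage_freq\n"
        )
        for s in segments:
            fh.write(
                f"{s.locus}\t{s.segment}\t{s.segment_type}\t{s.rss_type}\t"
                f"{s.heptamer}\t{s.spacer}\t{s.nonamer}\t{s.usage_freq!r}\n"
            )


@dataclass
class SimResult:
    config: SimConfig
    genome: dict
    truth: SimTruth
    junctions: dict  # dataset name -> list[Junction]
    patient_bps: list
    repertoire: Optional[list] = None


def simulate_all(
    config: SimConfig,
    datasets: Optional[Sequence[tuple[str, int, float]]] = None,
    repertoire: Optional[dict] = None,
) -> SimResult:
    """Run the full generator pipeline with one seeded generator.

    ``datasets`` is a sequence of (name, n_junctions, rss_proximal_fraction);
    the default is a single dataset using the config's values.  Patient
    breakpoints are planted against the first dataset's junctions and avoid
    the union of all datasets' junction neighborhoods, so chance overlaps are
    excluded by construction.
    """
    config.validate()
    rng = default_rng(config.seed)
    genome = make_genome(config, rng)
    planted = plant_rss_sites(genome, config, rng)
    truth = SimTruth(planted_rss=planted)
    if datasets is None:
        datasets = [("sim", config.n_junctions, config.rss_proximal_fraction)]
    junctions: dict[str, list[Junction]] = {}
    for name, n, frac in datasets:
        juncs, labels = simulate_junctions(
            planted, config, rng, dataset=name, n_junctions=n,
            rss_proximal_fraction=frac,
        )
        junctions[name] = juncs
        truth.junction_labels[name] = labels
    first = datasets[0][0]
    all_junctions = [j for name in junctions for j in junctions[name]]
    bps, overlap_labels = simulate_patient_breakpoints(
        junctions[first], config, rng, avoid_junctions=all_junctions
    )
    truth.overlap_labels = overlap_labels
    result = SimResult(
        config=config, genome=genome, truth=truth,
        junctions=junctions, patient_bps=bps,
    )
    if repertoire is not None:
        segs, expected = simulate_repertoire(rng=rng, **repertoire)
        truth.repertoire_expected_fraction = expected
        result.repertoire = segs
    return result
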