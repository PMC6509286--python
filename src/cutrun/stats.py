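"""Co-localization and association statistics for translocation junctions.

The centerpiece is the Poisson interval-overlap null: patient breakpoints
are modeled as uniform random points over the genome, so the number landing
within ``window`` bp of any junction is approximately Poisson with
λ = k·M/N, where k is the number of patient breakpoints, N the genome size
and M the number of bases covered by the junctions after extending each by
the window on both sides and merging (union semantics — double-counting
overlapping extensions would inflate λ).  A Monte-Carlo routine provides an
independent empirical null for the same hypothesis.

Also here: the upper-tail hypergeometric gene-list overlap test and the
one-tailed chi-square test of association with Yates' continuity correction
used to compare junction datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    Breakpoint,
    GenomicInterval,
    InputError,
    Junction,
    merge_intervals,
)


@dataclass(frozen=True)
class OverlapTest:
    """Poisson co-localization test result (λ = k·M/N)."""

    k_obs: int
    k_patient: int
    M: int
    N: int
    lam: float
    p_value: float


@dataclass(frozen=True)
class GeneOverlap:
    """Hypergeometric gene-list overlap result."""

    n_listA: int
    m_listB: int
    k_overlap: int
    universe: int
    p_value: float


def junction_coverage(
    junctions: Sequence[Junction],
    window: int = 100,
    chrom_sizes: Optional[dict] = None,
) -> dict[str, list[tuple[int, int]]]:
    """Merged union of [pos-window, pos+window+1) intervals per chromosome.

    Intervals are clipped to [0, chromosome length) when sizes are given.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for j in junctions:
        lo = max(0, j.pos - window)
        hi = j.pos + window + 1
        if chrom_sizes is not None:
            size = chrom_sizes.get(j.chrom)
            if size is None:
                raise InputError(f"no chromosome size for {j.chrom}")
            hi = min(hi, size)
            if lo >= hi:
                continue
        per_chrom.setdefault(j.chrom, []).append((lo, hi))
    return {c: merge_intervals(ivs) for c, ivs in per_chrom.items()}


def coverage_size(coverage: dict[str, list[tuple[int, int]]]) -> int:
    return int(sum(e - s for ivs in coverage.values() for s, e in ivs))


@dataclass(frozen=True)
class CountOverlapsResult:
    k_obs: int
    matched: tuple
    M: int
    coverage: dict


def count_overlaps(
    junctions: Sequence[Junction],
    patient_bps: Sequence[Breakpoint],
    window: int = 100,
    chrom_sizes: Optional[dict] = None,
) -> CountOverlapsResult:
    """Count patient breakpoints within ``window`` bp (inclusive) of a junction.

    Each patient breakpoint counts at most once regardless of how many
    junctions it is near.  M is the merged extended-junction coverage.
    Chromosomes present in one input but not the other produce a warning with
    a per-chromosome report, not an error.
    """
    if not junctions or not patient_bps:
        raise InputError("count_overlaps requires non-empty junction and breakpoint lists")
    if window < 0:
        raise InputError("window must be >= 0")
    coverage = junction_coverage(junctions, window, chrom_sizes)
    j_chroms = set(coverage)
    p_chroms = {bp.chrom for bp in patient_bps}
    if p_chroms - j_chroms or j_chroms - p_chroms:
        report = {
            "junctions_only": sorted(j_chroms - p_chroms),
            "breakpoints_only": sorted(p_chroms - j_chroms),
        }
        warnings.warn(f"chromosome sets differ between inputs: {report}", stacklevel=2)
    bounds = {
        c: np.array(ivs, dtype=np.int64).reshape(-1) for c, ivs in coverage.items()
    }
    matched = []
    for bp in patient_bps:
        b = bounds.get(bp.chrom)
        if b is None:
            continue
        if int(np.searchsorted(b, bp.pos, side="right")) % 2 == 1:
            matched.append(bp)
    return CountOverlapsResult(
        k_obs=len(matched),
        matched=tuple(matched),
        M=coverage_size(coverage),
        coverage=coverage,
    )


def poisson_overlap_test(k_obs: int, k_patient: int, M: int, N: int) -> OverlapTest:
    """Upper-tail Poisson test with λ = k_patient·M/N."""
    if N <= 0:
        raise InputError("N must be > 0")
    if not (0 <= M <= N):
        raise InputError(f"M must be in [0, N], got M={M}, N={N}")
    if k_obs < 0 or k_patient < 0:
        raise InputError("counts must be >= 0")
    lam = k_patient * M / N
    p = float(sps.poisson.sf(k_obs - 1, lam)) if k_obs > 0 else 1.0
    return OverlapTest(
        k_obs=k_obs, k_patient=k_patient, M=M, N=N, lam=lam, p_value=p
    )


def mc_overlap_null(
    coverage: dict[str, list[tuple[int, int]]],
    chrom_sizes: dict,
    k_patient: int,
    k_obs: int,
    n_iter: int = 100_000,
    seed: int = 0,
    chunk: int = 5000,
) -> float:
    """Empirical tail probability of >= ``k_obs`` overlaps under uniform breaks.

    Each iteration drops ``k_patient`` uniform points on the genome and counts
    those landing in the extended-junction coverage; returns the add-one
    smoothed fraction (successes+1)/(n_iter+1) of iterations reaching k_obs.
    """
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    names = list(chrom_sizes)
    offsets = np.concatenate([[0], np.cumsum([chrom_sizes[n] for n in names])])
    total = int(offsets[-1])
    bounds_list = []
    for i, name in enumerate(names):
        for s, e in coverage.get(name, []):
            bounds_list.extend((offsets[i] + s, offsets[i] + e))
    bounds = np.array(bounds_list, dtype=np.int64)
    rng = np.random.default_rng(seed)
    successes = 0
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        pts = rng.integers(0, total, size=(m, k_patient))
        if len(bounds):
            inside = np.searchsorted(bounds, pts, side="right") % 2 == 1
            counts = inside.sum(axis=1)
        else:
            counts = np.zeros(m, dtype=int)
        successes += int((counts >= k_obs).sum())
        done += m
    return (successes + 1) / (n_iter + 1)


def hypergeom_overlap_test(
    n_listA: int, m_listB: int, k_overlap: int, universe: int = 20_000
) -> GeneOverlap:
    """Upper-tail hypergeometric P(K >= k) for the overlap of two gene lists.

    ``n_listA`` genes are marked in a universe of ``universe`` genes;
    ``m_listB`` genes are drawn without replacement.
    """
    if not (0 <= k_overlap <= min(n_listA, m_listB)):
        raise InputError("k_overlap must be <= min(list sizes) and >= 0")
    if universe < n_listA + m_listB - k_overlap:
        raise InputError("universe smaller than the union of the lists")
    p = float(sps.hypergeom.sf(k_overlap - 1, universe, n_listA, m_listB))
    return GeneOverlap(
        n_listA=n_listA,
        m_listB=m_listB,
        k_overlap=k_overlap,
        universe=universe,
        p_value=p,
    )


def chi2_yates(
    table, alternative: str = "greater", tails: str = "one"
) -> tuple[float, float]:
    """Chi-square test of association on a 2x2 table with Yates' correction.

    The statistic floors each cell's correction at zero:
    sum(max(|O-E|-0.5, 0)^2 / E).  ``tails="two"`` returns the usual
    chi-square(1) upper tail.  The one-tailed p halves the two-tailed p when
    the observed direction matches ``alternative`` ("greater": row 0 has the
    larger column-0 proportion; "less": the smaller), else 1 - p_two/2.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise InputError("table must be 2x2 with non-negative counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise InputError("chi-square undefined: a row or column total is zero")
    expected = np.outer(rows, cols) / t.sum()
    stat = float(np.sum(np.maximum(np.abs(t - expected) - 0.5, 0.0) ** 2 / expected))
    p_two = float(sps.chi2.sf(stat, df=1))
    if tails == "two":
        return stat, p_two
    if tails != "one":
        raise InputError(f"tails must be 'one' or 'two', got {tails!r}")
    if alternative not in ("greater", "less"):
        raise InputError("alternative must be 'greater' or 'less'")
    diff = t[0, 0] / rows[0] - t[1, 0] / rows[1]
    matches = diff > 0 if alternative == "greater" else diff < 0
    p_one = p_two / 2 if matches or diff == 0 else 1 - p_two / 2
    return stat, p_one


def load_gene_bed(path) -> list[tuple[str, GenomicInterval]]:
    """BED with gene symbols in column 4 -> [(name, interval), ...]."""
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                genes.append(
                    (
                        fields[3] if len(fields) > 3 else f"gene{line_no}",
                        GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    )
                )
            except (IndexError, ValueError, InputError) as exc:
                raise InputError(f"{path}, line {line_no}: {exc}") from exc
    return genes


def gene_hit_table(
    junctions: Sequence[Junction],
    genes: Sequence[tuple[str, GenomicInterval]],
    gene_list: Optional[Sequence[str]] = None,
) -> tuple[pd.Series, set]:
    """Per-gene junction counts (half-open containment) and the hit-gene set.

    When ``gene_list`` is given, the returned set is restricted to listed
    genes, ready for :func:`hypergeom_overlap_test`.
    """
    counts = {name: 0 for name, _ in genes}
    by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for name, iv in genes:
        by_chrom.setdefault(iv.chrom, []).append((name, iv))
    for j in junctions:
        for name, iv in by_chrom.get(j.chrom, []):
            if iv.contains(j.pos):
                counts[name] += 1
    hit = {name for name, c in counts.items() if c > 0}
    if gene_list is not None:
        hit &= set(gene_list)
    return pd.Series(counts, dtype=int), hit
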