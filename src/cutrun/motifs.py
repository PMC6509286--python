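"""Position-probability models for RSS heptamers/nonamers.

Two scoring schemes live here:

* :class:`Pwm` — a log-odds position weight matrix in bits over a fixed
  background, with FIMO-style exact p-values computed by dynamic programming
  over the achievable-score distribution.  Used for heptamer scans at a
  p-value threshold.
* :class:`RssModel` — a composite 12/23-RSS scorer: per-position log10
  probabilities for the heptamer and nonamer, a set of allowed spacer
  lengths, and pass thresholds.  Scores are rescaled so the model's consensus
  sequence scores exactly 0 and are floored at ``score_floor`` (default
  −1000), matching the published recombination-information-content (RIC)
  convention in which 0 is a perfect RSS; a site passes when its score is
  strictly above the threshold for its type (−38.81 for 12-RSS, −58.45 for
  23-RSS by default).

The published RIC model's internal parameters are not public, so the default
:meth:`RssModel.default` matrix is a synthetic sharply-peaked profile: every
non-modal base carries probability 1e-10, making each mismatch cost ≈10
log10 units.  Under that scale the default thresholds admit at most 3
mismatches for a 12-RSS and 5 for a 23-RSS over the sixteen conserved
positions.  Real conservation matrices can be supplied from file.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    COMPLEMENT_CODES,
    GenomicInterval,
    InputError,
    Junction,
    decode,
    encode,
)

#: paper-style scan background: 20% C/G and 30% A/T
DEFAULT_BACKGROUND = np.array([0.3, 0.2, 0.2, 0.3])

CONSENSUS_HEPTAMER = "CACAGTG"
CONSENSUS_NONAMER = "ACAAAAACC"


class DegenerateModelError(ValueError):
    """A PWM column has no probability mass and no pseudocount to fall back on."""


# --------------------------------------------------------------------------
# PWM
# --------------------------------------------------------------------------


@dataclass
class Pwm:
    """Log-odds position weight matrix (bits) over a mononucleotide background."""

    probs: np.ndarray  # (width, 4) model probabilities
    background: np.ndarray  # (4,)
    pseudocount: float = 1.0
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.width < 1:
            raise InputError("PWM probabilities must have shape (width>=1, 4)")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise InputError("background must sum to 1 within 1e-9")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise InputError("each PWM position's probabilities must sum to 1")
        if self.pseudocount < 0:
            raise InputError("pseudocount must be non-negative")
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.probs / self.background)
        self._dist_cache: Optional[tuple[np.ndarray, np.ndarray]] = None

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def score_distribution(
        self, max_exact_width: int = 12, bin_width: float = 1e-3
    ) -> tuple[np.ndarray, np.ndarray]:
        """(sorted scores, upper-tail probabilities) of a random background window.

        For widths up to ``max_exact_width`` every achievable score sum is
        enumerated exactly by dynamic programming over positions (scores are
        accumulated left to right, the same order :func:`pwm_score` uses, so
        the floats agree bit for bit).  Wider models fall back to a
        discretized lattice with ``bin_width`` bits per bin.
        """
        if self._dist_cache is not None:
            return self._dist_cache
        exact = self.width <= max_exact_width
        dist: dict[float, float] = {0.0: 1.0}
        for i in range(self.width):
            new: dict[float, float] = {}
            row = self.log_odds[i]
            for s, pr in dist.items():
                for b in range(4):
                    pb = self.background[b]
                    if pb == 0.0:
                        continue
                    s2 = s + row[b]
                    if not exact:
                        s2 = round(s2 / bin_width) * bin_width
                    new[s2] = new.get(s2, 0.0) + pr * pb
            dist = new
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        tails = np.cumsum(probs[::-1])[::-1]
        self._dist_cache = (scores, tails)
        return self._dist_cache


def build_pwm(
    counts: Union[np.ndarray, Sequence[Sequence[float]]],
    pseudocount: float = 1.0,
    background: np.ndarray = DEFAULT_BACKGROUND,
) -> Pwm:
    """Build a PWM from per-position counts (or frequencies).

    Model probability p(b, i) = (count(b,i) + pseudocount*background(b)) /
    (total(i) + pseudocount); the pseudocount is allocated proportionally to
    the background.  Log-odds are log2(p/background).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise InputError("counts must have shape (width, 4) ordered A C G T")
    if np.any(counts < 0):
        raise InputError("counts must be non-negative")
    background = np.asarray(background, dtype=float)
    totals = counts.sum(axis=1)
    if pseudocount == 0 and np.any(totals == 0):
        raise DegenerateModelError(
            "a position has all-zero counts and the pseudocount is zero"
        )
    probs = (counts + pseudocount * background[None, :]) / (
        totals[:, None] + pseudocount
    )
    return Pwm(probs=probs, background=background, pseudocount=pseudocount)


def pwm_score(pwm: Pwm, window: str) -> float:
    """Log-odds score (bits) of one window; N contributes 0 bits."""
    if len(window) != pwm.width:
        raise InputError(
            f"window length {len(window)} != PWM width {pwm.width}"
        )
    codes = encode(window)
    score = 0.0
    for i, c in enumerate(codes):
        if c < 4:
            score += pwm.log_odds[i, c]
    return score


def pwm_exact_pvalue(pwm: Pwm, score: float) -> float:
    """P(random background window scores >= ``score``), exact by DP.

    Monotone non-increasing in ``score``; -inf (or anything below the minimum
    achievable score) gives 1.
    """
    if np.isnan(score):
        raise InputError("score must not be NaN")
    scores, tails = pwm.score_distribution()
    if score <= scores[0]:
        return 1.0
    idx = int(np.searchsorted(scores, score, side="left"))
    if idx >= len(scores):
        return 0.0
    return float(tails[idx])


def _window_scores(codes: np.ndarray, lut: np.ndarray, width: int) -> np.ndarray:
    """Sequential-order log-odds sums for every window of ``codes``.

    ``lut`` is (width, 5): four base columns plus a zero column for N.
    Accumulating position by position reproduces the float ordering of
    :func:`pwm_score` and of the DP score distribution exactly.
    """
    n = len(codes) - width + 1
    scores = np.zeros(n)
    for i in range(width):
        scores += lut[i, codes[i : i + n]]
    return scores


def scan_sequence(
    sequence: str,
    pwm: Pwm,
    p_threshold: float = 0.001,
    strands: str = "both",
) -> list[tuple[int, str, float, float]]:
    """Report every window with exact p-value <= ``p_threshold``.

    Minus-strand windows are scored on their reverse complement; p-values for
    both strands come from the PWM's own background null.  Hits are sorted by
    offset, '+' before '-'.  A sequence shorter than the PWM yields no hits.
    """
    w = pwm.width
    if len(sequence) < w:
        return []
    codes = encode(sequence)
    lut = np.zeros((w, 5))
    lut[:, :4] = pwm.log_odds
    scores_by_strand: dict[str, np.ndarray] = {}
    if strands in ("both", "+"):
        scores_by_strand["+"] = _window_scores(codes, lut, w)
    if strands in ("both", "-"):
        # score of revcomp(window) under the PWM: position i of the
        # reverse-complemented window is the complement of codes[k + w-1-i]
        n = len(codes) - w + 1
        minus = np.zeros(n)
        comp = COMPLEMENT_CODES
        for i in range(w):
            j = w - 1 - i
            minus += lut[i, comp[codes[j : j + n]]]
        scores_by_strand["-"] = minus
    dist_scores, dist_tails = pwm.score_distribution()
    hits: list[tuple[int, str, float, float]] = []
    for strand, scores in scores_by_strand.items():
        idx = np.searchsorted(dist_scores, scores, side="left")
        pvals = np.where(idx < len(dist_scores), dist_tails[np.minimum(idx, len(dist_tails) - 1)], 0.0)
        for k in np.nonzero(pvals <= p_threshold)[0]:
            hits.append((int(k), strand, float(scores[k]), float(pvals[k])))
    hits.sort(key=lambda h: (h[0], 0 if h[1] == "+" else 1))
    return hits


def load_matrix_tsv(path) -> np.ndarray:
    """Read a model matrix TSV (one row per position, columns A C G T).

    Rows may be probabilities or counts; callers auto-detect by row sums.
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in ("A", "C", "G", "T") if c in df.columns]
    if len(cols) != 4:
        raise InputError(f"matrix {path}: need columns A C G T")
    return df[["A", "C", "G", "T"]].to_numpy(dtype=float)


def default_heptamer_counts() -> np.ndarray:
    """Synthetic heptamer conservation counts peaked on CACAGTG.

    A stand-in profile (counts per 100 observations) with the invariant CAC
    strongly conserved and the AGTG tail moderately conserved; real
    conservation tables can be loaded with :func:`load_matrix_tsv`.
    """
    return np.array(
        [
            #  A    C    G    T
            [2, 94, 2, 2],  # C
            [94, 2, 2, 2],  # A
            [2, 94, 2, 2],  # C
            [80, 6, 8, 6],  # A
            [6, 6, 82, 6],  # G
            [6, 6, 6, 82],  # T
            [10, 10, 70, 10],  # G
        ],
        dtype=float,
    )


# --------------------------------------------------------------------------
# RIC-style RSS model
# --------------------------------------------------------------------------


def _sharp_matrix(consensus: str, eps: float = 1e-10) -> np.ndarray:
    mat = np.full((len(consensus), 4), eps)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 1.0 - 3 * eps
    return mat


@dataclass
class RssModel:
    """Composite heptamer/spacer/nonamer scorer with pass thresholds."""

    heptamer_probs: np.ndarray  # (7, 4)
    nonamer_probs: np.ndarray  # (9, 4)
    spacer_lengths_12: frozenset = frozenset({11, 12, 13})
    spacer_lengths_23: frozenset = frozenset({22, 23, 24})
    threshold_12: float = -38.81
    threshold_23: float = -58.45
    score_floor: float = -1000.0

    def __post_init__(self) -> None:
        self.heptamer_probs = np.asarray(self.heptamer_probs, dtype=float)
        self.nonamer_probs = np.asarray(self.nonamer_probs, dtype=float)
        if self.heptamer_probs.shape != (7, 4):
            raise InputError("heptamer_probs must have shape (7, 4)")
        if self.nonamer_probs.shape != (9, 4):
            raise InputError("nonamer_probs must have shape (9, 4)")
        for name, mat in (
            ("heptamer", self.heptamer_probs),
            ("nonamer", self.nonamer_probs),
        ):
            if np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-9):
                raise InputError(f"{name} probabilities must sum to 1 per position")
        if self.threshold_12 > 0 or self.threshold_23 > 0:
            raise InputError("thresholds must be <= 0")
        if self.score_floor > min(self.threshold_12, self.threshold_23):
            raise InputError("score_floor must lie at or below both thresholds")
        self.spacer_lengths_12 = frozenset(int(s) for s in self.spacer_lengths_12)
        self.spacer_lengths_23 = frozenset(int(s) for s in self.spacer_lengths_23)
        # rescaled contribution matrices: log10 p - log10 p_modal, with a
        # fifth zero column so N contributes no log-ratio
        self._pen_hept = self._penalties(self.heptamer_probs)
        self._pen_non = self._penalties(self.nonamer_probs)

    @staticmethod
    def _penalties(probs: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            logp = np.log10(probs)
        pen = np.zeros((probs.shape[0], 5))
        pen[:, :4] = logp - logp.max(axis=1, keepdims=True)
        return pen

    def spacers(self, rss_type: int) -> tuple[int, ...]:
        if rss_type == 12:
            return tuple(sorted(self.spacer_lengths_12))
        if rss_type == 23:
            return tuple(sorted(self.spacer_lengths_23))
        raise InputError(f"rss_type must be 12 or 23, got {rss_type}")

    def threshold(self, rss_type: int) -> float:
        return self.threshold_12 if rss_type == 12 else self.threshold_23

    @property
    def consensus_heptamer(self) -> str:
        return decode(np.argmax(self.heptamer_probs, axis=1).astype(np.uint8))

    @property
    def consensus_nonamer(self) -> str:
        return decode(np.argmax(self.nonamer_probs, axis=1).astype(np.uint8))

    @property
    def max_site_length(self) -> int:
        return 16 + max(max(self.spacer_lengths_12), max(self.spacer_lengths_23))

    @classmethod
    def default(cls) -> "RssModel":
        """Sharply-peaked synthetic model for CACAGTG / ACAAAAACC (see module docs)."""
        return cls(
            heptamer_probs=_sharp_matrix(CONSENSUS_HEPTAMER),
            nonamer_probs=_sharp_matrix(CONSENSUS_NONAMER),
        )

    @classmethod
    def from_toml(cls, path) -> "RssModel":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        kwargs = {}
        if "thresholds" in doc:
            kwargs["threshold_12"] = float(doc["thresholds"].get("rss12", -38.81))
            kwargs["threshold_23"] = float(doc["thresholds"].get("rss23", -58.45))
        if "spacers" in doc:
            kwargs["spacer_lengths_12"] = frozenset(doc["spacers"]["rss12"])
            kwargs["spacer_lengths_23"] = frozenset(doc["spacers"]["rss23"])
        if "score_floor" in doc:
            kwargs["score_floor"] = float(doc["score_floor"])
        hept = np.asarray(doc["heptamer"]["rows"], dtype=float)
        nona = np.asarray(doc["nonamer"]["rows"], dtype=float)
        # auto-detect counts vs probabilities by row sums
        if not np.allclose(hept.sum(axis=1), 1.0):
            hept = hept / hept.sum(axis=1, keepdims=True)
        if not np.allclose(nona.sum(axis=1), 1.0):
            nona = nona / nona.sum(axis=1, keepdims=True)
        return cls(heptamer_probs=hept, nonamer_probs=nona, **kwargs)

    def to_toml(self, path) -> None:
        def rows(mat: np.ndarray) -> str:
            lines = ",\n    ".join(
                "[" + ", ".join(repr(float(x)) for x in row) + "]" for row in mat
            )
            return f"rows = [\n    {lines},\n]\n"

        with open(path, "w") as fh:
            fh.write("score_floor = %r\n\n" % float(self.score_floor))
            fh.write("[thresholds]\nrss12 = %r\nrss23 = %r\n\n"
                     % (float(self.threshold_12), float(self.threshold_23)))
            fh.write("[spacers]\nrss12 = %s\nrss23 = %s\n\n"
                     % (sorted(self.spacer_lengths_12), sorted(self.spacer_lengths_23)))
            fh.write("[heptamer]\n" + rows(self.heptamer_probs) + "\n")
            fh.write("[nonamer]\n" + rows(self.nonamer_probs))


@dataclass(frozen=True)
class RssHit:
    """A scored candidate RSS covering heptamer through nonamer."""

    interval: GenomicInterval
    rss_type: int
    strand: str
    score: float
    passes: bool
    spacer_length: int


def score_rss(
    sequence: Union[str, np.ndarray],
    offset: int,
    rss_type: int,
    model: RssModel,
    strand: str = "+",
    chrom: str = "seq",
) -> RssHit:
    """Score the candidate RSS starting at ``offset`` (0-based, plus-strand
    coordinates; for strand '-' the covered window is reverse-complemented
    before scoring).

    For each allowed spacer length the heptamer and nonamer log10-probability
    sums are rescaled so the model consensus scores 0, floored at
    ``score_floor``; the best spacer's score is kept.  ``passes`` is a strict
    comparison against the threshold for the RSS type.
    """
    codes = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    spacers = model.spacers(rss_type)
    if offset < 0 or offset + 16 + min(spacers) > len(codes):
        raise InputError(
            f"offset {offset} out of range for a {rss_type}-RSS in a "
            f"{len(codes)}-base sequence"
        )
    best_score = -np.inf
    best_spacer = None
    for spacer in spacers:
        end = offset + 16 + spacer
        if end > len(codes):
            continue
        window = codes[offset:end]
        if strand == "-":
            window = COMPLEMENT_CODES[window[::-1]]
        s = 0.0
        for i in range(7):
            s += model._pen_hept[i, window[i]]
        for j in range(9):
            s += model._pen_non[j, window[7 + spacer + j]]
        s = max(s, model.score_floor)
        if s > best_score:
            best_score = s
            best_spacer = spacer
    score = float(best_score)
    return RssHit(
        interval=GenomicInterval(chrom, offset, offset + 16 + best_spacer),
        rss_type=rss_type,
        strand=strand,
        score=score,
        passes=score > model.threshold(rss_type),
        spacer_length=best_spacer,
    )


def scan_rss_region(
    codes: np.ndarray,
    model: RssModel,
    chrom: str = "seq",
    origin: int = 0,
    passing_only: bool = True,
) -> list[RssHit]:
    """Score every offset/strand/type in a region; best spacer per offset.

    Vectorized equivalent of calling :func:`score_rss` at every offset.
    ``origin`` shifts reported intervals into chromosome coordinates.
    """
    hits: list[RssHit] = []
    n = len(codes)
    comp = COMPLEMENT_CODES
    for rss_type in (12, 23):
        spacers = model.spacers(rss_type)
        threshold = model.threshold(rss_type)
        n_off = n - (16 + min(spacers)) + 1
        if n_off <= 0:
            continue
        for strand in ("+", "-"):
            per_spacer = np.full((len(spacers), n_off), -np.inf)
            for si, spacer in enumerate(spacers):
                m = n - (16 + spacer) + 1
                if m <= 0:
                    continue
                acc = np.zeros(m)
                if strand == "+":
                    for i in range(7):
                        acc += model._pen_hept[i, codes[i : i + m]]
                    for j in range(9):
                        acc += model._pen_non[j, codes[7 + spacer + j : 7 + spacer + j + m]]
                else:
                    # reverse-complemented window: rc-position i maps to
                    # plus-strand position (16 + spacer - 1 - i) from the offset
                    site_len = 16 + spacer
                    for i in range(7):
                        p = site_len - 1 - i
                        acc += model._pen_hept[i, comp[codes[p : p + m]]]
                    for j in range(9):
                        p = site_len - 1 - (7 + spacer + j)
                        acc += model._pen_non[j, comp[codes[p : p + m]]]
                per_spacer[si, :m] = np.maximum(acc, model.score_floor)
            best_idx = np.argmax(per_spacer, axis=0)
            best = per_spacer[best_idx, np.arange(n_off)]
            if passing_only:
                keep = np.nonzero(best > threshold)[0]
            else:
                keep = np.arange(n_off)
            for k in keep:
                spacer = spacers[int(best_idx[k])]
                hits.append(
                    RssHit(
                        interval=GenomicInterval(
                            chrom, origin + int(k), origin + int(k) + 16 + spacer
                        ),
                        rss_type=rss_type,
                        strand=strand,
                        score=float(best[k]),
                        passes=bool(best[k] > threshold),
                        spacer_length=spacer,
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, 0 if h.strand == "+" else 1, h.rss_type))
    return hits


@dataclass
class JunctionRssResult:
    junction: Junction
    hits: list[RssHit]
    has_passing_rss: bool


def find_rss_near_junctions(
    junctions: Sequence[Junction],
    genome: dict,
    model: Optional[RssModel] = None,
    window: int = 100,
) -> list[JunctionRssResult]:
    """Scan ±``window`` bp of each junction for passing RSS motifs.

    The scanned slice is extended by one full site length on each side so
    that any RSS whose nearest base lies within ``window`` of the junction
    point fits entirely; hits are then filtered to that distance rule
    (inclusive).  Windows overhanging chromosome ends are clipped.  Use
    ``window=1000`` for the wider patient-overlap context scan.
    """
    model = model or RssModel.default()
    pad = model.max_site_length - 1
    results: list[JunctionRssResult] = []
    for j in junctions:
        if j.chrom not in genome:
            raise InputError(
                f"junction {j.chrom}:{j.pos} ({j.dataset}): unknown chromosome"
            )
        codes = genome[j.chrom]
        if not isinstance(codes, np.ndarray):
            codes = encode(str(codes))
        if j.pos >= len(codes):
            raise InputError(
                f"junction {j.chrom}:{j.pos} beyond chromosome end {len(codes)}"
            )
        lo = max(0, j.pos - window - pad)
        hi = min(len(codes), j.pos + window + pad + 1)
        raw = scan_rss_region(codes[lo:hi], model, chrom=j.chrom, origin=lo)
        hits = [h for h in raw if h.interval.distance_to(j.pos) <= window]
        results.append(
            JunctionRssResult(
                junction=j, hits=hits, has_passing_rss=bool(hits)
            )
        )
    return results


def write_hits_tsv(results: Sequence[JunctionRssResult], path) -> None:
    """Full-fidelity per-hit table."""
    rows = []
    for r in results:
        for h in r.hits:
            rows.append(
                dict(
                    chrom=h.interval.chrom,
                    start=h.interval.start,
                    end=h.interval.end,
                    junction_pos=r.junction.pos,
                    dataset=r.junction.dataset,
                    rss_type=h.rss_type,
                    strand=h.strand,
                    spacer_length=h.spacer_length,
                    score=h.score,
                    passes=h.passes,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "junction_pos", "dataset",
            "rss_type", "strand", "spacer_length", "score", "passes",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_hits_bed(results: Sequence[JunctionRssResult], path) -> None:
    """BED6 with the score column carrying -score clamped to the 0-1000 range."""
    with open(path, "w") as fh:
        for r in results:
            for h in r.hits:
                bed_score = int(round(min(1000.0, max(0.0, -h.score))))
                fh.write(
                    f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}\t"
                    f"RSS{h.rss_type}\t{bed_score}\t{h.strand}\n"
                )
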