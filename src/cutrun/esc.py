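"""Excised signal circle (ESC) repertoire enumeration and consensus scoring.

Deletional V(D)J recombination excises the DNA between the recombining gene
segments as a circle whose two recombination signal sequences (RSSs) are
ligated head-to-head (the signal joint).  RAG re-binding of such circles is
efficient when both RSSs retain the critical conserved bases, so the fraction
of circles that look "consensus-like" bounds how much of the repertoire can
drive further genomic cutting.

A candidate ESC is scored against two criteria, applied to each RSS of the
head-to-head pair independently:

* heptamer: the first three bases must be the invariant ``CAC`` and the
  remaining four may deviate from ``AGTG`` at most at one position;
* nonamer: positions 5 and 6 (1-based) must both be ``A``.

The usage-weighted fraction of passing pairs is computed per locus (the
Cartesian product of 12-RSS x 23-RSS segments, weighted by the product of
normalized segment usage frequencies) and aggregated across loci.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import InputError

CONSENSUS_HEPTAMER = "CACAGTG"
CONSENSUS_NONAMER = "ACAAAAACC"

REPERTOIRE_COLUMNS = [
    "locus",
    "segment",
    "segment_type",
    "rss_type",
    "heptamer",
    "spacer",
    "nonamer",
    "usage_freq",
]


@dataclass(frozen=True)
class SegmentRss:
    """One gene segment's RSS plus its usage frequency."""

    locus: str
    segment: str
    segment_type: str
    rss_type: int
    heptamer: str
    spacer: str
    nonamer: str
    usage_freq: float

    def __post_init__(self) -> None:
        if len(self.heptamer) != 7:
            raise InputError(
                f"segment {self.segment}: heptamer must be 7 bases, "
                f"got {len(self.heptamer)}"
            )
        if len(self.nonamer) != 9:
            raise InputError(
                f"segment {self.segment}: nonamer must be 9 bases, "
                f"got {len(self.nonamer)}"
            )
        if self.rss_type not in (12, 23):
            raise InputError(f"segment {self.segment}: rss_type must be 12 or 23")
        if abs(len(self.spacer) - self.rss_type) > 1:
            raise InputError(
                f"segment {self.segment}: spacer length {len(self.spacer)} "
                f"inconsistent with declared {self.rss_type}-RSS (allowed +/-1)"
            )
        if self.usage_freq < 0:
            raise InputError(f"segment {self.segment}: usage_freq must be >= 0")


@dataclass(frozen=True)
class EscPair:
    """A head-to-head 12/23 RSS pair with its usage weight."""

    segment_a: SegmentRss
    segment_b: SegmentRss
    weight: float
    consensus_match: bool


def heptamer_class(heptamer: str) -> str:
    """Classify a heptamer as ``consensus``, ``cac_one_mismatch`` or ``fail``.

    Consensus is exactly CACAGTG.  The relaxed class keeps the invariant CAC
    and tolerates exactly one mismatch over the remaining AGTG.  Any other
    sequence (including non-ACGT characters) fails.
    """
    if len(heptamer) != 7:
        raise InputError(f"heptamer must be 7 bases, got {len(heptamer)}")
    h = heptamer.upper()
    if not set(h) <= set("ACGT"):
        return "fail"
    if h == CONSENSUS_HEPTAMER:
        return "consensus"
    if h[:3] == "CAC":
        mismatches = sum(a != b for a, b in zip(h[3:], "AGTG"))
        if mismatches == 1:
            return "cac_one_mismatch"
    return "fail"


def nonamer_ok(nonamer: str) -> bool:
    """True iff 1-based positions 5 and 6 of the nonamer are both A."""
    if len(nonamer) != 9:
        raise InputError(f"nonamer must be 9 bases, got {len(nonamer)}")
    n = nonamer.upper()
    return n[4] == "A" and n[5] == "A"


def classify_esc(pair: EscPair) -> bool:
    """Apply the pair-level consensus criteria to a head-to-head RSS pair."""
    return _classify(
        pair.segment_a.heptamer,
        pair.segment_a.nonamer,
        pair.segment_b.heptamer,
        pair.segment_b.nonamer,
    )


def _classify(hept_a: str, nona_a: str, hept_b: str, nona_b: str) -> bool:
    ok = {"consensus", "cac_one_mismatch"}
    return (
        heptamer_class(hept_a) in ok
        and heptamer_class(hept_b) in ok
        and nonamer_ok(nona_a)
        and nonamer_ok(nona_b)
    )


def load_repertoire(path) -> list[SegmentRss]:
    """Load a repertoire TSV and renormalize usage within (locus, segment_type).

    Expected header: locus  segment  segment_type  rss_type  heptamer  spacer
    nonamer  usage_freq.  Row-level validation errors report the file line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REPERTOIRE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"repertoire {path}: missing columns {missing}")
    segments: list[SegmentRss] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            segments.append(
                SegmentRss(
                    locus=row["locus"],
                    segment=row["segment"],
                    segment_type=row["segment_type"],
                    rss_type=int(row["rss_type"]),
                    heptamer=row["heptamer"].upper(),
                    spacer=row["spacer"].upper(),
                    nonamer=row["nonamer"].upper(),
                    usage_freq=float(row["usage_freq"]),
                )
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"repertoire {path}, line {line_no}: {exc}") from exc
    return renormalize_usage(segments)


def renormalize_usage(segments: Sequence[SegmentRss]) -> list[SegmentRss]:
    """Rescale usage frequencies to sum to 1 within each (locus, segment_type)."""
    totals: dict[tuple[str, str], float] = defaultdict(float)
    for seg in segments:
        totals[(seg.locus, seg.segment_type)] += seg.usage_freq
    out = []
    for seg in segments:
        total = totals[(seg.locus, seg.segment_type)]
        if total <= 0:
            raise InputError(
                f"usage frequencies for ({seg.locus}, {seg.segment_type}) sum to 0"
            )
        out.append(
            SegmentRss(
                locus=seg.locus,
                segment=seg.segment,
                segment_type=seg.segment_type,
                rss_type=seg.rss_type,
                heptamer=seg.heptamer,
                spacer=seg.spacer,
                nonamer=seg.nonamer,
                usage_freq=seg.usage_freq / total,
            )
        )
    return out


PairingRule = tuple[str, str, str]  # (locus or "*", segment_type_a, segment_type_b)


def enumerate_esc_pairs(
    repertoire: Sequence[SegmentRss],
    pairing_rules: Optional[Iterable[PairingRule]] = None,
) -> list[EscPair]:
    """All head-to-head 12x23 pairs within each locus.

    The default rule pairs every 12-RSS segment with every 23-RSS segment of
    the same locus; pair weight is the product of the two usage frequencies.
    ``pairing_rules`` restricts pairs to listed (locus, type_a, type_b)
    combinations, with ``"*"`` as a locus wildcard; a rule matches a pair in
    either orientation.  A locus carrying only one RSS type simply yields no
    pairs.
    """
    rules = list(pairing_rules) if pairing_rules is not None else None

    def allowed(locus: str, ta: str, tb: str) -> bool:
        if rules is None:
            return True
        for rl, ra, rb in rules:
            if rl not in ("*", locus):
                continue
            if (ta, tb) == (ra, rb) or (ta, tb) == (rb, ra):
                return True
        return False

    by_locus: dict[str, dict[int, list[SegmentRss]]] = defaultdict(
        lambda: {12: [], 23: []}
    )
    for seg in repertoire:
        by_locus[seg.locus][seg.rss_type].append(seg)

    pairs: list[EscPair] = []
    for locus in by_locus:
        for a in by_locus[locus][12]:
            for b in by_locus[locus][23]:
                if not allowed(locus, a.segment_type, b.segment_type):
                    continue
                pairs.append(
                    EscPair(
                        segment_a=a,
                        segment_b=b,
                        weight=a.usage_freq * b.usage_freq,
                        consensus_match=_classify(
                            a.heptamer, a.nonamer, b.heptamer, b.nonamer
                        ),
                    )
                )
    return pairs


def weighted_consensus_fraction(
    pairs: Sequence[EscPair],
    locus_weights: Optional[dict[str, float]] = None,
) -> tuple[dict[str, float], float]:
    """Usage-weighted fraction of criteria-passing pairs, per locus and overall.

    Per-locus fraction is sum(weight of matching pairs) / sum(weight).  The
    overall value is the weighted mean of locus fractions, with equal locus
    weights unless ``locus_weights`` is given.
    """
    num: dict[str, float] = defaultdict(float)
    den: dict[str, float] = defaultdict(float)
    for p in pairs:
        locus = p.segment_a.locus
        den[locus] += p.weight
        if p.consensus_match:
            num[locus] += p.weight
    per_locus: dict[str, float] = {}
    for locus, total in den.items():
        if total <= 0:
            raise InputError(f"total pair weight for locus {locus} is zero")
        per_locus[locus] = num[locus] / total
    if not per_locus:
        raise InputError("no pairs to aggregate")
    if locus_weights is None:
        overall = sum(per_locus.values()) / len(per_locus)
    else:
        wsum = sum(locus_weights.get(l, 0.0) for l in per_locus)
        if wsum <= 0:
            raise InputError("locus weights sum to zero over reported loci")
        overall = (
            sum(per_locus[l] * locus_weights.get(l, 0.0) for l in per_locus) / wsum
        )
    return per_locus, overall
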