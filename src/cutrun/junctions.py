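"""Translocation junction I/O, exclusion-region filtering, and tabulation.

Junctions are points: the prey-side breakpoint coordinate, 0-based
internally.  Two published artifact regions motivate the blacklist: the
EEF1A1 promoter (lentiviral EF1-alpha promoter capture at the bait break,
excluded from every dataset) and the TCR-beta 12-RSS vector origin on chr7
(excluded from 12-RSS datasets only).  Printed 1-based inclusive coordinates
are converted once, at the blacklist constructors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import GenomicInterval, InputError, Junction

DIALECTS = ("tsv0", "tsv1", "bed")


def read_junctions(path, dialect: str = "tsv0", dataset: Optional[str] = None) -> list[Junction]:
    """Read a junction table.

    Dialects: ``tsv0`` — header ``chrom pos strand dataset``, 0-based point;
    ``tsv1`` — same columns, 1-based point; ``bed`` — BED3+ where the prey
    point is the interval start, dataset from column 4 unless overridden.
    """
    if dialect not in DIALECTS:
        raise InputError(f"unknown junction dialect {dialect!r}; use one of {DIALECTS}")
    junctions: list[Junction] = []
    if dialect in ("tsv0", "tsv1"):
        offset = 0 if dialect == "tsv0" else 1
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            required = ["chrom", "pos"]
            if any(c not in header for c in required):
                raise InputError(f"{path}: junction TSV needs columns {required}")
            idx = {c: header.index(c) for c in header}
            for line_no, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                try:
                    junctions.append(
                        Junction(
                            chrom=fields[idx["chrom"]],
                            pos=int(fields[idx["pos"]]) - offset,
                            strand=fields[idx["strand"]] if "strand" in idx else "+",
                            dataset=(
                                dataset
                                or (fields[idx["dataset"]] if "dataset" in idx else "default")
                            ),
                        )
                    )
                except (IndexError, ValueError, InputError) as exc:
                    raise InputError(f"{path}, line {line_no}: {exc}") from exc
    else:
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                try:
                    start = int(fields[1])
                    int(fields[2])  # end; validates the row shape
                    junctions.append(
                        Junction(
                            chrom=fields[0],
                            pos=start,
                            strand=fields[5] if len(fields) > 5 else "+",
                            dataset=dataset or (fields[3] if len(fields) > 3 else "default"),
                        )
                    )
                except (IndexError, ValueError, InputError) as exc:
                    raise InputError(f"{path}, line {line_no}: {exc}") from exc
    return junctions


@dataclass(frozen=True)
class BlacklistRegion:
    """A named exclusion region, optionally scoped to specific dataset labels."""

    name: str
    interval: GenomicInterval
    dataset_scope: Optional[frozenset] = None  # None = applies to every dataset

    def applies_to(self, dataset: str) -> bool:
        return self.dataset_scope is None or dataset in self.dataset_scope

    def contains(self, junction: Junction) -> bool:
        return (
            self.applies_to(junction.dataset)
            and self.interval.chrom == junction.chrom
            and self.interval.contains(junction.pos)
        )


@dataclass
class Blacklist:
    regions: list

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise InputError("blacklist region names must be unique")

    @classmethod
    def from_tsv(cls, path) -> "Blacklist":
        """Columns: name chrom start end dataset_scope (0-based half-open;
        scope ``*`` or a comma-separated list of dataset labels)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["name", "chrom", "start", "end", "dataset_scope"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InputError(f"blacklist {path}: missing columns {missing}")
        regions = []
        for idx, row in df.iterrows():
            scope_field = row["dataset_scope"]
            scope = (
                None
                if scope_field in ("*", "", None) or pd.isna(scope_field)
                else frozenset(s.strip() for s in scope_field.split(","))
            )
            try:
                regions.append(
                    BlacklistRegion(
                        name=row["name"],
                        interval=GenomicInterval(
                            row["chrom"], int(row["start"]), int(row["end"])
                        ),
                        dataset_scope=scope,
                    )
                )
            except (ValueError, InputError) as exc:
                raise InputError(f"blacklist {path}, line {idx + 2}: {exc}") from exc
        return cls(regions=regions)

    @classmethod
    def default(cls, twelve_rss_datasets: Iterable[str] = ("12RSS",)) -> "Blacklist":
        """The two published hg19 exclusion regions.

        Printed 1-based inclusive coordinates become 0-based half-open here:
        chr6:74,222,954-74,233,993 -> [74222953, 74233993) (all datasets) and
        chr7:142,495,018-142,495,281 -> [142495017, 142495281) (12-RSS
        datasets only; pass the labels used for those libraries).
        """
        return cls(
            regions=[
                region_from_printed(
                    "EEF1A1_promoter", "chr6", 74_222_954, 74_233_993, None
                ),
                region_from_printed(
                    "TCRB_12RSS_vector_origin",
                    "chr7",
                    142_495_018,
                    142_495_281,
                    frozenset(twelve_rss_datasets),
                ),
            ]
        )


def region_from_printed(
    name: str,
    chrom: str,
    start_1based: int,
    end_inclusive: int,
    dataset_scope: Optional[frozenset] = None,
) -> BlacklistRegion:
    """Convert printed 1-based inclusive coordinates to the internal convention."""
    return BlacklistRegion(
        name=name,
        interval=GenomicInterval(chrom, start_1based - 1, end_inclusive),
        dataset_scope=dataset_scope,
    )


def filter_blacklist(
    junctions: Sequence[Junction], blacklist: Blacklist
) -> tuple[list[Junction], dict]:
    """Drop junctions inside applicable regions; report removals per region.

    Containment is half-open; a junction exactly at a region's end coordinate
    is retained.  Dataset-scoped regions only remove junctions whose dataset
    label is in scope.  Idempotent by construction.
    """
    removals = {r.name: 0 for r in blacklist.regions}
    retained: list[Junction] = []
    for j in junctions:
        hit = None
        for region in blacklist.regions:
            if region.contains(j):
                hit = region
                break
        if hit is None:
            retained.append(j)
        else:
            removals[hit.name] += 1
    return retained, removals


def chrom_distribution(junctions: Sequence[Junction]) -> pd.Series:
    """Junction counts per chromosome (sorted by name); sums to the input size."""
    counts: dict[str, int] = {}
    for j in junctions:
        counts[j.chrom] = counts.get(j.chrom, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
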