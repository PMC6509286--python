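"""Orchestrated simulate → filter → scan → statistics runs from one config.

The run configuration is a single TOML document; all randomness flows from
its one seed, from which each stage derives a child seed keyed by the stage
name.  Outputs are a machine-readable JSON report (no timestamps, so reruns
are byte-identical), TSV tables, and a manifest recording the config hash,
seed, and library versions.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .core import InputError, Junction
from .esc import enumerate_esc_pairs, load_repertoire, weighted_consensus_fraction
from .junctions import Blacklist, chrom_distribution, filter_blacklist, read_junctions
from .motifs import RssModel, find_rss_near_junctions, write_hits_bed, write_hits_tsv
from .stats import chi2_yates, count_overlaps, mc_overlap_null, poisson_overlap_test
from .synthetic import (
    SimConfig,
    simulate_all,
    write_breakpoints_bed,
    write_genome_fasta,
    write_junctions_tsv,
    write_repertoire_tsv,
    write_truth_bed,
)

from scipy import stats as sps


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed derived from the run seed and stage name."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])


@dataclass
class RunConfig:
    """Declarative run description (see examples/demo.toml)."""

    seed: int = 0
    outdir: str = "cutrun_run"
    simulate: Optional[dict] = None
    scan: dict = field(default_factory=dict)
    colocalize: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        return cls(
            seed=int(doc.get("seed", 0)),
            outdir=doc.get("outdir", "cutrun_run"),
            simulate=doc.get("simulate"),
            scan=doc.get("scan", {}),
            colocalize=doc.get("colocalize", {}),
            filter=doc.get("filter", {}),
            inputs=doc.get("inputs", {}),
            raw=doc,
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()


def compare_datasets(report_a: dict, report_b: dict):
    """Dataset-association tests from two per-dataset scan reports.

    Each report carries ``dataset``, per-junction ``rss_flags`` and
    ``chroms``.  Returns the 2x2 (dataset × RSS-present) table with its
    Yates-corrected one-tailed chi-square, plus the per-chromosome r×c table
    with an uncorrected chi-square.
    """
    for r in (report_a, report_b):
        if "rss_flags" not in r:
            raise InputError("dataset report lacks per-junction RSS flags")
    fa = np.asarray(report_a["rss_flags"], dtype=bool)
    fb = np.asarray(report_b["rss_flags"], dtype=bool)
    table = [
        [int(fa.sum()), int((~fa).sum())],
        [int(fb.sum()), int((~fb).sum())],
    ]
    stat, p = chi2_yates(table, alternative="greater")
    result = {
        "datasets": [report_a.get("dataset"), report_b.get("dataset")],
        "table": table,
        "chi2_yates_stat": stat,
        "chi2_yates_one_tailed_p": p,
    }
    if "chroms" in report_a and "chroms" in report_b:
        chroms = sorted(set(report_a["chroms"]) | set(report_b["chroms"]))
        counts = np.array(
            [
                [report_a["chroms"].count(c) for c in chroms],
                [report_b["chroms"].count(c) for c in chroms],
            ]
        )
        keep = counts.sum(axis=0) > 0
        counts = counts[:, keep]
        if counts.shape[1] >= 2 and counts.sum(axis=1).min() > 0:
            rc = sps.chi2_contingency(counts, correction=False)
            result["per_chromosome"] = {
                "chroms": [c for c, k in zip(chroms, keep) if k],
                "stat": float(rc.statistic),
                "p": float(rc.pvalue),
                "dof": int(rc.dof),
            }
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write the report bundle.

    Stages: simulate (optional) → read + filter junctions → RSS scan →
    co-localization statistics → dataset comparison → ESC fraction (if a
    repertoire is configured).  Any stage failure raises a
    :class:`StageError` naming the stage; the manifest flags partial output.
    """
    outdir = Path(config.outdir)
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    manifest = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "versions": {
            "cutrun": __version__,
            "numpy": np.__version__,
        },
        "stages": [],
        "complete": False,
    }

    def _manifest_write() -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    stage = "simulate"
    try:
        chrom_sizes: dict[str, int] = {}
        junction_files: list[tuple[str, Path]] = []
        patient_bed: Optional[Path] = None
        repertoire_tsv: Optional[Path] = None
        sim_result = None
        if config.simulate is not None:
            sim = dict(config.simulate)
            datasets = [
                (d["name"], int(d["n_junctions"]), float(d["rss_proximal_fraction"]))
                for d in sim.pop("datasets", [])
            ] or None
            repertoire = sim.pop("repertoire", None)
            sim_cfg = SimConfig(seed=stage_seed(config.seed, "simulate"), **sim)
            sim_result = simulate_all(sim_cfg, datasets=datasets, repertoire=repertoire)
            chrom_sizes = dict(sim_cfg.chrom_sizes)
            write_genome_fasta(sim_result.genome, outdir / "inputs" / "genome.fa")
            write_truth_bed(
                sim_result.truth.planted_rss, outdir / "inputs" / "planted_rss.bed"
            )
            for name, juncs in sim_result.junctions.items():
                p = outdir / "inputs" / f"junctions_{name}.tsv"
                write_junctions_tsv(juncs, p)
                junction_files.append((name, p))
            patient_bed = outdir / "inputs" / "patient_breakpoints.bed"
            write_breakpoints_bed(
                sim_result.patient_bps, patient_bed, sim_result.truth.overlap_labels
            )
            if sim_result.repertoire is not None:
                repertoire_tsv = outdir / "inputs" / "repertoire.tsv"
                write_repertoire_tsv(sim_result.repertoire, repertoire_tsv)
            manifest["stages"].append(
                {
                    "stage": stage,
                    "n_planted_rss": len(sim_result.truth.planted_rss),
                    "n_junctions": {
                        n: len(j) for n, j in sim_result.junctions.items()
                    },
                    "n_patient_bps": len(sim_result.patient_bps),
                }
            )
        else:
            chrom_sizes = {
                str(k): int(v) for k, v in config.inputs.get("chrom_sizes", {}).items()
            }
            for name, path in config.inputs.get("junctions", {}).items():
                junction_files.append((name, Path(path)))
            if "patient_breakpoints" in config.inputs:
                patient_bed = Path(config.inputs["patient_breakpoints"])
            if "repertoire" in config.inputs:
                repertoire_tsv = Path(config.inputs["repertoire"])

        stage = "read_filter"
        blacklist = None
        if config.filter.get("blacklist"):
            blacklist = Blacklist.from_tsv(config.filter["blacklist"])
        elif config.filter.get("use_default_blacklist"):
            blacklist = Blacklist.default(
                tuple(config.filter.get("twelve_rss_datasets", ("12RSS",)))
            )
        datasets_junc: dict[str, list[Junction]] = {}
        filter_report: dict = {}
        for name, path in junction_files:
            juncs = read_junctions(path, dialect="tsv0")
            n_in = len(juncs)
            removals: dict = {}
            if blacklist is not None:
                juncs, removals = filter_blacklist(juncs, blacklist)
            datasets_junc[name] = juncs
            filter_report[name] = {
                "input": n_in,
                "retained": len(juncs),
                "removed_per_region": removals,
            }
        report["filter"] = filter_report
        manifest["stages"].append(
            {"stage": stage, "counts": {n: len(j) for n, j in datasets_junc.items()}}
        )

        stage = "scan"
        genome = (
            sim_result.genome
            if sim_result is not None
            else _load_genome(config.inputs.get("genome"))
        )
        model = (
            RssModel.from_toml(config.scan["model"])
            if config.scan.get("model")
            else RssModel.default()
        )
        window = int(config.scan.get("window", 100))
        dataset_reports: dict[str, dict] = {}
        for name, juncs in datasets_junc.items():
            results = find_rss_near_junctions(juncs, genome, model, window=window)
            flags = [r.has_passing_rss for r in results]
            dataset_reports[name] = {
                "dataset": name,
                "n_junctions": len(juncs),
                "n_with_rss": int(sum(flags)),
                "rss_flags": flags,
                "chroms": [j.chrom for j in juncs],
                "chrom_distribution": chrom_distribution(juncs).to_dict(),
            }
            write_hits_tsv(results, outdir / f"rss_hits_{name}.tsv")
            write_hits_bed(results, outdir / f"rss_hits_{name}.bed")
        report["datasets"] = {
            n: {k: v for k, v in r.items() if k != "rss_flags"}
            for n, r in dataset_reports.items()
        }
        manifest["stages"].append(
            {
                "stage": stage,
                "n_with_rss": {
                    n: r["n_with_rss"] for n, r in dataset_reports.items()
                },
            }
        )

        stage = "colocalize"
        if patient_bed is not None and datasets_junc:
            bps = _read_breakpoints(patient_bed)
            window_c = int(config.colocalize.get("window", 100))
            N = sum(chrom_sizes.values()) if chrom_sizes else None
            coloc: dict[str, dict] = {}
            for name, juncs in datasets_junc.items():
                if not juncs:
                    continue
                res = count_overlaps(
                    juncs, bps, window=window_c, chrom_sizes=chrom_sizes or None
                )
                entry = {"k_obs": res.k_obs, "M": res.M}
                if N:
                    test = poisson_overlap_test(res.k_obs, len(bps), res.M, N)
                    entry.update(lam=test.lam, p_value=test.p_value, N=N)
                    if config.colocalize.get("monte_carlo"):
                        entry["mc_p_value"] = mc_overlap_null(
                            res.coverage,
                            chrom_sizes,
                            len(bps),
                            res.k_obs,
                            n_iter=int(config.colocalize.get("n_iter", 10_000)),
                            seed=stage_seed(config.seed, f"mc:{name}"),
                        )
                coloc[name] = entry
            report["colocalization"] = coloc
            manifest["stages"].append({"stage": stage, "n_patient_bps": len(bps)})

        stage = "compare"
        names = list(dataset_reports)
        if len(names) >= 2:
            report["comparison"] = compare_datasets(
                dataset_reports[names[0]], dataset_reports[names[1]]
            )

        stage = "esc_fraction"
        if repertoire_tsv is not None:
            segments = load_repertoire(repertoire_tsv)
            pairs = enumerate_esc_pairs(segments)
            per_locus, overall = weighted_consensus_fraction(pairs)
            esc_entry = {
                "per_locus": per_locus,
                "overall": overall,
                "n_pairs": len(pairs),
            }
            if (
                sim_result is not None
                and sim_result.truth.repertoire_expected_fraction is not None
            ):
                esc_entry["expected"] = sim_result.truth.repertoire_expected_fraction
            report["esc"] = esc_entry
    except Exception as exc:
        manifest["failed_stage"] = stage
        _manifest_write()
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest["complete"] = True
    _manifest_write()
    _write_summary(report, outdir / "summary.txt")
    return report


def _load_genome(path):
    if path is None:
        raise StageError("scan stage needs a genome (simulate it or set inputs.genome)")
    from .synthetic import load_genome_fasta

    return load_genome_fasta(path)


def _read_breakpoints(path):
    from .core import Breakpoint

    bps = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            bps.append(Breakpoint(f[0], int(f[1]), f[3] if len(f) > 3 else "breakpoint"))
    return bps


def _write_summary(report: dict, path) -> None:
    lines = [f"cutrun run (seed {report.get('seed')})", ""]
    for name, d in report.get("datasets", {}).items():
        lines.append(
            f"dataset {name}: {d['n_with_rss']}/{d['n_junctions']} junctions "
            "with a passing RSS within the scan window"
        )
    for name, c in report.get("colocalization", {}).items():
        lam = c.get("lam")
        p = c.get("p_value")
        extra = f", lambda={lam:.4g}, p={p:.3g}" if lam is not None else ""
        lines.append(
            f"co-localization [{name}]: k_obs={c['k_obs']}, M={c['M']}{extra}"
        )
    comp = report.get("comparison")
    if comp:
        lines.append(
            f"dataset comparison {comp['datasets']}: chi2={comp['chi2_yates_stat']:.4g}, "
            f"one-tailed p={comp['chi2_yates_one_tailed_p']:.3g}"
        )
    esc = report.get("esc")
    if esc:
        lines.append(
            f"ESC usage-weighted consensus fraction: {esc['overall']:.6f} "
            f"({esc['n_pairs']} pairs)"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
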