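"""Pipeline orchestration: simulate → map runs, configs, reports.

A run is described by a :class:`RunConfig` (constructible from a YAML
file), executed by :func:`run_pipeline`, and summarised in a
:class:`RunReport`.  All stochastic stages consume one integer seed, so a
repeated run writes byte-identical TSV/BED artifacts.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bsa, rilsim, vcf_io
from .genome import GenomeMap, default_genome_map
from .model import BulkSegregantModel, BulkSegregantResults
from .rilsim import (
    BulkDesign,
    CrossConfig,
    PhenotypeModel,
    QtlEffect,
    ReadSimConfig,
    SimulationResult,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3

LOW_SAMPLE = "low_bulk"
HIGH_SAMPLE = "high_bulk"


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs.

    ``mode`` is one of simulate / map / simulate+map / calibrate; ``seed``
    is mandatory for any stochastic mode.
    """

    mode: str = "simulate+map"
    seed: int | None = None
    out_dir: str = "bulkmap_out"
    # map-mode inputs
    vcf: str | None = None
    low_sample: str = LOW_SAMPLE
    high_sample: str = HIGH_SAMPLE
    # nested module configs
    cross: CrossConfig = field(default_factory=CrossConfig)
    phenotype: PhenotypeModel = field(default_factory=PhenotypeModel)
    design: BulkDesign = field(default_factory=BulkDesign)
    reads: ReadSimConfig = field(default_factory=ReadSimConfig)
    filters: bsa.FilterConfig = field(default_factory=bsa.FilterConfig)
    window: int = bsa.DEFAULT_WINDOW
    clamp: float = bsa.DEFAULT_CLAMP
    alpha: float = 0.05
    null: str = "mc"
    trials: int = 1_000_000
    max_gap: int = 0
    loess_span: float | None = None  # write LOESS TSV when set
    truth_tolerance: int = 2_000_000

    def validate(self) -> None:
        if self.mode not in ("simulate", "map", "simulate+map", "calibrate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        stochastic = self.mode in ("simulate", "simulate+map") or self.null == "mc"
        if stochastic and self.seed is None:
            raise ValueError(f"mode {self.mode!r} with null={self.null!r} needs a seed")
        if self.mode == "map" and not self.vcf:
            raise ValueError("map mode needs --vcf")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cross" in kwargs:
            sub = dict(kwargs["cross"])
            if "forced_regions" in sub:
                sub["forced_regions"] = [tuple(r) for r in sub["forced_regions"]]
            kwargs["cross"] = CrossConfig(**sub)
        if "phenotype" in kwargs:
            sub = dict(kwargs["phenotype"])
            if "qtls" in sub:
                sub["qtls"] = [QtlEffect(**q) for q in sub["qtls"]]
            kwargs["phenotype"] = PhenotypeModel(**sub)
        if "design" in kwargs:
            kwargs["design"] = BulkDesign(**kwargs["design"])
        if "reads" in kwargs:
            kwargs["reads"] = ReadSimConfig(**kwargs["reads"])
        if "filters" in kwargs:
            kwargs["filters"] = bsa.FilterConfig(**kwargs["filters"])
        return cls(**kwargs)


@dataclass
class RunReport:
    """Counts, thresholds and result tables from one pipeline run."""

    mode: str
    seed: int | None
    counts: dict[str, int] = field(default_factory=dict)
    threshold_low: float | None = None
    threshold_high: float | None = None
    window_summary: pd.DataFrame | None = None
    qtl_table: pd.DataFrame | None = None
    truth_comparison: pd.DataFrame | None = None

    def render(self) -> str:
        lines = [f"bulkmap run: mode={self.mode} seed={self.seed}"]
        if self.counts:
            lines.append("counts: " + ", ".join(f"{k}={v}" for k, v in self.counts.items()))
        if self.threshold_high is not None:
            lines.append(
                f"thresholds: low {self.threshold_low:+.4f} "
                f"high {self.threshold_high:+.4f}"
            )
        if self.qtl_table is not None:
            lines.append(
                f"QTL intervals called: {len(self.qtl_table)}"
            )
            if len(self.qtl_table):
                lines.append(self.qtl_table.to_string(index=False))
        if self.truth_comparison is not None:
            lines.append("truth comparison:")
            lines.append(self.truth_comparison.to_string(index=False))
        return "\n".join(lines)


def records_from_simulation(sim: SimulationResult) -> list[vcf_io.SnpRecord]:
    """Join the two bulks' read tables into SnpRecords (alt = CB4856 allele)."""
    low, high = sim.reads_low, sim.reads_high
    assert (low["chrom"].to_numpy() == high["chrom"].to_numpy()).all()
    assert (low["pos"].to_numpy() == high["pos"].to_numpy()).all()
    return [
        vcf_io.SnpRecord(
            chrom=c,
            pos=int(p),
            ref_allele="A",
            alt_allele="T",
            ref_count_low=int(rl),
            alt_count_low=int(al),
            depth_low=int(dl),
            gq_low=int(gl),
            ref_count_high=int(rh),
            alt_count_high=int(ah),
            depth_high=int(dh),
            gq_high=int(gh),
        )
        for c, p, rl, al, dl, gl, rh, ah, dh, gh in zip(
            low["chrom"], low["pos"],
            low["ref_count"], low["alt_count"], low["depth"], low["gq"],
            high["ref_count"], high["alt_count"], high["depth"], high["gq"],
        )
    ]


def compare_to_truth(
    called: list[bsa.QtlInterval],
    truth: list[QtlEffect],
    tolerance: int = 2_000_000,
) -> pd.DataFrame:
    """Score called intervals against planted QTLs.

    A planted QTL is a hit when some called interval of the correct sign
    (sign of the planted effect) has its peak-window midpoint within
    ``tolerance`` bp of the planted position on the same chromosome.
    """
    rows = []
    for q in truth:
        hit = False
        best = None
        for iv in called:
            if iv.chrom != q.chrom or iv.sign != q.sign:
                continue
            dist = abs(iv.peak_mid - q.pos)
            if best is None or dist < best:
                best = dist
            if dist <= tolerance:
                hit = True
        rows.append(
            {
                "chrom": q.chrom,
                "pos": q.pos,
                "effect": q.effect,
                "sign": q.sign,
                "hit": hit,
                "peak_distance": best if best is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _write_mapping_outputs(
    out: Path, results: BulkSegregantResults, cfg: RunConfig
) -> None:
    results.windows_frame.to_csv(out / "windows.tsv", sep="\t", index=False)
    results.qtl_frame.to_csv(out / "qtls.tsv", sep="\t", index=False)
    vcf_io.write_qtl_bed(results.qtls, str(out / "qtls.bed"))
    with open(out / "thresholds.txt", "w") as fh:
        fh.write(
            f"source\t{results.null.source}\n"
            f"alpha\t{results.null.alpha}\n"
            f"threshold_low\t{results.null.threshold_low:.6f}\n"
            f"threshold_high\t{results.null.threshold_high:.6f}\n"
            f"tail_mass\t{results.null.tail_mass:.6f}\n"
        )
    with open(out / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    if cfg.loess_span and len(results.frequencies) >= 10:
        results.loess(cfg.loess_span).to_csv(
            out / "loess.tsv", sep="\t", index=False, float_format="%.6f"
        )


def run_pipeline(config: RunConfig, gmap: GenomeMap | None = None) -> RunReport:
    """Execute the requested stages, persist artifacts, return the report."""
    config.validate()
    gmap = gmap or default_genome_map()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(mode=config.mode, seed=config.seed)
    _write_run_log(out, config)

    if config.mode == "calibrate":
        if config.null == "exact":
            dist = bsa.null_threshold_exact(config.design, config.alpha, config.clamp)
        else:
            dist = bsa.null_threshold_mc(
                config.design, config.alpha, config.trials,
                seed=config.seed, clamp=config.clamp,
            )
        report.threshold_low = dist.threshold_low
        report.threshold_high = dist.threshold_high
        with open(out / "thresholds.txt", "w") as fh:
            fh.write(
                f"source\t{dist.source}\nalpha\t{dist.alpha}\n"
                f"threshold_low\t{dist.threshold_low:.6f}\n"
                f"threshold_high\t{dist.threshold_high:.6f}\n"
            )
        return report

    records: list[vcf_io.SnpRecord]
    truth: list[QtlEffect] | None = None
    if config.mode in ("simulate", "simulate+map"):
        try:
            sim = rilsim.simulate_experiment(
                gmap=gmap,
                cross=config.cross,
                model=config.phenotype,
                design=config.design,
                reads=config.reads,
                seed=config.seed,
            )
        except ValueError as exc:
            raise PipelineError("simulate", str(exc)) from exc
        records = records_from_simulation(sim)
        truth = sim.truth
        vcf_io.write_bulk_vcf(
            records, str(out / "bulks.vcf"),
            config.low_sample, config.high_sample, gmap,
        )
        vcf_io.write_phenotypes_tsv(sim.phenotypes, str(out / "phenotypes.tsv"))
        vcf_io.write_truth_tsv(sim.truth, str(out / "truth.tsv"))
        report.counts["lines"] = len(sim.rils)
        report.counts["snps_simulated"] = len(records)
        if config.mode == "simulate":
            return report
    else:  # map
        try:
            records, scan_counts = vcf_io.scan_bulk_vcf(
                config.vcf, config.low_sample, config.high_sample
            )
        except (OSError, ValueError) as exc:
            raise PipelineError("map/read_vcf", str(exc)) from exc
        report.counts["snps_read"] = scan_counts["kept"]
        report.counts["skipped_not_biallelic"] = scan_counts["not_biallelic_snp"]
        report.counts["skipped_malformed_ad"] = scan_counts["malformed_ad"]

    model = BulkSegregantModel(
        records,
        design=config.design,
        filter_config=config.filters,
        window=config.window,
        clamp=config.clamp,
    )
    results = model.fit(
        null=config.null,
        alpha=config.alpha,
        trials=config.trials,
        seed=config.seed,
        max_gap=config.max_gap,
    )
    report.counts["snps_input"] = results.filter_counts["input"]
    report.counts["snps_pass_filters"] = results.filter_counts["kept"]
    report.counts["snps_filtered"] = (
        results.filter_counts["input"] - results.filter_counts["kept"]
    )
    report.threshold_low = results.threshold_low
    report.threshold_high = results.threshold_high
    wf = results.windows_frame
    if len(wf):
        report.window_summary = (
            wf.groupby("chrom", sort=False)
            .agg(
                n_windows=("log_odds", "size"),
                max_log_odds=("log_odds", "max"),
                min_log_odds=("log_odds", "min"),
            )
            .reset_index()
        )
    report.qtl_table = results.qtl_frame
    _write_mapping_outputs(out, results, config)

    if truth is not None:
        report.truth_comparison = compare_to_truth(
            results.qtls, truth, config.truth_tolerance
        )
        report.truth_comparison.to_csv(
            out / "truth_comparison.tsv", sep="\t", index=False
        )
    with open(out / "report.txt", "w") as fh:
        fh.write(report.render() + "\n")
    return report


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name for the run log."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write_run_log(out: Path, config: RunConfig) -> None:
    import bulkmap

    payload = {
        "package_version": bulkmap.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "mode": config.mode,
        "seed": config.seed,
        "design": {"n_low": config.design.n_low, "n_high": config.design.n_high},
        "window": config.window,
        "alpha": config.alpha,
        "null": config.null,
        "trials": config.trials,
        "filters": {
            "gq_min": config.filters.gq_min,
            "depth_min_low": config.filters.depth_min_low,
            "depth_min_high": config.filters.depth_min_high,
        },
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
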