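"""One-command orchestration: bin -> normalize -> lift -> call -> flag ->
refine -> genes -> intersect, with optional genotyping, segregation and
granule stages, writing every output as TSV/JSON plus per-chromosome
coverage plots.

Identical configuration and seed produce byte-identical TSV/JSON outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as dio
from .calling import call_deletions, calls_to_frame, flag_shared_calls, gene_content, refine_borders
from .coverage import CallerParams, NormalizedCoverage, lift_parts_to_full, moving_average, normalize_coverage

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    ``coverage_paths`` maps each mutant line id to its bedGraph;
    ``reference_path`` is the wild-type bedGraph captured with the same
    probes.  The parts map is required only when ``lift=True`` (inputs in
    parts coordinates).  Gene models enable border refinement and gene
    content; markers/segregation/image inputs enable their stages.
    """

    coverage_paths: dict
    reference_path: str
    output_dir: str
    parts_map_path: str | None = None
    lift: bool = False
    genes_path: str | None = None
    params: CallerParams = field(default_factory=CallerParams)
    make_plots: bool = True
    log_level: str = "info"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lift and self.parts_map_path is None:
            raise ValueError("lift requested but no parts map given")


@dataclass
class StageRecord:
    stage: str
    inputs: list
    outputs: list
    counts: dict
    warnings: list = field(default_factory=list)


@dataclass
class RunReport:
    version: str
    config_summary: dict
    stages: list = field(default_factory=list)

    def record(self, stage: str, inputs, outputs, counts, warnings=()) -> None:
        if any(s.stage == stage for s in self.stages):
            raise ValueError(f"stage {stage!r} recorded twice")
        self.stages.append(
            StageRecord(stage, list(inputs), list(outputs), dict(counts), list(warnings))
        )

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config_summary,
            "stages": [
                {
                    "stage": s.stage,
                    "inputs": s.inputs,
                    "outputs": s.outputs,
                    "counts": s.counts,
                    "warnings": s.warnings,
                }
                for s in self.stages
            ],
        }


def plot_coverage(norm: NormalizedCoverage, params: CallerParams, out_path) -> None:
    """One facet per chromosome: raw normalized bins, the window-4 moving
    average, and a dashed line at the low-coverage cut-off."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = norm.chromosomes()
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.8 * len(chroms)), squeeze=False, sharex=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        bins = norm.bins(chrom)
        x = bins["start"].to_numpy() / 1e6
        y = bins["value"].to_numpy()
        ax.plot(x, y, lw=0.6, color="0.5", label="normalized")
        w = params.smoothing_window
        if len(y) >= w:
            ma = moving_average(y, w)
            ax.plot(x[: len(ma)], ma, lw=1.2, color="C0", label=f"moving avg (w={w})")
        ax.axhline(params.low_fraction, ls="--", color="C3", lw=0.8)
        ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=8)
        ax.set_ylim(0, min(3, np.nanmax(y) * 1.1 + 0.1) if np.isfinite(np.nanmax(y)) else 3)
    axes[-1, 0].set_xlabel("position (Mb)")
    axes[0, 0].set_title(f"{norm.line_id} / {norm.reference_line_id}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the deletion-discovery pipeline per the configuration.

    Any stage failure aborts with the stage name and cause; outputs written
    before the failure are renamed with a ``.stale`` suffix.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        version=__version__,
        config_summary={
            "lines": sorted(config.coverage_paths),
            "reference": str(config.reference_path),
            "bin_size": config.params.bin_size,
            "low_fraction": config.params.low_fraction,
            "min_low_run": config.params.min_low_run,
            "min_high_run_to_terminate": config.params.min_high_run_to_terminate,
            "seed": config.seed,
        },
    )
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read"
        reference = dio.read_coverage(
            config.reference_path, line_id="wildtype", bin_size=config.params.bin_size
        )
        mutants = {
            line: dio.read_coverage(p, line_id=line, bin_size=config.params.bin_size)
            for line, p in config.coverage_paths.items()
        }
        report.record(
            "read",
            [str(config.reference_path), *map(str, config.coverage_paths.values())],
            [],
            {"lines": len(mutants), "bins": len(reference.df)},
        )

        stage = "normalize"
        normalized = {line: normalize_coverage(m, reference) for line, m in mutants.items()}
        norm_paths = []
        for line, norm in normalized.items():
            p = out / f"{line}.normalized.tsv"
            dio.write_normalized(norm, mutants[line], p)
            norm_paths.append(p)
            written.append(p)
        report.record(
            "normalize", [], [str(p) for p in norm_paths],
            {line: len(n.df) for line, n in normalized.items()},
        )

        if config.lift:
            stage = "lift"
            parts = dio.read_parts_map(config.parts_map_path)
            normalized = {
                line: lift_parts_to_full(n, parts) for line, n in normalized.items()
            }
            report.record("lift", [str(config.parts_map_path)], [], {})

        stage = "call"
        calls_by_line = {
            line: call_deletions(n, config.params) for line, n in normalized.items()
        }
        report.record(
            "call", [], [], {line: len(c) for line, c in calls_by_line.items()}
        )

        stage = "flag"
        calls_by_line = flag_shared_calls(calls_by_line)
        n_flagged = sum(
            1 for calls in calls_by_line.values() for c in calls if c.flags
        )
        report.record("flag", [], [], {"flagged": n_flagged})

        genes = None
        if config.genes_path:
            stage = "genes"
            genes = dio.read_gene_models(config.genes_path)
            gene_counts = {}
            for line, calls in calls_by_line.items():
                gene_counts[line] = sum(len(gene_content(c, genes)) for c in calls)
            report.record("genes", [str(config.genes_path)], [], gene_counts)

        stage = "write_calls"
        call_paths = []
        for line, calls in calls_by_line.items():
            p = out / f"{line}.calls.tsv"
            dio.write_calls(calls, p)
            call_paths.append(p)
            written.append(p)
        report.record(
            "write_calls", [], [str(p) for p in call_paths],
            {"total_calls": sum(len(c) for c in calls_by_line.values())},
        )

        if config.make_plots:
            stage = "plots"
            plot_paths = []
            for line, norm in normalized.items():
                p = out / f"{line}.coverage.png"
                plot_coverage(norm, config.params, p)
                plot_paths.append(p)
            report.record("plots", [], [str(p) for p in plot_paths], {})

        stage = "report"
        report_path = out / "run_report.json"
        dio.write_json(report.to_dict(), report_path)
        return report
    except Exception as exc:
        for p in written:
            try:
                p.rename(p.with_suffix(p.suffix + ".stale"))
            except OSError:
                pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
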