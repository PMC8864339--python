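"""End-to-end pipeline: simulate -> copy number -> tests -> power.

A single RunConfig drives all stages; every output TSV carries a header
comment with the tool version, the seed, and a hash of the config, and
re-running an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .copynum import copy_number_table
from .errors import ParameterError
from .io import write_fasta, write_tsv
from .power import curve_to_frame, power_curve
from .simulate import (
    CALIBRATION_GROUP,
    SimulationParams,
    default_params,
    make_cohort,
    make_reference,
    simulate_counts,
)
from .stats import test_marker

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "copynum", "test", "power")


@dataclass
class RunConfig:
    """Parameters for every stage of a pipeline run."""

    design: str = "booby"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["simulate", "copynum", "test"])
    loss_profile: dict[str, float] = field(default_factory=dict)
    mean_depth: float | None = None  # None: use the design's default scale
    depth_cv: float | None = None
    dispersion: float = 30.0
    divergence: float = 0.1
    alpha: float = 0.05
    calibration_group: str = CALIBRATION_GROUP
    outlier_rule: str = "iqr"
    mapq_min: int = 20
    k: int = 25
    shared_threshold: float = 0.5
    power_group: str | None = None  # default: oldest non-calibration group
    power_f_grid: list[float] = field(default_factory=lambda: [0.0, 0.1, 0.2, 0.3, 0.5])
    power_n_reps: int = 200

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ParameterError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ParameterError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def sim_params(self) -> SimulationParams:
        base = default_params(self.design, seed=self.seed)
        return SimulationParams(
            mean_depth=self.mean_depth if self.mean_depth is not None else base.mean_depth,
            depth_cv=self.depth_cv if self.depth_cv is not None else base.depth_cv,
            dispersion=self.dispersion,
            seed=self.seed,
        )


def _metadata(config: RunConfig) -> dict:
    return {
        "tool": f"lowdetect {__version__}",
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages, writing all outputs under outdir.

    Returns a machine-readable summary (also written as summary.json).
    Stages depend on their predecessors: copynum needs simulate's counts,
    test needs copynum's table; a missing upstream stage is an error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = _metadata(config)
    summary: dict = {"config": config.to_dict(), **meta, "stages": {}}

    panel = make_reference(config.design, seed=config.seed, divergence=config.divergence)
    cohort = None
    counts = None
    table = None

    if "simulate" in config.stages:
        cohort = make_cohort(config.design, loss_profile=config.loss_profile, seed=config.seed)
        counts = simulate_counts(cohort, panel, config.sim_params())
        write_fasta(panel.to_records(), outdir / "panel.fasta")
        write_tsv(cohort.to_frame(), outdir / "cohort.tsv", metadata=meta)
        counts.to_tsv(outdir / "counts.tsv", metadata=meta)
        summary["stages"]["simulate"] = {
            "n_samples": len(cohort),
            "loci": panel.locus_names,
            "total_reads": int(counts.df.values.sum()),
        }

    if "copynum" in config.stages:
        if counts is None or cohort is None:
            raise ParameterError("copynum stage requires the simulate stage (no counts available)")
        table = copy_number_table(
            counts, cohort, panel, calibration_group=config.calibration_group
        )
        write_tsv(table.reset_index(names="sample_id"), outdir / "copy_number.tsv", metadata=meta)
        nestling = table[table["group"] == config.calibration_group]
        summary["stages"]["copynum"] = {
            "calibration_group": config.calibration_group,
            "calibration_median_cn_W": float(nestling["cn_W"].median()),
            "calibration_median_cn_Z": float(nestling["cn_Z"].median()),
        }

    if "test" in config.stages:
        if table is None:
            raise ParameterError("test stage requires the copynum stage (no copy-number table)")
        marker_summaries = {}
        for marker in ("W", "Z"):
            report = test_marker(table, marker=marker, alpha=config.alpha,
                                 outlier_rule=config.outlier_rule)
            write_tsv(report.pairwise, outdir / f"tests_{marker}.tsv", metadata=meta)
            marker_summaries[marker] = {
                "n_comparisons": len(report.pairwise),
                "n_significant": report.n_significant,
                "trend_slope_per_year": report.trend.slope,
                "trend_p": report.trend.p_slope,
                "trend_outliers": list(report.trend.outlier_ids),
            }
        summary["stages"]["test"] = marker_summaries

    if "power" in config.stages:
        group = config.power_group
        if group is None:
            group = "old" if config.design == "booby" else "adult"
        results = power_curve(
            config.design,
            group,
            config.power_f_grid,
            params=config.sim_params(),
            alpha=config.alpha,
            n_reps=config.power_n_reps,
            seed=config.seed,
            calibration_group=config.calibration_group,
        )
        write_tsv(curve_to_frame(results), outdir / "power.tsv", metadata=meta)
        summary["stages"]["power"] = {
            "affected_group": group,
            "power": {str(r.loss_fraction): r.power for r in results},
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
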