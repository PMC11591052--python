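"""End-to-end orchestration: counts -> DE -> length-bias correction, plus
optional extracellular-flux and bench-assay stages, driven by one config.

Also hosts the ng/mL -> uM dose-conversion helper used to relate medium
concentrations to plasma pharmacokinetics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from . import assays as assays_mod
from . import de as de_mod
from . import length_bias as lb
from . import seahorse as sh

logger = logging.getLogger(__name__)

try:
    __version__ = version("ecdymet")
except PackageNotFoundError:  # pragma: no cover - not installed
    __version__ = "unknown"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and constants of one pipeline run."""

    counts: str | None = None
    samples: str | None = None
    gene_meta: str | None = None
    traces: str | None = None
    assay_values: str | None = None
    control_group: str = "control"
    fdr_threshold: float = 0.05
    logfc_threshold: float = 0.1
    prior_count: float = 0.5
    atp_constants: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.logfc_threshold <= 0:
            raise ValueError("logfc_threshold must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunReport:
    """Summary of one pipeline run; serialised as JSON for provenance."""

    version: str
    config: dict
    n_genes_tested: int = 0
    n_up: int = 0
    n_down: int = 0
    correction_model: dict | None = None
    seahorse_summary: list | None = None
    assay_summary: dict | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("differential_expression")
def _run_de_stage(config: PipelineConfig, out: Path, report: RunReport) -> None:
    cm = de_mod.read_counts(config.counts, config.samples)
    de_table = de_mod.run_de(cm, prior_count=config.prior_count)
    de_mod.write_de_table(de_table, out / "de_table.tsv")
    report.n_genes_tested = len(de_table)
    if config.gene_meta:
        meta = pd.read_csv(config.gene_meta, sep="\t")
        corrected, model = lb.correct_table(
            de_table,
            meta,
            fdr_threshold=config.fdr_threshold,
            logfc_threshold=config.logfc_threshold,
        )
        corrected.to_csv(out / "corrected_de_table.tsv", sep="\t")
        (out / "correction_model.txt").write_text(lb.model_summary(model) + "\n")
        report.correction_model = {
            "slope": model.slope,
            "intercept": model.intercept,
            "spearman_rho": model.spearman_rho,
            "pearson_r": model.pearson_r,
            "n_genes": model.n_genes,
        }
        calls = corrected["call"]
        report.n_up = int((calls == lb.CALL_UP).sum())
        report.n_down = int((calls == lb.CALL_DOWN).sum())
    else:
        logger.info("no gene metadata given: skipping length-bias correction")
        sig = (de_table["fdr"] <= config.fdr_threshold)
        report.n_up = int((sig & (de_table["logfc"] >= config.logfc_threshold)).sum())
        report.n_down = int((sig & (de_table["logfc"] <= -config.logfc_threshold)).sum())


@_stage("seahorse_atp")
def _run_seahorse_stage(config: PipelineConfig, out: Path, report: RunReport) -> None:
    traces = sh.read_traces(config.traces)
    rates = sh.phase_rates(traces)
    constants = sh.ATPRateConstants(**config.atp_constants)
    result = sh.atp_rates(rates, constants)
    result.to_csv(out / "atp_rates.tsv", sep="\t", index=False)
    summary = sh.summarize_groups(result, control_group=config.control_group)
    summary.to_csv(out / "atp_summary.tsv", sep="\t", index=False)
    report.seahorse_summary = summary.to_dict(orient="records")


@_stage("assay_stats")
def _run_assay_stage(config: PipelineConfig, out: Path, report: RunReport) -> None:
    table = pd.read_csv(config.assay_values)
    pct = assays_mod.percent_of_control(table, control_group=config.control_group)
    pct.to_csv(out / "assay_percent_of_control.tsv", sep="\t", index=False)
    groups = [g for g in pct["group"].unique() if g != config.control_group]
    ctrl_vals = pct.loc[pct["group"] == config.control_group, "value"]
    tests = {}
    for g in groups:
        res = assays_mod.two_group_test(
            pct.loc[pct["group"] == g, "value"], ctrl_vals, kind="auto"
        )
        tests[g] = {
            "test": res.test_name,
            "statistic": res.statistic,
            "pvalue": res.pvalue,
            "label": res.significance_label,
        }
    report.assay_summary = tests


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage for which the config names inputs; write all outputs.

    Partial configurations produce partial reports: a stage whose inputs are
    absent is skipped and its report fields stay at their empty defaults.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=asdict(config))
    if config.counts and config.samples:
        _run_de_stage(config, out, report)
    if config.traces:
        _run_seahorse_stage(config, out, report)
    if config.assay_values:
        _run_assay_stage(config, out, report)
    assert report.n_up + report.n_down <= max(report.n_genes_tested, 0)
    (out / "run_report.json").write_text(report.to_json() + "\n")
    return report


def mass_to_molar(conc_ng_per_ml: float, molecular_weight_g_per_mol: float) -> float:
    """Convert a mass concentration (ng/mL) to molarity in uM.

    ng/mL equals ug/L, so dividing by the molecular weight in g/mol gives
    umol/L directly. Rounding is for display only (2 decimals).
    """
    if conc_ng_per_ml <= 0 or molecular_weight_g_per_mol <= 0:
        raise ValueError("concentration and molecular weight must be positive")
    return conc_ng_per_ml / molecular_weight_g_per_mol
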