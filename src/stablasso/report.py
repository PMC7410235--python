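"""End-to-end pipeline orchestration and the stability report.

The full analysis runs: load (or simulate) the cohort → LLOD policy →
complete cases → design build → Spearman screen → bootstrap ensemble →
stability summary → rendered report.  Every stage's output plus a manifest
(config, seeds, exclusions, redraws) is written to the output directory;
re-running from the manifest reproduces every artifact byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bootstrap import (
    BootstrapConfig,
    StabilityRecord,
    bootstrap_ensemble,
    summarize_stability,
)
from .correlation import significant_pairs, spearman_matrix
from .preprocess import (
    CohortTable,
    apply_llod_policy,
    build_design,
    complete_cases,
)
from .simulate import SimConfig, generate_cohort, study_like_config, write_truth

logger = logging.getLogger(__name__)

GROUP_LABEL = {"parental": "Parental", "pup": "Pups'", "cytokine": "Cytokines"}
GROUP_ORDER = {"Parental": 0, "Pups'": 1, "Cytokines": 2, "": 3}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the culprit."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    cohort_path: str | None = None
    metadata_path: str | None = None
    simulate: bool = False
    sim_config: SimConfig | None = None
    exclusion_fraction: float = 0.20
    B: int = 500
    vip_threshold: float = 80.0
    ci_level: float = 95.0
    cv_folds: int = 10
    lambda_rule: str = "min"
    alpha: float = 1.0
    n_lambda: int = 100
    lambda_ratio: float = 1e-3
    master_seed: int = 0
    output_dir: str = "stablasso_out"
    ddof: int = 0
    stratified_bootstrap: bool = False
    restandardize: bool = False
    corr_alpha: float = 0.05
    heatmap: bool = False

    def __post_init__(self) -> None:
        for name in ("vip_threshold", "ci_level"):
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name} must be in (0, 100), got {v}")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not self.simulate and self.cohort_path is None:
            raise ValueError("either simulate=True or a cohort path is required")

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim_config is not None:
            d["sim_config"] = dataclasses.asdict(self.sim_config)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("sim_config")
        if sim is not None:
            if sim.get("litter_sizes") is not None:
                sim["litter_sizes"] = tuple(list(s) for s in sim["litter_sizes"])
            if sim.get("pups_per_litter_mean") is not None and not isinstance(
                sim["pups_per_litter_mean"], (int, float)
            ):
                sim["pups_per_litter_mean"] = tuple(sim["pups_per_litter_mean"])
            d["sim_config"] = SimConfig(**sim)
        return cls(**d)


@dataclass
class StabilityReport:
    """Ordered stability rows plus a provenance block."""

    rows: pd.DataFrame  # group, stage, variable, vip, mean_or, ci_low, ci_high, ...
    provenance: dict = field(default_factory=dict)


_STAGE_RE = re.compile(r"^([A-Za-z]+)([0-9.]*)$")


def _stage_key(stage: str) -> tuple:
    """Sort embryonic stages (E...) before postnatal (P...), then numerically."""
    m = _STAGE_RE.match(stage or "")
    if not m or not m.group(2):
        return (2, 0.0, stage)
    prefix = {"E": 0, "P": 1}.get(m.group(1).upper(), 2)
    try:
        num = float(m.group(2))
    except ValueError:
        num = 0.0
    return (prefix, num, stage)


def build_report(
    records: list[StabilityRecord],
    table: CohortTable,
    config: RunConfig,
    provenance: dict | None = None,
) -> StabilityReport:
    """Attach group/stage labels to stability records and sort Table-style:
    parental block, pup block, cytokines; within a block by stage then name."""
    if not records:
        raise PipelineError("report: no stability records")
    rows = []
    for rec in records:
        spec = table.meta.get(rec.variable)
        group = GROUP_LABEL.get(spec.role, "") if spec else ""
        stage = spec.stage if spec else ""
        rows.append(
            {
                "group": group,
                "stage": stage,
                "variable": rec.variable,
                "vip": rec.vip,
                "mean_or": rec.mean_or,
                "ci_low": rec.ci_low,
                "ci_high": rec.ci_high,
                "selected": rec.selected,
                "direction": rec.direction,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["group", "stage", "variable"],
        key=lambda s: (
            s.map(GROUP_ORDER)
            if s.name == "group"
            else s.map(_stage_key)
            if s.name == "stage"
            else s
        ),
        kind="stable",
    ).reset_index(drop=True)
    prov = dict(provenance or {})
    prov.setdefault("software", f"stablasso {__version__}")
    prov.setdefault("config", config.to_json())
    return StabilityReport(rows=df, provenance=prov)


def _fmt_row(r: pd.Series) -> dict:
    return {
        "group": r["group"],
        "stage": r["stage"],
        "variable": r["variable"],
        "vip": f"{r['vip']:.1f}%",
        "mean_or": f"{r['mean_or']:.3f}",
        "ci": f"[{r['ci_low']:.3f},{r['ci_high']:.3f}]",
        "selected": "*" if r["selected"] else "",
        "direction": r["direction"],
    }


def render_report(report: StabilityReport, fmt: str = "tsv") -> str:
    """Render the report as TSV or aligned text; identical numeric strings."""
    if report.rows.empty:
        raise PipelineError("report: refusing to render an empty report")
    formatted = [_fmt_row(r) for _, r in report.rows.iterrows()]
    header = ["Group", "Stage", "Variable", "VIP", "OR", "95% CI", "Flag", "Direction"]
    cells = [
        [f["group"], f["stage"], f["variable"], f["vip"], f["mean_or"], f["ci"],
         f["selected"], f["direction"]]
        for f in formatted
    ]
    if fmt == "tsv":
        lines = ["\t".join(header)] + ["\t".join(c) for c in cells]
        return "\n".join(lines) + "\n"
    if fmt == "text":
        widths = [
            max(len(header[i]), *(len(c[i]) for c in cells)) for i in range(len(header))
        ]
        def fmt_line(parts):
            return "  ".join(p.ljust(w) for p, w in zip(parts, widths)).rstrip()
        lines = [fmt_line(header), fmt_line(["-" * w for w in widths])]
        lines += [fmt_line(c) for c in cells]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")


def run_pipeline(config: RunConfig) -> StabilityReport:
    """Execute the full workflow and write all artifacts to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_json(), "software": f"stablasso {__version__}"}

    # --- load or simulate -------------------------------------------------
    try:
        if config.simulate:
            sim = config.sim_config or study_like_config(seed=config.master_seed)
            table, truth = generate_cohort(sim)
            table.to_tsv(out / "cohort.tsv", out / "cohort_metadata.tsv")
            write_truth(truth, out / "truth.tsv")
        else:
            table = CohortTable.from_tsv(config.cohort_path, config.metadata_path)
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineError(f"load/simulate: {exc}") from exc
    n_raw = len(table.data)

    # --- LLOD policy -------------------------------------------------------
    try:
        table, excluded = apply_llod_policy(table, config.exclusion_fraction)
    except Exception as exc:
        raise PipelineError(f"llod_policy: {exc}") from exc
    manifest["excluded_cytokines"] = excluded

    # --- complete cases ----------------------------------------------------
    try:
        before = set(table.data.index)
        table = complete_cases(table)
        manifest["dropped_subjects"] = sorted(before - set(table.data.index))
    except Exception as exc:
        raise PipelineError(f"complete_cases: {exc}") from exc
    manifest["n_subjects_raw"] = n_raw
    manifest["n_subjects_analyzed"] = len(table.data)

    # --- design ------------------------------------------------------------
    try:
        design = build_design(table, ddof=config.ddof)
    except Exception as exc:
        raise PipelineError(f"build_design: {exc}") from exc
    design.to_tsv(out / "design.tsv", out / "design_scaling.tsv")
    manifest["n_predictors"] = design.p
    manifest["outcome_counts"] = {
        label: int((design.y == code).sum())
        for label, code in design.outcome_coding.items()
    }

    # --- correlation screen -------------------------------------------------
    try:
        corr = spearman_matrix(table)
        corr.to_tsv(out / "correlation_r.tsv", out / "correlation_p.tsv")
        pairs = significant_pairs(corr, config.corr_alpha)
        pd.DataFrame(pairs, columns=["var1", "var2", "r", "p"]).to_csv(
            out / "correlation_significant_pairs.tsv", sep="\t", index=False
        )
        if config.heatmap:
            from .correlation import plot_heatmap

            plot_heatmap(corr, out / "correlation_heatmap.png", config.corr_alpha)
    except Exception as exc:
        raise PipelineError(f"correlation_screen: {exc}") from exc

    # --- bootstrap ensemble -------------------------------------------------
    boot_cfg = BootstrapConfig(
        cv_folds=config.cv_folds,
        n_lambda=config.n_lambda,
        lambda_ratio=config.lambda_ratio,
        alpha=config.alpha,
        lambda_rule=config.lambda_rule,
        stratified=config.stratified_bootstrap,
        restandardize=config.restandardize,
    )
    try:
        ensemble = bootstrap_ensemble(
            design, B=config.B, master_seed=config.master_seed, config=boot_cfg
        )
    except Exception as exc:
        raise PipelineError(f"bootstrap: {exc}") from exc
    ensemble.to_tsv(out)
    manifest["redraw_count"] = ensemble.redraw_count
    manifest["master_seed"] = config.master_seed

    # --- stability summary and report ----------------------------------------
    try:
        records = summarize_stability(
            ensemble, vip_threshold=config.vip_threshold, ci_level=config.ci_level
        )
        report = build_report(records, table, config, provenance=manifest)
    except Exception as exc:
        raise PipelineError(f"stability_summary: {exc}") from exc

    (out / "report.tsv").write_text(render_report(report, "tsv"))
    (out / "report.txt").write_text(render_report(report, "text"))
    report.rows.to_csv(out / "stability_records.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info(
        "pipeline done: %d subjects, %d predictors, %d/%d variables flagged",
        len(table.data), design.p, int(report.rows["selected"].sum()), design.p,
    )
    return report


def run_from_manifest(manifest_path: str | Path) -> StabilityReport:
    """Re-run a pipeline exactly as recorded in a manifest file."""
    manifest = json.loads(Path(manifest_path).read_text())
    config = RunConfig.from_json(manifest["config"])
    return run_pipeline(config)
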