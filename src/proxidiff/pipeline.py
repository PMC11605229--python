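"""End-to-end pipeline: simulate → quantify → score → enrich → modules → integrate.

Every stage writes TSV outputs whose comment headers carry the tool
version, seed and a hash of the configuration, plus a JSON run manifest
and a plain-text summary mirroring the study's reporting structure
(significant sets per condition, Venn counts, sets with >= min_n
interacting proteins, list-overlap test).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, integration, io
from .coexpression import CoexpressionNetwork
from .enrichment import GeneSetEnrichment
from .exceptions import PipelineError, ValidationError
from .interaction import BioIDInteractionModel
from .simulate import (
    BioIDSimConfig,
    ExpressionSimConfig,
    IntensityTable,
    generate_bioid,
    generate_expression,
    planted_set_collection,
)

logger = logging.getLogger(__name__)


def _default_expression_config(seed: int) -> ExpressionSimConfig:
    # three latent-factor modules plus one shifted and two null gene sets;
    # group sizes mirror the emulated myocardium study (16 controls, 86 cases)
    return ExpressionSimConfig.with_layout(
        600,
        module_sizes=[50, 50, 50],
        set_sizes=[("PLANTED_DOWN", 30, -1.0), ("NULL_SET_A", 30, 0.0),
                   ("NULL_SET_B", 30, 0.0)],
        noise_sd=1.0,
        seed=seed,
    )


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "proxidiff_run"
    alpha: float = 0.05
    q_threshold: float = 0.05
    min_n: int = 3
    background_n: int = 20_000
    n_perm: int = 200
    #: optional input paths; simulation fills in whatever is absent
    table_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    bioid: BioIDSimConfig | None = None
    expression: ExpressionSimConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        bioid = raw.pop("bioid", None)
        expression = raw.pop("expression", None)
        config = cls(**raw)
        if bioid is not None:
            config.bioid = BioIDSimConfig(**bioid)
        if expression is not None:
            config.expression = ExpressionSimConfig(**expression)
        return config

    def validate(self) -> None:
        for label, path in [("table_path", self.table_path),
                            ("design_path", self.design_path),
                            ("gmt_path", self.gmt_path)]:
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{label} does not exist: {path}")
        if (self.table_path is None) != (self.design_path is None):
            raise ValidationError("table_path and design_path must be given together")
        if not 0 < self.alpha < 1 or not 0 < self.q_threshold < 1:
            raise ValidationError("alpha and q_threshold must lie in (0, 1)")

    def asdict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _analysis_hash(config: PipelineConfig) -> str:
    # outdir is incidental to the analysis; two runs differing only in
    # where they write are the same run
    params = {k: v for k, v in config.asdict().items() if k != "outdir"}
    return io.config_hash(params)


def _headers(config: PipelineConfig) -> list[str]:
    return [
        f"proxidiff {__version__}",
        f"seed: {config.seed}",
        f"config: {_analysis_hash(config)}",
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict written to the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    headers = _headers(config)
    report: dict = {"version": __version__, "seed": config.seed,
                    "config_hash": _analysis_hash(config),
                    "thresholds": {"alpha": config.alpha,
                                   "q_threshold": config.q_threshold,
                                   "min_n": config.min_n,
                                   "background_n": config.background_n}}

    def stage(name):
        def decorate(func):
            try:
                return func()
            except ValidationError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(name, str(exc)) from exc
        return decorate

    # ---- BioID arm -------------------------------------------------------
    @stage("simulate")
    def table_truth():
        if config.table_path is not None:
            table = IntensityTable.from_tsv(config.table_path, config.design_path)
            return table, None
        bioid = config.bioid or BioIDSimConfig(seed=config.seed)
        table, truth = generate_bioid(bioid)
        table.to_tsv(outdir / "intensities.tsv", outdir / "design.tsv", headers)
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
        return table, truth

    table, truth = table_truth

    @stage("score")
    def interaction_results():
        model = BioIDInteractionModel(table, alpha=config.alpha)
        results = model.fit()
        results.to_tsv(outdir / "interactions.tsv", headers)
        return results

    results = interaction_results
    report["bioid"] = {
        "n_proteins": len(results.frame),
        "n_called": results.n_called,
    }
    if truth is not None:
        report["bioid"]["vs_truth"] = results.confusion(truth)

    # ---- expression arm --------------------------------------------------
    @stage("gsea")
    def enrichment_results():
        expr_config = config.expression or _default_expression_config(config.seed)
        expr, phenotype, _ = generate_expression(expr_config)
        if config.gmt_path is not None:
            sets = io.read_gmt(config.gmt_path)
        else:
            sets = planted_set_collection(expr_config)
        model = GeneSetEnrichment(expr, phenotype, sets)
        fitted = model.fit(n_perm=config.n_perm, seed=config.seed)
        io.write_matrix(fitted.frame.drop(columns="enriched_in").assign(
            enriched_in_case=(fitted.frame["enriched_in"] == "case").astype(int)
        ), outdir / "enrichment.tsv", headers)
        return expr, phenotype, fitted

    expr, phenotype, enrich = enrichment_results
    report["enrichment"] = {
        "n_sets": len(enrich.frame),
        "n_significant": int((enrich.frame["q"] < config.q_threshold).sum()),
    }

    @stage("modules")
    def module_results():
        network = CoexpressionNetwork(expr)
        fitted = network.fit()
        trait = (phenotype == "case").astype(float).to_numpy()
        _, stats = fitted.module_trait(trait)
        fitted.labels.to_frame().to_csv(outdir / "modules.tsv", sep="\t")
        stats.to_csv(outdir / "module_trait.tsv", sep="\t")
        return fitted, stats

    network_results, module_stats = module_results
    report["coexpression"] = {
        "soft_power": network_results.power,
        "n_modules": network_results.n_modules,
    }

    # ---- integration over the packaged disease fixtures ------------------
    @stage("integrate")
    def integrate():
        hallmark = integration.load_hallmark_table()
        sig_idio = integration.significant_sets(hallmark, "idiopathic",
                                                config.q_threshold)
        sig_isch = integration.significant_sets(hallmark, "ischemic",
                                                config.q_threshold)
        venn = integration.venn_compare(sig_idio, sig_isch)
        mapping = integration.fixture_mapping(hallmark)
        min_sets = integration.sets_with_min(mapping, venn.both, config.min_n)
        overlap = integration.overlap_test_counts(
            integration.PUBLISHED_OVERLAP["overlap"],
            integration.PUBLISHED_OVERLAP["size_a"],
            integration.PUBLISHED_OVERLAP["size_b"],
            config.background_n,
        )
        summary = {
            "significant_idiopathic": len(sig_idio),
            "significant_ischemic": len(sig_isch),
            "both": len(venn.both),
            "either": len(venn.either),
            f"both_with_min_{config.min_n}": len(min_sets),
            "overlap_p": overlap.p,
            "overlap_p_published": integration.PUBLISHED_OVERLAP["p"],
        }
        lines = ["# " + h for h in headers]
        lines += [f"{key}\t{value}" for key, value in summary.items()]
        (outdir / "integration.tsv").write_text("\n".join(lines) + "\n")
        return summary

    report["integration"] = integrate

    (outdir / "manifest.json").write_text(json.dumps(report, indent=2, default=str))
    (outdir / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: dict) -> str:
    integ = report["integration"]
    bioid = report["bioid"]
    lines = [
        f"proxidiff {report['version']} (seed {report['seed']})",
        "",
        f"BioID arm: {bioid['n_called']} of {bioid['n_proteins']} proteins "
        "called as corrected-positive interactors",
        f"Enrichment arm: {report['enrichment']['n_significant']} of "
        f"{report['enrichment']['n_sets']} gene sets significant",
        f"Co-expression arm: {report['coexpression']['n_modules']} modules at "
        f"soft power {report['coexpression']['soft_power']}",
        "",
        "Disease gene-set integration (packaged fixtures):",
        f"  significant sets, idiopathic: {integ['significant_idiopathic']}",
        f"  significant sets, ischemic:   {integ['significant_ischemic']}",
        f"  significant in both:          {integ['both']}",
        f"  significant in either:        {integ['either']}",
        f"  list-overlap p (computed):    {integ['overlap_p']:.3g}"
        f"  (published: {integ['overlap_p_published']:.3g})",
    ]
    return "\n".join(lines) + "\n"
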