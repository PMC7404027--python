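"""End-to-end orchestrator: CI -> filter -> DEGs -> modules -> hubs -> enrichment.

``run_all`` chains the analysis stages in dependency order on a bundle
of input tables (read from a :class:`~chillnet.io.PipelineConfig`'s
paths or passed in memory), writes every stage output as TSV under the
configured output directory, and returns a :class:`RunManifest` with
per-stage input/output counts and file checksums so the analysis funnel
(expressed -> DEG -> module -> hub) is auditable.

The module-detection input is the union of DEGs over all pairwise stage
comparisons — a construction rule, not a count target.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .design import SampleDesign
from .enrich import AnnotationTable, hypergeom_enrich
from .expression import deg_union, filter_expressed, sample_correlation
from .hubs import build_network, select_hubs, ssc, stage_zscores
from .injury import GradeCounts, ci_table, read_grade_counts
from .io import (PipelineConfig, file_checksum, read_design_tsv,
                 read_expression_tsv, read_traits_tsv)
from .network import CoexpressionNetwork
from .qpcr import concordance, ddct

__all__ = ["RunManifest", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    outputs: dict[str, str] = field(default_factory=dict)  # path -> checksum
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    started: str
    finished: str = ""
    stages: list[StageRecord] = field(default_factory=list)

    @property
    def stage_names(self) -> list[str]:
        return [s.name for s in self.stages]

    def add(self, name: str, n_in: int, n_out: int, outputs: dict[str, Path]):
        record = StageRecord(
            name=name, n_in=n_in, n_out=n_out,
            outputs={str(p): file_checksum(p) for p in outputs.values()},
        )
        if name in self.stage_names:
            raise RuntimeError(f"stage {name} already recorded")
        self.stages.append(record)
        logger.info("stage %-12s in=%d out=%d", name, n_in, n_out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"stage": s.name, "n_in": s.n_in, "n_out": s.n_out,
             "outputs": ";".join(s.outputs)}
            for s in self.stages
        ])


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    return path


def run_all(
    config: PipelineConfig,
    expression: pd.DataFrame | None = None,
    design: SampleDesign | None = None,
    traits: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    grades: list[GradeCounts] | None = None,
    ct_table: pd.DataFrame | None = None,
) -> RunManifest:
    """Execute the full analysis; inputs may come from config paths or memory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        started=_dt.datetime.now().isoformat(timespec="seconds"),
    )

    if expression is None:
        if config.expression is None:
            raise PipelineError("load", "no expression matrix given")
        expression = read_expression_tsv(config.expression)
    if design is None:
        if config.samples is None:
            raise PipelineError("load", "no sample design given")
        design = read_design_tsv(config.samples)
    design.check_covers(expression.columns)
    if traits is None and config.traits:
        traits = read_traits_tsv(config.traits)
    if annotation is None and config.annotation:
        annotation = pd.read_csv(config.annotation, sep="\t", comment="#")
    if grades is None and config.grades:
        grades = read_grade_counts(config.grades)
    if ct_table is None and config.ct:
        ct_table = pd.read_csv(config.ct, sep="\t", comment="#")

    # 1. chilling-injury scoring ----------------------------------------
    if grades:
        ci = ci_table(grades)
    else:
        ci = pd.DataFrame(columns=["variety", "N", "ci"])
    out = _write(ci, outdir / "ci_index.tsv", index=False)
    manifest.add("ci", len(grades or []), len(ci), {"ci": out})

    # 2. expressed-gene filter ------------------------------------------
    filt = filter_expressed(expression, config.expression_threshold)
    out = _write(filt.kept, outdir / "expression_filtered.tsv")
    manifest.add("filter", expression.shape[0], filt.n_kept, {"expr": out})
    expr = filt.kept

    # 3. sample correlation ---------------------------------------------
    corr = sample_correlation(expr)
    out = _write(corr, outdir / "sample_correlation.tsv")
    manifest.add("sample_corr", expr.shape[1], corr.shape[0], {"corr": out})

    # 4. DEG gating over all pairwise stage comparisons -----------------
    union, per_comparison = deg_union(
        expr, design, alpha=config.de_alpha, fold_change=config.fold_change)
    out = _write(per_comparison, outdir / "deg_counts.tsv", index=False)
    manifest.add("degs", expr.shape[0], len(union), {"degs": out})
    if not union:
        raise PipelineError(
            "modules", "zero DEGs survive the gate; nothing to cluster "
            "(check de_alpha / fold_change)")

    # 5. coexpression modules -------------------------------------------
    deg_matrix = expr.loc[sorted(union)]
    model = CoexpressionNetwork(
        deg_matrix, design,
        power=config.power, signed=config.signed,
        min_module_size=config.min_module_size,
        merge_cut_height=config.merge_cut_height,
    )
    res = model.fit()
    outs = {
        "modules": _write(
            res.partition.labels.rename("module").rename_axis("gene").to_frame(),
            outdir / "modules.tsv"),
        "eigengenes": _write(res.eigengenes, outdir / "eigengenes.tsv"),
        "kme": _write(res.kme_, outdir / "kme.tsv"),
    }
    manifest.add("modules", deg_matrix.shape[0], len(res.module_sizes), outs)

    # 6. module-sample / module-trait correlation -----------------------
    reports = [res.module_sample_correlations()]
    if traits is not None:
        reports.append(res.module_trait_correlations(traits))
    report = pd.concat(reports, ignore_index=True)
    out = _write(report, outdir / "module_correlations.tsv", index=False)
    manifest.add("correlations", len(res.eigengenes), len(report), {"report": out})

    # 7. hub mining ------------------------------------------------------
    summary = stage_zscores(deg_matrix, design)
    specificity = ssc(summary)
    peak = res.preponderant_stages()
    hub_table = select_hubs(
        res.kme_, specificity, res.partition, peak, summary=summary,
        kme_min=config.kme_min, ssc_min=config.ssc_min)
    outs = {"hubs": _write(hub_table, outdir / "hubs.tsv")}
    for module in res.eigengenes.index:
        module_hubs = hub_table.index[
            (hub_table["module"] == module) & hub_table["is_hub"]]
        if len(module_hubs) < 2:
            continue
        net = build_network(
            res.tom_, module_hubs,
            ranking=summary.zscores[peak[module]],
            weight_min=config.weight_min, top_n=config.top_n)
        outs[f"edges_{module}"] = _write(
            net.edges, outdir / f"network_{module}_edges.tsv", index=False)
        outs[f"nodes_{module}"] = _write(
            net.nodes, outdir / f"network_{module}_nodes.tsv", index=False)
    manifest.add("hubs", len(hub_table), int(hub_table["is_hub"].sum()), outs)

    # 8. enrichment per module ------------------------------------------
    enrich_rows = []
    if annotation is not None and len(annotation):
        annot = AnnotationTable.from_frame(annotation)
        for module, members in res.partition.modules.items():
            inside = [g for g in members if g in annot.universe]
            if not inside:
                continue
            table = hypergeom_enrich(inside, annot)
            table.insert(0, "module", module)
            enrich_rows.append(table)
    enrichment = (pd.concat(enrich_rows, ignore_index=True)
                  if enrich_rows else
                  pd.DataFrame(columns=["module", "term", "k", "K", "n", "M", "p", "q"]))
    out = _write(enrichment, outdir / "enrichment.tsv", index=False)
    n_sig = int((enrichment["p"] < config.enrich_alpha).sum()) if len(enrichment) else 0
    manifest.add("enrichment", len(res.module_sizes), n_sig, {"enrichment": out})

    # 9. optional qPCR concordance --------------------------------------
    if ct_table is not None:
        control = config.qpcr_control or str(ct_table["condition"].iloc[0])
        rq = ddct(ct_table, control=control)
        out = _write(rq, outdir / "qpcr_rq.tsv", index=False)
        manifest.add("qpcr", len(ct_table), len(rq), {"rq": out})

    manifest.finished = _dt.datetime.now().isoformat(timespec="seconds")
    _write(manifest.to_frame(), outdir / "manifest.tsv", index=False)
    return manifest
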