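"""Synthetic chilling-stress transcriptome generator with planted truth.

Emulates a 2-genotype x 3-timepoint x 3-replicate cotyledon experiment
(18 samples, 6 stages) with the statistical structure the downstream
analysis assumes:

* planted coexpression modules whose latent stage profile peaks at one
  assigned stage (a standardized one-hot stage indicator scaled by a
  log2-fold amplitude);
* per-gene loadings on that profile — hubs at ``hub_loading``, the rest
  at Normal(0.6 * hub_loading, background_loading_sd) — plus i.i.d.
  Gaussian replicate noise on the log2 scale, exponentiated to an
  FPKM-like skewed scale;
* background genes that are stage-flat noise;
* physiological traits coupled linearly to a module's latent profile;
* a gene -> term annotation with terms planted in one module at a
  configurable odds over the background rate;
* per-variety ordinal injury-grade cohorts drawn from a binomial-thinned
  multinomial: grade ~ Binomial(7, 1 - theta), so theta = 1 concentrates
  at grade 0 and theta = 0 at grade 7.

Everything is deterministic given (config, seed), and a
:class:`SyntheticTruth` records the planted structure for
parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SampleDesign
from .injury import GradeCounts, write_grade_counts

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_expression",
    "generate_grades",
    "generate_traits",
    "generate_annotation",
    "simulate_all",
]

N_SEEDLING_GRADES = 8
BACKGROUND = "background"


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    The defaults emulate the cotyledon chilling-stress design: two
    genotypes of contrasting cold tolerance sampled at 0, 3 and 24 h of
    4 degC stress in three biological replicates, five planted modules
    of 60 genes with 10% hubs, replicate noise of 0.3 on the log2 scale,
    and two grading cohorts whose tolerance parameters put the expected
    chilling-injury indices near 4.5% and 43%.
    """

    n_genes: int = 500
    module_sizes: tuple[int, ...] = (60, 60, 60, 60, 60)
    n_genotypes: int = 2
    n_timepoints: int = 3
    n_replicates: int = 3
    hub_fraction_per_module: float = 0.1
    hub_loading: float = 0.95
    background_loading_sd: float = 0.04
    noise_sd: float = 0.3
    stage_amplitude: float = 1.1      # log2-fold scale of the stage profile
    stage_assignment: dict[str, str] | None = None  # module -> stage label
    trait_coupling: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: {
            "MDA": ("M1", 1.5, 0.2),
            "proline": ("M2", 1.5, 0.2),
            "soluble_sugar": ("M3", 1.5, 0.2),
            "soluble_protein": ("M4", 1.5, 0.2),
            "SAC": ("M5", 1.5, 0.2),
        }
    )
    n_terms: int = 40
    base_annotation_prob: float = 0.05
    enriched_term_plants: tuple[tuple[str, str, float], ...] = (
        ("GO:0009409", "M1", 20.0),   # response to cold
        ("GO:0006979", "M2", 20.0),   # response to oxidative stress
    )
    varieties: tuple[tuple[str, float], ...] = (
        ("tolerant", 0.949),
        ("sensitive", 0.507),
    )
    cohort_size: int = 200
    seed: int = 0

    def __post_init__(self):
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.n_genotypes < 1 or self.n_timepoints < 1 or self.n_replicates < 1:
            raise ValueError("empty design")
        if not 0.0 <= self.hub_fraction_per_module <= 1.0:
            raise ValueError("hub_fraction_per_module must be in [0, 1]")
        if not 0.0 < self.hub_loading <= 1.0:
            raise ValueError("hub_loading must be in (0, 1]")
        for sd_name in ("background_loading_sd", "noise_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be nonnegative")
        for name, theta in self.varieties:
            if not 0.0 <= theta <= 1.0:
                raise ValueError(f"tolerance theta for {name!r} outside [0, 1]")
        for term, module, odds in self.enriched_term_plants:
            if odds < 1.0:
                raise ValueError(f"enrichment odds < 1 for term {term!r}")
        if len(self.enriched_term_plants) > self.n_terms:
            raise ValueError("more planted terms than n_terms")

    # -- derived layout --------------------------------------------------

    @property
    def module_names(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.module_sizes))]

    def design(self) -> SampleDesign:
        genotypes = [f"G{i + 1}" for i in range(self.n_genotypes)]
        timepoints = ["T0", "T3", "T24"][: self.n_timepoints]
        timepoints += [f"TP{i + 1}" for i in range(len(timepoints), self.n_timepoints)]
        return SampleDesign.from_layout(genotypes, timepoints, self.n_replicates)

    def resolved_stage_assignment(self) -> dict[str, str]:
        stages = self.design().stages
        if self.stage_assignment is not None:
            unknown = set(self.stage_assignment.values()) - set(stages)
            if unknown:
                raise ValueError(f"stage labels not in the design: {sorted(unknown)}")
            return dict(self.stage_assignment)
        # round-robin over stages, distinct while modules <= stages
        return {m: stages[i % len(stages)] for i, m in enumerate(self.module_names)}


@dataclass
class SyntheticTruth:
    """Planted structure: the answer key for recovery tests."""

    gene_module: pd.Series               # gene -> module label or "background"
    module_stage: dict[str, str]         # module -> peak stage
    hub_genes: set[str]
    gene_loading: pd.Series              # gene -> loading on its module profile
    latent_eigengenes: pd.DataFrame      # module x sample latent stage profile
    trait_module: dict[str, str]         # trait -> coupled module
    term_module: dict[str, str]          # planted term -> target module

    def members(self, module: str) -> list[str]:
        return list(self.gene_module.index[self.gene_module == module])

    def validate(self) -> None:
        for hub in self.hub_genes:
            if self.gene_module[hub] == BACKGROUND:
                raise AssertionError(f"hub {hub} not a module member")


def _stage_profile(design: SampleDesign, stage: str, amplitude: float) -> np.ndarray:
    """Standardized one-hot stage indicator, scaled to log2-fold units."""
    ind = design.stage_indicator(stage).to_numpy(dtype=float)
    z = (ind - ind.mean()) / ind.std()
    return amplitude * z


def generate_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, SampleDesign, SyntheticTruth]:
    """FPKM-like matrix, design sheet and planted-structure truth table.

    Module gene g with loading lambda_g has
    log2 FPKM = mu_g + lambda_g * e_m + eps, eps ~ N(0, noise_sd), where
    e_m is the module's latent stage profile; background genes are
    mu_g + eps. Values are exponentiated (base 2) to the FPKM scale.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design()
    samples = design.sample_ids
    n_samples = len(samples)
    assignment = config.resolved_stage_assignment()

    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    module_of = pd.Series(BACKGROUND, index=gene_ids, dtype=object)
    loading = pd.Series(0.0, index=gene_ids)
    hubs: set[str] = set()

    profiles = {
        m: _stage_profile(design, assignment[m], config.stage_amplitude)
        for m in config.module_names
    }

    log2x = np.empty((config.n_genes, n_samples))
    cursor = 0
    for m, size in zip(config.module_names, config.module_sizes):
        start = cursor
        members = gene_ids[cursor: cursor + size]
        cursor += size
        n_hubs = int(round(config.hub_fraction_per_module * size))
        lam = np.empty(size)
        lam[:n_hubs] = config.hub_loading
        lam[n_hubs:] = rng.normal(
            0.6 * config.hub_loading, config.background_loading_sd, size - n_hubs)
        lam = np.clip(lam, 0.05, 1.0)
        module_of[members] = m
        loading[members] = lam
        hubs.update(members[:n_hubs])
        mu = rng.normal(3.0, 1.0, size)
        eps = rng.normal(0.0, config.noise_sd, (size, n_samples))
        log2x[start:cursor, :] = mu[:, None] + lam[:, None] * profiles[m][None, :] + eps

    n_bg = config.n_genes - cursor
    if n_bg:
        mu = rng.normal(2.0, 2.0, n_bg)
        eps = rng.normal(0.0, config.noise_sd, (n_bg, n_samples))
        log2x[cursor:, :] = mu[:, None] + eps

    fpkm = pd.DataFrame(np.power(2.0, log2x), index=gene_ids, columns=samples)
    latent = pd.DataFrame(
        {m: profiles[m] for m in config.module_names}, index=samples
    ).T

    truth = SyntheticTruth(
        gene_module=module_of,
        module_stage=assignment,
        hub_genes=hubs,
        gene_loading=loading,
        latent_eigengenes=latent,
        trait_module={t: m for t, (m, _, _) in config.trait_coupling.items()},
        term_module={term: m for term, m, _ in config.enriched_term_plants},
    )
    truth.validate()
    return fpkm, design, truth


def generate_grades(config: SimConfig) -> list[GradeCounts]:
    """Per-variety ordinal injury-grade cohorts.

    Each seedling's grade is Binomial(7, 1 - theta): the grade
    distribution shifts monotonically toward grade 7 as 1 - theta grows,
    with degenerate mass at grade 0 (theta = 1) or grade 7 (theta = 0).
    """
    if config.cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    out = []
    for name, theta in config.varieties:
        grades = rng.binomial(N_SEEDLING_GRADES - 1, 1.0 - theta, config.cohort_size)
        out.append(GradeCounts.from_grades(name, grades.tolist()))
    return out


def generate_traits(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Physiological trait table (samples x traits) coupled to latent profiles."""
    rng = np.random.default_rng(config.seed + 2)
    samples = truth.latent_eigengenes.columns
    cols = {}
    for trait, (module, coef, noise_sd) in config.trait_coupling.items():
        if module not in truth.latent_eigengenes.index:
            raise ValueError(f"trait {trait!r} coupled to unknown module {module!r}")
        e = truth.latent_eigengenes.loc[module].to_numpy(dtype=float)
        # traits couple to the profile's shape, not its amplitude
        e = e / e.std()
        cols[trait] = coef * e + rng.normal(0.0, noise_sd, len(samples))
    return pd.DataFrame(cols, index=samples)


def generate_annotation(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Long gene -> term table with planted enrichment.

    Background: each (gene, term) pair annotated independently at
    ``base_annotation_prob``. Planted terms annotate their target
    module's genes at ``odds`` times the background rate (capped at 1).
    """
    rng = np.random.default_rng(config.seed + 3)
    genes = list(truth.gene_module.index)
    planted = {term: (module, odds) for term, module, odds in config.enriched_term_plants}
    n_background = config.n_terms - len(planted)
    terms = list(planted) + [f"TERM{i + 1:04d}" for i in range(n_background)]
    rows = []
    p0 = config.base_annotation_prob
    for term in terms:
        probs = np.full(len(genes), p0)
        if term in planted:
            module, odds = planted[term]
            in_module = (truth.gene_module == module).to_numpy()
            probs = np.where(in_module, min(1.0, odds * p0), p0)
        hit = rng.random(len(genes)) < probs
        rows.extend({"gene": g, "term": term} for g in np.array(genes)[hit])
    return pd.DataFrame(rows, columns=["gene", "term"])


def simulate_all(config: SimConfig, outdir: str | Path | None = None):
    """Run all four generators; optionally write the TSV input bundle.

    Returns (expression, design, truth, grades, traits, annotation).
    """
    fpkm, design, truth = generate_expression(config)
    grades = generate_grades(config)
    traits = generate_traits(config, truth)
    annotation = generate_annotation(config, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_expression_tsv  # local import to avoid a cycle

        write_expression_tsv(fpkm, outdir / "expression.tsv")
        design.table.drop(columns="stage").to_csv(
            outdir / "samples.tsv", sep="\t", index=False)
        traits.rename_axis("sample_id").to_csv(outdir / "traits.tsv", sep="\t")
        annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        write_grade_counts(grades, outdir / "grades.tsv")
        truth.gene_module.rename("module").rename_axis("gene").to_frame().assign(
            loading=truth.gene_loading,
            is_hub=[g in truth.hub_genes for g in truth.gene_module.index],
        ).to_csv(outdir / "truth_genes.tsv", sep="\t")
        pd.DataFrame(
            {"module": list(truth.module_stage),
             "stage": list(truth.module_stage.values())}
        ).to_csv(outdir / "truth_modules.tsv", sep="\t", index=False)
    return fpkm, design, truth, grades, traits, annotation


# -- recovery metrics ------------------------------------------------------

def module_recovery_ari(truth: SyntheticTruth, labels: pd.Series) -> float:
    """Adjusted Rand index between planted and detected partitions.

    Computed over the genes present in ``labels``; truth background and
    detected "unassigned" each count as a label of their own.
    """
    from sklearn.metrics import adjusted_rand_score

    common = [g for g in labels.index if g in truth.gene_module.index]
    return float(adjusted_rand_score(
        truth.gene_module[common].to_numpy(),
        labels[common].astype(str).to_numpy(),
    ))


def hub_recovery(truth: SyntheticTruth, hub_table: pd.DataFrame) -> tuple[float, float]:
    """(precision, recall) of the detected hub set versus planted hubs."""
    detected = set(hub_table.index[hub_table["is_hub"]])
    planted = set(truth.hub_genes)
    if not detected:
        return 0.0, 0.0
    tp = len(detected & planted)
    return tp / len(detected), tp / len(planted)
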