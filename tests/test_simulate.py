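"""Synthetic-generator contracts: determinism, planted structure, monotonicity."""

import numpy as np
import pandas as pd
import pytest

import chillnet as cn


class TestConfigValidation:
    def test_module_sizes_exceed_genes(self):
        with pytest.raises(ValueError, match="module sizes"):
            cn.SimConfig(n_genes=100, module_sizes=(60, 60))

    def test_empty_design(self):
        with pytest.raises(ValueError, match="empty design"):
            cn.SimConfig(n_replicates=0)

    def test_theta_bounds(self):
        with pytest.raises(ValueError, match="theta"):
            cn.SimConfig(varieties=(("v", 1.2),))

    def test_odds_below_one(self):
        with pytest.raises(ValueError, match="odds"):
            cn.SimConfig(enriched_term_plants=(("T", "M1", 0.5),))

    def test_unknown_stage_assignment(self):
        cfg = cn.SimConfig(stage_assignment={"M1": "nope"})
        with pytest.raises(ValueError, match="stage labels"):
            cfg.resolved_stage_assignment()


class TestExpressionGenerator:
    def test_determinism_byte_identical(self):
        a = cn.generate_expression(cn.SimConfig(seed=7))
        b = cn.generate_expression(cn.SimConfig(seed=7))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_series_equal(a[2].gene_module, b[2].gene_module)
        assert a[2].hub_genes == b[2].hub_genes

    def test_design_layout(self, bundle):
        _, design, _ = bundle
        assert len(design) == 18
        assert len(design.stages) == 6

    def test_zero_noise_hub_proportional_to_profile(self):
        cfg = cn.SimConfig(seed=3, noise_sd=0.0)
        fpkm, _, truth = cn.generate_expression(cfg)
        hub = sorted(truth.hub_genes)[0]
        module = truth.gene_module[hub]
        e = truth.latent_eigengenes.loc[module].to_numpy()
        log2x = np.log2(fpkm.loc[hub].to_numpy())
        centered = log2x - log2x.mean()
        # exact proportionality on the log scale: slope = planted loading
        ratio = centered[np.abs(e) > 1e-12] / e[np.abs(e) > 1e-12]
        np.testing.assert_allclose(ratio, truth.gene_loading[hub], atol=1e-9)

    def test_truth_consistency(self, bundle):
        _, _, truth = bundle
        truth.validate()
        for module, stage in truth.module_stage.items():
            assert len(truth.members(module)) > 0
            e = truth.latent_eigengenes.loc[module]
            # peak of the latent profile sits at the assigned stage
            assert stage in e.idxmax()

    def test_module_recovery_from_planted_structure(self):
        """The spec's downstream recovery contract at the default conditions."""
        cfg = cn.SimConfig(seed=1)
        fpkm, design, truth = cn.generate_expression(cfg)
        res = cn.CoexpressionNetwork(
            fpkm.loc[truth.gene_module != "background"], design).fit()
        assert cn.module_recovery_ari(truth, res.partition.labels) >= 0.8


class TestGradeGenerator:
    def test_theta_one_all_grade_zero(self):
        cfg = cn.SimConfig(seed=0, varieties=(("v", 1.0),))
        (counts,) = cn.generate_grades(cfg)
        assert counts.counts[0] == cfg.cohort_size
        assert cn.ci_index(counts).ci == 0.0

    def test_theta_zero_formula_maximum(self):
        cfg = cn.SimConfig(seed=0, varieties=(("v", 0.0),))
        (counts,) = cn.generate_grades(cfg)
        assert counts.counts[7] == cfg.cohort_size
        assert cn.ci_index(counts).ci == 87.5

    def test_tolerance_ordering_monte_carlo(self):
        """More tolerant variety scores lower CI in >= 99/100 replicates."""
        wins = 0
        for seed in range(100):
            cfg = cn.SimConfig(seed=seed, cohort_size=200,
                               varieties=(("A", 0.9), ("B", 0.2)))
            a, b = cn.generate_grades(cfg)
            if cn.ci_index(a).ci < cn.ci_index(b).ci:
                wins += 1
        assert wins >= 99


class TestTraitGenerator:
    def test_noiseless_unit_coefficient(self):
        cfg = cn.SimConfig(seed=5, trait_coupling={"t": ("M1", 1.0, 0.0)})
        _, _, truth = cn.generate_expression(cfg)
        traits = cn.generate_traits(cfg, truth)
        e = truth.latent_eigengenes.loc["M1"]
        r = np.corrcoef(traits["t"], e)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-6

    def test_null_coupling_pvalues(self):
        """Coefficient 0: trait-eigengene correlation insignificant ~95% of seeds."""
        insig = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = cn.SimConfig(seed=seed, trait_coupling={"t": ("M1", 0.0, 1.0)})
            _, _, truth = cn.generate_expression(cfg)
            traits = cn.generate_traits(cfg, truth)
            e = truth.latent_eigengenes.loc["M1"].to_numpy()
            r = np.corrcoef(traits["t"], e)[0, 1]
            if cn.correlation_pvalue(r, len(e)) > 0.05:
                insig += 1
        assert insig >= 0.88 * n_seeds   # binomial slack around the nominal 95%

    def test_strong_coupling_recovered(self):
        hits = 0
        for seed in range(100):
            cfg = cn.SimConfig(seed=seed, trait_coupling={"t": ("M1", 2.0, 0.2)})
            _, _, truth = cn.generate_expression(cfg)
            traits = cn.generate_traits(cfg, truth)
            e = truth.latent_eigengenes.loc["M1"].to_numpy()
            if abs(np.corrcoef(traits["t"], e)[0, 1]) > 0.9:
                hits += 1
        assert hits >= 90

    def test_unknown_module_rejected(self):
        cfg = cn.SimConfig(seed=0, trait_coupling={"t": ("M9", 1.0, 0.1)})
        _, _, truth = cn.generate_expression(cn.SimConfig(seed=0))
        with pytest.raises(ValueError, match="unknown module"):
            cn.generate_traits(cfg, truth)


class TestAnnotationGenerator:
    def test_empty_term_list(self):
        cfg = cn.SimConfig(seed=0, n_terms=0, enriched_term_plants=())
        _, _, truth = cn.generate_expression(cfg)
        table = cn.generate_annotation(cfg, truth)
        assert table.empty

    def test_planted_odds_enriched(self):
        """odds=20 on a 60-gene module: enrichment p < 1e-4 in >= 95% of seeds."""
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = cn.SimConfig(seed=seed)
            _, _, truth = cn.generate_expression(cfg)
            table = cn.generate_annotation(cfg, truth)
            annot = cn.AnnotationTable.from_frame(
                table, universe=truth.gene_module.index)
            res = cn.hypergeom_enrich(truth.members("M1"), annot).set_index("term")
            if res.loc["GO:0009409", "p"] < 1e-4:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_determinism(self):
        cfg = cn.SimConfig(seed=11)
        _, _, truth = cn.generate_expression(cfg)
        a = cn.generate_annotation(cfg, truth)
        b = cn.generate_annotation(cfg, truth)
        pd.testing.assert_frame_equal(a, b)
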