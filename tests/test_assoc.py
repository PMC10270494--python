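"""NB GLM fits, size factors, BH control and the gene-genus grid."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import gutliver as gl
from gutliver._rng import substream


class TestSizeFactors:
    def test_exact_scaling(self):
        a = pd.DataFrame({"s0": [10, 20, 30], "s1": [20, 40, 60]})
        sf = gl.size_factors(a)
        assert sf["s1"] / sf["s0"] == pytest.approx(2.0)
        assert np.prod(sf) == pytest.approx(1.0)  # geometric mean 1

    def test_identical_samples_give_unit_factors(self):
        a = pd.DataFrame({"s0": [5, 7], "s1": [5, 7], "s2": [5, 7]})
        assert np.allclose(gl.size_factors(a), 1.0)

    def test_matches_median_of_ratios_oracle(self):
        rng = substream(0, "sf")
        mat = rng.integers(1, 500, size=(30, 6)).astype(float)
        counts = pd.DataFrame(mat, columns=[f"s{i}" for i in range(6)])
        sf = gl.size_factors(counts)
        # direct oracle: ratios to geometric reference, median per sample
        logref = np.log(mat).mean(axis=1)
        raw = np.exp(np.median(np.log(mat) - logref[:, None], axis=0))
        oracle = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(sf.to_numpy(), oracle, atol=1e-12)

    def test_fallback_to_library_sizes(self, caplog):
        a = pd.DataFrame({"s0": [0, 10], "s1": [10, 0]})
        with caplog.at_level("WARNING", logger="gutliver"):
            sf = gl.size_factors(a)
        assert "library-size" in caplog.text
        assert np.allclose(sf, 1.0)


class TestNbGlm:
    def test_two_group_closed_form_log_ratio(self):
        """Group means 5 and 50 with a log link: beta1 is exactly ln 10."""
        y = np.array([5.0] * 10 + [50.0] * 10)
        x = np.array([0.0] * 10 + [1.0] * 10)
        fit = gl.nb_glm(y, x)
        assert fit.converged
        assert fit.beta1 == pytest.approx(math.log(10), abs=1e-6)

    def test_group_mean_ratio_property_any_dispersion(self):
        """The log-link MLE reproduces group-mean ratios for noisy NB data."""
        rng = substream(1, "nbmeans")
        y = np.concatenate([rng.negative_binomial(5, 5 / (5 + 20), 15),
                            rng.negative_binomial(5, 5 / (5 + 80), 15)]).astype(float)
        x = np.array([0.0] * 15 + [1.0] * 15)
        fit = gl.nb_glm(y, x)
        assert fit.beta1 == pytest.approx(
            math.log(y[15:].mean() / y[:15].mean()), abs=1e-5)

    def test_poisson_oracle_agreement_in_small_dispersion_limit(self):
        rng = substream(2, "poislim")
        n = 200
        x = rng.uniform(0, 1, n)
        y = rng.poisson(np.exp(2.0 + 1.0 * x)).astype(float)
        fit = gl.nb_glm(y, x)
        oracle = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        assert fit.beta1 == pytest.approx(oracle.params[1], rel=0.01)
        assert fit.beta1 / fit.se1 == pytest.approx(
            oracle.params[1] / oracle.bse[1], rel=0.01)

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="variance"):
            gl.nb_glm(np.arange(6, dtype=float), np.ones(6))

    def test_offset_shifts_intercept_not_slope(self):
        rng = substream(3, "offset")
        x = rng.uniform(0, 1, 60)
        y = rng.poisson(2 * np.exp(1.0 + 0.8 * x)).astype(float)
        f0 = gl.nb_glm(y, x)
        f1 = gl.nb_glm(y, x, offset=np.full(60, math.log(2.0)))
        assert f1.beta1 == pytest.approx(f0.beta1, abs=1e-6)
        assert f1.beta0 == pytest.approx(f0.beta0 - math.log(2.0), abs=1e-6)

    def test_direction_equals_sign_of_beta1(self):
        rng = substream(4, "sign")
        x = rng.uniform(0, 1, 50)
        for b1 in (-1.5, 1.5):
            y = rng.poisson(np.exp(3.0 + b1 * x)).astype(float)
            fit = gl.nb_glm(y, x)
            assert np.sign(fit.z) == np.sign(fit.beta1)


@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
def test_bh_matches_step_up_oracle(pvals):
    """BH q-values match a brute-force step-up implementation."""
    p = np.asarray(pvals)
    q_impl = multipletests(p, method="fdr_bh")[1]
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        q[i] = prev
    assert np.allclose(q_impl, q, atol=1e-12)


N_PLANTED_DE = 12


@pytest.fixture(scope="module")
def planted_de():
    """10 vs 10 samples; the first 12 of 80 genes 4-fold up in group two.

    Most genes must be non-differential for median-of-ratios size factors
    to hold their anchor, as in real transcriptomes.
    """
    rng = substream(5, "de")
    n_genes, fc = 80, 4.0
    base = rng.uniform(np.log(30), np.log(300), n_genes)
    alpha = 0.05
    groups = pd.Series(["NAFLD"] * 10 + ["HCC"] * 10,
                       index=[f"s{i}" for i in range(20)])
    mu = np.exp(base)[:, None] * np.ones((n_genes, 20))
    mu[:N_PLANTED_DE, 10:] *= fc
    lam = rng.gamma(1 / alpha, alpha * mu)
    counts = pd.DataFrame(rng.poisson(lam), index=[f"g{i}" for i in range(n_genes)],
                          columns=groups.index)
    return counts, groups


class TestDifferentialExpression:
    def test_planted_fold_change_recovered(self, planted_de):
        counts, groups = planted_de
        de = gl.differential_expression(counts, groups, ("NAFLD", "HCC"))
        planted = de.iloc[:N_PLANTED_DE]
        assert np.median(planted["log2fc"]) == pytest.approx(2.0, abs=0.3)
        assert (planted["q"] < 0.05).mean() > 0.9

    def test_contrast_relabel_negates_log2fc(self, planted_de):
        counts, groups = planted_de
        a = gl.differential_expression(counts, groups, ("NAFLD", "HCC"))
        b = gl.differential_expression(counts, groups, ("HCC", "NAFLD"))
        assert np.allclose(a["log2fc"], -b["log2fc"], atol=1e-6)

    def test_all_zero_gene_excluded_and_flagged(self, planted_de):
        counts, groups = planted_de
        counts = counts.copy()
        counts.loc["g_zero"] = 0
        de = gl.differential_expression(counts, groups, ("NAFLD", "HCC"))
        assert bool(de.loc["g_zero", "excluded"])
        assert math.isnan(de.loc["g_zero", "q"])

    def test_small_group_errors(self, planted_de):
        counts, groups = planted_de
        with pytest.raises(ValueError, match="n >= 2"):
            gl.differential_expression(counts.iloc[:, :11], groups.iloc[:11],
                                       ("NAFLD", "HCC"))


def _liver_with_spread(seed, n_subjects=14, **kw):
    """Cohort whose liver genus abundances vary strongly across subjects."""
    cfg = gl.SimConfig(
        n_subjects_per_group={"NAFLD": n_subjects, "cirrhosis": n_subjects,
                              "HCC": n_subjects},
        pi_by_group={"NAFLD": {"blood": 0.0, "liver": 0.05},
                     "cirrhosis": {"blood": 0.0, "liver": 0.45},
                     "HCC": {"blood": 0.0, "liver": 0.85}},
        n_genera=25, n_background_taxa=15, depth_feces=5000,
        depth_blood=2000, depth_liver=5000, seed=seed, **kw)
    return cfg, *gl.simulate_cohort(cfg)


class TestGeneGenusGrid:
    def test_planted_pair_found_and_pruned_grid_keeps_it(self):
        cfg, table, truth = _liver_with_spread(
            31, n_genes=12, n_de_genes=0, n_planted_pairs=1, planted_beta1=2.0,
            dispersion_mean=0.02, theta=200.0)
        genes, truth = gl.simulate_transcriptome(cfg, truth, table)
        grid = gl.gene_genus_grid(genes, table, min_nonzero=5)
        gene, genus, _ = truth.planted_pairs.iloc[0]
        hit = grid.records[(grid.records["gene"] == gene)
                           & (grid.records["genus"] == genus)]
        assert bool(hit["significant"].iloc[0])
        assert hit["direction"].iloc[0] == 1
        assert gene in set(grid.pruned["gene"])
        assert genus in set(grid.pruned["genus"])

    def test_min_nonzero_above_n_gives_structured_empty(self):
        cfg, table, _ = _liver_with_spread(32, n_subjects=4, n_genes=6)
        genes_df = pd.DataFrame(
            5, index=["g0"], columns=table.subset(compartment="liver").sample_ids)
        grid = gl.gene_genus_grid(genes_df, table, min_nonzero=10_000)
        assert grid.records.empty
        assert grid.genera_tested == ()

    def test_de_annotation_attached(self):
        cfg, table, truth = _liver_with_spread(
            33, n_genes=15, n_de_genes=5, n_planted_pairs=1, planted_beta1=2.0,
            dispersion_mean=0.02, theta=200.0)
        genes, truth = gl.simulate_transcriptome(cfg, truth, table)
        de = gl.differential_expression(genes, table.meta["group"], ("NAFLD", "HCC"))
        grid = gl.gene_genus_grid(genes, table, de_table=de)
        assert "de_direction" in grid.records.columns
        annotated = grid.records["de_direction"].dropna().unique()
        assert set(annotated) <= {"up", "down"}
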