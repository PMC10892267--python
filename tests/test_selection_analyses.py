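"""ENc-GC3s, PR2, neutrality regression, correlations, expression."""
import numpy as np
import pandas as pd
import pytest

from cubkit import (
    CodonCountTable,
    GeneratorConfig,
    classify_bias,
    correlation_matrix,
    count_codons,
    compute_profiles,
    enc_gc3s_analysis,
    expected_enc,
    expression_correlation,
    generate_cds_set,
    generate_regime,
    neutrality_regression,
    pr2_point,
    profile_frame,
)
from cubkit.errors import UndefinedMetricError
from cubkit.selection_analyses import significance_stars


class TestExpectedEnc:
    @pytest.mark.parametrize("gc3s,expected", [(0.0, 31.0), (0.5, 60.5), (1.0, 32.0)])
    def test_closed_form_values(self, gc3s, expected):
        assert expected_enc(gc3s) == pytest.approx(expected)

    def test_symmetry_about_half(self):
        # f(s) - s is symmetric under s -> 1-s
        for s in np.linspace(0, 1, 21):
            assert expected_enc(s) - s == pytest.approx(expected_enc(1 - s) - (1 - s))

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            expected_enc(bad)


def frame(enc_values, gc3s_values):
    n = len(enc_values)
    return pd.DataFrame({
        "enc": enc_values, "gc3s": gc3s_values,
        "gc12": np.full(n, 0.45), "gc3": np.full(n, 0.5),
    }, index=[f"g{i}" for i in range(n)])


class TestEncGc3sAnalysis:
    def test_weak_bias_fraction_94_of_140(self, worked):
        df = frame(worked.enc_values, np.full(140, 0.48))
        _, summary = enc_gc3s_analysis(df)
        assert summary.n_weak == 94 and summary.n_strong == 0
        assert summary.pct_weak == pytest.approx(67.14, abs=0.005)

    def test_gene_on_the_curve(self):
        df = frame([expected_enc(0.4)], [0.4])
        points, _ = enc_gc3s_analysis(df)
        assert points[0].position == "on" and points[0].residual == pytest.approx(0)

    def test_class_partition(self, worked):
        df = frame(worked.enc_values, np.full(140, 0.48))
        _, s = enc_gc3s_analysis(df)
        assert s.n_strong + s.n_intermediate + s.n_weak == s.n == 140
        assert s.n_below_curve + s.n_on_curve + s.n_above_curve == s.n

    def test_selection_regime_genes_fall_below_curve(self):
        ds = generate_regime(GeneratorConfig(seed=7, n_genes=200), "selection")
        profiles, _ = compute_profiles(ds.cds)
        _, s = enc_gc3s_analysis(profiles)
        assert s.n_below_curve > s.n / 2

    def test_bias_class_thresholds(self):
        assert classify_bias(35.0) == "strong"
        assert classify_bias(42.0) == "intermediate"
        assert classify_bias(50.0) == "weak"


class TestPR2:
    def test_balanced_gene_at_center(self):
        t = CodonCountTable("g", {"GCA": 1, "GCT": 1, "GCG": 1, "GCC": 1})
        p = pr2_point(t)
        assert (p.x, p.y) == (0.5, 0.5)

    def test_t_and_g_ending_extreme(self):
        t = CodonCountTable("g", {"GCT": 3, "GCG": 2})
        p = pr2_point(t)
        assert p.y == 0.0 and p.x == 1.0

    def test_matches_hand_tally(self, code, small_counts):
        t = next(iter(small_counts.values()))
        third = {b: 0 for b in "ACGT"}
        for fam in code.degenerate_families.values():
            for c in fam:
                third[c[2]] += t[c]
        p = pr2_point(t)
        assert p.x == pytest.approx(third["G"] / (third["G"] + third["C"]))
        assert p.y == pytest.approx(third["A"] / (third["A"] + third["T"]))

    def test_fourfold_scope_ignores_twofold_families(self):
        # Lys (AAA/AAG) is 2-fold: present only in the all_synonymous scope
        t = CodonCountTable("g", {"AAA": 5, "GCT": 1, "GCG": 1, "GCA": 1, "GCC": 1})
        assert pr2_point(t, scope="fourfold_only").y == 0.5
        assert pr2_point(t, scope="all_synonymous").y > 0.5

    def test_zero_denominator_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pr2_point(CodonCountTable("g", {"GCT": 2, "GCA": 1}))  # no G/C-ending


class TestNeutralityRegression:
    def test_perfect_line_recovered(self):
        gc3 = np.linspace(0.3, 0.7, 10)
        df = pd.DataFrame({"gc3": gc3, "gc12": 0.10 * gc3 + 0.30})
        fit = neutrality_regression(df)
        assert fit.slope == pytest.approx(0.10, abs=1e-12)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_slope_to_pressure_percentages(self):
        gc3 = np.linspace(0.3, 0.7, 10)
        df = pd.DataFrame({"gc3": gc3, "gc12": 0.1034 * gc3 + 0.3})
        fit = neutrality_regression(df)
        assert fit.mutation_pct == pytest.approx(10.34, abs=1e-9)
        assert fit.selection_pct == pytest.approx(89.66, abs=1e-9)
        assert fit.mutation_pct + fit.selection_pct == pytest.approx(100.0)

    def test_order_invariance(self, small_dataset):
        profiles, _ = compute_profiles(small_dataset.cds)
        df = profile_frame(profiles)
        a = neutrality_regression(df)
        b = neutrality_regression(df.sample(frac=1, random_state=0))
        assert a.slope == pytest.approx(b.slope, abs=1e-12)

    def test_mutation_regime_slope_high(self):
        ds = generate_regime(GeneratorConfig(seed=7, n_genes=500), "mutation")
        profiles, _ = compute_profiles(ds.cds)
        assert neutrality_regression(profiles).slope > 0.5

    def test_selection_regime_slope_low(self):
        ds = generate_regime(GeneratorConfig(seed=7, n_genes=500), "selection")
        profiles, _ = compute_profiles(ds.cds)
        assert neutrality_regression(profiles).slope < 0.15


class TestCorrelationMatrix:
    def test_diagonal_and_antisymmetric_pair(self):
        x = np.linspace(0, 1, 12)
        df = pd.DataFrame({"a": x, "b": -x, "c": x ** 2})
        cm = correlation_matrix(df, indices=("a", "b", "c"))
        assert cm.r.loc["a", "a"] == 1.0
        assert cm.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_symmetry_and_bounds(self, small_dataset):
        profiles, _ = compute_profiles(small_dataset.cds)
        cm = correlation_matrix(profiles)
        assert np.allclose(cm.r.to_numpy(float), cm.r.to_numpy(float).T, equal_nan=True)
        vals = cm.r.to_numpy(float)
        assert np.nanmax(np.abs(vals)) <= 1.0 + 1e-12

    def test_gc_gc3_positive_under_planted_gradient(self):
        genes = []
        for i, g in enumerate(np.linspace(-0.8, 0.8, 30)):
            cfg = GeneratorConfig(seed=100 + i, n_genes=1, gamma=float(g),
                                  bias_strength_max=0.0, bias_baseline=0.0)
            cds = generate_cds_set(cfg).cds[0]
            cds.gene_id = f"z{i:02d}"
            genes.append(cds)
        profiles, _ = compute_profiles(genes)
        cm = correlation_matrix(profiles, indices=("gc", "gc3"))
        assert cm.r.loc["gc", "gc3"] > 0.5
        assert cm.stars.loc["gc", "gc3"] == "***"

    def test_constant_column_marked_undefined(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        cm = correlation_matrix(df, indices=("a", "b"))
        assert np.isnan(cm.r.loc["a", "b"]) and cm.stars.loc["a", "b"] == ""

    def test_star_tiers(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.2) == ""


class TestExpressionCorrelation:
    def test_exact_linear_relationship(self):
        enc_vals = np.linspace(40, 60, 10)
        df = pd.DataFrame({"enc": enc_vals}, index=[f"g{i}" for i in range(10)])
        expr = pd.DataFrame({"normal": -2 * enc_vals + 150}, index=df.index)
        fits = expression_correlation(df, expr)
        assert fits["normal"].pearson_r == pytest.approx(-1.0)
        assert fits["normal"].slope == pytest.approx(-2.0)
        # total == single condition here
        assert fits["total"].slope == pytest.approx(-2.0)

    def test_permuted_expression_uncorrelated(self):
        rng = np.random.default_rng(3)
        enc_vals = rng.uniform(40, 60, 100)
        df = pd.DataFrame({"enc": enc_vals}, index=[f"g{i}" for i in range(100)])
        fpkm = -2 * enc_vals + 150
        expr = pd.DataFrame({"normal": rng.permutation(fpkm)}, index=df.index)
        fits = expression_correlation(df, expr)
        assert abs(fits["normal"].pearson_r) < 0.2

    def test_generator_expression_negatively_tracks_enc(self, small_dataset):
        profiles, _ = compute_profiles(small_dataset.cds)
        fits = expression_correlation(profile_frame(profiles), small_dataset.expression)
        for cond in ("normal", "salinity", "drought", "total"):
            assert fits[cond].pearson_r < 0

    def test_total_is_condition_sum(self, small_dataset):
        profiles, _ = compute_profiles(small_dataset.cds)
        df = profile_frame(profiles)
        expr = small_dataset.expression
        fits = expression_correlation(df, expr)
        manual = expr.sum(axis=1)
        expr2 = expr.copy()
        expr2["total"] = manual
        fits2 = expression_correlation(df, expr2)
        assert fits["total"].slope == pytest.approx(fits2["total"].slope)
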