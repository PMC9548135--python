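"""Compositional and efficiency metric correctness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.spatial.distance import jensenshannon

import contambench as cb
from contambench.profile_metrics import EmptyProfileError
from oracles import jsd_oracle, random_abundance_profile


class TestTotalSumScale:
    def test_simple_normalization(self, profile_factory):
        p = profile_factory([("A", "sequins", 1), ("B", "sequins", 3)])
        assert cb.total_sum_scale(p) == {"A": 0.25, "B": 0.75}

    def test_three_taxa(self, profile_factory):
        p = profile_factory([("A", "sequins", 2), ("B", "sequins", 2),
                             ("C", "kit_contaminant", 6)])
        assert cb.total_sum_scale(p) == {"A": 0.2, "B": 0.2, "C": 0.6}

    def test_label_subset(self, profile_factory):
        p = profile_factory([("A", "sequins", 90),
                             ("X", "kit_contaminant", 10)])
        assert cb.total_sum_scale(p, labels=["sequins"]) == {"A": 1.0}

    def test_empty_selection_rejected(self, profile_factory):
        p = profile_factory([("A", "sequins", 5),
                             ("X", "kit_contaminant", 0)])
        with pytest.raises(EmptyProfileError):
            cb.total_sum_scale(p, labels=["kit_contaminant"])


class TestJSD:
    def test_identity_is_zero(self):
        p = {"a": 0.3, "b": 0.7}
        assert cb.jsd(p, p) == 0.0

    def test_disjoint_supports_are_maximally_distant(self):
        assert cb.jsd({"a": 1.0}, {"b": 1.0}) == pytest.approx(1.0)

    def test_worked_value_against_kl_oracle(self):
        p, q = {"a": 1.0, "b": 0.0}, {"a": 0.5, "b": 0.5}
        expected = jsd_oracle(p, q)
        assert expected == pytest.approx(0.5579230452841438, abs=1e-12)
        assert cb.jsd(p, q) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_on_random_profiles(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = random_abundance_profile(rng, int(rng.integers(1, 8)))
            q = random_abundance_profile(rng, int(rng.integers(1, 8)))
            support = sorted(set(p) | set(q))
            pa = [p.get(t, 0.0) for t in support]
            qa = [q.get(t, 0.0) for t in support]
            assert cb.jsd(p, q) == pytest.approx(
                float(jensenshannon(pa, qa, base=2)), abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p = random_abundance_profile(rng, int(rng.integers(1, 10)))
        q = random_abundance_profile(rng, int(rng.integers(1, 10)))
        d = cb.jsd(p, q)
        assert d == pytest.approx(cb.jsd(q, p), abs=1e-12)
        assert 0.0 <= d <= 1.0


class TestFidelityReproducibility:
    def test_identical_profiles_have_unit_fidelity(self):
        p = {"a": 0.5, "b": 0.5}
        assert cb.fidelity(p, p) == 1.0
        assert cb.reproducibility(p, p) == 1.0

    def test_disjoint_profiles_have_zero_fidelity(self):
        assert cb.fidelity({"a": 1.0}, {"b": 1.0}) == pytest.approx(0.0)

    def test_worked_pair(self):
        got = cb.fidelity({"a": 1.0}, {"a": 0.5, "b": 0.5})
        assert got == pytest.approx(1 - 0.5579230452841438, abs=1e-9)


class TestProportionDesignated:
    def test_mixed_profile(self, profile_factory):
        p = profile_factory([("A", "sequins", 900),
                             ("X", "kit_contaminant", 100)])
        assert cb.proportion_designated(p) == 0.9

    def test_all_sequins(self, profile_factory):
        p = profile_factory([("A", "sequins", 10)])
        assert cb.proportion_designated(p) == 1.0


class TestConversionRate:
    def test_perfect_efficiency_identity(self):
        q = cb.LibraryQuantification(q_library=5 * 2 ** 10, q_input=5,
                                     n_pcr=10, r_designated=1.0)
        assert cb.conversion_rate(q) == pytest.approx(1.0)

    def test_no_designated_reads_means_zero(self):
        q = cb.LibraryQuantification(q_library=100, q_input=5, n_pcr=10,
                                     r_designated=0.0)
        assert cb.conversion_rate(q) == 0.0

    def test_worked_value(self):
        q = cb.LibraryQuantification(q_library=5120, q_input=5, n_pcr=10,
                                     r_designated=0.5)
        assert cb.conversion_rate(q) == pytest.approx(0.5)

    def test_linearity_in_yield_and_designated_fraction(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = cb.LibraryQuantification(
                q_library=float(rng.uniform(1, 1e4)),
                q_input=float(rng.uniform(0.5, 5000)),
                n_pcr=int(rng.integers(1, 20)),
                r_designated=float(rng.uniform(0.01, 1)))
            base = cb.conversion_rate(q)
            q2 = cb.LibraryQuantification(q_library=3 * q.q_library,
                                          q_input=q.q_input, n_pcr=q.n_pcr,
                                          r_designated=q.r_designated)
            assert cb.conversion_rate(q2) == pytest.approx(3 * base)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            cb.conversion_rate(cb.LibraryQuantification(
                q_library=1, q_input=0, n_pcr=1, r_designated=1))


class TestDuplicationRate:
    def test_all_unique_reads(self, profile_factory):
        p = profile_factory([("A", "sequins", 100)],
                            meta={"n_unique_molecules": 100})
        assert cb.duplication_rate(p) == 0.0

    def test_single_molecule(self, profile_factory):
        p = profile_factory([("A", "sequins", 50)],
                            meta={"n_unique_molecules": 1})
        assert cb.duplication_rate(p) == pytest.approx(49 / 50)

    def test_missing_bookkeeping_rejected(self, profile_factory):
        with pytest.raises(ValueError):
            cb.duplication_rate(profile_factory([("A", "sequins", 5)]))

    def test_unique_count_matches_occupancy_expectation(self):
        # E[unique] = M (1 - (1 - 1/M)^D) for D draws from M molecules
        m_pool, draws, reps = 1000, 2000, 200
        rng = np.random.default_rng(2)
        uniques = [np.unique(rng.integers(0, m_pool, draws)).size
                   for _ in range(reps)]
        expected = m_pool * (1 - (1 - 1 / m_pool) ** draws)
        se = np.std(uniques, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(uniques) - expected) < 3 * se


class TestAbundanceBias:
    def test_unbiased_measurement(self):
        p = {"a": 0.4, "b": 0.6}
        assert cb.abundance_bias(p, p) == {"a": 1.0, "b": 1.0}

    def test_worked_ratios(self):
        measured = {"A": 0.5, "B": 0.25, "C": 0.25}
        reference = {"A": 0.25, "B": 0.375, "C": 0.375}
        ratios = cb.abundance_bias(measured, reference)
        assert ratios == pytest.approx({"A": 2.0, "B": 2 / 3, "C": 2 / 3})

    def test_zero_reference_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            ratios = cb.abundance_bias({"a": 0.5, "b": 0.5}, {"a": 1.0})
        assert ratios == {"a": 0.5}

    def test_empty_intersection(self):
        with pytest.warns(UserWarning):
            assert cb.abundance_bias({"a": 1.0}, {"b": 1.0}) == {}


class TestLengthBiasRegression:
    def test_affine_relation_is_perfect_fit(self):
        lengths = {f"c{i}": 2000 + 500 * i for i in range(10)}
        bias = {k: 0.5 + 3e-4 * v for k, v in lengths.items()}
        res = cb.length_bias_regression(bias, lengths)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(3e-4)

    def test_constant_bias_has_zero_slope(self):
        lengths = {f"c{i}": 2000 + 500 * i for i in range(6)}
        bias = {k: 1.0 for k in lengths}
        res = cb.length_bias_regression(bias, lengths)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        lengths = {f"c{i}": float(v) for i, v in
                   enumerate(rng.uniform(1929, 9120, 30))}
        bias = {k: 1 + 1e-4 * v + rng.normal(0, 0.2)
                for k, v in lengths.items()}
        res = cb.length_bias_regression(bias, lengths)
        x = np.array([lengths[k] for k in sorted(lengths)])
        y = np.array([bias[k] for k in sorted(lengths)])
        design = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.lstsq(design, y, rcond=None)[0]
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        resid = y - design @ [slope, intercept]
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cb.length_bias_regression({"a": 1, "b": 2}, {"a": 1.0, "b": 2.0})

    def test_zero_length_variance_rejected(self):
        with pytest.raises(ValueError):
            cb.length_bias_regression({"a": 1, "b": 2, "c": 3},
                                      {"a": 5.0, "b": 5.0, "c": 5.0})


class TestGCShift:
    def test_single_component_shift_is_exactly_zero(self, profile_factory):
        comp = cb.Component(id="X", length_bp=3000, gc=0.5, tier=1,
                            molar_level=1.0, mass_fraction=1.0)
        design = cb.CommunityDesign(components=[comp], n_tiers=1)
        p = profile_factory([("X", "sequins", 1000)])
        assert cb.gc_shift(p, design) == 0.0

    def test_unbiased_simulation_has_near_zero_shift(self, default_design,
                                                     pool_factory, no_endo):
        cfg = cb.LibraryConfig(library_id="x", kit="Tn5_V", input_mass_pg=50,
                               replicate=1, depth=500_000, seed=3)
        p = cb.simulate_library(default_design, cfg,
                                pool_factory(median_pg=0.0), endo=no_endo)
        assert abs(cb.gc_shift(p, default_design)) < 0.01

    def test_negative_gc_coefficient_shifts_low(self, default_design,
                                                pool_factory, no_endo):
        cfg = cb.LibraryConfig(library_id="x", kit="Tn5_V", input_mass_pg=50,
                               replicate=1, depth=500_000, seed=3)
        bias = cb.BiasModel(gc_coefficient=-3.0)
        p = cb.simulate_library(default_design, cfg,
                                pool_factory(median_pg=0.0), bias=bias,
                                endo=no_endo)
        assert cb.gc_shift(p, default_design) < -0.01


class TestRarefy:
    def test_full_depth_is_identity(self, profile_factory):
        p = profile_factory([("A", "sequins", 30), ("B", "sequins", 70)])
        r = cb.rarefy(p, 100, seed=1)
        assert list(r.counts["reads"]) == [30, 70]

    def test_zero_depth_zeroes_everything(self, profile_factory):
        p = profile_factory([("A", "sequins", 30), ("B", "sequins", 70)])
        r = cb.rarefy(p, 0, seed=1)
        assert r.total_depth == 0
        assert list(r.counts["reads"]) == [0, 0]

    def test_depth_beyond_library_rejected(self, profile_factory):
        p = profile_factory([("A", "sequins", 10)])
        with pytest.raises(ValueError):
            cb.rarefy(p, 11, seed=1)

    def test_zero_taxa_stay_zero_and_counts_bounded(self, profile_factory):
        p = profile_factory([("A", "sequins", 40), ("B", "sequins", 0),
                             ("C", "kit_contaminant", 60)])
        for seed in range(20):
            r = cb.rarefy(p, 25, seed=seed)
            assert r.total_depth == 25
            by = dict(zip(r.counts["taxon"], r.counts["reads"]))
            assert by["B"] == 0
            assert by["A"] <= 40 and by["C"] <= 60

    def test_taxon_count_follows_hypergeometric(self, profile_factory):
        # chi-square goodness of fit of one taxon's rarefied count
        p = profile_factory([("A", "sequins", 20), ("B", "sequins", 30)])
        depth, n_draws = 10, 10_000
        counts = np.array([
            dict(zip(cb.rarefy(p, depth, seed=s).counts["taxon"],
                     cb.rarefy(p, depth, seed=s).counts["reads"]))["A"]
            for s in range(n_draws)])
        support = np.arange(0, depth + 1)
        probs = stats.hypergeom.pmf(support, 50, 20, depth)
        observed = np.bincount(counts, minlength=depth + 1)
        keep = probs * n_draws >= 5
        chi2 = ((observed[keep] - n_draws * probs[keep]) ** 2
                / (n_draws * probs[keep])).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.01

    def test_mean_matches_expectation(self, profile_factory):
        p = profile_factory([("A", "sequins", 35), ("B", "sequins", 65)])
        depth = 40
        means = np.mean([
            dict(zip(cb.rarefy(p, depth, seed=s).counts["taxon"],
                     cb.rarefy(p, depth, seed=s).counts["reads"]))["A"]
            for s in range(400)])
        assert means == pytest.approx(35 * depth / 100, abs=0.5)
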