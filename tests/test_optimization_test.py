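import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonopt.alt_codes import build_code, enumerate_triples
from codonopt.code_tables import category_masks, transition_index_arrays
from codonopt.impact_metrics import ImpactTable, category_total, impact_table_from_profiles
from codonopt.optimization_test import (
    ecdf_p,
    ensemble_category_totals,
    metric_correlation,
    run_ensemble_test,
)
from codonopt.synthetic_data import GeneratorConfig, generate_profiles


def naive_ecdf(observed, ensemble):
    return sum(1 for v in ensemble if v <= observed) / len(ensemble)


class TestEcdf:
    def test_basic_example(self):
        assert ecdf_p(2, list(range(1, 11))) == pytest.approx(0.2)

    def test_below_minimum(self):
        assert ecdf_p(-1.0, [0.0, 1.0, 2.0]) == 0.0

    def test_equal_to_maximum_ties_counted(self):
        assert ecdf_p(2.0, [0.0, 1.0, 2.0]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf_p(0.0, [])

    def test_nan_entries_dropped(self):
        assert ecdf_p(1.0, [0.0, np.nan, 2.0]) == pytest.approx(0.5)

    @given(
        st.floats(-5, 5),
        st.lists(
            st.one_of(st.floats(-5, 5), st.integers(-5, 5).map(float)),
            min_size=1,
            max_size=50,
        ),
    )
    def test_matches_naive_oracle(self, observed, ensemble):
        assert ecdf_p(observed, ensemble) == pytest.approx(
            naive_ecdf(observed, ensemble)
        )


@pytest.fixture(scope="module")
def impact_values():
    rng = np.random.default_rng(5)
    v = rng.random(576)
    idx = transition_index_arrays()
    return 0.5 * (v + v[idx["reverse_perm"]])


class TestEnsembleTotals:

    def test_identity_row_matches_canonical(self, canonical, impact_values):
        table = ImpactTable("dFLUX", impact_values)
        totals = ensemble_category_totals(impact_values, ("S", "N"), mode="sum")
        assert totals["S"][0] == pytest.approx(category_total(table, canonical, "S"))
        assert totals["N"][0] == pytest.approx(category_total(table, canonical, "N"))

    def test_oracle_equivalence_on_random_triples(self, canonical, impact_values):
        """Stream path vs explicit code rebuild on 100 random triples."""
        table = ImpactTable("dFLUX", impact_values)
        totals = ensemble_category_totals(
            impact_values, ("S", "N", "SS", "NN", "SN"), mode="sum"
        )
        triples = list(enumerate_triples())
        rng = np.random.default_rng(6)
        for k in rng.choice(len(triples), 100, replace=False):
            alt = build_code(triples[k], canonical)
            for cat in ("S", "N", "SS", "NN", "SN"):
                assert totals[cat][k] == pytest.approx(
                    category_total(table, alt, cat, mode="sum")
                )

    def test_deterministic(self, impact_values):
        a = ensemble_category_totals(impact_values, ("S",), mode="sum")
        b = ensemble_category_totals(impact_values, ("S",), mode="sum")
        assert (a["S"] == b["S"]).all()

    def test_chunk_size_irrelevant(self, impact_values):
        a = ensemble_category_totals(impact_values, ("SN",), chunk_size=1536)
        b = ensemble_category_totals(impact_values, ("SN",), chunk_size=977)
        assert np.allclose(a["SN"], b["SN"])

    def test_multi_table_pass_matches_single(self, impact_values):
        rng = np.random.default_rng(7)
        other = rng.random(576)
        stacked = np.column_stack([impact_values, other])
        multi = ensemble_category_totals(stacked, ("S",), mode="sum")
        single = ensemble_category_totals(other, ("S",), mode="sum")
        assert np.allclose(multi["S"][:, 1], single["S"])

    def test_s_plus_n_equals_total_for_every_code(self, impact_values):
        totals = ensemble_category_totals(impact_values, ("S", "N"), mode="sum")
        assert np.allclose(totals["S"] + totals["N"], impact_values.sum())

    def test_mean_mode_empty_category_is_nan(self):
        ones = np.ones(576)
        means = ensemble_category_totals(ones, ("SS",), mode="mean")["SS"]
        counts = ensemble_category_totals(ones, ("SS",), mode="sum")["SS"]
        assert np.isnan(means[counts == 0]).all()
        assert np.allclose(means[counts > 0], 1.0)


class TestRunEnsembleTest:
    def test_synonymous_neutral_canonical_is_minimal(self, canonical):
        profiles = generate_profiles(
            GeneratorConfig(model="aa_determined", noise_sd=0.0, seed=11)
        )
        table = impact_table_from_profiles(profiles, "dFLUX")
        (result,) = run_ensemble_test(table, categories=("S",))
        assert result.canonical_value == 0.0
        assert result.canonical_value <= np.nanmin(result.ensemble_values)
        assert result.n_alternatives == 13_823

    def test_result_fields_and_p_range(self):
        rng = np.random.default_rng(8)
        table = ImpactTable("dCORR", rng.random(576))
        results = run_ensemble_test(table)
        assert [r.category for r in results] == ["N", "S", "NN", "SN", "SS"]
        for r in results:
            assert 0.0 <= r.empirical_p <= 1.0
            assert r.ensemble_values.size == 13_823
            finite = r.ensemble_values[np.isfinite(r.ensemble_values)]
            assert r.empirical_p == pytest.approx(
                naive_ecdf(r.canonical_value, finite.tolist())
            )

    def test_mode_defaults_follow_metric(self):
        values = np.linspace(0, 1, 576)
        assert run_ensemble_test(ImpactTable("dFLUX", values))[0].mode == "sum"
        assert run_ensemble_test(ImpactTable("dTRX", values))[0].mode == "mean"


class TestMetricCorrelation:
    def test_identical_tables(self):
        rng = np.random.default_rng(9)
        v = rng.random(576)
        t = ImpactTable("dFLUX", v)
        assert metric_correlation(t, t) == pytest.approx(1.0)

    def test_reflected_table_anticorrelates(self):
        rng = np.random.default_rng(10)
        v = rng.random(576)
        a = ImpactTable("dFLUX", v)
        b = ImpactTable("dCORR", v.max() - v)  # negation up to a constant shift
        assert metric_correlation(a, b) == pytest.approx(-1.0)

    def test_independent_tables_near_zero(self):
        rng = np.random.default_rng(11)
        rs = [
            metric_correlation(
                ImpactTable("dFLUX", rng.random(576)),
                ImpactTable("dCORR", rng.random(576)),
            )
            for _ in range(20)
        ]
        # sampling s.d. of r at n=576 is ~0.042
        assert np.mean(np.abs(rs)) < 0.1

    def test_zero_variance_rejected(self):
        flat = ImpactTable("dFLUX", np.ones(576))
        other = ImpactTable("dCORR", np.linspace(0, 1, 576))
        with pytest.raises(ValueError):
            metric_correlation(flat, other)
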