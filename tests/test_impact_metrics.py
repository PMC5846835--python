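import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonopt.alt_codes import enumerate_triples, build_code
from codonopt.code_tables import ALL_CODONS, enumerate_transitions, transition_index_arrays
from codonopt.impact_metrics import (
    CodonMDProfile,
    ImpactTable,
    category_total,
    impact_table_from_profiles,
    summarize_corr,
    summarize_flux,
    transition_impact,
)
from codonopt.synthetic_data import GeneratorConfig, generate_profiles

from conftest import make_profiles


def profile_with(flux, corr=None):
    flux = np.asarray(flux, dtype=float)
    if corr is None:
        corr = np.eye(flux.size)
    return CodonMDProfile(codon="AAA", flux=flux, corr=corr)


class TestSummaries:
    def test_flux_constant(self):
        assert summarize_flux(profile_with([1.0, 1.0, 1.0])) == 1.0

    def test_flux_mean(self):
        assert summarize_flux(profile_with([0.5, 1.5])) == pytest.approx(1.0)

    @given(st.floats(0.1, 10.0))
    def test_flux_scaling_linearity(self, c):
        base = np.array([0.3, 0.7, 1.1])
        assert summarize_flux(profile_with(base * c)) == pytest.approx(
            c * summarize_flux(profile_with(base))
        )

    def test_corr_identity_is_zero(self):
        assert summarize_corr(profile_with([1, 1, 1], np.eye(3))) == 0.0

    def test_corr_all_ones(self):
        assert summarize_corr(profile_with([1, 1], np.ones((2, 2)))) == 1.0

    def test_corr_constant_offdiag(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        assert summarize_corr(profile_with([1, 1, 1], m)) == pytest.approx(0.5)

    def test_flux_sum_option(self):
        assert summarize_flux(profile_with([0.5, 1.5]), stat="sum") == pytest.approx(2.0)
        with pytest.raises(ValueError):
            summarize_flux(profile_with([1.0]), stat="median")

    def test_corr_adjacent_pairs_option(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.4
        m[1, 2] = m[2, 1] = 0.8
        m[0, 2] = m[2, 0] = 0.0
        p = profile_with([1, 1, 1], m)
        assert summarize_corr(p, pairs="adjacent") == pytest.approx(0.6)
        assert summarize_corr(p, pairs="all") == pytest.approx((0.4 + 0.8 + 0.0) / 3)

    def test_corr_rejects_asymmetric(self):
        m = np.eye(3)
        m[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            summarize_corr(profile_with([1, 1, 1], m))

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            CodonMDProfile("AAA", np.array([-0.1, 0.2]), np.eye(2))
        with pytest.raises(ValueError):
            CodonMDProfile("AAA", np.array([0.1, 0.2]), np.eye(3))


class TestTransitionImpact:
    def test_examples(self):
        assert transition_impact(1.2, 1.0) == pytest.approx(0.2)
        assert transition_impact(3.3, 3.3) == 0.0

    @given(st.floats(-100, 100), st.floats(-100, 100))
    def test_symmetry(self, a, b):
        assert transition_impact(a, b) == transition_impact(b, a)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            transition_impact(np.nan, 1.0)


class TestImpactTable:
    def test_shape_enforced(self):
        with pytest.raises(ValueError):
            ImpactTable("dFLUX", np.zeros(100))
        with pytest.raises(ValueError):
            ImpactTable("dFLUX", -np.ones(576))

    def test_reversal_symmetry_from_profiles(self):
        profiles = generate_profiles(GeneratorConfig(model="iid_noise", seed=3))
        table = impact_table_from_profiles(profiles, "dFLUX")
        idx = transition_index_arrays()
        assert np.allclose(table.values, table.values[idx["reverse_perm"]])
        assert (table.values >= 0).all()

    def test_export_frame(self, canonical):
        table = ImpactTable("dCORR", np.arange(576, dtype=float) / 576)
        df = table.as_frame(canonical)
        assert len(df) == 576
        assert set(df["coding_class"]) == {"S", "N"}
        assert set(df["strand_class"]) == {"SS", "NN", "SN"}
        assert list(df.columns) == [
            "from_codon", "to_codon", "position", "coding_class",
            "strand_class", "metric", "value",
        ]

    def test_missing_codon_rejected(self, constant_profiles):
        del constant_profiles["AAA"]
        with pytest.raises(ValueError, match="AAA"):
            impact_table_from_profiles(constant_profiles, "dFLUX")


class TestCategoryTotal:
    def test_constant_sum(self, canonical):
        table = ImpactTable("dFLUX", np.full(576, 0.25))
        from codonopt.code_tables import category_masks

        for cat, mask in category_masks(canonical).items():
            assert category_total(table, canonical, cat, mode="sum") == pytest.approx(
                0.25 * mask.sum()
            )

    def test_constant_mean(self, canonical):
        table = ImpactTable("dTRX", np.full(576, 0.7))
        assert category_total(table, canonical, "S", mode="mean") == pytest.approx(0.7)

    def test_sum_plus_sum_is_total(self, canonical):
        rng = np.random.default_rng(0)
        table = ImpactTable("dFLUX", rng.random(576))
        s = category_total(table, canonical, "S")
        n = category_total(table, canonical, "N")
        assert s + n == pytest.approx(table.values.sum())

    def test_synonymous_neutral_gives_zero(self, canonical):
        profiles = generate_profiles(
            GeneratorConfig(model="aa_determined", noise_sd=0.0, seed=1)
        )
        for metric in ("dFLUX", "dCORR"):
            table = impact_table_from_profiles(profiles, metric)
            assert category_total(table, canonical, "S") == 0.0

    def test_brute_force_oracle_on_alternative_codes(self, canonical):
        """Totals match an oracle that re-classifies transition-by-transition."""
        rng = np.random.default_rng(42)
        values = rng.random(576)
        idx = transition_index_arrays()
        values = 0.5 * (values + values[idx["reverse_perm"]])
        table = ImpactTable("dFLUX", values)
        triples = list(enumerate_triples())
        trans = enumerate_transitions()
        from codonopt.code_tables import classify_transition, strand_classify

        for k in rng.choice(len(triples), 20, replace=False):
            alt = build_code(triples[k], canonical)
            expected = {"S": 0.0, "N": 0.0, "SS": 0.0, "NN": 0.0, "SN": 0.0}
            for t, v in zip(trans, values):
                expected[classify_transition(t, alt)] += v
                expected[strand_classify(t, alt)] += v
            for cat in expected:
                assert category_total(table, alt, cat) == pytest.approx(expected[cat])

    def test_mean_of_empty_category_rejected(self, canonical):
        table = ImpactTable("dTRX", np.zeros(576))
        with pytest.raises(ValueError, match="unknown category"):
            category_total(table, canonical, "XX")
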