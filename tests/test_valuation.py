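import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import esvpipe as ep
from esvpipe.errors import DomainError, SchemaError
from esvpipe.grids import block_regions


def naive_esv(fractions, vc_matrix, cell_area):
    """Independent triple-loop oracle for compute_esv."""
    n_services, n_classes = vc_matrix.shape
    _, rows, cols = fractions.shape
    out = np.zeros((n_services, rows, cols))
    for j in range(n_services):
        for r in range(rows):
            for c in range(cols):
                acc = 0.0
                for i in range(n_classes):
                    acc += fractions[i, r, c] * cell_area * vc_matrix[j, i]
                out[j, r, c] = acc
    return out


class TestEquivalentCorrection:
    def test_unit_standard_equivalent(self):
        # one standard equivalent = 1/7 of grain value: P*Q/A = 7 -> E = E0
        grain = ep.GrainStats(P=7.0, Q=1.0, A=1.0, alpha=1.0)
        assert ep.correct_equivalents(1.0, grain) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        grain = ep.GrainStats(P=2.0, Q=3500.0, A=1.0, alpha=1.39)
        assert ep.correct_equivalents(1.0, grain) == pytest.approx(1390.0)

    def test_linearity_in_price(self):
        e0 = np.array([[1.0, 2.0], [0.5, 3.0]])
        g1 = ep.GrainStats(P=2.0, Q=100.0, A=10.0)
        g2 = ep.GrainStats(P=4.0, Q=100.0, A=10.0)
        np.testing.assert_allclose(
            ep.correct_equivalents(e0, g2), 2.0 * ep.correct_equivalents(e0, g1)
        )

    def test_invalid_grain_stats(self):
        with pytest.raises(ZeroDivisionError):
            ep.GrainStats(P=1.0, Q=1.0, A=0.0)
        with pytest.raises(DomainError):
            ep.GrainStats(P=-1.0, Q=1.0, A=1.0)
        with pytest.raises(DomainError):
            ep.correct_equivalents(-1.0, ep.GrainStats(P=1, Q=1, A=1))


class TestCpiDeflation:
    def test_identity_rebase(self):
        assert ep.deflate_cpi(123.4, ep.CpiSeries(100.0, 100.0)) == pytest.approx(123.4)

    def test_direct_evaluation(self):
        assert ep.deflate_cpi(100.0, ep.CpiSeries(110.0, 100.0)) == pytest.approx(110.0)

    def test_zero_preservation(self):
        assert ep.deflate_cpi(0.0, ep.CpiSeries(137.0, 93.0)) == 0.0

    def test_zero_index_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ep.CpiSeries(100.0, 0.0)


class TestComputeEsv:
    def test_pure_water_hydrological_regulation(self, coeffs, single_class_composition):
        esv = ep.compute_esv(single_class_composition("water"), coeffs, cell_area_hm2=1.0)
        j = ep.SERVICES.index("hydrological_regulation")
        assert esv.values[j, 0, 0] == pytest.approx(24860.6)

    def test_construction_is_worthless(self, coeffs, single_class_composition):
        esv = ep.compute_esv(single_class_composition("construction"), coeffs)
        assert esv.total() == 0.0

    def test_mixed_cell_hand_value(self, coeffs):
        fr = np.zeros((6, 4, 4))
        fr[ep.LAND_CLASSES.index("cropland")] = 0.5
        fr[ep.LAND_CLASSES.index("forestland")] = 0.5
        comp = ep.LandComposition(fr, ep.GridSpec(4, 4), "2015")
        esv = ep.compute_esv(comp, coeffs, cell_area_hm2=1.0)
        j = ep.SERVICES.index("food_production")
        assert esv.values[j, 0, 0] == pytest.approx(0.5 * 1324.5 + 0.5 * 437.1)

    def test_matches_triple_loop_oracle(self, coeffs):
        rng = np.random.default_rng(11)
        spec = ep.GridSpec(4, 5)
        fr = rng.random((6, 4, 5))
        fr = fr / fr.sum(axis=0)
        comp = ep.LandComposition(fr, spec, "2000")
        esv = ep.compute_esv(comp, coeffs, cell_area_hm2=100.0)
        expected = naive_esv(fr, coeffs.matrix, 100.0)
        np.testing.assert_allclose(esv.values, expected, rtol=1e-9)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_homogeneity_in_coefficients(self, scale):
        coeffs = ep.load_coefficients()
        rng = np.random.default_rng(3)
        fr = rng.random((6, 4, 4))
        fr = fr / fr.sum(axis=0)
        comp = ep.LandComposition(fr, ep.GridSpec(4, 4), "2000")
        base = ep.compute_esv(comp, coeffs).total()
        scaled = ep.compute_esv(comp, coeffs.scaled(scale)).total()
        assert scaled == pytest.approx(scale * base, rel=1e-9)

    def test_monotonicity_shift_toward_richer_class(self, coeffs):
        # moving area from cropland to forestland never decreases gas regulation
        j = ep.SERVICES.index("gas_regulation")
        fr = np.zeros((6, 4, 4))
        fr[0] = 0.6
        fr[1] = 0.4
        comp_lo = ep.LandComposition(fr.copy(), ep.GridSpec(4, 4), "y")
        fr2 = fr.copy()
        fr2[0] -= 0.2
        fr2[1] += 0.2
        comp_hi = ep.LandComposition(fr2, ep.GridSpec(4, 4), "y")
        lo = ep.compute_esv(comp_lo, coeffs).values[j].sum()
        hi = ep.compute_esv(comp_hi, coeffs).values[j].sum()
        assert hi >= lo


class TestAggregate:
    def test_region_partition_additivity(self, coeffs, small_bundle):
        esv = ep.compute_esv(small_bundle.compositions["2000"], coeffs)
        regions = block_regions(small_bundle.spec)
        table = ep.aggregate(esv, regions)
        assert table["esv_yuan"].sum() == pytest.approx(esv.total(), rel=1e-12)
        # invariance to the grouping: a different partition, same total
        other = ep.aggregate(esv, block_regions(small_bundle.spec, 2, 2))
        assert other["esv_yuan"].sum() == pytest.approx(esv.total(), rel=1e-12)

    def test_first_level_sums_second_level(self, coeffs, small_bundle):
        esv = ep.compute_esv(small_bundle.compositions["2000"], coeffs)
        second = ep.aggregate(esv, level="second")
        first = ep.aggregate(esv, level="first")
        by_cat = second.groupby("category")["esv_yuan"].sum()
        for _, row in first.iterrows():
            assert row["esv_yuan"] == pytest.approx(by_cat[row["category"]], rel=1e-12)

    def test_unknown_level_rejected(self, coeffs, single_class_composition):
        esv = ep.compute_esv(single_class_composition("water"), coeffs)
        with pytest.raises(SchemaError):
            ep.aggregate(esv, level="third")


def test_coefficient_table_schema_checks():
    bad = pd.DataFrame(
        {"cropland": [1.0]}, index=["food_production"]
    )
    with pytest.raises(SchemaError):
        ep.CoefficientTable(bad)


def test_composition_closure_enforced():
    fr = np.zeros((6, 4, 4))
    fr[0] = 0.9  # does not sum to 1
    with pytest.raises(DomainError):
        ep.LandComposition(fr, ep.GridSpec(4, 4), "2000")
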