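"""Tests for emission rates, TVOC, class totals and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import indoorvoc as iv


class TestEmissionRate:
    def test_zero_net_source(self):
        assert iv.emission_rate(5.0, 5.0, 1.0, 50.0) == 0.0

    def test_worked_example(self):
        """10 ug/m3 excess at ACR 1.3615/h in 50 m3 -> 680.75 ug/h."""
        q = iv.emission_rate(12.0, 2.0, 1.3615, 50.0)
        assert q == pytest.approx(680.75, rel=1e-12)

    @given(
        q_true=st.floats(-1e4, 1e4),
        acr=st.floats(0.05, 5.0),
        vol=st.floats(5.0, 300.0),
        c_out=st.floats(0.0, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_inversion(self, q_true, acr, vol, c_out):
        """Constructing c_in from a known q recovers q exactly."""
        c_in = c_out + q_true / (acr * vol)
        if c_in < 0:
            return
        assert iv.emission_rate(c_in, c_out, acr, vol) == pytest.approx(
            q_true, rel=1e-9, abs=1e-9
        )

    @pytest.mark.parametrize("factor", [0.5, 2.0, 10.0])
    def test_linearity_in_each_argument(self, factor):
        base = iv.emission_rate(12.0, 2.0, 1.0, 50.0)
        assert iv.emission_rate(12.0, 2.0, factor, 50.0) == pytest.approx(factor * base)
        assert iv.emission_rate(12.0, 2.0, 1.0, factor * 50.0) == pytest.approx(factor * base)
        c_in = 2.0 + factor * 10.0  # scale the concentration difference
        assert iv.emission_rate(c_in, 2.0, 1.0, 50.0) == pytest.approx(factor * base)

    def test_negative_q_permitted(self):
        assert iv.emission_rate(1.0, 5.0, 1.0, 50.0) == pytest.approx(-200.0)

    @pytest.mark.parametrize("acr, vol", [(0.0, 50.0), (1.0, 0.0), (-1.0, 50.0)])
    def test_rejects_nonpositive_acr_or_volume(self, acr, vol):
        with pytest.raises(ValueError):
            iv.emission_rate(1.0, 0.5, acr, vol)


class TestTvoc:
    def test_sum(self):
        assert iv.tvoc({"a": 1.0, "b": 2.0, "c": 3.0}) == 6.0

    def test_absent_equals_present_at_zero(self):
        assert iv.tvoc({"a": 1.0, "b": 2.0}) == iv.tvoc({"a": 1.0, "b": 2.0, "c": 0.0})

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iv.tvoc({})

    def test_table_matches_columnwise_oracle(self, small_cohort):
        _, cohort = small_cohort
        _, conc = iv.cohort_to_tables(cohort)
        table = iv.tvoc_table(conc)
        # independent oracle: pivot and sum columns
        wide = conc.pivot(index="home_id", columns="voc", values="indoor_conc")
        oracle = wide.sum(axis=1)
        for _, row in table.iterrows():
            assert row["tvoc"] == pytest.approx(oracle[row["home_id"]], rel=1e-12)


class TestClassTotal:
    @pytest.fixture()
    def records(self):
        return pd.DataFrame(
            {
                "home_id": ["H1", "H1", "H1", "H2", "H2", "H2"],
                "voc": ["alpha-pinene", "limonene", "ethanol"] * 2,
                "q": [10.0, 20.0, 500.0, 1.0, 2.0, 100.0],
            }
        )

    def test_disjoint_members_give_zero(self, records):
        totals = iv.class_total(records, {"benzene"})
        assert (totals == 0.0).all()

    def test_monoterpene_sum(self, records):
        totals = iv.class_total(records, {"alpha-pinene", "limonene"})
        assert totals["H1"] == pytest.approx(30.0)
        assert totals["H2"] == pytest.approx(3.0)

    def test_partition_consistency(self, records):
        """Class totals over a partition of the panel sum to the grand total."""
        mono = iv.class_total(records, {"alpha-pinene", "limonene"})
        rest = iv.class_total(records, {"ethanol"})
        everything = iv.class_total(records, set(records["voc"]))
        np.testing.assert_allclose(mono + rest, everything)

    def test_empty_members_rejected(self, records):
        with pytest.raises(ValueError):
            iv.class_total(records, set())


class TestNormalize:
    def test_endpoints(self):
        records = pd.DataFrame(
            {"home_id": ["H1", "H2"], "voc": ["a", "a"], "q": [10.0, 20.0]}
        )
        out = iv.normalize_emissions(records)
        assert sorted(out["x_hat"]) == [0.0, 1.0]

    def test_bounds_and_extremes_per_voc(self, rng):
        records = pd.DataFrame(
            {
                "home_id": [f"H{i}" for i in range(30)] * 2,
                "voc": ["a"] * 30 + ["b"] * 30,
                "q": np.concatenate([rng.normal(0, 5, 30), rng.lognormal(2, 1, 30)]),
            }
        )
        out = iv.normalize_emissions(records)
        for _, grp in out.groupby("voc"):
            x = grp["x_hat"].to_numpy()
            assert x.min() == 0.0 and x.max() == 1.0
            assert np.all((x >= 0) & (x <= 1))
            assert 0.0 < x.mean() < 1.0

    @given(a=st.floats(0.01, 100.0), b=st.floats(-1000.0, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        q = np.array([3.0, -1.0, 7.5, 0.0, 12.0])
        records = pd.DataFrame(
            {"home_id": [f"H{i}" for i in range(5)], "voc": "v", "q": q}
        )
        mapped = records.assign(q=a * q + b)
        np.testing.assert_allclose(
            iv.normalize_emissions(records)["x_hat"],
            iv.normalize_emissions(mapped)["x_hat"],
            atol=1e-9,
        )

    def test_constant_series_rejected_naming_voc(self):
        records = pd.DataFrame(
            {"home_id": ["H1", "H2"], "voc": ["limonene"] * 2, "q": [5.0, 5.0]}
        )
        with pytest.raises(ValueError, match="limonene"):
            iv.normalize_emissions(records)


class TestSensitivity:
    def test_identity_point(self):
        grid = iv.sensitivity_analysis(100.0, [0.0], [0.0])
        assert grid["q"].iloc[0] == pytest.approx(100.0)

    def test_ten_percent_acr(self):
        grid = iv.sensitivity_analysis(100.0, [0.10], [0.0])
        assert grid["q"].iloc[0] == pytest.approx(110.0)

    def test_full_grid_equals_outer_product_oracle(self):
        q = 42.0
        da = [-0.2, 0.0, 0.1, 0.3]
        dv = [-0.1, 0.0, 0.25]
        grid = iv.sensitivity_analysis(q, da, dv)
        assert len(grid) == len(da) * len(dv)
        for _, row in grid.iterrows():
            # brute-force recomputation from the emission model itself
            c_in, c_out, acr, vol = 12.0, 2.0, 1.0, q / 10.0
            expected = iv.emission_rate(
                c_in, c_out, acr * (1 + row["acr_delta"]),
                vol * (1 + row["volume_delta"]),
            )
            assert row["q"] == pytest.approx(expected, rel=1e-12)

    def test_rejects_degenerate_perturbation(self):
        with pytest.raises(ValueError):
            iv.sensitivity_analysis(1.0, [-1.0], [0.0])


class TestEmissionTable:
    def test_missing_outdoor_rows_skipped(self, small_cohort):
        spec, cohort = small_cohort
        homes, conc = iv.cohort_to_tables(cohort)
        conc = conc.copy()
        conc.loc[conc.index[:5], "outdoor_conc"] = np.nan
        acr = iv.acr_table(cohort, spec.acr_params)
        em = iv.emission_table(conc, acr)
        assert len(em) == len(conc) - 5

    def test_roundtrip_with_generator_truth(self, small_cohort):
        """Emission rates recomputed from generated concentrations and true
        ACR match the table exactly."""
        spec, cohort = small_cohort
        homes, conc = iv.cohort_to_tables(cohort)
        acr = iv.acr_table(cohort, spec.acr_params)
        em = iv.emission_table(conc, acr)
        by_home = {h.home_id: h for h in cohort}
        sample = em.sample(20, random_state=0)
        for _, row in sample.iterrows():
            h = by_home[row["home_id"]]
            v_adj = iv.adjusted_volume(h.volume_raw, spec.acr_params)
            expected = h.true_acr * v_adj * (
                h.indoor_conc[row["voc"]] - h.outdoor_conc[row["voc"]]
            )
            assert row["q"] == pytest.approx(expected, rel=1e-9)
            assert row["negative"] == (expected < 0)
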