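import numpy as np
import pandas as pd
import pytest

import macpolar as mp
from macpolar.errors import DegenerateDataError, ValidationError
from macpolar.cytokine_profile import Spot, SpotGrid, assemble_cytokine_matrix


def grid(spots):
    return SpotGrid("mem1", [Spot(*s) for s in spots])


class TestSpotAggregation:
    def test_equal_duplicates(self):
        g = grid([(0, 0, "IL6", 100), (0, 1, "IL6", 100)])
        assert mp.aggregate_spots(g)["IL6"] == 100.0

    def test_background_subtraction(self):
        g = grid([(0, 0, "IL6", 80), (0, 1, "IL6", 120),
                  (1, 0, "negative", 10), (1, 1, "negative", 10)])
        assert mp.aggregate_spots(g, "negative_control")["IL6"] == 90.0

    def test_background_floors_at_zero(self):
        g = grid([(0, 0, "IL6", 5), (0, 1, "IL6", 5),
                  (1, 0, "negative", 10), (1, 1, "negative", 10)])
        assert mp.aggregate_spots(g, "negative_control")["IL6"] == 0.0

    def test_background_off_by_default(self):
        g = grid([(0, 0, "IL6", 80), (0, 1, "IL6", 120),
                  (1, 0, "negative", 10), (1, 1, "negative", 10)])
        assert mp.aggregate_spots(g)["IL6"] == 100.0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            Spot(0, 0, "IL6", -5)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValidationError, match="coordinates"):
            grid([(0, 0, "IL6", 1), (0, 0, "IL8", 2)])

    def test_unequal_duplicate_counts_rejected(self):
        with pytest.raises(ValidationError, match="duplicate counts"):
            grid([(0, 0, "IL6", 1), (0, 1, "IL6", 2), (0, 2, "IL8", 3)])

    def test_no_analytes_rejected(self):
        with pytest.raises(ValidationError, match="no analyte"):
            mp.aggregate_spots(grid([(0, 0, "negative", 1)]))

    def test_assemble_matrix(self):
        g1 = SpotGrid("A", [Spot(0, 0, "IL6", 10), Spot(0, 1, "IL6", 20)])
        g2 = SpotGrid("B", [Spot(0, 0, "IL6", 30), Spot(0, 1, "IL6", 50)])
        m = assemble_cytokine_matrix([g1, g2])
        assert m.loc["A", "IL6"] == 15 and m.loc["B", "IL6"] == 40

    def test_spot_grid_tsv_reader(self, tmp_path):
        path = tmp_path / "spots.tsv"
        path.write_text("row\tcol\tanalyte\tintensity\n"
                        "0\t0\tIL6\t80\n0\t1\tIL6\t120\n"
                        "1\t0\tnegative\t10\n1\t1\tnegative\t10\n")
        g = mp.read_spot_grid(path, "m")
        assert mp.aggregate_spots(g, "negative_control")["IL6"] == 90.0


class TestNormalize:
    def test_delegates_to_modified_z(self):
        df = pd.DataFrame({"IL6": np.arange(1.0, 9.0)},
                          index=[f"L{i}" for i in range(8)])
        z = mp.normalize_cytokines(df, clip=False)
        med, mad = 4.5, 2.0
        expected = 0.6745 * (np.arange(1.0, 9.0) - med) / mad
        np.testing.assert_allclose(z.z_values["IL6"], expected)

    def test_constant_analyte_warned(self):
        df = pd.DataFrame({"IL6": [3.0] * 8}, index=[f"L{i}" for i in range(8)])
        z = mp.normalize_cytokines(df)
        assert z.mad_zero_features == ["IL6"]

    def test_clip_bounds(self):
        df = pd.DataFrame({"IL6": [1, 2, 3, 4, 1000.0]},
                          index=[f"L{i}" for i in range(5)])
        assert mp.normalize_cytokines(df).z_values["IL6"].abs().max() == 3.5


class TestTopExpressed:
    def make_z(self):
        df = pd.DataFrame({"IL6": [2.0, -1.0], "IL8": [1.0, 0.2],
                           "TNF": [0.4, 3.0]}, index=["A", "B"])
        return mp.ZMatrix(df)

    def test_sorted_by_decreasing_z(self):
        assert mp.top_expressed(self.make_z(), "A") == ["IL6", "IL8"]

    def test_cutoff_is_closed(self):
        assert "IL8" in mp.top_expressed(self.make_z(), "A", cutoff=1.0)

    def test_empty_when_all_below(self):
        assert mp.top_expressed(self.make_z(), "A", cutoff=5.0) == []

    def test_planted_elevation_recovered(self):
        rng = np.random.default_rng(11)
        base = rng.lognormal(6, 0.3, (8, 20))
        df = pd.DataFrame(base, index=[f"L{i}" for i in range(8)],
                          columns=[f"an{i}" for i in range(20)])
        elevated = ["an2", "an5", "an9", "an13", "an17"]
        df.loc["L3", elevated] *= 8.0  # far above +1 MAD in that line
        z = mp.normalize_cytokines(df)
        top = mp.top_expressed(z, "L3", cutoff=1.0)
        # planted analytes are all reported and outrank everything else
        assert set(top[:5]) == set(elevated)
        assert set(elevated) <= set(top)


class TestAssociation:
    def make_pair(self, y_of_x):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        cyt = pd.DataFrame({"IL6": x}, index=[f"L{i}" for i in range(8)])
        mfi = pd.DataFrame({"CD86": y_of_x(x)}, index=cyt.index)
        return cyt, mfi

    def test_perfect_correlation_degenerate_ci(self):
        cyt, mfi = self.make_pair(lambda x: 2 * x)
        out = mp.cytokine_marker_association(cyt, mfi)
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["ci_low"] == row["ci_high"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        cyt, mfi = self.make_pair(lambda x: -3 * x + 7)
        assert mp.cytokine_marker_association(cyt, mfi).iloc[0]["r"] == \
            pytest.approx(-1.0)

    def test_hand_computed_r(self):
        cyt = pd.DataFrame({"IL6": [1.0, 2, 3, 4]}, index=list("abcd"))
        mfi = pd.DataFrame({"CD86": [1.0, 3, 2, 4]}, index=list("abcd"))
        out = mp.cytokine_marker_association(cyt, mfi)
        # covariance/variance sums by hand: r = 4 / sqrt(5 * 5)
        assert out.iloc[0]["r"] == pytest.approx(0.8)

    def test_zero_variance_flagged_not_zeroed(self):
        cyt = pd.DataFrame({"IL6": [5.0] * 8}, index=[f"L{i}" for i in range(8)])
        mfi = pd.DataFrame({"CD86": np.arange(8.0)}, index=cyt.index)
        out = mp.cytokine_marker_association(cyt, mfi)
        assert bool(out.iloc[0]["undefined"]) and np.isnan(out.iloc[0]["r"])

    def test_requires_matching_samples(self):
        cyt = pd.DataFrame({"IL6": [1.0, 2, 3]}, index=["a", "b", "c"])
        mfi = pd.DataFrame({"CD86": [1.0, 2, 3]}, index=["a", "b", "x"])
        with pytest.raises(ValidationError):
            mp.cytokine_marker_association(cyt, mfi)

    def test_small_n_rejected(self):
        cyt = pd.DataFrame({"IL6": [1.0, 2]}, index=["a", "b"])
        mfi = pd.DataFrame({"CD86": [1.0, 2]}, index=["a", "b"])
        with pytest.raises(DegenerateDataError):
            mp.cytokine_marker_association(cyt, mfi)

    def test_q_at_least_p_and_flags_consistent(self):
        cyt, mfi = mp.simulate_cytokine_study(mp.SyntheticConfig(seed=5))
        out = mp.cytokine_marker_association(cyt, mfi)
        ok = ~out["undefined"]
        assert (out.loc[ok, "q"] >= out.loc[ok, "p"] - 1e-12).all()
        assert (out.loc[ok, "significant_raw"] == (out.loc[ok, "p"] < 0.05)).all()
        assert ((out.loc[ok, "ci_low"] <= out.loc[ok, "r"]) &
                (out.loc[ok, "r"] <= out.loc[ok, "ci_high"])).all()

    def test_sign_flip_under_negation(self):
        cyt, mfi = self.make_pair(lambda x: x + np.sin(x))
        r1 = mp.cytokine_marker_association(cyt, mfi).iloc[0]["r"]
        mfi_neg = -mfi + 100  # keeps values positive but reverses direction
        r2 = mp.cytokine_marker_association(cyt, mfi_neg).iloc[0]["r"]
        assert r2 == pytest.approx(-r1)

    def test_ci_coverage_monte_carlo(self, rng):
        # planted rho=0.9, n=8: the Fisher-z 95% CI covers the truth in
        # about 95% of simulations and mean r is near 0.9
        rho, n, sims = 0.9, 8, 1000
        covered, rs = 0, []
        for _ in range(sims):
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
            cyt = pd.DataFrame({"A": 1000 + 100 * x},
                               index=[f"L{i}" for i in range(n)])
            mfi = pd.DataFrame({"M": 1000 + 100 * y}, index=cyt.index)
            row = mp.cytokine_marker_association(cyt, mfi).iloc[0]
            rs.append(row["r"])
            covered += row["ci_low"] <= rho <= row["ci_high"]
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)
        assert 0.90 <= covered / sims <= 0.99

    def test_null_data_fdr_calibration(self, rng):
        # decoupled data: raw-significant fraction near 0.05, and the
        # FDR-significant fraction stays at or below the alpha=0.10 target
        raw_frac, fdr_frac, sims = [], [], 60
        for _ in range(sims):
            cyt = pd.DataFrame(rng.lognormal(6, 0.4, (8, 10)),
                               index=[f"L{i}" for i in range(8)],
                               columns=[f"an{i}" for i in range(10)])
            mfi = pd.DataFrame(rng.lognormal(6, 0.4, (8, 5)),
                               index=cyt.index,
                               columns=[f"mk{i}" for i in range(5)])
            out = mp.cytokine_marker_association(cyt, mfi)
            raw_frac.append(out["significant_raw"].mean())
            fdr_frac.append(out["significant_fdr"].mean())
        assert np.mean(raw_frac) == pytest.approx(0.05, abs=0.03)
        assert np.mean(fdr_frac) <= 0.10
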