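import numpy as np
import pandas as pd
import pytest
import pywt

import oracles
from wavemics import (
    FILTER_BANKS,
    PROFILE_NAMES,
    build_all_profiles,
    build_profile,
    dwt2_single_level,
    matrix_criteria,
    pair_regression,
    reshape_signal,
    whole_signal_criteria,
)


class TestFilterBankSet:
    def test_exactly_31_banks_with_family_counts(self):
        assert len(FILTER_BANKS) == 31
        counts = {
            "bior": sum(b.startswith("bior") for b in FILTER_BANKS),
            "db": sum(b.startswith("db") for b in FILTER_BANKS),
            "sym": sum(b.startswith("sym") for b in FILTER_BANKS),
            "coif": sum(b.startswith("coif") for b in FILTER_BANKS),
        }
        assert counts == {"bior": 11, "db": 8, "sym": 7, "coif": 5}


class TestReshape:
    def test_twelve_values_no_padding(self):
        M, n_pad = reshape_signal(np.arange(12.0))
        assert M.shape == (4, 3) and n_pad == 0

    def test_ten_values_two_pads(self):
        M, n_pad = reshape_signal(np.arange(10.0))
        assert M.shape == (4, 3) and n_pad == 2
        assert M[3, 1] == 0.0 and M[3, 2] == 0.0

    def test_round_trip_on_unpadded_cells(self, rng):
        v = rng.normal(size=11)
        M, n_pad = reshape_signal(v)
        flat = M.ravel()
        np.testing.assert_array_equal(flat[: len(v)], v)

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            reshape_signal(np.ones(3))


class TestDWT2:
    def test_constant_matrix_has_vanishing_details(self):
        _, cH, cV, cD = dwt2_single_level(np.full((4, 4), 3.0), "db2")
        for M in (cH, cV, cD):
            assert np.abs(M).max() < 1e-10

    @pytest.mark.parametrize("bank", ["db2", "sym3", "coif1", "bior2.2"])
    def test_against_convolve_downsample_oracle(self, bank, rng):
        M = rng.integers(0, 10, size=(6, 8)).astype(float)
        wav = pywt.Wavelet(bank)
        lo, hi = np.array(wav.dec_lo), np.array(wav.dec_hi)
        cA, cH, cV, cD = dwt2_single_level(M, bank)
        rA, rH, rV, rD = oracles.dwt2_bf(M, lo, hi)
        np.testing.assert_allclose(cA, rA, atol=1e-10)
        np.testing.assert_allclose(cH, rH, atol=1e-10)
        np.testing.assert_allclose(cV, rV, atol=1e-10)
        np.testing.assert_allclose(cD, rD, atol=1e-10)

    @pytest.mark.parametrize("bank", ["db3", "sym4", "coif2"])
    def test_orthogonal_banks_preserve_energy_periodized(self, bank, rng):
        M = rng.normal(size=(8, 8))
        cA, cH, cV, cD = dwt2_single_level(M, bank, mode="periodization")
        total = sum(float((c**2).sum()) for c in (cA, cH, cV, cD))
        assert total == pytest.approx(float((M**2).sum()), rel=1e-10)

    def test_unknown_bank_rejected_with_list(self):
        with pytest.raises(ValueError, match="bior1.3"):
            dwt2_single_level(np.ones((4, 4)), "db99")


class TestCriteria:
    def test_zero_matrix(self):
        c = matrix_criteria(np.zeros((2, 2)))
        assert c["max"] == 0 and c["energy"] == 0 and c["entropy"] == 0

    def test_symmetric_two_level_matrix(self):
        c = matrix_criteria(np.array([[1.0, -1.0], [1.0, -1.0]]))
        assert c["energy"] == pytest.approx(4.0)
        assert c["entropy"] == pytest.approx(2.0)  # uniform p = 1/4
        assert c["mean"] == 0.0 and c["std"] == 1.0

    def test_against_direct_formulas(self, rng):
        M = rng.normal(size=(3, 3))
        c = matrix_criteria(M)
        x = M.ravel()
        p = x**2 / (x**2).sum()
        assert c["max"] == pytest.approx(x.max(), abs=1e-12)
        assert c["min"] == pytest.approx(x.min(), abs=1e-12)
        assert c["mean"] == pytest.approx(x.mean(), abs=1e-12)
        assert c["median"] == pytest.approx(np.median(x), abs=1e-12)
        assert c["std"] == pytest.approx(x.std(), abs=1e-12)
        assert c["energy"] == pytest.approx((x**2).sum(), abs=1e-12)
        assert c["entropy"] == pytest.approx(-(p * np.log2(p)).sum(), abs=1e-12)


class TestPairRegression:
    def test_exact_linear_relation(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        slope, se = pair_regression(a, 2 * a)
        assert slope == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_independent_detail_slope_near_zero(self, rng):
        a = rng.normal(size=400)
        d = rng.normal(size=400)
        slope, _ = pair_regression(a, d)
        assert abs(slope) < 0.2

    def test_matches_closed_form_ols(self, rng):
        a = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 9.0])
        d = np.array([2.0, 2.5, 5.5, 5.0, 8.5, 10.0])
        slope, se = pair_regression(a, d)
        ref_slope, ref_se = oracles.ols_slope_se_bf(a, d)
        assert slope == pytest.approx(ref_slope, abs=1e-12)
        assert se == pytest.approx(ref_se, abs=1e-12)

    def test_degenerate_constant_ca(self):
        slope, se = pair_regression(np.ones(6), np.arange(6.0))
        assert slope == 0.0 and se == 0.0


class TestWholeSignal:
    def test_constant_vector_zero_waveform_length(self):
        energy, wl = whole_signal_criteria(np.full(5, 2.0))
        assert wl == 0.0 and energy == pytest.approx(20.0)

    def test_alternating_vector(self):
        energy, wl = whole_signal_criteria(np.array([0.0, 1.0, 0.0, 1.0]))
        assert energy == pytest.approx(2.0)
        assert wl == pytest.approx(3.0)

    def test_direct_formulas(self, rng):
        v = rng.normal(size=17)
        energy, wl = whole_signal_criteria(v)
        assert energy == pytest.approx((v**2).sum(), abs=1e-12)
        assert wl == pytest.approx(np.abs(np.diff(v)).sum(), abs=1e-12)


class TestProfile:
    def test_profile_block_structure(self, rng):
        prof = build_profile(rng.normal(size=14), "db5")
        assert len(prof) == 36
        matrix_block = [n for n in PROFILE_NAMES if n.split("_")[1] in
                        ("max", "min", "mean", "median", "std", "entropy", "energy")
                        and n.split("_")[0].startswith("c")]
        regression_block = [n for n in PROFILE_NAMES if n.endswith(("slope", "stderr"))]
        whole_block = [n for n in PROFILE_NAMES if n.startswith("signal_")]
        assert len(matrix_block) == 28
        assert len(regression_block) == 6
        assert len(whole_block) == 2

    def test_scaling_covariance(self, rng):
        v = rng.normal(size=13)
        c = 3.0
        for bank in ("db2", "bior3.1", "sym5", "coif1"):
            p1 = build_profile(v, bank)
            p2 = build_profile(c * v, bank)
            for tag in ("cA", "cH", "cV", "cD"):
                assert p2[f"{tag}_energy"] == pytest.approx(c**2 * p1[f"{tag}_energy"], rel=1e-9)
                assert p2[f"{tag}_max"] == pytest.approx(c * p1[f"{tag}_max"], rel=1e-9)
                assert p2[f"{tag}_std"] == pytest.approx(c * p1[f"{tag}_std"], rel=1e-9)
                assert p2[f"{tag}_entropy"] == pytest.approx(p1[f"{tag}_entropy"], abs=1e-9)
            for tag in ("cH", "cV", "cD"):
                assert p2[f"{tag}_slope"] == pytest.approx(p1[f"{tag}_slope"], abs=1e-9)
            assert p2["signal_energy"] == pytest.approx(c**2 * p1["signal_energy"], rel=1e-12)

    def test_all_profiles_31_tables_aligned_and_deterministic(self, rng):
        table = pd.DataFrame(rng.normal(size=(5, 12)),
                             columns=[f"f{i}" for i in range(12)],
                             index=[f"P{i}" for i in range(5)])
        table["label"] = [0, 1, 0, 1, 0]
        profiles = build_all_profiles(table)
        assert len(profiles) == 31
        for bank, prof in profiles.items():
            assert list(prof.index) == list(table.index)
            assert prof.shape == (5, 37)  # 36 criteria + label
        again = build_all_profiles(table)
        for bank in profiles:
            pd.testing.assert_frame_equal(profiles[bank], again[bank])

    def test_row_permutation_permutes_profiles(self, rng):
        table = pd.DataFrame(rng.normal(size=(4, 8)),
                             columns=[f"f{i}" for i in range(8)],
                             index=list("abcd"))
        shuffled = table.loc[list("dbca")]
        p1 = build_all_profiles(table, banks=("db2",))["db2"]
        p2 = build_all_profiles(shuffled, banks=("db2",))["db2"]
        pd.testing.assert_frame_equal(p1.loc[list("abcd")], p2.loc[list("abcd")])

    def test_identical_rows_give_identical_profiles(self):
        table = pd.DataFrame([[1.0, 2, 3, 4, 5, 6, 7, 8]] * 2,
                             columns=[f"f{i}" for i in range(8)])
        prof = build_all_profiles(table, banks=("sym2",))["sym2"]
        pd.testing.assert_series_equal(prof.iloc[0], prof.iloc[1], check_names=False)
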