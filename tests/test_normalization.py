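"""Normalization, subgroup centering and calibration behaviour."""

import numpy as np
import pandas as pd
import pytest

import bcsubtype as bc
from bcsubtype.normalization import (
    NormalizationError,
    build_sgpct_reference,
    fit_calibration_factors,
    read_calibration,
    read_reference,
    write_calibration,
    write_reference,
)


def _matrix(values, scale="log_generic", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return bc.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale)


class TestLog2Cpm:
    def test_single_sample_by_definition(self):
        m = _matrix([[750000.0], [250000.0]], "counts")
        out = bc.log2_cpm(m)
        np.testing.assert_allclose(
            out.values[:, 0], np.log2(np.array([750000.0, 250000.0]) + 1)
        )
        assert out.scale == "log2cpm"

    def test_all_zero_gene_maps_to_zero(self):
        m = _matrix([[0.0, 0.0], [10.0, 20.0]], "counts")
        out = bc.log2_cpm(m)
        np.testing.assert_array_equal(out.values[0], [0.0, 0.0])

    def test_cpm_columns_sum_to_million(self, count_matrix):
        out = bc.log2_cpm(count_matrix)
        cpm = 2.0 ** out.values - 1.0
        np.testing.assert_allclose(cpm.sum(axis=0), 1e6, atol=1e-6)

    def test_zero_library_size_names_sample(self):
        m = _matrix([[0.0, 5.0], [0.0, 5.0]], "counts", samples=["empty", "ok"])
        with pytest.raises(NormalizationError, match="empty"):
            bc.log2_cpm(m)


class TestQuantileNormalize:
    def test_hand_computed_three_by_two(self):
        # sorted columns: [2,3,5] and [1,2,4] -> reference [1.5, 2.5, 4.5]
        m = _matrix([[5.0, 4.0], [2.0, 1.0], [3.0, 2.0]])
        out = bc.quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[4.5, 4.5], [1.5, 1.5], [2.5, 2.5]])

    def test_permuted_samples_share_sorted_reference(self, rng):
        col = rng.normal(size=30)
        m = _matrix(np.column_stack([col, rng.permutation(col)]))
        out = bc.quantile_normalize(m)
        np.testing.assert_allclose(
            np.sort(out.values[:, 0]), np.sort(out.values[:, 1]), atol=1e-12
        )

    def test_sorted_columns_identical(self, random_matrix):
        out = bc.quantile_normalize(random_matrix)
        s = np.sort(out.values, axis=0)
        np.testing.assert_allclose(s, s[:, [0]] * np.ones((1, s.shape[1])), atol=1e-12)

    def test_idempotent(self, random_matrix):
        once = bc.quantile_normalize(random_matrix)
        twice = bc.quantile_normalize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_ties_receive_mean_of_spanned_reference(self):
        m = _matrix([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]])
        out = bc.quantile_normalize(m)
        ref = np.sort(m.values, axis=0).mean(axis=1)
        # first column has the two smallest values tied
        np.testing.assert_allclose(out.values[:2, 0], ref[:2].mean())

    def test_single_sample_rejected(self):
        with pytest.raises(NormalizationError):
            bc.quantile_normalize(_matrix([[1.0], [2.0]]))


class TestUqFpkm:
    def test_count_equal_to_upper_quartile_gives_one(self):
        # single protein-coding gene of length 1000 bp: UQ equals its own count
        m = _matrix([[800.0]], "counts", genes=["g0"])
        lengths = pd.Series([1000], index=["g0"])
        coding = pd.Series([True], index=["g0"])
        out = bc.uq_fpkm(m, lengths, coding)
        np.testing.assert_allclose(out.values, np.log2(2.0))  # pre-log value 1

    def test_library_scale_invariance(self, rng):
        counts = rng.poisson(100, (20, 3)).astype(float) + 1
        genes = [f"g{i}" for i in range(20)]
        lengths = pd.Series(rng.integers(500, 5000, 20), index=genes)
        coding = pd.Series(rng.random(20) < 0.7, index=genes)
        coding.iloc[0] = True
        a = bc.uq_fpkm(_matrix(counts, "counts", genes=genes), lengths, coding)
        b = bc.uq_fpkm(_matrix(2 * counts, "counts", genes=genes), lengths, coding)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_matches_brute_force(self, rng):
        counts = rng.poisson(50, (20, 4)).astype(float)
        genes = [f"g{i}" for i in range(20)]
        lengths = pd.Series(rng.integers(200, 3000, 20), index=genes)
        coding = pd.Series([True] * 12 + [False] * 8, index=genes)
        out = bc.uq_fpkm(_matrix(counts, "counts", genes=genes), lengths, coding)
        for j in range(4):
            uq = np.percentile(counts[:12, j], 75)
            expected = np.log2(counts[:, j] / (lengths.to_numpy() / 1e3 * uq) + 1)
            np.testing.assert_allclose(out.values[:, j], expected, atol=1e-12)

    def test_zero_upper_quartile_names_sample(self):
        m = _matrix([[0.0], [5.0]], "counts", genes=["pc", "other"], samples=["bad"])
        with pytest.raises(NormalizationError, match="bad"):
            bc.uq_fpkm(
                m,
                pd.Series([1000, 1000], index=["pc", "other"]),
                pd.Series([True, False], index=["pc", "other"]),
            )


class TestHousekeeping:
    def test_constant_housekeeping_subtracts_constant(self):
        m = _matrix([[3.0, 7.0], [3.0, 7.0], [10.0, 1.0]], genes=["hk1", "hk2", "g"])
        out = bc.housekeeping_normalize(m, ["hk1", "hk2"])
        np.testing.assert_allclose(out.values[2], [7.0, -6.0])

    def test_housekeeping_mean_is_zero(self, random_matrix):
        hk = random_matrix.gene_ids[:8]
        out = bc.housekeeping_normalize(random_matrix, hk)
        np.testing.assert_allclose(out.data.loc[hk].mean(axis=0), 0.0, atol=1e-12)

    def test_per_sample_offset_invariance(self, random_matrix, rng):
        hk = random_matrix.gene_ids[:8]
        offsets = rng.normal(0, 5, random_matrix.n_samples)
        shifted = random_matrix.with_values(random_matrix.values + offsets[None, :])
        a = bc.housekeeping_normalize(random_matrix, hk)
        b = bc.housekeeping_normalize(shifted, hk)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_missing_gene_listed(self, random_matrix):
        with pytest.raises(NormalizationError, match="nope"):
            bc.housekeeping_normalize(random_matrix, ["nope"])


class TestSgPct:
    def test_full_cohort_subgroup_maps_median_to_fifty(self, rng):
        m = _matrix(rng.normal(size=(10, 9)))  # odd sample count
        ref = build_sgpct_reference(m, np.ones(9, dtype=bool))
        np.testing.assert_allclose(ref.mapped_percentile, 50.0, atol=1e-9)

    def test_interpolated_percentile_oracle(self):
        # cohort 1..10 (median 5.5); subgroup {4,5,6,7,8}
        vals = np.arange(1.0, 11.0)[None, :]
        m = _matrix(vals, genes=["g"], samples=[f"s{i}" for i in range(10)])
        mask = np.isin(vals[0], [4, 5, 6, 7, 8])
        ref = build_sgpct_reference(m, mask)
        # subgroup order stats at percentiles [0,25,50,75,100]; 5.5 sits
        # halfway between 5 (25th) and 6 (50th)
        np.testing.assert_allclose(ref.mapped_percentile, [37.5], atol=1e-9)
        np.testing.assert_allclose(ref.global_median, [5.5])

    def test_clamped_to_zero_when_median_below_subgroup(self):
        vals = np.array([[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]])
        m = _matrix(vals, genes=["g"])
        mask = np.array([False, False, False, True, True, True])
        ref = build_sgpct_reference(m, mask)
        np.testing.assert_allclose(ref.mapped_percentile, [0.0])
        assert ref.clamped[0]

    def test_small_subgroup_rejected(self, random_matrix):
        mask = np.zeros(random_matrix.n_samples, dtype=bool)
        mask[0] = True
        with pytest.raises(NormalizationError):
            build_sgpct_reference(random_matrix, mask)

    def test_center_at_fifty_equals_median_centering(self, random_matrix, rng):
        ref_m = _matrix(rng.normal(size=(20, 9)), genes=random_matrix.gene_ids)
        ref = build_sgpct_reference(ref_m, np.ones(9, dtype=bool))
        out = bc.sgpct_center(random_matrix, ref)
        expected = random_matrix.values - np.median(random_matrix.values, axis=1, keepdims=True)
        np.testing.assert_allclose(out.values, expected, atol=1e-9)
        assert out.scale == "centered"

    def test_constant_gene_centers_to_zero(self, rng):
        ref_m = _matrix(rng.normal(size=(1, 9)), genes=["g"])
        ref = build_sgpct_reference(ref_m, np.ones(9, dtype=bool))
        test = _matrix(np.full((1, 5), 3.14), genes=["g"])
        out = bc.sgpct_center(test, ref)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_self_consistency_subtracts_global_median(self, scenario):
        """Centering the reference subgroup itself removes the global median."""
        sub = scenario.reference.data.loc[:, scenario.subgroup_mask]
        sub_m = bc.ExpressionMatrix(sub, scenario.reference.scale)
        out = bc.sgpct_center(sub_m, scenario.sgpct_reference)
        recovered = sub_m.values - out.values  # the subtracted per-gene center
        ok = ~scenario.sgpct_reference.clamped
        np.testing.assert_allclose(
            recovered[ok, 0], scenario.sgpct_reference.global_median[ok], atol=1e-9
        )

    def test_reference_round_trip(self, tmp_path, scenario):
        path = tmp_path / "ref.tsv"
        write_reference(scenario.sgpct_reference, path)
        back = read_reference(path)
        np.testing.assert_allclose(
            back.mapped_percentile, scenario.sgpct_reference.mapped_percentile, atol=1e-12
        )
        np.testing.assert_allclose(
            back.subgroup_median, scenario.sgpct_reference.subgroup_median, atol=1e-12
        )


class TestSgMd:
    def _ref(self, rng, genes):
        m = _matrix(rng.normal(2, 1, size=(len(genes), 20)), genes=genes)
        return build_sgpct_reference(m, np.ones(20, dtype=bool)), m

    def test_fixed_point_when_medians_match(self, rng):
        genes = [f"g{i}" for i in range(5)]
        ref, ref_m = self._ref(rng, genes)
        # a test cohort whose per-gene medians already equal the subgroup medians
        test = _matrix(
            ref.subgroup_median[:, None] + np.array([[-1.0, 0.0, 1.0]]), genes=genes
        )
        out = bc.sgmd_center(test, ref)
        np.testing.assert_allclose(out.values, test.values, atol=1e-12)

    def test_post_centering_medians_hit_target(self, rng, random_matrix):
        ref, _ = self._ref(rng, random_matrix.gene_ids)
        out = bc.sgmd_center(random_matrix, ref)
        np.testing.assert_allclose(
            np.median(out.values, axis=1), ref.subgroup_median, atol=1e-12
        )

    def test_shifted_copy_recovers_original(self, rng):
        genes = [f"g{i}" for i in range(8)]
        ref, ref_m = self._ref(rng, genes)
        shift = rng.normal(0, 3, 8)
        shifted = ref_m.with_values(ref_m.values + shift[:, None])
        out = bc.sgmd_center(shifted, ref)
        np.testing.assert_allclose(out.values, ref_m.values, atol=1e-10)


class TestCalibration:
    def test_identity_factors(self, random_matrix):
        f = bc.CalibrationFactors(
            random_matrix.gene_ids, np.ones(20), np.zeros(20)
        )
        out = bc.apply_technical_calibration(random_matrix, f)
        np.testing.assert_array_equal(out.values, random_matrix.values)

    def test_inverse_composition(self, random_matrix, rng):
        f = bc.CalibrationFactors(
            random_matrix.gene_ids,
            np.exp(rng.normal(0, 0.3, 20)),
            rng.normal(0, 1, 20),
        )
        out = bc.apply_technical_calibration(
            bc.apply_technical_calibration(random_matrix, f), f.inverse()
        )
        np.testing.assert_allclose(out.values, random_matrix.values, atol=1e-10)

    def test_fitted_factors_recover_source_within_noise(self, rng):
        """Paired-platform fit: distorted -> noisy reference, then invert."""
        genes = [f"g{i}" for i in range(30)]
        clean = rng.normal(8, 2, (30, 200))
        scale = np.exp(rng.normal(0, 0.2, 30))
        shift = rng.normal(0, 1, 30)
        tau = 0.3
        distorted = _matrix(scale[:, None] * clean + shift[:, None], genes=genes)
        noisy_ref = _matrix(clean + rng.normal(0, tau, clean.shape), genes=genes)
        factors = fit_calibration_factors(distorted, noisy_ref)
        corrected = bc.apply_technical_calibration(distorted, factors)
        rmse = np.sqrt(((corrected.values - clean) ** 2).mean(axis=1))
        assert (rmse < tau).all()

    def test_positive_scale_enforced(self):
        with pytest.raises(bc.FormatError, match="positive"):
            bc.CalibrationFactors(["g1"], np.array([-0.5]), np.array([0.0]))

    def test_round_trip(self, tmp_path, rng):
        f = bc.CalibrationFactors(
            ["g1", "g2"], np.array([1.5, 0.8]), np.array([-0.2, 3.0])
        )
        path = tmp_path / "f.tsv"
        write_calibration(f, path)
        back = read_calibration(path)
        np.testing.assert_allclose(back.scale, f.scale, atol=1e-12)
        np.testing.assert_allclose(back.shift, f.shift, atol=1e-12)


@pytest.mark.parametrize("center", ["sgpct", "sgmd"])
def test_centering_commutes_with_per_gene_constant(center, rng):
    """Adding c_g to both reference and test commutes predictably.

    sgPct output is invariant (the percentile map and the subtracted
    quantile both absorb the constant); sgMd output, which lives on the
    reference's absolute scale, shifts by exactly that constant.
    """
    genes = [f"g{i}" for i in range(10)]
    ref_m = _matrix(rng.normal(size=(10, 21)), genes=genes)
    test_m = _matrix(rng.normal(size=(10, 7)), genes=genes)
    const = rng.normal(0, 4, 10)[:, None]
    mask = np.ones(21, dtype=bool)
    fn = bc.sgpct_center if center == "sgpct" else bc.sgmd_center
    base = fn(test_m, build_sgpct_reference(ref_m, mask))
    shifted = fn(
        test_m.with_values(test_m.values + const),
        build_sgpct_reference(ref_m.with_values(ref_m.values + const), mask),
    )
    expected = base.values if center == "sgpct" else base.values + const
    np.testing.assert_allclose(shifted.values, expected, atol=1e-9)
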