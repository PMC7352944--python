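"""Imputation and the NMR chain: referencing, bucketing, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import bilemark as bm
from bilemark.prep import BucketingConfig, process_spectra
from conftest import make_table


class TestImputeMissing:
    def test_identical_neighbor_supplies_its_value(self):
        t = make_table([[1.0, 2.0, np.nan], [1.0, 2.0, 7.0], [50.0, 60.0, 9.0]])
        out = bm.impute_missing(t, k=1)
        assert out.data.iloc[0, 2] == pytest.approx(7.0)

    def test_equidistant_neighbors_average(self):
        # sample 0 is equidistant from samples 1 and 2 on the observed feature
        t = make_table([[0.0, np.nan], [1.0, 2.0], [-1.0, 4.0]])
        out = bm.impute_missing(t, k=2)
        assert out.data.iloc[0, 1] == pytest.approx(3.0)

    def test_complete_table_returned_unchanged(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0]])
        assert bm.impute_missing(t, k=1) is t

    def test_observed_entries_untouched_and_mask_cleared(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=(12, 6))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        t = make_table(vals)
        out = bm.impute_missing(t, k=3)
        assert not out.has_missing
        obs = ~np.isnan(vals)
        assert np.array_equal(out.values[obs], vals[obs])

    def test_fully_missing_feature_named_in_error(self):
        t = make_table([[1.0, np.nan], [2.0, np.nan]], feature_ids=["ok", "gone"])
        with pytest.raises(ValueError, match="gone"):
            bm.impute_missing(t)

    def test_large_k_clamped_with_warning(self):
        t = make_table([[1.0, np.nan], [2.0, 5.0], [3.0, 6.0]])
        with pytest.warns(UserWarning, match="clamp"):
            out = bm.impute_missing(t, k=10)
        assert not out.has_missing

    @given(arrays(np.float64, (4, 3), elements=st.floats(0.1, 100)))
    def test_idempotent_on_complete_tables(self, vals):
        t = make_table(vals)
        assert bm.impute_missing(t, k=2) is t


class TestReferencing:
    def _spectra(self, offsets):
        spec = bm.SpectrumSimSpec(ppm_grid=(-0.5, 9.5, 0.001), noise_sd=0.0,
                                  reference_peak_offset=offsets)
        ss, _ = bm.generate_spectra(spec, len(np.atleast_1d(offsets)))
        return ss

    def test_offset_standard_peak_moved_to_zero(self):
        ss = self._spectra([0.02])
        out = bm.reference_to_standard(ss)
        win = (out.ppm >= -0.2) & (out.ppm <= 0.2)
        peak = out.ppm[win][np.argmax(out.intensities[0][win])]
        assert abs(peak) <= 0.001

    def test_already_centered_peak_is_identity(self):
        ss = self._spectra([0.0])
        out = bm.reference_to_standard(ss)
        assert np.allclose(out.intensities, ss.intensities)

    def test_opposite_offsets_align_within_one_grid_step(self):
        ss = self._spectra([0.01, -0.01])
        out = bm.reference_to_standard(ss)
        win = (out.ppm >= -0.2) & (out.ppm <= 0.2)
        peaks = [out.ppm[win][np.argmax(out.intensities[s][win])] for s in (0, 1)]
        assert abs(peaks[0] - peaks[1]) <= 0.001

    def test_flat_window_warns_and_leaves_spectrum(self):
        ss = bm.SpectrumSet(np.linspace(-1, 1, 201), np.ones((1, 201)))
        with pytest.warns(UserWarning, match="flat"):
            out = bm.reference_to_standard(ss)
        assert np.array_equal(out.intensities, ss.intensities)


class TestBucketing:
    def test_bucket_counts(self):
        ppm = np.arange(-0.5, 9.5, 0.001)
        ss = bm.SpectrumSet(ppm, np.ones((1, ppm.size)))
        simple = bm.bucket_spectra(ss, BucketingConfig(width=0.01, region=(0.0, 1.0),
                                                       exclusions=()))
        assert len(simple.intervals) == 100
        paper_region = bm.bucket_spectra(ss, BucketingConfig(exclusions=()))
        assert len(paper_region.intervals) == 850  # 849 full + 1 truncated

    def test_constant_intensity_full_buckets_integrate_to_width(self):
        ppm = np.arange(-0.1, 1.2, 0.001)
        ss = bm.SpectrumSet(ppm, np.ones((1, ppm.size)))
        bt = bm.bucket_spectra(ss, BucketingConfig(width=0.01, region=(0.0, 1.0),
                                                   exclusions=()))
        assert np.allclose(bt.values.to_numpy(), 0.01)

    def test_mass_conservation_with_exclusions(self):
        spec = bm.SpectrumSimSpec(noise_sd=0.05, seed=4,
                                  artifact_regions=((4.59, 4.78),))
        ss, _ = bm.generate_spectra(spec, 3)
        bt = bm.bucket_spectra(ss)
        assert len(bt.dropped_intervals) > 0
        kept = bt.values.to_numpy().sum(axis=1)
        dropped = bt.dropped_values.to_numpy().sum(axis=1)
        lo, hi = 0.261, 8.757
        from bilemark.prep import _cumulative_integral
        for s in range(3):
            total = np.diff(_cumulative_integral(ss.ppm, ss.intensities[s],
                                                 np.array([lo, hi])))[0]
            assert kept[s] + dropped[s] == pytest.approx(total, abs=1e-9)

    def test_excluded_buckets_do_not_appear(self):
        ss, _ = bm.generate_spectra(bm.SpectrumSimSpec(noise_sd=0.0), 1)
        bt = bm.bucket_spectra(ss)
        for lo, hi in bt.intervals:
            for elo, ehi in BucketingConfig().exclusions:
                assert not (lo < ehi and elo < hi)

    def test_region_outside_axis_errors(self):
        ss = bm.SpectrumSet(np.linspace(0, 1, 101), np.ones((1, 101)))
        with pytest.raises(ValueError, match="region"):
            bm.bucket_spectra(ss, BucketingConfig(region=(0.0, 2.0)))


class TestNormalization:
    def _bt(self, rows):
        rows = np.asarray(rows, dtype=float)
        intervals = [(0.01 * j, 0.01 * (j + 1)) for j in range(rows.shape[1])]
        vals = pd.DataFrame(rows, index=[f"s{i}" for i in range(rows.shape[0])],
                            columns=[f"{0.005 + 0.01 * j:.4f}" for j in range(rows.shape[1])])
        return bm.BucketTable(intervals=intervals, values=vals)

    def test_total_area_rows_sum_to_one(self):
        bt = bm.normalize_buckets(self._bt([[1, 2, 3], [5, 5, 10]]), "total_area")
        assert np.allclose(bt.values.sum(axis=1), 1.0, atol=1e-9)
        assert bt.normalization == "total_area"

    def test_pqn_hand_example(self):
        bt = bm.normalize_buckets(self._bt([[2, 4, 9]]), "pqn",
                                  reference=np.array([1.0, 2.0, 3.0]))
        assert bt.dilution_factors.iloc[0] == pytest.approx(2.0)
        assert np.allclose(bt.values.to_numpy()[0], [1.0, 2.0, 4.5])

    def test_pqn_doubled_row_against_reference(self):
        ref = np.array([1.0, 3.0, 2.0, 5.0])
        bt = bm.normalize_buckets(self._bt([2 * ref]), "pqn", reference=ref)
        assert bt.dilution_factors.iloc[0] == pytest.approx(2.0)
        assert np.allclose(bt.values.to_numpy()[0], ref)

    def test_zero_total_row_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            bm.normalize_buckets(self._bt([[1, 2, 3], [0, 0, 0]]), "total_area")


class TestPqnDilutionRecovery:
    def test_noiseless_recovery_exact_up_to_reference_scale(self):
        dil = np.linspace(0.5, 2.0, 20)
        spec = bm.SpectrumSimSpec(dilution_factors=list(dil), noise_sd=0.0, seed=1)
        ss, truth = bm.generate_spectra(spec, 20)
        pq = bm.normalize_buckets(bm.bucket_spectra(ss), "pqn")
        est = pq.dilution_factors.to_numpy()
        # PQN determines dilution up to the reference's own scale
        est, truth = est / np.median(est), truth / np.median(truth)
        assert np.max(np.abs(est - truth) / truth) < 1e-9

    def test_noisy_recovery_median_error_under_two_percent(self):
        dil = np.linspace(0.5, 2.0, 20)
        spec = bm.SpectrumSimSpec(dilution_factors=list(dil), noise_sd=0.02, seed=2)
        ss, truth = bm.generate_spectra(spec, 20)
        pq = bm.normalize_buckets(bm.bucket_spectra(ss), "pqn")
        est = pq.dilution_factors.to_numpy()
        est, truth = est / np.median(est), truth / np.median(truth)
        assert np.median(np.abs(est - truth) / truth) < 0.02

    def test_full_chain_runs_and_records_factors(self):
        spec = bm.SpectrumSimSpec(dilution_factors=[0.8, 1.0, 1.5], noise_sd=0.01,
                                  reference_peak_offset=[0.01, 0.0, -0.01], seed=3)
        ss, _ = bm.generate_spectra(spec, 3)
        bt = process_spectra(ss)
        assert bt.normalization == "pqn"
        assert bt.dilution_factors is not None and len(bt.dilution_factors) == 3
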