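import numpy as np
import pytest
from scipy import signal

from mupool import lowdim, preprocess
from mupool.preprocess import (
    DegenerateUnitError,
    ForceSummary,
    PipelineOrderError,
    binarize,
    detrend_standardize,
    force_rmse,
    hanning_cutoff_hz,
    select_post_skill_trials,
    smooth_rates,
)
from mupool.recordings_io import DischargeTrain

FS = 2048.0


class TestForceRMSE:
    def test_identity_gives_zero(self):
        t = np.linspace(0, 30, int(30 * FS))
        target = 10 + np.sin(2 * np.pi * 0.5 * t)
        s = force_rmse(target, target, FS)
        # only the force passes the 15-Hz filter, so "zero" is met to the
        # filter's passband accuracy, not machine precision
        assert s.rmse < 0.01

    def test_constant_offset_removed_by_detrend(self):
        t = np.linspace(0, 30, int(30 * FS))
        target = 10 + np.sin(2 * np.pi * 0.5 * t)
        s = force_rmse(target + 2.5, target, FS)
        assert s.rmse < 0.01

    def test_additive_sine_rmse_closed_form(self):
        # force = target + A sin(2*pi*0.5 t) -> RMSE = A / sqrt(2)
        rng = np.random.default_rng(0)
        t = np.linspace(0, 30, int(30 * FS))
        target = 10 + 0.5 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 1))
        A = 0.8
        s = force_rmse(target + A * np.sin(2 * np.pi * 0.5 * t), target, FS)
        assert s.rmse == pytest.approx(A / np.sqrt(2), rel=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            force_rmse(np.ones(100), np.ones(99), FS)

    def test_cov_is_sd_over_mean_percent(self):
        t = np.linspace(0, 30, int(30 * FS))
        f = 10 + np.sin(2 * np.pi * 1.0 * t)  # SD 1/sqrt(2), mean 10
        s = force_rmse(f, f, FS)
        assert s.cov_force == pytest.approx(100 / (10 * np.sqrt(2)), rel=0.02)


class TestTrialSelection:
    @staticmethod
    def summaries(rmses):
        return [
            ForceSummary(rmse=r, cov_force=0.0, trial_index=i + 1)
            for i, r in enumerate(rmses)
        ]

    def test_lowest_consecutive_triplet_selected(self):
        sel = select_post_skill_trials(
            self.summaries([5, 4, 3, 3, 3, 4, 5, 6, 7, 8])
        )
        assert sel.selected_indices == (3, 4, 5)

    def test_tie_breaks_to_earliest(self):
        sel = select_post_skill_trials(self.summaries([2, 2, 2, 2, 2]))
        assert sel.selected_indices == (1, 2, 3)

    def test_matches_exhaustive_scan_on_random_sequences(self, rng):
        for _ in range(50):
            rmses = rng.uniform(1, 10, size=15)
            sel = select_post_skill_trials(self.summaries(rmses))
            means = [rmses[i:i + 3].mean() for i in range(13)]
            best = int(np.argmin(means)) + 1  # earliest via argmin
            assert sel.selected_indices == (best, best + 1, best + 2)

    def test_late_minimum_selects_late_triplet(self):
        rmses = list(np.linspace(10, 2, 15))  # monotone learning curve
        sel = select_post_skill_trials(self.summaries(rmses))
        assert sel.selected_indices == (13, 14, 15)

    def test_fewer_than_three_trials_rejected(self):
        with pytest.raises(ValueError):
            select_post_skill_trials(self.summaries([1, 2]))


class TestBinarize:
    def test_half_open_window_convention(self):
        train = DischargeTrain("MU01", [2048, 4096], FS)
        m = binarize([train], 1.0, 2.0)
        assert m.data.sum() == 1
        assert m.data[0, 0] == 1  # spike at window start -> row 0; end excluded

    def test_count_conservation(self, rng):
        trains = [
            DischargeTrain(
                f"MU{j}", np.sort(rng.choice(40960, 80, replace=False)), FS
            )
            for j in range(4)
        ]
        m = binarize(trains, 2.0, 18.0)
        for j, t in enumerate(trains):
            s = t.discharge_samples
            in_win = np.sum((s >= int(2.0 * FS)) & (s < int(18.0 * FS)))
            assert m.data[:, j].sum() == in_win

    def test_column_sums_match_truth_ledger(self, single_input_cohort):
        sim = single_input_cohort
        tr = sim.cohort.trials[0]
        w = sim.analysis_window_s
        m = binarize(tr.trains, *w)
        fs = tr.fs
        for j, t in enumerate(tr.trains):
            s = t.discharge_samples
            expected = np.sum((s >= round(w[0] * fs)) & (s < round(w[1] * fs)))
            assert m.data[:, j].sum() == expected

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            binarize([DischargeTrain("MU01", [10], FS)], 2.0, 2.0)


class TestSmoothing:
    def test_zero_column_stays_zero(self):
        m = binarize([DischargeTrain("MU01", [], FS)], 0.0, 5.0)
        rates = smooth_rates(m)
        assert np.all(rates.data == 0.0)

    def test_single_spike_yields_centered_normalized_hanning(self):
        train = DischargeTrain("MU01", [int(2.5 * FS)], FS)
        rates = smooth_rates(binarize([train], 0.0, 5.0))
        col = rates.data[:, 0]
        # unit time-integral -> pulses/s units
        assert col.sum() / FS == pytest.approx(1.0, abs=1e-9)
        assert abs(np.argmax(col) - int(2.5 * FS)) <= 1
        width = int(round(0.4 * FS))
        kernel = signal.windows.hann(width, sym=True)
        kernel = kernel * FS / kernel.sum()
        lo = int(2.5 * FS) - width // 2
        np.testing.assert_allclose(
            col[lo:lo + width], kernel, atol=1e-9
        )

    def test_minus_3db_cutoff_near_1p8_hz(self):
        assert hanning_cutoff_hz(400.0, FS) == pytest.approx(1.8, abs=0.05)
        # closed form ~0.72 / T for a Hanning of length T
        assert hanning_cutoff_hz(400.0, FS) == pytest.approx(0.72 / 0.4, rel=0.01)

    def test_commutes_with_time_reversal(self, rng):
        data = (rng.random((4096, 3)) < 0.01).astype(np.uint8)
        m = preprocess.SpikeTrainMatrix(data, FS, ["a", "b", "c"], (0, 4096))
        r = smooth_rates(m).data
        m_rev = preprocess.SpikeTrainMatrix(data[::-1], FS, ["a", "b", "c"], (0, 4096))
        r_rev = smooth_rates(m_rev).data
        np.testing.assert_allclose(r[::-1], r_rev, atol=1e-12)

    def test_window_longer_than_record_rejected(self):
        m = binarize([DischargeTrain("MU01", [10], FS)], 0.0, 0.2)
        with pytest.raises(ValueError):
            smooth_rates(m, window_ms=400.0)


class TestDetrendStandardize:
    @staticmethod
    def rates_from(data):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return preprocess.SmoothedRateMatrix(
                data, FS, [f"u{j}" for j in range(data.shape[1])]
            )

    def test_columns_become_zero_mean_unit_sd(self, rng):
        data = rng.random((int(10 * FS), 3)) + np.arange(3)
        z = detrend_standardize(self.rates_from(data))
        assert np.all(np.abs(z.data.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(z.data.std(axis=0) - 1) < 1e-9)
        assert z.detrended and z.standardized

    def test_slow_oscillation_removed(self):
        t = np.arange(int(20 * FS)) / FS
        slow = np.sin(2 * np.pi * 0.1 * t)
        sos = signal.butter(3, 0.75, "high", fs=FS, output="sos")
        resid = signal.sosfiltfilt(sos, slow)
        assert resid.var() / slow.var() < 0.05

    def test_band_oscillation_retained(self):
        t = np.arange(int(20 * FS)) / FS
        band = np.sin(2 * np.pi * 2.0 * t)
        sos = signal.butter(3, 0.75, "high", fs=FS, output="sos")
        out = signal.sosfiltfilt(sos, band)
        assert out.var() / band.var() > 0.90

    def test_constant_column_names_unit(self):
        data = np.ones((int(5 * FS), 2))
        data[:, 0] = np.sin(np.arange(int(5 * FS)) / FS)
        with pytest.raises(DegenerateUnitError, match="u1"):
            detrend_standardize(self.rates_from(data))

    def test_double_standardization_rejected(self, rng):
        z = detrend_standardize(self.rates_from(rng.random((int(5 * FS), 2))))
        with pytest.raises(PipelineOrderError):
            detrend_standardize(z)


class TestEndToEndRecovery:
    def test_pc1_tracks_ground_truth_shared_input(self, single_input_cohort,
                                                  single_input_matrices):
        # first PC of the rate matrix recovers the common drive
        sim = single_input_cohort
        fs = sim.cohort.trials[0].fs
        w = sim.analysis_window_s
        sl = slice(int(round(w[0] * fs)), int(round(w[1] * fs)))
        rs = []
        for k, Z in enumerate(single_input_matrices):
            comp = lowdim.extract_components(Z, "PCA")
            drive = sim.truth["drives"][k][0][sl]
            rs.append(abs(lowdim.xcorr_peak(comp.scores[:, 0], drive, fs).peak_r))
        assert np.mean(rs) > 0.8
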