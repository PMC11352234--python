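import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from datbio import (EEGRecording, FormatError, read_recording,
                    stabilization_index, write_recording)
from datbio.eeg_io import edf_quantization_step


def make_rec(samples, **kw):
    return EEGRecording(samples=np.asarray(samples, dtype=float), **kw)


class TestRecordingValidation:
    def test_rejects_nonfinite_samples(self):
        with pytest.raises(ValueError, match="non-finite"):
            make_rec([0.0, np.nan, 1.0])

    def test_rejects_bad_phase(self):
        with pytest.raises(ValueError, match="phase"):
            make_rec([0.0], phase="relaxing")

    def test_rejects_out_of_range_quality_flag(self):
        with pytest.raises(ValueError, match="poor_signal"):
            make_rec([0.0, 1.0], poor_signal=[0, 300])

    def test_duration_from_sample_count(self):
        rec = make_rec(np.zeros(1024), fs=512)
        assert rec.duration_s == pytest.approx(2.0)


class TestCsvRoundTrip:
    def test_round_trip_preserves_samples_and_metadata(self, tmp_path, rng):
        rec = make_rec(rng.standard_normal(256) * 50, fs=512, phase="during",
                       subject_id="S03", poor_signal=rng.integers(0, 256, 256))
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        back = read_recording(path)
        assert np.array_equal(back.samples, rec.samples)
        assert np.array_equal(back.poor_signal, rec.poor_signal)
        assert (back.fs, back.phase, back.subject_id) == (512, "during", "S03")

    @given(samples=arrays(np.float64, st.integers(1, 64),
                          elements=st.floats(-1e6, 1e6, allow_nan=False,
                                             width=64)))
    def test_round_trip_is_lossless_for_any_finite_signal(self, tmp_path_factory, samples):
        path = tmp_path_factory.mktemp("csv") / "x.csv"
        write_recording(make_rec(samples), path)
        assert np.array_equal(read_recording(path).samples, samples)

    def test_nonnumeric_sample_raises_format_error_with_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# fs=512\nuV\n1.0\nbogus\n")
        with pytest.raises(FormatError, match=":4"):
            read_recording(path)

    def test_nonfinite_value_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# fs=512\nuV\n1.0\ninf\n")
        with pytest.raises(FormatError, match="non-finite"):
            read_recording(path)

    def test_missing_fs_header_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("uV\n1.0\n")
        with pytest.raises(FormatError, match="fs"):
            read_recording(path)

    def test_empty_recording_rejected_on_write(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_recording(make_rec(np.empty(0)), tmp_path / "x.csv")


class TestEdf:
    def test_round_trip_within_quantization_step(self, tmp_path, rng):
        rec = make_rec(rng.standard_normal(1024) * 80, fs=512, phase="after",
                       subject_id="S02")
        path = tmp_path / "rec.edf"
        write_recording(rec, path)
        back = read_recording(path)
        amp = np.max(np.abs(rec.samples)) * 1.0001
        step = edf_quantization_step(-amp, amp)
        assert np.max(np.abs(back.samples - rec.samples)) <= step
        assert back.fs == 512
        assert (back.phase, back.subject_id) == ("after", "S02")

    def test_mne_reads_our_edf_identically(self, tmp_path, rng):
        mne = pytest.importorskip("mne")
        rec = make_rec(rng.standard_normal(512) * 40, fs=512)
        path = tmp_path / "rec.edf"
        write_recording(rec, path)
        raw = mne.io.read_raw_edf(path, verbose="error")
        theirs = raw.get_data()[0] * 1e6  # volts back to microvolts
        ours = read_recording(path).samples
        assert np.allclose(theirs, ours, atol=1e-9)

    def test_fractional_second_recording_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="whole number of seconds"):
            write_recording(make_rec(np.zeros(700), fs=512), tmp_path / "x.edf")


class TestStabilizationIndex:
    @pytest.mark.parametrize("series,expected", [
        ([200, 80, 51, 0], 2),   # threshold rule is <= 51
        ([0, 0, 0], 0),
        ([255, 255], None),
    ])
    def test_threshold_rule(self, series, expected):
        assert stabilization_index(series) == expected

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            stabilization_index([])

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            stabilization_index([100, 256])

    @given(st.lists(st.integers(0, 255), min_size=1, max_size=40),
           st.integers(0, 254))
    def test_monotone_in_threshold(self, series, threshold):
        """Raising the threshold never yields a later stabilization index."""
        low = stabilization_index(series, threshold)
        high = stabilization_index(series, threshold + 1)
        if low is not None:
            assert high is not None and high <= low

    def test_stabilized_drops_prefix(self):
        rec = make_rec([1.0, 2.0, 3.0, 4.0], poor_signal=[200, 200, 30, 0])
        trimmed = rec.stabilized()
        assert np.array_equal(trimmed.samples, [3.0, 4.0])

    def test_never_stabilized_recording_raises(self):
        rec = make_rec([1.0, 2.0], poor_signal=[200, 200])
        with pytest.raises(ValueError, match="never stabilized"):
            rec.stabilized()
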