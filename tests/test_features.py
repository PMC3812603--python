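import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_psd, tone_segment
from eegattn.features import (
    BandPowerExtractor,
    DegenerateSegmentError,
    alpha_beta_ratio,
    band_energy,
    compute_psd,
    extract_dataset,
    extract_features,
)
from eegattn.io import ATTENTIVE, DISCARD, INATTENTIVE, EEGRecording, LabelTrack
from eegattn.preprocess import Segment


class TestComputePsd:
    def test_matches_brute_force_dft(self, rng):
        for _ in range(20):
            x = rng.normal(0, 40, 512)
            ps = compute_psd(x)
            oracle = brute_force_psd(x)
            assert np.max(np.abs(ps.P - oracle) / oracle.max()) < 1e-9

    def test_zero_segment_gives_zero_spectrum(self):
        assert np.all(compute_psd(np.zeros(512)).P == 0)

    def test_pure_tone_concentrates_at_its_bin(self):
        ps = compute_psd(tone_segment(10.0))
        assert ps.P[10] == pytest.approx(128.0, rel=1e-9)
        assert ps.P[512 - 10] == pytest.approx(128.0, rel=1e-9)
        others = np.delete(ps.P, [10, 512 - 10])
        assert np.max(others) < 1e-9

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            compute_psd(np.zeros(511))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_parseval_identity(self, seed):
        x = np.random.default_rng(seed).normal(0, 25, 512)
        ps = compute_psd(x)
        assert ps.P.sum() == pytest.approx(np.sum(x**2), rel=1e-9)

    def test_hann_taper_keeps_parseval_of_tapered_series(self, rng):
        x = rng.normal(0, 10, 512)
        ps = compute_psd(x, taper="hann")
        assert ps.P.sum() == pytest.approx(np.sum((x * np.hanning(512)) ** 2), rel=1e-9)


class TestBandEnergy:
    def test_zero_spectrum_zero_everywhere(self):
        ps = compute_psd(np.zeros(512))
        assert all(band_energy(ps, b) == 0 for b in ("alpha", "beta", "theta", "delta"))

    @pytest.mark.parametrize(
        "freq,hot",
        [(10.0, "alpha"), (20.0, "beta"), (5.0, "theta"), (2.0, "delta")],
    )
    def test_tone_routes_to_single_band(self, freq, hot):
        ps = compute_psd(tone_segment(freq))
        for band in ("alpha", "beta", "theta", "delta"):
            expected = 128.0 if band == hot else 0.0
            assert band_energy(ps, band) == pytest.approx(expected, abs=1e-9)

    def test_band_edges_inclusive(self):
        assert band_energy(compute_psd(tone_segment(13.0)), "alpha") == pytest.approx(128.0, rel=1e-9)
        assert band_energy(compute_psd(tone_segment(14.0)), "beta") == pytest.approx(128.0, rel=1e-9)

    def test_dc_excluded_from_delta(self):
        ps = compute_psd(np.full(512, 3.0))
        assert band_energy(ps, "delta") == pytest.approx(0.0, abs=1e-9)

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError):
            band_energy(compute_psd(np.zeros(512)), "gamma2")


class TestRatioAndFeatures:
    def test_ratio_arithmetic(self):
        assert alpha_beta_ratio(128.0, 128.0) == 1.0
        assert alpha_beta_ratio(128.0, 64.0) == 2.0

    def test_zero_beta_is_degenerate(self):
        with pytest.raises(DegenerateSegmentError):
            alpha_beta_ratio(128.0, 0.0)

    def test_pure_alpha_tone_is_degenerate_segment(self):
        with pytest.raises(DegenerateSegmentError):
            extract_features(tone_segment(10.0))

    def test_mixed_tone_features(self):
        t = np.arange(512) / 512.0
        seg = Segment(
            samples=np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 20 * t),
            start_index=0,
            label=ATTENTIVE,
        )
        row = extract_features(seg)
        assert row["E_alpha"] == pytest.approx(128.0, rel=1e-9)
        assert row["E_beta"] == pytest.approx(128.0, rel=1e-9)
        assert row["R"] == pytest.approx(1.0, rel=1e-9)
        assert row["label"] == ATTENTIVE

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scaling_covariance(self, c):
        """Scaling a segment by c scales energies by c² and leaves R fixed."""
        x = np.random.default_rng(3).normal(0, 20, 512)
        base = compute_psd(x)
        scaled = compute_psd(c * x)
        for band in ("alpha", "beta", "theta", "delta"):
            assert band_energy(scaled, band) == pytest.approx(
                c**2 * band_energy(base, band), rel=1e-9
            )
        r0 = alpha_beta_ratio(band_energy(base, "alpha"), band_energy(base, "beta"))
        r1 = alpha_beta_ratio(band_energy(scaled, "alpha"), band_energy(scaled, "beta"))
        assert r1 == pytest.approx(r0, rel=1e-9)


class TestExtractDataset:
    def _recording(self, rng, seconds, fs=512):
        return EEGRecording(
            samples=rng.normal(0, 20, seconds * fs), fs=fs, subject_id="s", group="F"
        )

    def test_all_attentive_four_seconds_gives_seven_rows(self, rng):
        rec = self._recording(rng, 4)
        df = extract_dataset([(rec, LabelTrack([ATTENTIVE] * 4))])
        assert len(df) == 7
        assert set(df["label"]) == {ATTENTIVE}
        assert list(df["group"].unique()) == ["F"]

    def test_all_discard_gives_no_rows(self, rng):
        rec = self._recording(rng, 4)
        df = extract_dataset([(rec, LabelTrack([DISCARD] * 4))])
        assert len(df) == 0

    def test_straddling_windows_excluded_by_unanimity(self, rng):
        rec = self._recording(rng, 4)
        track = LabelTrack([ATTENTIVE, INATTENTIVE, ATTENTIVE, INATTENTIVE])
        df = extract_dataset([(rec, track)])
        # 7 windows; the 3 odd-offset windows straddle two labels
        assert len(df) == 4


class TestBandPowerExtractor:
    def test_matches_feature_composition(self, rng):
        X = rng.normal(0, 15, (8, 512))
        out = BandPowerExtractor().fit_transform(X)
        row = extract_features(Segment(samples=X[3], start_index=0, label=ATTENTIVE))
        assert out[3] == pytest.approx(
            [row["E_alpha"], row["E_beta"], row["E_theta"], row["E_delta"], row["R"]]
        )

    def test_rejects_wrong_width(self, rng):
        with pytest.raises(ValueError):
            BandPowerExtractor().fit(rng.normal(size=(4, 100)))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        ext = BandPowerExtractor(taper="hann")
        assert clone(ext).get_params() == ext.get_params()
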