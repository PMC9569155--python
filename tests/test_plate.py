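"""Plate pipeline: I/O round-trips, background correction, synchronization,
z-normalization, end-to-end recovery on synthetic plates."""

import numpy as np
import pandas as pd
import pytest

import kinrates as kr
from kinrates.plate import (
    NormalizedProfile,
    build_synthetic_plate,
    characterize_sample,
    compare_to_reference,
    normalize_profile,
    peak_time,
    read_plate_csv,
    subtract_background,
)


@pytest.fixture(scope="module")
def gomp_mu(gomp):
    return lambda t: kr.gompertz_growth_rate(gomp, t)


@pytest.fixture(scope="module")
def smooth_phi():
    """A smooth single-peak expression truth on [0, 24] h."""
    return lambda t: np.exp(-((np.asarray(t, float) - 8.0) ** 2) / 18.0)


@pytest.fixture(scope="module")
def clean_plate(gomp_mu, smooth_phi):
    """Noise-free synthetic plate: recovery should be essentially exact."""
    return build_synthetic_plate(gomp_mu, smooth_phi, n_replicates=4,
                                 noise=kr.NoiseSpec(sigma=0.0), seed=1)


@pytest.fixture(scope="module")
def noisy_plate(gomp_mu, smooth_phi):
    return build_synthetic_plate(gomp_mu, smooth_phi, n_replicates=10,
                                 noise=kr.NoiseSpec(sigma=0.01), seed=2)


class TestPlateIO:
    def test_roundtrip(self, tmp_path, noisy_plate):
        path = tmp_path / "plate.csv"
        noisy_plate.to_csv(path)
        again = read_plate_csv(path)
        assert noisy_plate.equals(again)

    def test_shuffled_rows_ingest_identically(self, tmp_path, noisy_plate):
        path = tmp_path / "plate.csv"
        df = noisy_plate.data.sample(frac=1.0, random_state=0)
        df.to_csv(path, index=False)
        noisy_plate.metadata.to_csv(tmp_path / "plate_meta.csv", index=False)
        again = read_plate_csv(path)
        assert noisy_plate.equals(again)

    def test_missing_columns_rejected(self, noisy_plate):
        with pytest.raises(ValueError, match="missing columns"):
            kr.PlateDataset(noisy_plate.data.drop(columns=["value"]),
                            noisy_plate.metadata)

    def test_duplicate_rows_named(self, noisy_plate):
        dup = pd.concat([noisy_plate.data, noisy_plate.data.head(1)])
        with pytest.raises(ValueError, match="duplicate"):
            kr.PlateDataset(dup, noisy_plate.metadata)

    def test_missing_controls_fail_only_at_correction(self, noisy_plate):
        no_ctrl = noisy_plate.data[~noisy_plate.data["sample"].isin(
            ["MEDIA_BLANK", "NO_REPORTER"])]
        ds = kr.PlateDataset(no_ctrl, noisy_plate.metadata)  # loads fine
        with pytest.raises(ValueError, match="control"):
            subtract_background(ds)

    def test_time_origin_shifted_on_ingestion(self, gomp_mu, smooth_phi):
        shifted = build_synthetic_plate(gomp_mu, smooth_phi, n_replicates=3,
                                        noise=kr.NoiseSpec(sigma=0.0),
                                        seed=3, time_offset=5.0)
        assert shifted.data["time_h"].min() == 0.0


class TestBackgroundSubtraction:
    def test_sigma_zero_blanks_correct_to_exact_zero(self, clean_plate):
        corr = subtract_background(clean_plate)
        blanks = corr.data[corr.data["sample"] == "MEDIA_BLANK"]
        assert np.allclose(blanks[blanks.channel == "OD"]["value"], 0.0)

    def test_corrected_controls_mean_near_zero(self, gomp_mu, smooth_phi):
        plate = build_synthetic_plate(gomp_mu, smooth_phi, n_replicates=2,
                                      noise=kr.NoiseSpec(sigma=0.05),
                                      n_blanks=100, seed=4)
        corr = subtract_background(plate)
        od = corr.data[(corr.data["sample"] == "MEDIA_BLANK")
                       & (corr.data.channel == "OD")]
        means = od.groupby("time_h")["value"].mean()
        # centering is exact at each time by construction of the correction
        assert np.all(np.abs(means) < 1e-12)

    def test_double_application_refused(self, clean_plate):
        corr = subtract_background(clean_plate)
        with pytest.raises(ValueError, match="already"):
            subtract_background(corr)


class TestPeakTime:
    def test_gompertz_peak_location(self, noiseless_gompertz_well, gomp):
        well, noise = noiseless_gompertz_well
        biomass, _ = well.corrected(noise)
        res = kr.GrowthRateModel(biomass).fit(lambda_reg=0.0)
        assert peak_time(res, t_end=24.0) == pytest.approx(gomp.peak_time, abs=0.25)

    def test_single_basis_bump_peaks_at_center(self):
        w = np.zeros(25)
        w[7] = 2.0
        prof = kr.BasisProfile(1.0, w, 24.0)
        assert peak_time(prof, t_end=24.0) == pytest.approx(7.0, abs=0.01)

    def test_monotone_decreasing_peaks_at_origin(self):
        prof = kr.GriddedProfile(np.linspace(0, 10, 11), np.linspace(1, 0, 11))
        assert peak_time(prof, t_end=10.0) == 0.0

    def test_flat_profile_rejected(self):
        prof = kr.GriddedProfile(np.linspace(0, 10, 11), np.full(11, 0.5))
        with pytest.raises(ValueError, match="peak"):
            peak_time(prof, t_end=10.0)


class TestNormalizeProfile:
    def test_mean_zero_std_one(self, rng):
        vals = rng.uniform(0, 3, 50)
        prof = normalize_profile(vals, np.linspace(0, 10, 50), t0=4.0)
        assert abs(prof.z.mean()) < 1e-8
        assert abs(prof.z.std() - 1.0) < 1e-8
        assert prof.tau[0] == pytest.approx(-4.0)

    def test_affine_invariance_and_sign_flip(self, rng):
        t = np.linspace(0, 10, 50)
        vals = rng.uniform(0, 3, 50)
        base = normalize_profile(vals, t, 0.0)
        scaled = normalize_profile(2.5 * vals + 7.0, t, 0.0)
        flipped = normalize_profile(-vals, t, 0.0)
        assert np.allclose(base.z, scaled.z)
        assert np.allclose(base.z, -flipped.z)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normalize_profile(np.ones(10), np.linspace(0, 9, 10), 0.0)


class TestCompareToReference:
    def _profile(self, z, tau=None):
        tau = np.linspace(-5, 10, len(z)) if tau is None else tau
        sd = np.std(z)
        zz = (z - np.mean(z)) / sd
        return NormalizedProfile(tau, zz)

    def test_self_comparison(self, rng):
        p = self._profile(rng.normal(size=100))
        rec = compare_to_reference(p, p)
        assert rec.rmsd == pytest.approx(0.0, abs=1e-12)
        assert rec.pearson_r == pytest.approx(1.0)

    def test_negation_anticorrelates(self, rng):
        z = rng.normal(size=100)
        rec = compare_to_reference(self._profile(z), self._profile(-z))
        assert rec.pearson_r == pytest.approx(-1.0)

    def test_insufficient_overlap_rejected(self, rng):
        a = self._profile(rng.normal(size=30), tau=np.linspace(-5, -2, 30))
        b = self._profile(rng.normal(size=30), tau=np.linspace(2, 5, 30))
        with pytest.raises(ValueError, match="overlap"):
            compare_to_reference(a, b)

    def test_independent_noise_profiles_weakly_correlated(self):
        """Null distribution: |r| < 0.5 in >= 95% of independent pairs.

        Noise is drawn per tau grid point so the 51 shared points are
        independent samples; smooth profiles would not satisfy this."""
        rng = np.random.default_rng(77)
        tau = np.linspace(-5, 5, 51)
        n_ok = 0
        trials = 1000
        for _ in range(trials):
            a = self._profile(rng.normal(size=51), tau)
            b = self._profile(rng.normal(size=51), tau)
            if abs(compare_to_reference(a, b, step=0.2).pearson_r) < 0.5:
                n_ok += 1
        assert n_ok >= 0.95 * trials


class TestCharacterizeEndToEnd:
    def test_low_noise_recovery_of_known_truth(self, noisy_plate, smooth_phi,
                                               gomp_mu, gomp):
        char = characterize_sample(noisy_plate, "sampleA", "RFP",
                                   method="inverse", lambda_reg=1e-4)
        assert char.reliable and char.n_replicates >= 8
        # z-normalized truth on the same tau grid
        t0 = gomp.peak_time
        truth_vals = smooth_phi(char.tau + t0)
        truth_z = (truth_vals - truth_vals.mean()) / truth_vals.std()
        rmsd = np.sqrt(np.mean((char.z_mean - truth_z) ** 2))
        assert rmsd < 0.2

    def test_noise_free_pipeline_recovers_truth(self, clean_plate, smooth_phi,
                                                gomp):
        char = characterize_sample(clean_plate, "sampleA", "RFP",
                                   method="inverse", lambda_reg=0.0)
        truth_vals = smooth_phi(char.tau + gomp.peak_time)
        truth_z = (truth_vals - truth_vals.mean()) / truth_vals.std()
        assert np.mean((char.z_mean - truth_z) ** 2) < 1e-3

    def test_two_samples_same_truth_agree(self, gomp_mu, smooth_phi):
        chars = []
        for seed in (21, 22):
            plate = build_synthetic_plate(gomp_mu, smooth_phi, n_replicates=6,
                                          noise=kr.NoiseSpec(sigma=0.01),
                                          seed=seed)
            chars.append(characterize_sample(plate, "sampleA", "RFP",
                                             method="inverse", lambda_reg=1e-4))
        rec = compare_to_reference(chars[0].mean_profile, chars[1].mean_profile)
        assert rec.rmsd < 0.2
        assert rec.pearson_r > 0.95

    def test_time_shift_invariance(self, gomp, smooth_phi):
        """A 1 h biological delay of the whole experiment is absorbed by the
        tau synchronization: normalized profiles match within RMSD 0.05."""
        def delayed(fn, delay):
            return lambda t: fn(np.clip(np.asarray(t, float) - delay, 0, None))

        mu = lambda t: kr.gompertz_growth_rate(gomp, t)
        base = build_synthetic_plate(mu, smooth_phi, n_replicates=4,
                                     noise=kr.NoiseSpec(sigma=0.0), seed=5)
        shifted = build_synthetic_plate(delayed(mu, 1.0), delayed(smooth_phi, 1.0),
                                        n_replicates=4,
                                        noise=kr.NoiseSpec(sigma=0.0), seed=5)
        a = characterize_sample(base, "sampleA", "RFP", lambda_reg=0.0)
        b = characterize_sample(shifted, "sampleA", "RFP", lambda_reg=0.0)
        rec = compare_to_reference(a.mean_profile, b.mean_profile)
        assert rec.rmsd < 0.05

    def test_zero_fluorescence_sample_flagged(self, gomp_mu):
        plate = build_synthetic_plate(gomp_mu,
                                      lambda t: np.zeros_like(np.asarray(t, float)),
                                      n_replicates=3,
                                      noise=kr.NoiseSpec(sigma=0.0), seed=6)
        with pytest.raises(ValueError, match="no usable replicates"):
            with pytest.warns(RuntimeWarning):
                characterize_sample(plate, "sampleA", "RFP", lambda_reg=0.0)
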