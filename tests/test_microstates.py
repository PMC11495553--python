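"""Microstate segmentation, parameters and features."""

import numpy as np
import pytest

from rsbagging.eeg_io import Recording
from rsbagging.microstates import (
    backfit,
    compute_gfp,
    gfp_peaks,
    microstate_features,
    microstate_parameters,
    modified_kmeans,
    MicrostatePrototypes,
    MicrostateSegmentation,
)
from rsbagging.synthetic import MicrostateSpec, gen_microstate_eeg, random_templates


@pytest.fixture(scope="module")
def planted():
    """4 orthogonal templates, 80 ms mean duration, high SNR."""
    tmpl = random_templates(4, 20, seed=1)
    spec = MicrostateSpec(templates=tmpl, mean_duration_ms=80.0,
                          noise_sd=0.3, duration_s=40, fs=250.0, seed=2)
    rec, truth = gen_microstate_eeg(spec)
    return tmpl, rec, truth


def true_run_stats(truth: np.ndarray, fs: float, k: int):
    """Per-state duration (ms), occurrence (1/s), coverage from true labels."""
    runs = []
    s = 0
    for t in range(1, len(truth) + 1):
        if t == len(truth) or truth[t] != truth[s]:
            runs.append((truth[s], t - s))
            s = t
    total_s = len(truth) / fs
    out = {}
    for state in range(k):
        lens = [ln for st, ln in runs if st == state]
        out[state] = (
            np.mean(lens) / fs * 1000.0,
            len(lens) / total_s,
            sum(lens) / len(truth),
        )
    return out


class TestGFP:
    def test_zero_sample(self):
        rec = Recording(np.zeros((3, 10)), 100.0, ["a", "b", "c"])
        assert np.all(compute_gfp(rec).values == 0)

    def test_plus_minus_one(self):
        rec = Recording(np.array([[1.0], [-1.0]]), 100.0, ["a", "b"])
        assert compute_gfp(rec).values[0] == pytest.approx(1.0)

    def test_white_noise_gfp_near_sigma(self, rng):
        sigma = 4.0
        rec = Recording(sigma * rng.standard_normal((50, 5000)), 100.0,
                        [f"c{i}" for i in range(50)])
        # average reference removes 1/n of the variance
        expected = sigma * np.sqrt(1 - 1 / 50)
        assert compute_gfp(rec).values.mean() == pytest.approx(expected, rel=0.02)

    def test_auto_rereference_warns(self, rng):
        rec = Recording(rng.standard_normal((3, 100)) + 100.0, 100.0,
                        ["a", "b", "c"])
        with pytest.warns(UserWarning):
            compute_gfp(rec)


class TestModifiedKMeans:
    def test_single_template_with_sign_flips(self, rng):
        tmpl = random_templates(1, 10, seed=3)[0]
        signs = rng.choice([-1.0, 1.0], size=50)
        maps = np.outer(signs, tmpl) * rng.uniform(5, 15, size=(50, 1))
        protos = modified_kmeans(maps, k=1, restarts=3, seed=0)
        assert abs(protos.maps[0] @ tmpl) == pytest.approx(1.0, abs=1e-9)

    def test_recovers_planted_templates(self, planted):
        tmpl, rec, _ = planted
        peaks = gfp_peaks(rec)
        protos = modified_kmeans(rec.data[:, peaks].T, k=4, restarts=10, seed=0)
        corr = np.abs(protos.maps @ tmpl.T)
        # one-to-one matching: every template found by a distinct prototype
        assert (corr.max(axis=1) > 0.95).all()
        assert len(set(corr.argmax(axis=1))) == 4

    def test_k_sweep_2_to_30_accepted(self, rng):
        maps = rng.standard_normal((60, 20))
        for k in (2, 15, 30):
            protos = modified_kmeans(maps, k=k, restarts=2, seed=0)
            assert protos.k == k

    def test_identical_seeds_identical_results(self, rng):
        maps = rng.standard_normal((80, 12))
        p1 = modified_kmeans(maps, 3, restarts=5, seed=7)
        p2 = modified_kmeans(maps, 3, restarts=5, seed=7)
        np.testing.assert_array_equal(p1.maps, p2.maps)

    def test_more_restarts_never_decrease_gev(self, rng):
        maps = rng.standard_normal((100, 12))
        g1 = modified_kmeans(maps, 4, restarts=1, seed=3).training_gev
        g10 = modified_kmeans(maps, 4, restarts=10, seed=3).training_gev
        assert g10 >= g1 - 1e-12

    def test_gev_nondecreasing_in_k(self, rng):
        tmpl = random_templates(5, 20, seed=5)
        rec, _ = gen_microstate_eeg(MicrostateSpec(
            templates=tmpl, noise_sd=2.0, duration_s=20, fs=250.0, seed=6))
        maps = rec.data[:, gfp_peaks(rec)].T
        gevs = [modified_kmeans(maps, k, restarts=20, seed=0).training_gev
                for k in range(2, 9)]
        assert all(b >= a - 1e-6 for a, b in zip(gevs, gevs[1:]))
        assert all(0 <= g <= 1 for g in gevs)


class TestBackfit:
    def test_exact_prototype_samples(self):
        protos = MicrostatePrototypes(random_templates(3, 8, seed=0))
        data = np.vstack([protos.maps[2], -protos.maps[2],
                          protos.maps[2]]).T * 10.0
        rec = Recording(data, 100.0, [f"c{i}" for i in range(8)])
        seg = backfit(rec, protos)
        assert np.all(seg.labels == 2)

    def test_alternating_templates_recover_runs(self):
        tmpl = random_templates(2, 8, seed=1)
        fs = 500.0
        run = int(0.040 * fs)  # 40 ms
        labels = np.tile(np.repeat([0, 1], run), 20)
        data = tmpl[labels].T * 10.0
        rec = Recording(data, fs, [f"c{i}" for i in range(8)])
        seg = backfit(rec, MicrostatePrototypes(tmpl))
        np.testing.assert_array_equal(seg.labels, labels)

    def test_zero_smoothing_is_identity(self, planted):
        _, rec, _ = planted
        protos = MicrostatePrototypes(random_templates(4, 20, seed=9))
        s0 = backfit(rec, protos, min_duration_ms=0.0)
        s1 = backfit(rec, protos)
        np.testing.assert_array_equal(s0.labels, s1.labels)

    def test_global_sign_flip_invariance(self, planted):
        _, rec, _ = planted
        peaks = gfp_peaks(rec)
        p1 = modified_kmeans(rec.data[:, peaks].T, 4, restarts=5, seed=0)
        flipped = Recording(-rec.data, rec.fs, rec.channel_labels, "flip")
        p2 = modified_kmeans(flipped.data[:, gfp_peaks(flipped)].T, 4,
                             restarts=5, seed=0)
        s1 = backfit(rec, p1)
        s2 = backfit(flipped, p2)
        # maps agree up to sign and order; segmentations agree up to relabel
        m = np.abs(p1.maps @ p2.maps.T)
        assert np.allclose(np.sort(m.max(axis=1)), 1.0, atol=1e-6)
        perm = m.argmax(axis=1)
        np.testing.assert_array_equal(perm[s1.labels], s2.labels)


class TestParameters:
    def test_single_state(self):
        protos = MicrostatePrototypes(random_templates(1, 6, seed=0))
        rec = Recording(np.tile(protos.maps[0], (100, 1)).T * 5.0, 100.0,
                        [f"c{i}" for i in range(6)])
        seg = MicrostateSegmentation(np.zeros(100, dtype=int), 100.0)
        p = microstate_parameters(seg, rec, protos)
        assert p.coverage[0] == pytest.approx(1.0)
        assert p.occurrence_per_s[0] == pytest.approx(1.0)  # 1 run in 1 s
        assert p.duration_ms[0] == pytest.approx(1000.0)

    def test_two_alternating_states(self):
        tmpl = random_templates(2, 6, seed=1)
        fs = 1000.0
        run = 50  # 50 ms
        labels = np.tile(np.repeat([0, 1], run), 10)
        rec = Recording(tmpl[labels].T * 3.0, fs,
                        [f"c{i}" for i in range(6)])
        p = microstate_parameters(MicrostateSegmentation(labels, fs), rec,
                                  MicrostatePrototypes(tmpl))
        np.testing.assert_allclose(p.coverage, [0.5, 0.5])
        np.testing.assert_allclose(p.occurrence_per_s, [10.0, 10.0])
        np.testing.assert_allclose(p.duration_ms, [50.0, 50.0])

    def test_coverage_identity_and_sum(self, planted):
        """coverage == occurrence x mean duration; coverages sum to 1."""
        tmpl, rec, _ = planted
        protos = MicrostatePrototypes(tmpl)
        seg = backfit(rec, protos)
        p = microstate_parameters(seg, rec, protos)
        assert p.coverage.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            p.coverage, p.occurrence_per_s * p.duration_ms / 1000.0, atol=1e-9
        )
        assert p.gev.sum() <= 1.0 and np.all(p.gev >= 0)

    def test_recovery_of_planted_parameters(self, planted):
        """Backfit statistics within 10% of the ground-truth label statistics."""
        tmpl, rec, truth = planted
        protos = MicrostatePrototypes(tmpl)
        seg = backfit(rec, protos)
        p = microstate_parameters(seg, rec, protos)
        expected = true_run_stats(truth, rec.fs, 4)
        for state in range(4):
            dur, occ, cov = expected[state]
            assert p.duration_ms[state] == pytest.approx(dur, rel=0.10)
            assert p.occurrence_per_s[state] == pytest.approx(occ, rel=0.10)
            assert p.coverage[state] == pytest.approx(cov, rel=0.10)

    def test_missing_state_warns_with_zeros(self):
        tmpl = random_templates(3, 6, seed=2)
        rec = Recording(np.tile(tmpl[0], (200, 1)).T * 4.0, 100.0,
                        [f"c{i}" for i in range(6)])
        seg = MicrostateSegmentation(np.zeros(200, dtype=int), 100.0)
        with pytest.warns(UserWarning):
            p = microstate_parameters(seg, rec, MicrostatePrototypes(tmpl))
        assert p.coverage[1] == 0 and p.duration_ms[2] == 0


class TestFeatures:
    @pytest.mark.parametrize("k,length", [(2, 10), (16, 80)])
    def test_feature_length_is_5k(self, planted, k, length):
        _, rec, _ = planted
        fv = microstate_features(rec, k, restarts=3, seed=0)
        assert len(fv.values) == length

    def test_k_out_of_range(self, planted):
        _, rec, _ = planted
        with pytest.raises(ValueError):
            microstate_features(rec, 1)
        with pytest.raises(ValueError):
            microstate_features(rec, 31)

    def test_coverage_ordering(self, planted):
        _, rec, _ = planted
        fv = microstate_features(rec, 4, restarts=5, seed=0)
        coverages = fv.values[3::5]
        assert np.all(np.diff(coverages) <= 1e-12)

    def test_channel_permutation_invariance(self, planted):
        _, rec, _ = planted
        rng = np.random.default_rng(0)
        perm = rng.permutation(rec.n_channels)
        rec_p = Recording(rec.data[perm], rec.fs,
                          [rec.channel_labels[i] for i in perm], "perm")
        fv1 = microstate_features(rec, 4, restarts=5, seed=0)
        fv2 = microstate_features(rec_p, 4, restarts=5, seed=0)
        np.testing.assert_allclose(fv1.values, fv2.values, atol=1e-6)
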