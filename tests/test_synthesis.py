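import numpy as np
import pytest
from scipy.stats import multivariate_normal

from hsibg.core import Hypercube
from hsibg.correction import rb_correct
from hsibg.synthesis import (
    SpectrumLibrary,
    SynthConfig,
    gaussian_density,
    make_background_cube,
    make_phantom_layout,
    noise_robustness_sim,
    sample_illumination,
    synth_gt_cube,
    synth_triplet,
    to_absorbance_triplet,
)
from hsibg.classification import generate_condition_cubes


def local_maxima(spectrum):
    s = np.asarray(spectrum)
    return {
        i for i in range(1, len(s) - 1) if s[i] > s[i - 1] and s[i] > s[i + 1]
    }


class TestSpectrumLibrary:
    def test_blood_peak_locations(self, library100, grid300):
        lib300 = SpectrumLibrary.default(grid300)
        for lib in (library100, lib300):
            oxy = local_maxima(lib.absorbance("blood_oxy"))
            assert lib.grid.index_of(540) in oxy and lib.grid.index_of(560) in oxy
            deoxy = local_maxima(lib.absorbance("blood_deoxy"))
            assert lib.grid.index_of(550) in deoxy

    def test_reference_wavelength_absorption(self, library100):
        ref = library100.grid.index_of(800)
        mb = library100.absorbance("methylene_blue")
        assert mb[ref] < 0.01
        nig = library100.absorbance("nigrosin")
        assert 0 < nig[ref] < 0.5 * nig.max()

    def test_reflectance_spectra_within_unit_interval(self, library100):
        for name, rho in library100.samples.items():
            assert np.all(rho > 0) and np.all(rho <= 1), name


class TestIllumination:
    def test_deterministic_and_scaled_to_unit_max(self):
        a = sample_illumination((32, 48), seed=7)
        b = sample_illumination((32, 48), seed=7)
        assert np.array_equal(a.m, b.m)
        assert a.m.max() == 1.0
        assert a.m.min() >= 0.05

    def test_wide_sigma_tends_to_uniform(self):
        field = sample_illumination((16, 16), seed=3, sigma_frac=100.0)
        assert field.m.min() > 0.999

    def test_density_matches_closed_form_gaussian(self):
        centre, sigma = (5.0, 11.0), 4.0
        d = gaussian_density((12, 20), centre, sigma)
        mvn = multivariate_normal(mean=centre, cov=sigma**2 * np.eye(2))
        x, y = np.meshgrid(np.arange(12), np.arange(20), indexing="ij")
        pts = np.stack([x.ravel(), y.ravel()], axis=1)
        expected = mvn.pdf(pts).reshape(12, 20)
        ratio = d / expected
        assert np.allclose(ratio, ratio[0, 0], rtol=1e-10)


class TestBackgroundCube:
    def test_unit_power_reproduces_source_everywhere(self, library100):
        ill = sample_illumination((4, 5), seed=0, sigma_frac=1e6)
        ill = type(ill)(np.ones((4, 5)), ill.centre, 0)
        bg = make_background_cube(ill, library100.source, library100.grid)
        assert np.allclose(bg.field, library100.source[None, None, :])

    def test_separability_ratio_is_wavelength_independent(self, library100):
        ill = sample_illumination((6, 7), seed=1)
        bg = make_background_cube(ill, library100.source, library100.grid)
        ratio = bg.field / library100.source[None, None, :]
        assert np.allclose(ratio, ill.m[:, :, None], rtol=1e-12)

    def test_matches_double_loop_oracle(self, library100, rng):
        ill = sample_illumination((3, 4), seed=2)
        bg = make_background_cube(ill, library100.source, library100.grid)
        for x in range(3):
            for y in range(4):
                for k in (0, 17, 99):
                    assert bg.field[x, y, k] == ill.m[x, y] * library100.source[k]


class TestPhantomLayout:
    def test_all_classes_present_and_scaled_radius(self):
        for shape in ((256, 512), (64, 128)):
            layout = make_phantom_layout(shape)
            assert set(np.unique(layout.labels)) == {0, 1, 2, 3}

    def test_rejects_missing_classes(self):
        from hsibg.synthesis import PhantomLayout

        with pytest.raises(ValueError):
            PhantomLayout(np.zeros((8, 8), dtype=int))


class TestSynthGTCube:
    @pytest.fixture
    def cfg(self):
        return SynthConfig(shape=(16, 24), n_channels=100, n_train=2, n_test=1, seed=5)

    def test_noiseless_limit_equals_class_spectra(self, library100, cfg):
        layout = make_phantom_layout(cfg.shape)
        quiet = SynthConfig(
            shape=cfg.shape, n_channels=100, n_train=2, n_test=1,
            alpha_max=1e-12, seed=5,
        )
        scene = synth_gt_cube(layout, library100, quiet, seed=3)
        from hsibg.synthesis import PHANTOM_CLASSES

        base = np.stack([library100.samples[n] for n in PHANTOM_CLASSES])
        assert np.allclose(scene.gt.data, base[layout.labels], rtol=1e-10)

    def test_noise_stays_below_alpha_max_of_signal(self, library100, cfg):
        layout = make_phantom_layout(cfg.shape)
        scene = synth_gt_cube(layout, library100, cfg, seed=3)
        from hsibg.synthesis import PHANTOM_CLASSES

        base = np.stack([library100.samples[n] for n in PHANTOM_CLASSES])[layout.labels]
        rel = np.abs(scene.gt.data - base) / base
        assert rel.max() <= cfg.alpha_max + 1e-12

    def test_seeded_replay_oracle(self, library100, cfg):
        layout = make_phantom_layout(cfg.shape)
        scene = synth_gt_cube(layout, library100, cfg, seed=11)
        from hsibg.synthesis import PHANTOM_CLASSES

        base = np.stack([library100.samples[n] for n in PHANTOM_CLASSES])[layout.labels]
        replay = base * (
            1.0 + scene.alpha[:, :, None] * library100.noise_pool[scene.noise_index]
        )
        assert np.array_equal(scene.gt.data, np.maximum(replay, 1e-12))

    def test_reproducible_and_seed_sensitive(self, library100, cfg):
        layout = make_phantom_layout(cfg.shape)
        a = synth_gt_cube(layout, library100, cfg, seed=3)
        b = synth_gt_cube(layout, library100, cfg, seed=3)
        c = synth_gt_cube(layout, library100, cfg, seed=4)
        assert np.array_equal(a.gt.data, b.gt.data)
        assert not np.array_equal(a.gt.data, c.gt.data)


class TestSynthTriplet:
    @pytest.fixture
    def pieces(self, library100):
        cfg = SynthConfig(shape=(12, 16), n_channels=100, n_train=2, n_test=1, seed=9)
        layout = make_phantom_layout(cfg.shape)
        scene = synth_gt_cube(layout, library100, cfg, seed=21)
        ill = sample_illumination(cfg.shape, seed=22)
        return cfg, scene, ill

    def test_uniform_illumination_collapses_the_triplet(self, library100, pieces):
        from hsibg.synthesis import IlluminationField

        cfg, scene, ill = pieces
        flat = IlluminationField(np.ones(cfg.shape), (0.0, 0.0), 0)
        triplet = synth_triplet(scene, flat, library100)
        assert np.allclose(triplet.sb.data, triplet.gt.data, rtol=1e-12)
        keep = library100.profile().reliable_channels
        # RB deviates from GT only through the min-max vs proportional
        # normalisation mismatch of the source, which is small away from the
        # blue band edge
        interior = keep & (library100.grid.values > 520)
        assert np.allclose(
            triplet.rb.data[:, :, interior],
            triplet.gt.data[:, :, interior]
            / triplet.gt.data[:, :, library100.profile().ref_index][:, :, None],
            rtol=0.05,
        )

    def test_sb_over_gt_ratio_equals_illumination(self, library100, pieces):
        cfg, scene, ill = pieces
        triplet = synth_triplet(scene, ill, library100)
        ratio = triplet.sb.data / triplet.gt.data
        assert np.allclose(ratio, ill.m[:, :, None], rtol=1e-10)

    def test_rb_path_is_shared_with_rb_correct(self, library100, pieces):
        cfg, scene, ill = pieces
        profile = library100.profile()
        triplet = synth_triplet(scene, ill, library100, profile)
        bg = make_background_cube(ill, library100.source, library100.grid)
        raw = Hypercube(bg.field * scene.gt.data, library100.grid, kind="counts")
        recomputed = rb_correct(raw, profile, mode="reflectance")
        assert np.array_equal(triplet.rb.data, recomputed.data)

    def test_absorbance_triplet_offset_law_and_oracle(self, library100, pieces):
        cfg, scene, ill = pieces
        triplet = synth_triplet(scene, ill, library100)
        abs_triplet = to_absorbance_triplet(triplet)
        offsets = abs_triplet.sb.data - abs_triplet.gt.data
        assert np.allclose(offsets, -np.log10(ill.m)[:, :, None], atol=1e-10)
        assert np.allclose(abs_triplet.gt.data, -np.log10(triplet.gt.data), rtol=1e-12)


class TestDatasetSplits:
    def test_train_and_test_share_no_noise_draws(self, library100):
        cfg = SynthConfig(shape=(12, 16), n_channels=100, n_train=2, n_test=2, seed=33)
        layout = make_phantom_layout(cfg.shape)
        root = np.random.SeedSequence(cfg.seed)
        train_seq, test_seq = root.spawn(2)
        train_alphas = []
        test_alphas = []
        for seq, sink in ((train_seq, train_alphas), (test_seq, test_alphas)):
            for child in seq.spawn(2):
                seed = int(child.generate_state(1)[0] % 2**31)
                sub = np.random.SeedSequence(seed).generate_state(2)
                scene = synth_gt_cube(layout, library100, cfg, int(sub[1] % 2**31))
                sink.append(scene.alpha.ravel())
        shared = np.intersect1d(np.concatenate(train_alphas), np.concatenate(test_alphas))
        assert shared.size == 0

    def test_condition_cubes_are_reproducible(self, library100):
        cfg = SynthConfig(shape=(8, 12), n_channels=100, n_train=1, n_test=1, seed=2)
        a = generate_condition_cubes(cfg, library100, "absorbance", "test")
        b = generate_condition_cubes(cfg, library100, "absorbance", "test")
        for cond in ("GT", "SB", "RB"):
            assert np.array_equal(a[cond][0].spectra, b[cond][0].spectra)


class TestNoiseRobustness:
    def test_zero_noise_gives_zero_error(self, library100):
        raw = library100.source * library100.samples["blood_oxy"]
        table = noise_robustness_sim(
            raw, library100.profile(), noise_levels=[0.0], n_reps=3, seed=0
        )
        assert table["mean_pct_error"].iloc[0] == 0.0

    def test_error_grows_with_noise_level(self, library100):
        raw = library100.source * library100.samples["blood_oxy"]
        table = noise_robustness_sim(
            raw, library100.profile(), noise_levels=[0.01, 0.05, 0.10, 0.20],
            n_reps=40, seed=1,
        )
        means = table["mean_pct_error"].to_numpy()
        assert np.all(np.diff(means) >= 0)

    def test_single_draw_matches_hand_computation(self, grid100, ramp_profile):
        """One fixed noise draw reproduces a from-scratch retrieval-and-log
        computation done with plain array arithmetic."""
        rng = np.random.default_rng(77)
        spectrum = ramp_profile.ns * 0.6 + 0.2  # positive raw spectrum
        level = 0.1
        noisy = np.maximum(spectrum * (1 + level * rng.standard_normal(spectrum.size)), 1e-9)
        keep = ramp_profile.reliable_channels
        ns_c = ramp_profile.ns_clamped
        k = ramp_profile.ref_index

        def rb_abs(s):
            rm = (s[k] / ramp_profile.cb) * ns_c
            return -np.log10(np.maximum(s / rm, 1e-6))

        a0, a1 = rb_abs(spectrum), rb_abs(noisy)
        expected = 100 * np.mean(np.abs(a1 - a0)[keep]) / np.mean(np.abs(a0[keep]))
        table = noise_robustness_sim(
            spectrum, ramp_profile, noise_levels=[level], n_reps=1, seed=77
        )
        assert table["mean_pct_error"].iloc[0] == pytest.approx(expected, rel=1e-9)
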