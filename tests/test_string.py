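"""String method: path handling, exchange sampling, mean-force integration."""

import numpy as np
import pytest

from loopstring.potentials import (
    HarmonicWell,
    make_three_well_potential,
    make_two_well_potential,
)
from loopstring.stringmethod import (
    FreeEnergyProfile,
    ImageSample,
    RefinementConfig,
    StringImage,
    StringPath,
    detect_metastable_states,
    init_images_from_trajectory,
    init_path_linear,
    integrate_mean_forces,
    profile_disagreement,
    refine,
    sample_images_with_exchange,
    update_path,
)
from loopstring.structures import AtomSelection, Trajectory


def _point_path(points, k=10.0):
    sel = AtomSelection((0,))
    return StringPath([StringImage(np.atleast_2d(p), k) for p in points], sel)


class TestInitPath:
    def test_three_image_midpoint(self, rng):
        a = rng.normal(size=(5, 3))
        b = a + np.array([1.0, 0, 0])
        path = init_path_linear(a, b, 3, align=False)
        np.testing.assert_allclose(
            path.images[1].reference, 0.5 * (a + b), atol=1e-12
        )

    def test_two_images_are_the_endpoints(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        path = init_path_linear(a, b, 2, align=False)
        np.testing.assert_array_equal(path.images[0].reference, a)
        np.testing.assert_array_equal(path.images[1].reference, b)

    def test_even_arc_spacing(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        path = init_path_linear(a, b, 10, align=False)
        gaps = np.diff(path.arc_lengths())
        assert np.ptp(gaps) < 1e-6 * gaps.mean()


class TestInitFromTrajectory:
    def test_exact_frames_selected_with_zero_rmsd(self):
        pts = [np.array([[float(i), 0.0, 0.0]]) for i in range(5)]
        path = _point_path(pts)
        frames = [np.array([[float(i), 0.0, 0.0]]) for i in range(5)]
        traj = Trajectory(frames, np.arange(5.0))
        chosen, starts = init_images_from_trajectory(traj, path)
        np.testing.assert_array_equal(chosen, np.arange(5))
        np.testing.assert_allclose(np.array(starts)[:, 0, 0], np.arange(5.0))

    def test_monotone_trajectory_gives_monotone_indices(self, rng):
        # brute force over all frame x image pairs confirms monotonicity
        pts = [np.array([[t, 0.0, 0.0]]) for t in np.linspace(0, 4, 9)]
        path = _point_path(pts)
        ts = np.sort(rng.uniform(0, 4, size=40))
        frames = [np.array([[t, 0.0, 0.0]]) for t in ts]
        traj = Trajectory(frames, np.arange(40.0))
        chosen, _ = init_images_from_trajectory(traj, path)
        assert np.all(np.diff(chosen) >= 0)
        for img_i, fr_i in enumerate(chosen):
            dists = [abs(t - pts[img_i][0, 0]) for t in ts]
            assert dists[fr_i] == pytest.approx(min(dists))

    def test_tie_broken_by_earliest_frame(self):
        path = _point_path([np.array([[0.0, 0.0, 0.0]])])
        frames = [np.array([[-1.0, 0.0, 0.0]]), np.array([[1.0, 0.0, 0.0]])]
        traj = Trajectory(frames, np.array([0.0, 1.0]))
        chosen, _ = init_images_from_trajectory(traj, path)
        assert chosen[0] == 0


class TestExchangeSampling:
    def test_identical_references_always_accept(self):
        model = HarmonicWell(kappa=1.0, dim=1, temperature=300.0)
        ref = np.array([[0.2]])
        path = StringPath(
            [StringImage(ref, 5.0), StringImage(ref, 5.0)], AtomSelection((0,))
        )
        cfg = RefinementConfig(
            n_images=3, sampling_time=1.0, exchange_interval=0.05,
            timestep=0.005, temperature=300.0, burn_in=0.0,
        )
        _, stats = sample_images_with_exchange(model, path, cfg, 7)
        assert stats.acceptance.iloc[0] == 1.0

    def test_same_seed_reproduces_samples(self):
        model = HarmonicWell(kappa=2.0, dim=1, temperature=300.0)
        path = _point_path([np.array([[0.0]]), np.array([[0.3]]), np.array([[0.6]])])
        cfg = RefinementConfig(
            n_images=3, sampling_time=0.5, exchange_interval=0.05,
            timestep=0.005, temperature=300.0,
        )
        s1, _ = sample_images_with_exchange(model, path, cfg, 99)
        s2, _ = sample_images_with_exchange(model, path, cfg, 99)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.mean_positions, b.mean_positions)

    def test_walker_distribution_matches_boltzmann(self):
        # covered in depth by the acceptance suite; quick sanity: the mean of
        # the restrained walker sits at k*ref/(kappa+k)
        model = HarmonicWell(kappa=2.0, dim=1, temperature=300.0)
        ref = np.array([[0.5]])
        path = StringPath([StringImage(ref, 10.0), StringImage(ref, 10.0)],
                          AtomSelection((0,)))
        cfg = RefinementConfig(
            n_images=3, sampling_time=30.0, exchange_interval=0.5,
            timestep=0.005, friction=2.0, temperature=300.0,
        )
        samples, _ = sample_images_with_exchange(model, path, cfg, 13)
        expected = 10.0 * 0.5 / 12.0
        assert samples[0].mean_positions.item() == pytest.approx(expected, abs=0.03)


class TestUpdatePath:
    def _samples_from(self, means):
        return [
            ImageSample(np.atleast_2d(m), np.zeros_like(np.atleast_2d(m)), 1)
            for m in means
        ]

    def test_straight_line_is_a_fixed_point(self):
        means = [np.array([[t, 0.0]]) for t in np.linspace(0, 3, 12)]
        path = _point_path([m[0] for m in means])
        new = update_path(self._samples_from(means), None, path)
        np.testing.assert_allclose(
            new.references(), path.references(), atol=1e-6
        )

    def test_endpoints_fixed_under_noise(self, rng):
        truth = [np.array([[t, np.sin(t)]]) for t in np.linspace(0, 3, 15)]
        path = _point_path([m[0] for m in truth])
        noisy = [m + rng.normal(scale=0.05, size=(1, 2)) for m in truth]
        new = update_path(self._samples_from(noisy), None, path)
        np.testing.assert_array_equal(
            new.images[0].reference, path.images[0].reference
        )
        np.testing.assert_array_equal(
            new.images[-1].reference, path.images[-1].reference
        )

    def test_smoothing_recovers_known_curve(self, rng):
        ts = np.linspace(0, np.pi, 25)
        truth = np.stack([ts, np.sin(ts)], axis=1)
        path = _point_path(list(truth))
        sigma = 0.05
        noisy = [
            t[None, :] + rng.normal(scale=sigma, size=(1, 2)) for t in truth
        ]
        new = update_path(self._samples_from(noisy), None, path)
        refs = new.references().reshape(-1, 2)
        # pointwise distance to the dense true curve: smoothing beats noise
        dense_t = np.linspace(0, np.pi, 2000)
        dense = np.stack([dense_t, np.sin(dense_t)], axis=1)
        err = [np.min(np.linalg.norm(dense - p, axis=1)) for p in refs]
        assert np.median(err) < sigma
        assert max(err) < 3 * sigma

    def test_reparametrization_gaps_within_two_percent(self, rng):
        truth = [np.array([[t, t**2 / 3]]) for t in np.linspace(0, 3, 20)]
        path = _point_path([m[0] for m in truth])
        noisy = [m + rng.normal(scale=0.02, size=(1, 2)) for m in truth]
        new = update_path(self._samples_from(noisy), None, path)
        gaps = np.diff(new.arc_lengths())
        assert np.ptp(gaps) / gaps.mean() < 0.02

    def test_bad_breaks_rejected(self):
        means = [np.array([[t, 0.0]]) for t in np.linspace(0, 3, 10)]
        path = _point_path([m[0] for m in means])
        with pytest.raises(ValueError):
            update_path(self._samples_from(means), None, path, minima_breaks=[0])
        with pytest.raises(ValueError):
            update_path(self._samples_from(means), None, path, minima_breaks=[9])


class TestFreeEnergy:
    def test_flat_profile_for_means_at_references(self):
        pts = [np.array([t, 0.0]) for t in np.linspace(0, 2, 8)]
        path = _point_path(pts)
        samples = [
            ImageSample(im.reference.copy(), np.zeros_like(im.reference), 1)
            for im in path.images
        ]
        prof = integrate_mean_forces(samples, path)
        np.testing.assert_array_equal(prof.free_energy, np.zeros(8))

    def test_harmonic_closed_form_from_analytic_means(self):
        # <x> = k s/(kappa+k) exactly; integration must recover (1/2) kappa s^2
        kappa, k = 2.0, 200.0
        s_vals = np.linspace(0.0, 1.5, 11)
        path = _point_path([np.array([s]) for s in s_vals], k=k)
        samples = [
            ImageSample(
                np.array([[k * s / (kappa + k)]]),
                k * (np.array([[k * s / (kappa + k)]]) - np.array([[s]])),
                1,
            )
            for s in s_vals
        ]
        prof = integrate_mean_forces(samples, path)
        exact = 0.5 * kappa * s_vals**2
        np.testing.assert_allclose(prof.free_energy[1:], exact[1:], rtol=0.05)

    def test_gauge_invariance_under_potential_offset(self):
        pot1 = make_two_well_potential(4.0)
        pot2 = make_two_well_potential(4.0)
        pot2.offset = 123.0
        path = _point_path(
            [np.array([t, 0.0]) for t in np.linspace(-1.4, 1.4, 8)], k=40.0
        )
        cfg = RefinementConfig(
            n_images=3, sampling_time=1.0, exchange_interval=0.1,
            timestep=0.005, temperature=150.0,
        )
        s1, _ = sample_images_with_exchange(pot1, path, cfg, 5)
        s2, _ = sample_images_with_exchange(pot2, path, cfg, 5)
        p1 = integrate_mean_forces(s1, path)
        p2 = integrate_mean_forces(s2, path)
        np.testing.assert_array_equal(p1.free_energy, p2.free_energy)

    def test_profile_anchored_at_zero(self):
        with pytest.raises(ValueError):
            FreeEnergyProfile(np.arange(3.0), np.array([1.0, 0.0, 0.0]))


class TestMetastableStates:
    def test_monotone_profile_has_none(self):
        prof = FreeEnergyProfile(np.arange(6.0), np.array([0, 1, 2, 3, 4, 5.0]))
        assert detect_metastable_states(prof, 0.5) == []

    def test_w_shaped_profile(self):
        g = np.array([0.0, 3.0, 1.0, 3.0, 0.5])
        prof = FreeEnergyProfile(np.arange(5.0), g)
        assert detect_metastable_states(prof, 1.0) == [2]

    def test_three_well_energy_profile_consistent_with_oracle(self):
        from loopstring.potentials import locate_critical_points

        pot = make_three_well_potential(4.0)
        xs = np.linspace(-3.0, 3.0, 61)
        g = pot.energy(np.stack([xs, np.zeros_like(xs)], axis=1))
        prof = FreeEnergyProfile(xs - xs[0], g - g[0])
        minima = detect_metastable_states(prof, 0.5)
        assert len(minima) == 1
        mid = [c for c in locate_critical_points(pot, 0.4) if c.kind == "minimum"]
        mid = sorted(mid, key=lambda c: c.position[0])[1]
        assert xs[minima[0]] == pytest.approx(mid.position[0], abs=0.1)


class TestRefine:
    def test_endpoints_never_move_and_gaps_even(self):
        pot = make_two_well_potential(4.0)
        a, b = np.array([[-1.4, 0.0]]), np.array([[1.4, 0.0]])
        path0 = init_path_linear(a, b, 8, align=False, spring_constant=40.0)
        cfg = RefinementConfig(
            n_images=8, spring_constant=40.0, sampling_time=0.5,
            n_iterations=2, exchange_interval=0.1, timestep=0.005,
            temperature=150.0, final_n_images=8, final_spring_constant=40.0,
            final_sampling_time=0.5,
        )
        res = refine(pot, path0, cfg)
        np.testing.assert_array_equal(res.path.images[0].reference, a)
        np.testing.assert_array_equal(res.path.images[-1].reference, b)
        gaps = np.diff(res.path.arc_lengths())
        assert np.ptp(gaps) / gaps.mean() < 0.02

    def test_undersampled_groups_disagree(self):
        # negative control: biased, barely-sampled groups with different
        # initial coordinates must trip the hysteresis detector
        pot = make_two_well_potential(4.0)
        a, b = np.array([[-1.4, 0.0]]), np.array([[1.4, 0.0]])
        path = init_path_linear(a, b, 10, align=False, spring_constant=25.0)
        cfg = RefinementConfig(
            n_images=10, sampling_time=0.2, exchange_interval=0.05,
            timestep=0.005, temperature=150.0, burn_in=0.0,
        )
        on_path = path.references()
        displaced = on_path + np.array([[0.0, 1.5]])
        sa, _ = sample_images_with_exchange(pot, path, cfg, 1, on_path)
        sb, _ = sample_images_with_exchange(pot, path, cfg, 2, displaced)
        pa = integrate_mean_forces(sa, path, "a")
        pb = integrate_mean_forces(sb, path, "b")
        assert profile_disagreement(pa, pb) > 4.0
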