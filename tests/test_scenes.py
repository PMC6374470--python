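"""Ground-truth generator: geometry, dynamics, rendering, reproducibility."""

import math

import numpy as np
import pytest

import punctakit as pk
from punctakit.scenes import _sample_perinuclear

from conftest import snr_render_params


def static_params(**kw):
    kw.setdefault("rng_seed", 7)
    return pk.SceneParams(**kw)


class TestSceneGeometry:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            pk.SceneParams(cell_radius=3.0, nucleus_radius=4.0)
        with pytest.raises(ValueError):
            pk.SceneParams(image_size=(64, 64), pixel_size=0.1,
                           cell_radius=12.0)  # cell larger than the image

    def test_zero_diffusion_spread_spots_are_static_and_in_cytoplasm(self):
        p = static_params(n_frames=8)
        scene = pk.make_scene(p, [pk.PunctaPopulation(
            n_spots=60, spatial_mode="spread", diffusion_coeff=0.0)])
        for s in scene.spots:
            assert np.all(s.positions == s.positions[0])
            assert p.in_cytoplasm(s.positions).all()

    def test_brownian_spots_stay_in_cytoplasm(self):
        p = static_params(n_frames=30)
        scene = pk.make_scene(p, [pk.PunctaPopulation(
            n_spots=20, diffusion_coeff=0.05)])
        for s in scene.spots:
            assert p.in_cytoplasm(s.positions).all()
            assert np.any(s.positions[1:] != s.positions[0])

    def test_perinuclear_radii_match_truncated_exponential_median(self):
        # Golgi at the cell center makes the cytoplasm exactly the radial
        # band [nucleus_radius, cell_radius], so the sampled distance is a
        # doubly truncated exponential with a closed-form quantile.
        p = static_params(image_size=(512, 512), cell_radius=20.0,
                          nucleus_radius=2.0)
        p.golgi_center = p.cell_center
        lam, n = 2.0, 4000
        rng = np.random.default_rng(11)
        r = np.array([np.hypot(*(np.array(_sample_perinuclear(p, lam, rng))
                                 - p.cell_center)) * p.pixel_size
                      for _ in range(n)])
        a, b = p.nucleus_radius, p.cell_radius
        # median of Exp(lam) truncated to [a, b]
        za, zb = math.exp(-a / lam), math.exp(-b / lam)
        med = -lam * math.log(za - 0.5 * (za - zb))
        assert (r >= a - 1e-9).all() and (r <= b + 1e-9).all()
        # Monte-Carlo error of the sample median ~ 1/(2 f(med) sqrt(n))
        assert abs(np.median(r) - med) < 0.15

    def test_perinuclear_spots_concentrate_near_golgi(self):
        p = static_params()
        peri = pk.make_scene(p, [pk.PunctaPopulation(
            n_spots=150, spatial_mode="perinuclear", decay_length=2.0)])
        spread = pk.make_scene(p, [pk.PunctaPopulation(
            n_spots=150, spatial_mode="spread")])
        assert (peri.perinuclear_fraction(7.5)
                > spread.perinuclear_fraction(7.5) + 0.2)

    def test_make_scene_is_reproducible(self):
        p1 = static_params(n_frames=5)
        p2 = static_params(n_frames=5)
        pops = [pk.PunctaPopulation(n_spots=25, diffusion_coeff=0.02)]
        s1 = pk.make_scene(p1, pops)
        s2 = pk.make_scene(p2, pops)
        for a, b in zip(s1.spots, s2.spots):
            assert np.array_equal(a.positions, b.positions)

    def test_impossible_placement_rejected(self):
        p = static_params()
        p.golgi_center = p.cell_center  # decay mass entirely in the nucleus
        huge = pk.PunctaPopulation(n_spots=5, spatial_mode="perinuclear",
                                   decay_length=1e-9)
        with pytest.raises(RuntimeError):
            pk.make_scene(p, [huge])


class TestInteractionConstruction:
    def test_pair_within_vicinity_exactly_on_interaction_frames(self):
        p = static_params(n_frames=20)
        tr = pk.InteractionTruth(start_frame=6, duration=5, vicinity_px=3.0)
        scene = pk.make_scene(p, [], [tr])
        (rid, gid) = scene.interactions[0].pair_ids
        red = next(s for s in scene.spots if s.spot_id == rid)
        green = next(s for s in scene.spots if s.spot_id == gid)
        d = np.hypot(*(red.positions - green.positions).T)
        on = np.zeros(20, dtype=bool)
        on[6:11] = True
        assert (d[on] <= 3.0).all()
        assert (d[~on] > 3.0).all()

    def test_truth_list_recoverable_by_brute_force(self):
        from conftest import brute_force_events, tracks_from_truth

        p = static_params(n_frames=25)
        inters = [pk.InteractionTruth(start_frame=f, duration=4)
                  for f in (2, 10, 18)]
        scene = pk.make_scene(
            p, [pk.PunctaPopulation(n_spots=10, channel_profile="red_only",
                                    diffusion_coeff=0.01),
                pk.PunctaPopulation(n_spots=10, channel_profile="green_only",
                                    diffusion_coeff=0.01)],
            inters)
        tracks = tracks_from_truth(scene)
        found = brute_force_events(tracks["red"], tracks["green"],
                                   pk.InteractionConfig(), p.pixel_size)
        expected = sorted((t.pair_ids[0], t.pair_ids[1], t.start_frame,
                           t.duration) for t in scene.interactions)
        assert [e[:4] for e in found] == expected


class TestRender:
    def test_empty_noise_free_scene_renders_to_zero(self):
        p = static_params()
        scene = pk.SceneTruth(params=p)
        rp = pk.RenderParams(background=0.0, shot_noise=False,
                             read_noise_sd=0.0)
        assert pk.render(scene, rp).sum() == 0.0

    def test_single_spot_argmax_near_truth_and_flux_conserved(self):
        p = static_params()
        scene = pk.make_scene(p, [pk.PunctaPopulation(n_spots=1,
                                                      amplitude_mean=500.0)])
        rp = pk.RenderParams(background=0.0, shot_noise=False,
                             photon_scale=2.0)
        img = pk.render(scene, rp)
        y, x = np.unravel_index(np.argmax(img), img.shape)
        tx, ty = scene.spots[0].positions[0]
        assert np.hypot(x - tx, y - ty) <= 1.0
        # pixel-integrated Gaussian conserves amplitude * photon_scale
        assert img.sum() == pytest.approx(500.0 * 2.0, rel=1e-6)

    def test_render_reproducible_and_noise_statistics(self):
        p = static_params()
        scene = pk.make_scene(p, [pk.PunctaPopulation(n_spots=5)])
        rp = snr_render_params(seed=3)
        a = pk.render(scene, rp)
        b = pk.render(scene, rp)
        assert np.array_equal(a, b)
        flat = pk.render(pk.SceneTruth(params=p), rp)
        assert flat.mean() == pytest.approx(rp.background, rel=0.02)
        assert flat.std() == pytest.approx(math.sqrt(rp.background), rel=0.05)

    def test_bit_depth_clipping(self):
        p = static_params()
        scene = pk.make_scene(p, [pk.PunctaPopulation(n_spots=1,
                                                      amplitude_mean=1e6)])
        img8 = pk.render(scene, pk.RenderParams(bit_depth=8, shot_noise=False,
                                                background=0.0))
        assert img8.max() == 255.0


class TestFrapAndEmGenerators:
    def test_frap_trace_endpoints_and_closed_form(self):
        tr = pk.make_frap_trace(0.2, 0.9, 30.0, t_max=300.0, dt=10.0)
        assert tr.F[tr.n_prebleach] == pytest.approx(0.2)
        assert tr.F[-1] == pytest.approx(0.9, abs=1e-4)
        assert np.all(tr.F[:tr.n_prebleach] == 1.0)
        # F(tau) - F_bleach = (1 - 1/e)(F_inf - F_bleach)
        i_tau = tr.n_prebleach + 3  # t = 30 s at dt = 10 s
        assert (tr.F[i_tau] - 0.2) == pytest.approx(
            (1 - math.exp(-1)) * 0.7, rel=1e-12)

    def test_frap_trace_default_sampling_is_10s(self):
        tr = pk.make_frap_trace(0.1, 0.8, 40.0)
        assert np.allclose(np.diff(tr.t), 10.0)

    def test_frap_trace_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            pk.make_frap_trace(0.8, 0.1, 40.0)
        with pytest.raises(ValueError):
            pk.make_frap_trace(0.1, 0.8, -1.0)

    def test_em_annotation_deterministic_and_background(self):
        ann = pk.make_em_annotation(10, 2.0, poisson=False, n_background=7,
                                    seed=9)
        assert len(ann.golgi_stacks) == 10
        assert len(ann.lysosomes) == 27
        # the in-window count ignores the background population
        assert pk.lysosomes_near_golgi(ann) == 20
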