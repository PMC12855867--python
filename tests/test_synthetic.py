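"""Generator determinism, ground-truth structure, transduction, rendering."""

import numpy as np
import pandas as pd
import pytest

from plasmonet.connectivity import plf_matrix
from plasmonet.io_roi import grid_channels
from plasmonet.synthetic import (
    NetworkSimConfig,
    SceneConfig,
    chain_coupling,
    default_scene,
    render_image_stack,
    simulate_burst_oscillators,
    simulate_patch_trace,
    transduce_spr,
)


def small_config(**kwargs):
    base = dict(
        n_cells=4,
        coupling=chain_coupling(4),
        duration_s=20.0,
        amplitude_per_condition={"glucose": 1.0},
        seed=7,
    )
    base.update(kwargs)
    return NetworkSimConfig(**base)


class TestBurstOscillators:
    def test_identical_seeds_are_bit_identical(self):
        r1 = simulate_burst_oscillators(small_config())
        r2 = simulate_burst_oscillators(small_config())
        np.testing.assert_array_equal(r1.shifts.to_numpy(), r2.shifts.to_numpy())
        np.testing.assert_array_equal(
            r1.intensity.values.to_numpy(), r2.intensity.values.to_numpy()
        )
        r3 = simulate_burst_oscillators(small_config(seed=8))
        assert not np.array_equal(r1.shifts.to_numpy(), r3.shifts.to_numpy())

    def test_strong_coupling_synchronizes_phases(self):
        cfg = small_config(
            coupling=np.ones((4, 4)) - np.eye(4),
            phase_coupling=2.0,
            phase_noise=0.0,
            burst_jitter_s=0.0,
        )
        rec = simulate_burst_oscillators(cfg)
        m = plf_matrix(rec.truth_phases[500:])
        off = m.weights[~np.eye(4, dtype=bool)]
        assert np.all(off > 0.999)

    def test_uncoupled_noisy_phases_lock_less_than_coupled(self):
        kwargs = dict(coupling=np.ones((4, 4)) - np.eye(4), phase_noise=0.5)
        locked = simulate_burst_oscillators(small_config(phase_coupling=2.0, **kwargs))
        free = simulate_burst_oscillators(small_config(phase_coupling=0.0, **kwargs))
        plf_locked = plf_matrix(locked.truth_phases).offdiag_mean()
        plf_free = plf_matrix(free.truth_phases).offdiag_mean()
        assert plf_free < plf_locked

    def test_silent_cell_trace_is_noise(self):
        cfg = small_config(silent_cells=(2,), noise_sd=0.05)
        rec = simulate_burst_oscillators(cfg)
        silent = rec.shifts["cell3"].to_numpy()
        assert np.std(silent) == pytest.approx(0.05, rel=0.1)
        for other in ("cell1", "cell2", "cell4"):
            r = np.corrcoef(silent, rec.shifts[other])[0, 1]
            assert abs(r) < 0.1

    def test_unstable_step_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            simulate_burst_oscillators(
                small_config(coupling=np.ones((4, 4)) - np.eye(4), phase_coupling=10.0)
            )

    def test_condition_scaling_is_exactly_multiplicative(self):
        amps = {"baseline": 1.0, "glucose": 2.0, "nifedipine": 0.3}
        flat = {c: 1.0 for c in amps}
        kwargs = dict(noise_sd=0.0, n_background=0, duration_s=10.0)
        ref = simulate_burst_oscillators(small_config(amplitude_per_condition=flat, **kwargs))
        scaled = simulate_burst_oscillators(small_config(amplitude_per_condition=amps, **kwargs))
        for cond, a in amps.items():
            mask = ref.condition_labels == cond
            np.testing.assert_allclose(
                scaled.shifts.to_numpy()[mask],
                a * ref.shifts.to_numpy()[mask],
                atol=1e-9,
            )

    def test_burst_suppressed_condition_has_flat_envelope(self):
        cfg = small_config(
            amplitude_per_condition={"glucose": 1.0, "nifedipine": 1.0},
            burst_suppressed_conditions=("nifedipine",),
            burst_floor=0.3,
        )
        rec = simulate_burst_oscillators(cfg)
        nif = rec.burst_envelope[rec.condition_labels == "nifedipine"]
        np.testing.assert_allclose(nif, 0.3, atol=1e-12)
        glu = rec.burst_envelope[rec.condition_labels == "glucose"]
        assert glu.max() > 0.9


class TestTransduceSPR:
    def test_opposite_gradients_anticorrelate_exactly(self, rng):
        s = rng.standard_normal(500) * 0.1
        shifts = pd.DataFrame({"cell": s, "bg": s})
        table = transduce_spr(shifts, {"cell": -0.5, "bg": 0.5}, 1000.0, 100.0)
        r = np.corrcoef(table.values["cell"], table.values["bg"])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_gradient_gives_constant(self, rng):
        shifts = pd.DataFrame({"cell": rng.standard_normal(100)})
        table = transduce_spr(shifts, {"cell": 0.0}, 1234.0, 100.0)
        np.testing.assert_array_equal(table.values["cell"], 1234.0)

    def test_linearization_matches_transfer_matrix_oracle(self):
        # the per-unit-shift gradient from the full optics model stays linear
        # to better than 5% for medium index shifts up to 1e-4
        from plasmonet import optics

        cell, bg = optics.build_interface_stacks()
        theta = optics.operating_angle(optics.spr_curve(cell), optics.spr_curve(bg))

        def refl(n_med):
            s = optics.OpticalLayerStack((
                optics.OpticalLayer("glass", optics.N_GLASS),
                optics.OpticalLayer("gold", optics.N_GOLD, 50.0),
                optics.OpticalLayer("medium", n_med),
            ))
            return abs(optics.reflection_coefficient(s, theta)) ** 2

        n0 = optics.N_MEDIUM
        d = 1e-6
        g = (refl(n0 + d) - refl(n0 - d)) / (2 * d)
        for dn in (1e-5, 1e-4):
            full = refl(n0 + dn) - refl(n0)
            assert g * dn == pytest.approx(full, rel=0.05)


class TestRenderImageStack:
    def make_recording(self, n_cells=2, **kwargs):
        cfg = small_config(n_cells=n_cells, coupling=chain_coupling(n_cells),
                           duration_s=5.0, **kwargs)
        return simulate_burst_oscillators(cfg)

    def test_zero_spread_leaves_background_at_baseline(self):
        rec = self.make_recording(noise_sd=0.0)
        scene = SceneConfig(
            field_size_um=(30.0, 30.0),
            cell_centres_um=((10.0, 10.0), (22.0, 22.0)),
            cell_radii_um=(4.0, 4.0),
            spread_length_um=0.0,
            pixel_noise_sd=0.0,
        )
        stack, rois = render_image_stack(scene, rec)
        far_corner = stack.frames[:, 0, 29]
        np.testing.assert_allclose(far_corner, scene.baseline, rtol=1e-12)

    def test_single_source_correlates_everywhere(self):
        rec = self.make_recording(n_cells=1, noise_sd=0.0)
        scene = SceneConfig(
            field_size_um=(20.0, 20.0),
            cell_centres_um=((10.0, 10.0),),
            cell_radii_um=(4.0,),
            spread_length_um=5.0,
            pixel_noise_sd=0.0,
        )
        stack, _ = render_image_stack(scene, rec)
        src = rec.shifts["cell1"].to_numpy()
        for (y, x) in [(10, 10), (2, 2), (17, 5)]:
            px = stack.frames[:, y, x].astype(float)
            if np.std(px) > 0:
                assert abs(np.corrcoef(px, src)[0, 1]) > 0.999

    def test_default_scene_yields_7735_grid_channels(self):
        rec = simulate_burst_oscillators(
            NetworkSimConfig(duration_s=2.0, amplitude_per_condition={"glucose": 1.0}, seed=1)
        )
        stack, _ = render_image_stack(default_scene(), rec)
        assert len(grid_channels(stack, 1.0).names) == 7735

    def test_cell_outside_field_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SceneConfig(field_size_um=(20.0, 20.0), cell_centres_um=((25.0, 5.0),),
                        cell_radii_um=(3.0,))


class TestPatchTrace:
    def test_zero_rate_yields_no_events(self):
        res = simulate_patch_trace({"baseline": 0.0}, 10.0, seed=0)
        assert len(res.truth_times_s) == 0

    def test_event_counts_near_poisson_expectation(self):
        rates = {"baseline": 0.88, "glucose": 1.57, "nifedipine": 0.26}
        res = simulate_patch_trace(rates, 100.0, seed=5)
        for cond, rate in rates.items():
            n = int(np.sum(res.truth_conditions == cond))
            assert abs(n - rate * 100) <= 3 * np.sqrt(rate * 100)

    def test_deterministic_under_seed(self):
        r1 = simulate_patch_trace({"g": 1.0}, 20.0, seed=9)
        r2 = simulate_patch_trace({"g": 1.0}, 20.0, seed=9)
        np.testing.assert_array_equal(r1.trace_pa, r2.trace_pa)
        np.testing.assert_array_equal(r1.truth_times_s, r2.truth_times_s)

    def test_subsample_event_width_warns(self):
        with pytest.warns(UserWarning, match="width"):
            simulate_patch_trace({"g": 0.5}, 5.0, event_width_s=0.00002, seed=0)
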