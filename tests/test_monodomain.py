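"""Tissue solver: conductivity tensors, propagation, stability, determinism."""

import numpy as np
import pytest

import infarctvt as iv
from infarctvt import monodomain as md
from tests.conftest import make_cable


def _sigma_from_d(grid, component):
    """Recover sigma (S/m) from the stored diffusion tensor (cm²/ms)."""
    bcm = (grid.cparams.surface_to_volume
           * grid.cparams.membrane_capacitance)
    return getattr(grid, component) * bcm / 10.0


class TestTensors:
    def test_fiber_along_x_gives_paper_conductivities(self):
        ct = np.full((2, 2, 2), md.CT_NORMAL, dtype=np.uint8)
        grid = md.build_tissue_grid(ct, 0.0, (0.2, 0.2, 0.2))
        assert _sigma_from_d(grid, "dxx")[0, 0, 0] == pytest.approx(0.28)
        assert _sigma_from_d(grid, "dyy")[0, 0, 0] == pytest.approx(0.026)
        assert _sigma_from_d(grid, "dzz")[0, 0, 0] == pytest.approx(0.026)
        assert grid.dxy[0, 0, 0] == pytest.approx(0.0)

    def test_fiber_at_90_degrees_swaps_in_plane_entries(self):
        ct = np.full((2, 2, 1), md.CT_NORMAL, dtype=np.uint8)
        grid = md.build_tissue_grid(ct, 90.0, (0.2, 0.2, 0.2))
        assert _sigma_from_d(grid, "dxx")[0, 0, 0] == pytest.approx(0.026)
        assert _sigma_from_d(grid, "dyy")[0, 0, 0] == pytest.approx(0.28)

    def test_gz_transverse_reduced_by_90_percent(self):
        ct = np.full((2, 2, 1), md.CT_GZ, dtype=np.uint8)
        grid = md.build_tissue_grid(ct, 0.0, (0.2, 0.2, 0.2))
        assert _sigma_from_d(grid, "dyy")[0, 0, 0] == pytest.approx(0.0026)
        assert _sigma_from_d(grid, "dxx")[0, 0, 0] == pytest.approx(0.28)

    def test_mismatched_fiber_field_rejected(self):
        ct = np.full((4, 4, 1), md.CT_NORMAL, dtype=np.uint8)
        with pytest.raises(ValueError, match="does not match"):
            md.build_tissue_grid(ct, np.zeros((3, 3, 1)), (0.2, 0.2, 0.2))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            md.ConductivityParams(sigma_longitudinal=-1.0)
        with pytest.raises(ValueError):
            md.ConductivityParams(gz_transverse_scale=1.5)


class TestPropagation:
    def test_unstimulated_tissue_stays_at_rest(self):
        ct = np.full((10, 10, 1), md.CT_NORMAL, dtype=np.uint8)
        grid = md.build_tissue_grid(ct, 0.0, (0.2, 0.2, 0.2))
        rec = md.run_monodomain(grid, [], 200.0, dt=0.02,
                                probes_mm=[(1.0, 1.0, 0.1)])
        v_rest = iv.RESTING_STATE[0]
        assert np.max(np.abs(rec.final_states[:, 0] - v_rest)) < 0.05
        assert rec.act_count.max() == 0

    def test_cable_activation_times_increase_with_distance(self):
        grid, rec = make_cable(h_mm=0.2, length_mm=15.0)
        lats = []
        c = 0.1
        for x in np.arange(3.0, 13.0, 1.0):
            acts = rec.activations_at((x, c, c))
            assert acts.size == 1
            lats.append(acts[0])
        assert np.all(np.diff(lats) > 0)

    def test_cfl_violation_refused_with_bound(self):
        ct = np.full((20, 1, 1), md.CT_NORMAL, dtype=np.uint8)
        grid = md.build_tissue_grid(ct, 0.0, (0.05, 0.05, 0.05))
        bound = md.stability_bound(grid)
        with pytest.raises(ValueError, match="stability bound"):
            md.run_monodomain(grid, [], 10.0, dt=bound * 2.0)

    def test_wavefront_wraps_nonexcitable_disc_and_activates_all(self):
        """A central passive disc splits the wavefront, which re-merges
        distally; every excitable node is activated exactly once."""
        h = 0.2
        n = 50  # 10 x 10 mm sheet
        ct = np.full((n, n, 1), md.CT_NORMAL, dtype=np.uint8)
        x = (np.arange(n) + 0.5) * h
        X, Y = np.meshgrid(x, x, indexing="ij")
        disc = (X - 5.0) ** 2 + (Y - 5.0) ** 2 <= 2.0 ** 2
        ct[disc[:, :, None]] = md.CT_SCAR
        grid = md.build_tissue_grid(ct, 0.0, (h, h, h))
        stim = md.StimulusEvent(5.0, 2.0, 60.0, (0.5, 5.0, 0.1), 1.2)
        rec = md.run_monodomain(grid, [stim], 500.0, dt=0.02)
        excitable = ((grid.celltype == md.CT_NORMAL)
                     | (grid.celltype == md.CT_GZ)).ravel()
        assert np.all(rec.act_count[excitable] >= 1)  # total activated area
        assert np.all(rec.act_count[~excitable] == 0)

    def test_passive_tissue_relaxes_monotonically_no_boundary_leak(self):
        """All-passive sheet with an initial voltage bump: the spatial mean
        decays monotonically back to rest (no-flux boundaries create no
        energy)."""
        ct = np.full((12, 12, 1), md.CT_SCAR, dtype=np.uint8)
        grid = md.build_tissue_grid(ct, 0.0, (0.2, 0.2, 0.2))
        states = md.initial_tissue_states(grid)
        v3 = states[:, 0].reshape(grid.shape)
        v3[4:8, 4:8, 0] += 40.0
        rec = md.run_monodomain(grid, [], 150.0, dt=0.02,
                                probes_mm=[(1.2, 1.2, 0.1)],
                                initial_states=states,
                                frame_interval_ms=5.0)
        v_rest = grid.cparams.scar_rest_mv
        mean_dev = [float(np.abs(f - v_rest).mean()) for f in rec.frames]
        assert np.all(np.diff(mean_dev) <= 1e-9)
        assert mean_dev[-1] < 0.05 * mean_dev[0]

    def test_bit_reproducible_given_grid_and_stimuli(self):
        grid, rec1 = make_cable(h_mm=0.2, length_mm=10.0,
                                duration_tail_ms=120.0)
        _, rec2 = make_cable(h_mm=0.2, length_mm=10.0,
                             duration_tail_ms=120.0)
        assert np.array_equal(rec1.final_states, rec2.final_states)
        assert np.array_equal(rec1.act_times, rec2.act_times,
                              equal_nan=True)


class TestMeasureCV:
    def test_default_parameters_give_45_cm_per_s(self, cv_cable):
        _, _, cv = cv_cable
        assert cv == pytest.approx(45.0, rel=0.10)

    def test_probes_too_close_rejected(self, cv_cable):
        grid, rec, _ = cv_cable
        c = grid.spacing_mm[1] / 2.0
        with pytest.raises(ValueError, match="5 mm"):
            md.measure_cv(rec, (5.0, c, c), (7.0, c, c))

    def test_unactivated_probe_reports_propagation_failure(self):
        ct = np.full((50, 1, 1), md.CT_NORMAL, dtype=np.uint8)
        ct[25:] = md.CT_SCAR  # distal half passive: wave cannot reach it
        grid = md.build_tissue_grid(ct, 0.0, (0.2, 0.2, 0.2))
        stim = md.StimulusEvent(5.0, 2.0, 60.0, (0.5, 0.1, 0.1), 1.0)
        rec = md.run_monodomain(grid, [stim], 150.0, dt=0.02)
        with pytest.raises(RuntimeError, match="propagation failure"):
            md.measure_cv(rec, (1.0, 0.1, 0.1), (9.0, 0.1, 0.1))

    def test_transverse_cv_below_longitudinal(self, cv_cable):
        _, _, cv_l = cv_cable
        h = 0.2
        ct = np.full((6, 100, 1), md.CT_NORMAL, dtype=np.uint8)
        grid = md.build_tissue_grid(ct, 0.0, (h, h, h))
        stim = md.StimulusEvent(5.0, 2.0, 60.0, (0.6, 1.0, 0.1), 1.5)
        rec = md.run_monodomain(grid, [stim], 500.0, dt=0.02)
        cv_t = md.measure_cv(rec, (0.6, 5.0, 0.1), (0.6, 15.0, 0.1))
        assert cv_t < cv_l / 2.0

    def test_refinement_consistency_under_5_percent(self, cv_cable):
        _, _, cv_ref = cv_cable
        grid, rec = make_cable(h_mm=0.05, dt=0.01)
        c = 0.025
        cv_fine = md.measure_cv(rec, (5.0, c, c), (15.0, c, c))
        assert abs(cv_fine - cv_ref) / cv_ref < 0.05

    def test_cv_scales_as_sqrt_sigma(self):
        """Quartering the conductivity halves the conduction velocity
        (cable-equation square-root scaling)."""
        c = 0.025
        _, rec_full = make_cable(h_mm=0.05)
        _, rec_quarter = make_cable(h_mm=0.05, sigma_l=0.07)
        cv_full = md.measure_cv(rec_full, (5.0, c, c), (15.0, c, c))
        cv_quarter = md.measure_cv(rec_quarter, (5.0, c, c), (15.0, c, c))
        assert cv_quarter / cv_full == pytest.approx(0.5, rel=0.10)


def test_record_hdf5_roundtrip(tmp_path):
    import h5py

    _, rec = make_cable(h_mm=0.2, length_mm=10.0, duration_tail_ms=100.0)
    path = tmp_path / "rec.h5"
    rec.save_hdf5(path)
    with h5py.File(path) as fh:
        assert fh.attrs["dt"] == rec.dt
        assert np.allclose(fh["probe_traces"][...], rec.probe_traces)
        assert np.allclose(fh["final_states"][...], rec.final_states)
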