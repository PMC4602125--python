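"""Activation maps, pseudo-ECG, MAD metric, reentry localization, study."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import infarctvt as iv
from infarctvt import monodomain as md
from infarctvt.analysis import ReentryLocation
from tests.conftest import make_cable


@pytest.fixture(scope="module")
def cable_with_frames():
    grid, _ = make_cable(h_mm=0.2, length_mm=20.0)
    c = 0.1
    stim = md.StimulusEvent(5.0, 2.0, 60.0, (0.5, c, c), 1.0)
    rec = md.run_monodomain(grid, [stim], 300.0, dt=0.02,
                            probes_mm=[(5.0, c, c), (15.0, c, c)],
                            frame_interval_ms=1.0)
    return grid, rec


# ---------------------------------------------------------------------------
# MAD
# ---------------------------------------------------------------------------

class TestMAD:
    def test_hand_example_is_75_percent(self):
        assert iv.mad_score([0.0, 1.0, 0.0], [0.0, 0.0, 1.0]) == pytest.approx(75.0)

    def test_identical_waveforms_score_zero_exactly(self):
        x = np.sin(np.linspace(0, 7, 40))
        assert iv.mad_score(x, x) == 0.0

    def test_sign_inverted_waveform_scores_100_exactly(self):
        x = np.sin(np.linspace(0, 7, 40)) + 3.0
        assert iv.mad_score(x, -x) == pytest.approx(100.0)

    def test_both_constant_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            iv.mad_score([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            iv.mad_score([0.0, 1.0], [0.0, 1.0, 2.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40),
           st.lists(st.floats(-100, 100), min_size=3, max_size=40),
           st.floats(-50, 50), st.floats(0.1, 10))
    def test_symmetry_bounds_and_invariances(self, xs, ys, shift, scale):
        n = min(len(xs), len(ys))
        x = np.asarray(xs[:n])
        y = np.asarray(ys[:n])
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            return
        m = iv.mad_score(x, y)
        assert 0.0 <= m <= 100.0
        assert iv.mad_score(y, x) == pytest.approx(m)
        # adding a constant to either trace changes nothing
        assert iv.mad_score(x + shift, y) == pytest.approx(m, abs=1e-6)
        # common positive rescaling of both centred traces changes nothing
        assert iv.mad_score(scale * x, scale * y) == pytest.approx(m, abs=1e-6)


# ---------------------------------------------------------------------------
# Activation maps
# ---------------------------------------------------------------------------

class TestActivationMap:
    def test_planar_wave_lat_linear_slope_matches_cv(self, cable_with_frames):
        grid, rec = cable_with_frames
        amap = iv.activation_map(rec, (0.0, 300.0))
        c = 0.1
        xs = np.arange(4.0, 16.0, 0.6)
        lats = np.array([amap.at((x, c, c)) for x in xs])
        assert np.all(np.isfinite(lats))
        slope = np.polyfit(xs, lats, 1)[0]  # ms/mm
        cv_from_map = 100.0 / slope  # cm/s
        cv = md.measure_cv(rec, (5.0, c, c), (15.0, c, c))
        assert cv_from_map == pytest.approx(cv, rel=0.05)

    def test_never_activated_nodes_are_nan(self):
        ct = np.full((30, 1, 1), md.CT_NORMAL, dtype=np.uint8)
        ct[20:] = md.CT_SCAR
        grid = md.build_tissue_grid(ct, 0.0, (0.2, 0.2, 0.2))
        stim = md.StimulusEvent(5.0, 2.0, 60.0, (0.5, 0.1, 0.1), 1.0)
        rec = md.run_monodomain(grid, [stim], 120.0, dt=0.02)
        amap = iv.activation_map(rec, (0.0, 120.0))
        assert np.isfinite(amap.at((1.0, 0.1, 0.1)))
        assert np.isnan(amap.at((5.5, 0.1, 0.1)))  # scar carries no upstroke

    def test_empty_window_rejected(self, cable_with_frames):
        _, rec = cable_with_frames
        with pytest.raises(ValueError, match="empty"):
            iv.activation_map(rec, (100.0, 100.0))


# ---------------------------------------------------------------------------
# Pseudo-ECG
# ---------------------------------------------------------------------------

class TestPseudoECG:
    ELECTRODES = ((-100.0, 0.1, 0.1), (120.0, 0.1, 0.1))

    def test_resting_tissue_gives_identically_zero_trace(self):
        ct = np.full((20, 4, 1), md.CT_NORMAL, dtype=np.uint8)
        grid = md.build_tissue_grid(ct, 0.0, (0.2, 0.2, 0.2))
        rec = md.run_monodomain(grid, [], 50.0, dt=0.02,
                                frame_interval_ms=5.0)
        trace = iv.pseudo_ecg(rec, self.ELECTRODES)
        assert np.allclose(trace.samples, 0.0, atol=1e-12)

    def test_propagating_wave_biphasic_and_antisymmetric_under_swap(
            self, cable_with_frames):
        _, rec = cable_with_frames
        e1, e2 = self.ELECTRODES
        trace = iv.pseudo_ecg(rec, (e1, e2))
        swapped = iv.pseudo_ecg(rec, (e2, e1))
        assert np.array_equal(trace.samples, -swapped.samples)
        assert trace.samples.max() > 0 and trace.samples.min() < 0

    def test_electrode_inside_tissue_rejected(self, cable_with_frames):
        _, rec = cable_with_frames
        with pytest.raises(ValueError, match="singular"):
            iv.pseudo_ecg(rec, ((5.0, 0.1, 0.1), (120.0, 0.1, 0.1)))

    def test_frames_required(self):
        _, rec = make_cable(h_mm=0.2, length_mm=10.0, duration_tail_ms=100.0)
        with pytest.raises(ValueError, match="frames"):
            iv.pseudo_ecg(rec, self.ELECTRODES)


# ---------------------------------------------------------------------------
# Reentry localization
# ---------------------------------------------------------------------------

class TestCircuitDistance:
    def _loc(self, xyz):
        return ReentryLocation(organizing_center_mm=np.asarray(xyz, float),
                               anchor_component=1, pattern="reentry")

    def test_identical_locations_zero(self):
        assert iv.circuit_distance(self._loc((1, 2, 3)), self._loc((1, 2, 3))) == 0.0

    def test_pythagorean_triple(self):
        assert iv.circuit_distance(self._loc((0, 0, 0)),
                                   self._loc((3, 4, 0))) == pytest.approx(5.0)

    def test_frame_mismatch_rejected(self):
        a = ReentryLocation(organizing_center_mm=np.zeros(3),
                            anchor_component=1, pattern="reentry")
        b = ReentryLocation(organizing_center_mm=np.zeros(2),
                            anchor_component=1, pattern="reentry")
        with pytest.raises(ValueError, match="coordinate frames"):
            iv.circuit_distance(a, b)


class TestLocateReentry:
    @staticmethod
    def _rebuild_record(rec, celltype, fibers, frames):
        grid = md.build_tissue_grid(celltype, fibers, rec.grid.spacing_mm,
                                    cparams=rec.grid.cparams,
                                    remodeling=rec.grid.remodeling)
        n = grid.n_nodes
        return md.SimulationRecord(
            grid=grid, dt=rec.dt, t_start=rec.t_start, t_end=rec.t_end,
            probe_indices=np.array([], dtype=np.int64),
            probe_times=rec.probe_times, probe_traces=np.zeros((0, 1)),
            act_times=np.full((n, 4), np.nan),
            act_count=np.zeros(n, dtype=np.int32),
            frames=frames, frame_times=rec.frame_times,
            final_states=np.zeros((n, 14)))

    def test_translated_record_gives_translated_organizing_center(
            self, vt_outcome, vt_location):
        """Rigidly translating the whole fixture shifts the organizing
        centre by the same amount (equivariance of the localization)."""
        grid, outcome = vt_outcome
        rec = outcome.record
        loc = vt_location
        pad = 10  # nodes of background prepended along x
        v_rest = float(iv.RESTING_STATE[0])
        ct = np.concatenate([np.zeros((pad,) + grid.shape[1:], np.uint8),
                             grid.celltype])
        fib = np.concatenate([np.zeros((pad,) + grid.shape[1:]),
                              grid.fiber_angle_deg])
        frames = np.concatenate(
            [np.full((rec.frames.shape[0], pad) + grid.shape[1:], v_rest,
                     dtype=rec.frames.dtype), rec.frames], axis=1)
        t_rec = self._rebuild_record(rec, ct, fib, frames)
        t_loc = iv.locate_reentry(t_rec)
        shift = pad * grid.spacing_mm[0]
        assert t_loc.organizing_center_mm[0] == pytest.approx(
            loc.organizing_center_mm[0] + shift, abs=grid.spacing_mm[0])
        assert t_loc.organizing_center_mm[1] == pytest.approx(
            loc.organizing_center_mm[1], abs=grid.spacing_mm[1])
        assert t_loc.pattern == loc.pattern

    def test_mirrored_record_preserves_pattern_and_flips_windings(
            self, vt_outcome, vt_location):
        """Reflecting the fixture about x keeps the figure-of-eight pattern
        and flips each anchor's chirality."""
        grid, outcome = vt_outcome
        rec = outcome.record
        m_rec = self._rebuild_record(
            rec, np.ascontiguousarray(grid.celltype[::-1]),
            np.ascontiguousarray(grid.fiber_angle_deg[::-1]),
            np.ascontiguousarray(rec.frames[:, ::-1]))
        m_loc = iv.locate_reentry(m_rec)
        assert m_loc.pattern == vt_location.pattern == "figure-of-eight"
        assert (sorted(m_loc.chirality["scar_windings"].values())
                == sorted(vt_location.chirality["scar_windings"].values()))

    def test_quiescent_record_raises_inconsistency(self):
        ct = np.full((16, 16, 1), md.CT_NORMAL, dtype=np.uint8)
        ct[6:10, 6:10] = md.CT_SCAR
        grid = md.build_tissue_grid(ct, 0.0, (0.2, 0.2, 0.2))
        rec = md.run_monodomain(grid, [], 100.0, dt=0.02,
                                frame_interval_ms=2.0)
        with pytest.raises(RuntimeError, match="no phase singularity"):
            iv.locate_reentry(rec)


# ---------------------------------------------------------------------------
# Resolution study
# ---------------------------------------------------------------------------

class TestResolutionStudy:
    def test_identity_pipeline_native_target(self):
        """Downsampling to the native resolution is the identity: volumes
        match the native row exactly and the pseudo-ECG MAD is 0."""
        proto = iv.PacingProtocol(n_s1=1, max_extrastimuli=0,
                                  vt_duration=1000.0)
        spec = iv.study_phantom_spec()
        native_target = iv.DownsampleTarget(spec.spacing)
        res = iv.resolution_study(spec, [native_target], proto)
        t = res.table
        assert list(t["status"]) == ["ok", "ok"]
        for col in ("normal_cm3", "gz_cm3", "scar_cm3", "total_cm3"):
            assert t[col].iloc[1] == pytest.approx(t[col].iloc[0])
        assert t["mad_vs_native_pct"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_smoke_med_low_rows_fully_populated(self, study_smoke):
        t = study_smoke.table
        assert list(t["resolution"]) == ["native", "1.5x1.5x4", "1.5x1.5x8"]
        assert list(t["status"]) == ["ok"] * 3
        for col in ("normal_cm3", "gz_cm3", "scar_cm3", "total_cm3",
                    "normal_pct", "gz_pct", "scar_pct"):
            assert np.isfinite(t[col]).all()
        # downsampled rows carry a MAD against the native trace
        assert np.isfinite(t["mad_vs_native_pct"].iloc[1:]).all()
        # not induced under the light protocol: distances stay empty
        if not t["induced"].any():
            assert t["distance_to_native_mm"].isna().all()

    def test_report_serialization(self, study_smoke, tmp_path):
        study_smoke.to_csv(tmp_path / "report.csv")
        study_smoke.to_json(tmp_path / "report.json")
        import json
        rows = json.loads((tmp_path / "report.json").read_text())
        assert len(rows) == 3
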