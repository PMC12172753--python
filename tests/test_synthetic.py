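"""Generators: schedules, meshes, fields, EMG synthesis, cohorts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tmsmap.emg import detect_mep, highpass_filter
from tmsmap.io import events_to_frame
from tmsmap.synthetic import (
    ExperimentDesign,
    GroundTruthField,
    InvalidDesignError,
    design_experiment,
    disc_iou,
    make_cohort,
    make_flat_patch_mesh,
    make_hemisphere_mesh,
    sample_field_amplitude,
    synth_emg,
)


class TestDesignExperiment:
    def test_default_design_yields_720_events(self):
        events = design_experiment(ExperimentDesign(), seed=0)
        assert len(events) == 720  # 3 intensities x 120 pulses x 2 repetitions

    def test_minimal_design(self):
        events = design_experiment(
            ExperimentDesign(1, 1, 1, grid_extent_mm=50.0), seed=0, hotspot=(1.0, 2.0, 0.0)
        )
        assert len(events) == 1
        assert np.all(np.abs(events[0].coil_position[:2] - [1.0, 2.0]) <= 25.0)

    def test_seeded_determinism_byte_identical(self):
        d = ExperimentDesign(2, 10, 3)
        a = events_to_frame(design_experiment(d, seed=7), "s")
        b = events_to_frame(design_experiment(d, seed=7), "s")
        assert a.equals(b)

    def test_positions_uniform_over_grid(self):
        d = ExperimentDesign(3, 120, 2, grid_extent_mm=50.0)
        events = design_experiment(d, seed=3, hotspot=(10.0, -5.0, 0.0))
        xy = np.array([ev.coil_position[:2] for ev in events])
        assert np.all(np.abs(xy - [10.0, -5.0]) <= 25.0)
        # roughly uniform: each quadrant gets a fair share
        q = ((xy[:, 0] > 10.0).astype(int) * 2 + (xy[:, 1] > -5.0)).astype(int)
        counts = np.bincount(q, minlength=4)
        assert counts.min() > 0.15 * len(events)

    def test_timestamps_spaced_by_isi(self):
        events = design_experiment(ExperimentDesign(2, 5, 1, inter_stimulus_s=5.0), seed=0)
        t = np.array([ev.time_s for ev in events])
        np.testing.assert_allclose(np.diff(t), 5.0)

    @pytest.mark.parametrize("bad", [dict(n_intensities=0), dict(stims_per_block=0), dict(inter_stimulus_s=0.0)])
    def test_invalid_design_rejected(self, bad):
        with pytest.raises(InvalidDesignError):
            ExperimentDesign(**bad)


class TestFlatPatch:
    def test_unit_square(self):
        m = make_flat_patch_mesh(2, 2, 1.0)
        assert m.n_vertices == 4 and m.n_faces == 2
        assert m.total_area() == pytest.approx(1.0)

    def test_3x3_area(self):
        m = make_flat_patch_mesh(3, 3, 2.0)
        assert m.n_vertices == 9 and m.n_faces == 8
        assert m.total_area() == pytest.approx(16.0)

    @given(
        nx=st.integers(2, 8), ny=st.integers(2, 8),
        s=st.floats(0.2, 5.0, allow_nan=False),
    )
    def test_area_matches_closed_form(self, nx, ny, s):
        m = make_flat_patch_mesh(nx, ny, s)
        assert m.total_area() == pytest.approx((nx - 1) * (ny - 1) * s**2, rel=1e-9)
        assert m.n_faces == 2 * (nx - 1) * (ny - 1)

    def test_band_labelling(self):
        m = make_flat_patch_mesh(11, 11, 1.0, m1_band_mm=2.0)
        in_band = np.abs(m.vertices[:, 0]) <= 2.0
        assert np.all(m.atlas_labels[in_band] == "precentral L")
        assert np.all(m.atlas_labels[~in_band] == "other")

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            make_flat_patch_mesh(1, 5, 1.0)


class TestHemisphere:
    def test_vertices_on_sphere(self):
        m = make_hemisphere_mesh(0, 1.0)
        np.testing.assert_allclose(np.linalg.norm(m.vertices, axis=1), 1.0, atol=1e-9)

    def test_area_close_to_analytic(self):
        m = make_hemisphere_mesh(3, 10.0)
        assert m.total_area() == pytest.approx(2 * np.pi * 100.0, rel=0.02)

    def test_sphere_registration_unit_norm(self):
        m = make_hemisphere_mesh(2, 7.5)
        np.testing.assert_allclose(np.linalg.norm(m.sphere, axis=1), 1.0, atol=1e-9)

    def test_curvature_is_inverse_radius(self):
        m = make_hemisphere_mesh(1, 4.0)
        np.testing.assert_allclose(m.curvature, 0.25)

    @pytest.mark.parametrize("maker", [lambda: make_flat_patch_mesh(6, 4, 1.3), lambda: make_hemisphere_mesh(2, 10.0)])
    def test_meshes_are_valid_manifolds(self, maker):
        import trimesh

        m = maker()
        tm = trimesh.Trimesh(vertices=m.vertices, faces=m.faces, process=False)
        assert tm.is_winding_consistent
        assert np.all(m.face_areas() > 0)
        edges = m.edges()
        # edge-manifold: every edge borders at most two faces
        e_all = np.sort(
            np.vstack([m.faces[:, [0, 1]], m.faces[:, [1, 2]], m.faces[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(e_all, axis=0, return_counts=True)
        assert counts.max() <= 2
        assert len(edges) == len(counts)


class TestFieldSampling:
    field = GroundTruthField("FDI", np.array([1.0, 2.0, 0.0]), 5.0, 600.0)

    def test_peak_at_center(self):
        assert sample_field_amplitude(self.field, self.field.center, 0.0) == pytest.approx(600.0)

    def test_half_maximum_radius(self):
        r = 5.0 * np.sqrt(2 * np.log(2))
        point = self.field.center + np.array([r, 0, 0])
        assert sample_field_amplitude(self.field, point, 0.0) == pytest.approx(300.0, abs=1e-9)

    def test_monte_carlo_mean(self):
        point = self.field.center + np.array([3.0, 0, 0])
        clean = sample_field_amplitude(self.field, point, 0.0)
        rng = np.random.default_rng(5)
        draws = np.array(
            [sample_field_amplitude(self.field, point, 10.0, seed=rng) for _ in range(10_000)]
        )
        se = 10.0 / np.sqrt(len(draws))
        assert abs(draws.mean() - clean) < 3 * se
        assert draws.min() >= 0.0


class TestSynthEMG:
    def test_clean_p2p_matches_requested(self):
        tr = synth_emg(500.0, baseline_sd=0.0, seed=0)
        seg = tr.window(0.010, 0.040)
        assert seg.max() - seg.min() == pytest.approx(500.0, rel=0.01)

    def test_zero_amplitude_stays_within_noise_bound(self):
        tr = synth_emg(0.0, baseline_sd=5.0, seed=1)
        assert np.abs(tr.samples).max() < 6 * 5.0

    def test_seeded_determinism(self):
        a = synth_emg(300.0, seed=11)
        b = synth_emg(300.0, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_latency_outside_trace_rejected(self):
        with pytest.raises(ValueError, match="latency"):
            synth_emg(300.0, latency_ms=500.0, post_ms=100.0)

    def test_detection_chain_flags_injected_mep(self):
        tr = highpass_filter(synth_emg(500.0, baseline_sd=5.0, seed=2))
        res = detect_mep(tr)
        assert res.is_mep and res.reason == "ok"


class TestCohort:
    def test_zero_jitter_shares_centers(self):
        c = make_cohort(
            n_subjects=3, jitter_mm=0.0, seed=0,
            design=ExperimentDesign(1, 5, 1),
        )
        for m in c.muscles:
            centers = [s.fields[m].center for s in c.subjects]
            for x in centers[1:]:
                np.testing.assert_array_equal(x, centers[0])

    def test_event_and_trace_counts_at_study_scale(self):
        c = make_cohort(n_subjects=20, seed=0)
        assert c.n_events == 20 * 720
        assert c.n_traces == 20 * 720 * 8

    def test_identical_fields_have_unit_disc_overlap(self):
        assert disc_iou([0, 0, 0], 10.0, [0, 0, 0], 10.0) == pytest.approx(1.0)
        c = make_cohort(n_subjects=2, jitter_mm=0.0, seed=0, design=ExperimentDesign(1, 2, 1))
        ov = c.ground_truth["disc_overlaps"]
        row = ov[(ov.muscle_k == "FDI") & (ov.muscle_l == "FDI")]
        assert len(row) == 0  # no self-pairs recorded

    def test_ground_truth_self_consistent(self):
        c = make_cohort(n_subjects=2, seed=3, design=ExperimentDesign(1, 2, 1))
        for sid, fields in c.ground_truth["fields"].items():
            subj = next(s for s in c.subjects if s.subject_id == sid)
            for m, rec in fields.items():
                val = sample_field_amplitude(subj.fields[m], np.array(rec["center"]), 0.0)
                assert val == pytest.approx(rec["peak_amplitude"], rel=1e-12)

    def test_seeded_determinism(self):
        d = ExperimentDesign(2, 3, 1)
        a = make_cohort(n_subjects=2, seed=9, design=d)
        b = make_cohort(n_subjects=2, seed=9, design=d)
        np.testing.assert_array_equal(a.subjects[0].amplitudes, b.subjects[0].amplitudes)
        np.testing.assert_array_equal(a.subjects[1].mesh.vertices, b.subjects[1].mesh.vertices)
        ta = a.emg_trace(0, 0, "FDI")
        tb = b.emg_trace(0, 0, "FDI")
        np.testing.assert_array_equal(ta.samples, tb.samples)

    def test_amplitudes_non_negative(self):
        c = make_cohort(n_subjects=2, seed=1, design=ExperimentDesign(1, 20, 1), amplitude_noise_sd_uv=300.0)
        for s in c.subjects:
            assert np.all(s.amplitudes >= 0)
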