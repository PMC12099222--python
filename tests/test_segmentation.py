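"""Template registration, label transfer, fiducial detection, mid-slice crop."""

import numpy as np
import pytest

from phantomqc import geometry as geo
from phantomqc import simulate as sim
from phantomqc.segment import (
    RigidTransform,
    detect_fiducials,
    mid_slice_crop,
    register_template,
    transfer_labels,
)

from conftest import design_positions


class TestRigidTransform:
    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))

    def test_rejects_reflection(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_inverse_composes_to_identity(self):
        truth = sim.SessionGroundTruth(rotation_deg=(3, -7, 12), translation_mm=(4, 5, -6))
        t = RigidTransform(truth.rotation_matrix(), np.array([4.0, 5.0, -6.0]))
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(ident.translation, 0.0, atol=1e-12)


class TestRegistration:
    def test_identity_session_registers_to_identity(self, template_pair, clean_session):
        template, _ = template_pair
        scans, _, _ = clean_session
        t = register_template(template, scans["axial_t2w"])
        assert not t.low_confidence
        assert np.all(np.abs(t.rotation_angles_deg()) < 0.1)
        assert np.all(np.abs(t.translation) < 0.1)

    def test_known_misplacement_recovered(self, template_pair, misplaced_session):
        template, _ = template_pair
        scans, _, truth = misplaced_session
        t = register_template(template, scans["axial_t2w"])
        # acquired->design must invert the session's design->acquired motion
        expected = RigidTransform(truth.rotation_matrix(), np.asarray(truth.translation_mm)).inverse()
        angle_err = np.abs(t.rotation_angles_deg() - expected.rotation_angles_deg())
        assert np.all(angle_err < 0.2)
        assert np.all(np.abs(t.translation - expected.translation) < 0.25)
        assert t.objective >= 0.9

    def test_registered_transform_improves_on_identity_roundtrip(
        self, template_pair, misplaced_session
    ):
        """The recovered transform maps design points onto their displaced
        detections far better than the identity would."""
        template, _ = template_pair
        scans, _, truth = misplaced_session
        t = register_template(template, scans["axial_t2w"])
        pts = np.array([f.design_position for f in geo.design_fiducial_coordinates()])
        displaced = truth.displace(pts)
        err_reg = np.linalg.norm(t.apply(displaced) - pts, axis=1).max()
        err_ident = np.linalg.norm(displaced - pts, axis=1).max()
        assert err_reg < 0.5 < err_ident


class TestLabelTransfer:
    def test_identity_transfer_bit_identical(self, template_pair):
        template, labels = template_pair
        out = transfer_labels(RigidTransform.identity(), labels, template)
        assert np.array_equal(out.labels, labels.labels)
        assert out.legend == labels.legend

    def test_one_voxel_translation_shifts_labels(self, template_pair):
        template, labels = template_pair
        dx = float(template.voxel_size[0])
        t = RigidTransform(np.eye(3), np.array([dx, 0.0, 0.0]))
        out = transfer_labels(t, labels, template)
        assert np.array_equal(out.labels[:-1], labels.labels[1:])

    def test_legend_never_grows(self, template_pair, clean_session):
        template, labels = template_pair
        scans, _, _ = clean_session
        out = transfer_labels(RigidTransform.identity(), labels, scans["axial_t2w"])
        assert set(out.legend.items()) <= set(labels.legend.items())

    def test_transferred_mimic_labels_overlap_ground_truth(
        self, template_pair, misplaced_session, phantom
    ):
        template, labels = template_pair
        scans, _, truth = misplaced_session
        axial = scans["axial_t2w"]
        t = register_template(template, axial)
        transferred = transfer_labels(t, labels, axial)
        _, gt = sim.rasterize_phantom(phantom, sim.t2w_sequence("axial"), truth, seed=None, with_labels=True)
        for k in range(1, 15):
            fid = f"MnCl2-{k}"
            a = transferred.feature_mask(fid)
            b = gt.feature_mask(fid)
            dice = 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
            assert dice >= 0.8, f"{fid}: Dice {dice:.3f}"


class TestFiducialDetection:
    def test_all_fifteen_detected_with_unique_ids(self, clean_session, design):
        scans, _, _ = clean_session
        detected = detect_fiducials(scans["axial_t2w"], design)
        ids = [i for i, _ in detected]
        assert ids == list(range(1, 16))

    def test_ablated_fiducial_reported_missing(self, phantom, design):
        # render fiducial 7 with fill-solution signal: invisible to the detector
        table = sim.default_relax_table(phantom)
        table["fiducial-07"] = table["fill"]
        vol = sim.rasterize_phantom(phantom, sim.t2w_sequence("axial"), sim.SessionGroundTruth(), table)
        detected = detect_fiducials(vol, design)
        ids = {i for i, _ in detected}
        assert len(detected) == 14
        assert ids == set(range(1, 16)) - {7}

    def test_translation_shifts_all_centroids(self, phantom, design):
        shift = np.array([2.0, 2.0, 0.0])
        truth = sim.SessionGroundTruth(translation_mm=tuple(shift))
        vol = sim.rasterize_phantom(phantom, sim.t2w_sequence("axial"), truth)
        detected = detect_fiducials(vol, design)
        pos = design_positions(design)
        tol = vol.voxel_size / 2.0
        for fid, centroid in detected:
            assert np.all(np.abs(centroid - (pos[fid] + shift)) <= tol)

    def test_too_few_candidates_rejected(self, phantom):
        # uniform volume: nothing to detect
        vol = sim.rasterize_phantom(
            phantom, sim.t2w_sequence("axial"), sim.SessionGroundTruth(),
            {fid: (1.0, geo.FILL_T1_S, geo.FILL_T2_S) for fid in sim.default_relax_table(phantom)},
        )
        with pytest.raises(ValueError, match="candidates"):
            detect_fiducials(vol, geo.design_fiducial_coordinates())

    def test_noisy_detection_precision(self, phantom, design):
        """In-plane centroid precision stays below 0.5 mm at 3% noise."""
        seq = sim.t2w_sequence("axial")
        clean = sim.rasterize_phantom(phantom, seq, sim.SessionGroundTruth(), seed=None)
        fill = sim._sequence_signal(seq, 1.0, geo.FILL_T1_S, geo.FILL_T2_S)
        pos = design_positions(design)
        errs = []
        for s in range(20):
            vol = sim.add_noise(clean, 0.03, fill, 300 + s)
            for fid, centroid in detect_fiducials(vol, design):
                errs.append(np.hypot(*(centroid - pos[fid])[:2]))
        assert np.mean(errs) < 0.5


class TestMidSliceCrop:
    def test_thick_slice_crop_spans_one_slice(self, clean_axial_with_labels):
        vol, labels, _ = clean_axial_with_labels
        center = next(m.center for m in geo.mimic_table("T2-MnCl2") if m.index == 4)
        out = mid_slice_crop(labels, center, RigidTransform.identity())
        occupied = np.unique(np.argwhere(out.labels > 0)[:, 2])
        assert len(occupied) == 1

    def test_crop_is_subset_of_input(self, clean_axial_with_labels):
        _, labels, _ = clean_axial_with_labels
        center = geo.mimic_table("T2-MnCl2")[0].center
        out = mid_slice_crop(labels, center, RigidTransform.identity())
        assert np.all((out.labels == 0) | (out.labels == labels.labels))

    def test_isotropic_crop_takes_largest_cross_section(self, template_pair):
        template, labels = template_pair
        m = geo.mimic_table("T2-MnCl2")[6]
        out = mid_slice_crop(labels, m.center, RigidTransform.identity())
        sel = out.feature_mask(m.feature_id)
        full = labels.feature_mask(m.feature_id)
        # isotropic grid: the crop falls back to axis 0, keeping the slice
        # through the sphere center, i.e. the largest cross-section
        per_slice = full.sum(axis=(1, 2))
        assert sel.sum() == per_slice.max()

    def test_center_outside_grid_rejected(self, clean_axial_with_labels):
        _, labels, _ = clean_axial_with_labels
        with pytest.raises(ValueError, match="outside"):
            mid_slice_crop(labels, (0.0, 0.0, 500.0), RigidTransform.identity())
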