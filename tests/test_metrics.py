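"""PSNR, contrast, Kabsch distortion analysis, and thermometer reading."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from phantomqc import geometry as geo
from phantomqc import simulate as sim
from phantomqc.metrics import (
    DistortionRecord,
    compute_distortions,
    contrast,
    kabsch,
    psnr,
    read_thermometer,
    summarize_distortions,
)
from phantomqc.segment import RigidTransform, detect_fiducials
from phantomqc.volume import ScanVolume

from conftest import design_positions


def _vol(data):
    data = np.asarray(data, dtype=float)
    return ScanVolume(data, np.eye(4))


class TestPsnr:
    def test_closed_form_20db(self):
        a = np.ones((6, 6, 6))
        b = np.ones((6, 6, 6))
        b[0, 0, 0] = 1.0  # keep max 1
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[:3] = True
        bb = b.copy()
        bb[mask] -= 0.1  # masked MSE = 0.01 after (trivial) normalization
        bb[0, 0, 0] = 1.0
        mask[0, 0, 0] = False
        res = psnr(_vol(a), _vol(bb), mask)
        assert np.isclose(res.psnr, 20.0, atol=1e-9)
        assert np.isclose(res.mod_psnr, 100.0, atol=1e-6)

    def test_mod_psnr_invariant(self):
        rng = np.random.default_rng(0)
        a = rng.random((5, 5, 5)) + 0.5
        b = a + rng.normal(0, 0.05, a.shape)
        res = psnr(_vol(a), _vol(np.abs(b)), np.ones(a.shape, bool))
        assert np.isclose(res.mod_psnr, 10 ** (res.psnr / 10.0), rtol=1e-12)

    def test_identical_inputs_rejected(self):
        a = np.ones((4, 4, 4))
        with pytest.raises(ValueError, match="identical"):
            psnr(_vol(a), _vol(a.copy()), np.ones(a.shape, bool))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            psnr(_vol(np.ones((4, 4, 4))), _vol(np.ones((5, 4, 4))), np.ones((4, 4, 4), bool))

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        a = rng.random((6, 6, 6)) + 0.2
        b = rng.random((6, 6, 6)) + 0.2
        mask = rng.random((6, 6, 6)) > 0.4
        assert psnr(_vol(a), _vol(b), mask).psnr == psnr(_vol(b), _vol(a), mask).psnr

    def test_noise_law_6db_per_doubling(self, phantom, clean_axial_with_labels):
        """Doubling the noise SD costs 20*log10(2) = 6.02 dB of PSNR.

        Holds in the regime where the masked MSE is noise-dominated while
        the normalization maximum stays signal-dominated.
        """
        clean, labels, _ = clean_axial_with_labels
        seq = sim.t2w_sequence("axial")
        fill = sim._sequence_signal(seq, 1.0, geo.FILL_T1_S, geo.FILL_T2_S)
        mask = labels.mask()
        drops = []
        for s in range(10):
            vals = {}
            for sigma in (0.002, 0.004):
                a = sim.add_noise(clean, sigma, fill, 50_000 + s)
                b = sim.add_noise(clean, sigma, fill, 60_000 + s)
                vals[sigma] = psnr(a, b, mask).psnr
            drops.append(vals[0.002] - vals[0.004])
        assert abs(np.mean(drops) - 20 * np.log10(2.0)) < 0.2

    def test_repeat_pair_psnr_matches_noise_prediction(self, phantom, clean_axial_with_labels):
        """PSNR of a simulated repeat pair lands on -10 log10(2 sigma_n^2)."""
        clean, labels, _ = clean_axial_with_labels
        seq = sim.t2w_sequence("axial")
        fill = sim._sequence_signal(seq, 1.0, geo.FILL_T1_S, geo.FILL_T2_S)
        sigma = 0.002
        vals = []
        for s in range(10):
            a = sim.add_noise(clean, sigma, fill, 70_000 + s)
            b = sim.add_noise(clean, sigma, fill, 80_000 + s)
            sigma_n = sigma * fill / a.data.max()  # noise SD on the normalized scale
            vals.append(psnr(a, b, labels.mask()).psnr - (-10 * np.log10(2 * sigma_n**2)))
        assert abs(np.mean(vals)) < 0.3


class TestContrast:
    def _setup(self, clean_axial_with_labels):
        vol, labels, _ = clean_axial_with_labels
        array = [f"MnCl2-{k}" for k in range(1, 15)]
        return vol, labels, array

    def test_direct_formula(self, clean_axial_with_labels):
        vol, labels, array = self._setup(clean_axial_with_labels)
        res = contrast(vol, labels, "MnCl2-4", "MnCl2-8", array, RigidTransform.identity())
        assert np.isclose(res.con, (res.s_wm - res.s_gm) / res.s_ref, rtol=1e-12)

    def test_equal_mimics_zero_contrast(self, clean_axial_with_labels):
        vol, labels, array = self._setup(clean_axial_with_labels)
        res = contrast(vol, labels, "MnCl2-5", "MnCl2-5", array, RigidTransform.identity())
        assert res.con == 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        # scaling the whole image cancels through S_ref
        s_wm, s_gm, means = 1.2, 0.8, [1.0, 1.2, 0.8]
        con = (s_wm - s_gm) / np.mean(means)
        con_scaled = (scale * s_wm - scale * s_gm) / np.mean([scale * m for m in means])
        assert np.isclose(con, con_scaled, rtol=1e-12)

    def test_image_scaling_leaves_con_unchanged(self, clean_axial_with_labels):
        vol, labels, array = self._setup(clean_axial_with_labels)
        t = RigidTransform.identity()
        res1 = contrast(vol, labels, "MnCl2-4", "MnCl2-8", array, t)
        scaled = ScanVolume(vol.data * 37.5, vol.affine, vol.scan_plane)
        res2 = contrast(scaled, labels, "MnCl2-4", "MnCl2-8", array, t)
        assert np.isclose(res1.con, res2.con, rtol=1e-12)

    def test_forward_model_prediction(self, phantom):
        """Measured contrast matches the signal equation on the mimic T1/T2."""
        table = sim.default_relax_table(phantom)
        for idx, vals in ((4, (0.768, 0.339)), (8, (0.244, 0.131))):
            table[f"MnCl2-{idx}"] = (1.0, *vals)
        seq = sim.t2w_sequence("axial")
        vol, labels = sim.rasterize_phantom(phantom, seq, sim.SessionGroundTruth(), table, with_labels=True)
        array = [f"MnCl2-{k}" for k in range(1, 15)]
        res = contrast(vol, labels, "MnCl2-4", "MnCl2-8", array, RigidTransform.identity())
        tr, te = seq.tr_ms / 1000, float(seq.te_ms) / 1000
        pred = {
            k: sim.fse_signal(1.0, *table[f"MnCl2-{k}"][1:], tr, te) for k in range(1, 15)
        }
        expected = (pred[4] - pred[8]) / np.mean(list(pred.values()))
        assert res.con > 0
        # label-edge voxels mix in fill solution (partial volume), biasing the
        # mimic means toward the fill level; the pure-signal prediction is
        # therefore only matched to ~15%
        assert np.isclose(res.con, expected, rtol=0.15)


class TestKabschAndDistortion:
    def test_pure_rigid_motion_absorbed(self, design):
        pts = np.array([f.design_position for f in design])
        R = Rotation.from_euler("xyz", [4, -3, 10], degrees=True).as_matrix()
        moved = pts @ R.T + np.array([5.0, -7.0, 2.0])
        detected = [(f.id, moved[i]) for i, f in enumerate(design)]
        records, _ = compute_distortions(detected, design, "axial")
        assert all(np.linalg.norm(r.delta) < 1e-9 for r in records)

    def test_kabsch_agrees_with_independent_rotation_solver(self, design):
        rng = np.random.default_rng(3)
        pts = np.array([f.design_position for f in design])
        noisy = pts + rng.normal(0, 0.5, pts.shape)
        R, t = kabsch(noisy, pts)
        rot_scipy, _ = Rotation.align_vectors(pts - pts.mean(0), noisy - noisy.mean(0))
        assert np.allclose(R, rot_scipy.as_matrix(), atol=1e-8)

    def test_collinear_configuration_rejected(self):
        pts = np.array([[float(i), 0.0, 0.0] for i in range(6)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch(pts, pts * 2.0)

    def test_outlier_excluded_at_20mm(self, design):
        pts = np.array([f.design_position for f in design], dtype=float)
        detected = [(f.id, pts[i].copy()) for i, f in enumerate(design)]
        detected[6] = (detected[6][0], detected[6][1] + np.array([25.0, 0.0, 0.0]))
        records, _ = compute_distortions(detected, design, "axial")
        excluded = [r for r in records if r.excluded]
        assert len(excluded) == 1
        assert excluded[0].fiducial_id == detected[6][0]
        summary = summarize_distortions(records, "axial")
        assert summary["n_excluded"] == 1
        kept_ids = {r["fiducial_id"] for r in summary["per_fiducial"]}
        assert excluded[0].fiducial_id not in kept_ids

    def test_exclusion_rule_is_exactly_20mm(self):
        r_in = DistortionRecord(1, (19.9, 0, 0), 19.9, 50.0, excluded=False)
        assert np.linalg.norm(r_in.delta) <= 20.0
        r_out = DistortionRecord(2, (20.1, 0, 0), 20.1, 50.0, excluded=True)
        assert np.linalg.norm(r_out.delta) > 20.0

    def test_too_few_pairs_rejected(self, design):
        detected = [(f.id, np.asarray(f.design_position)) for f in design[:3]]
        with pytest.raises(ValueError, match="4"):
            compute_distortions(detected, design, "axial")

    def test_group_labels_are_design_radii(self, design):
        pts = {f.id: np.asarray(f.design_position, dtype=float) for f in design}
        detected = [(i, p.copy()) for i, p in pts.items()]
        records, _ = compute_distortions(detected, design, "sagittal")
        groups = {r.radius_group for r in records}
        assert groups == {0.0, 50.0, 70.7}

    def test_zero_deltas_give_zero_group_means(self, design):
        detected = [(f.id, np.asarray(f.design_position, dtype=float)) for f in design]
        records, _ = compute_distortions(detected, design, "coronal")
        summary = summarize_distortions(records, "coronal")
        for g, stats in summary["groups"].items():
            if stats is not None:
                assert stats["mean"] < 1e-9

    def test_radial_field_recovered_after_rigid_removal(self, phantom, design):
        """Computed per-fiducial distortion equals the applied smooth field
        minus its best rigid approximation (independent solver), < 0.5 mm."""
        field = sim.radial_field(2.0, order=2)
        truth = sim.SessionGroundTruth(distortion=field)
        seq = sim.t2w_sequence("axial")
        vol = sim.rasterize_phantom(phantom, seq, truth)
        detected = detect_fiducials(vol, design)
        records, _ = compute_distortions(detected, design, "axial")
        pos = design_positions(design)
        # independent oracle: rigid-fit the displacement field with scipy
        pts = np.array([pos[i] for i, _ in detected])
        displaced = pts + field(pts)
        rot, _ = Rotation.align_vectors(pts - pts.mean(0), displaced - displaced.mean(0))
        aligned = (displaced - displaced.mean(0)) @ rot.as_matrix().T + pts.mean(0)
        residual = aligned - pts  # distortion after rigid removal
        for rec, res in zip(records, residual):
            assert np.linalg.norm(np.asarray(rec.delta) + res) < 0.5

    def test_monotone_group_means_under_radial_field(self, phantom, design):
        truth = sim.SessionGroundTruth(distortion=sim.radial_field(2.0, order=1))
        vol = sim.rasterize_phantom(phantom, sim.t2w_sequence("sagittal"), truth)
        detected = detect_fiducials(vol, design)
        records, _ = compute_distortions(detected, design, "sagittal")
        summary = summarize_distortions(records, "sagittal")
        means = [summary["groups"][g]["mean"] for g in (0.0, 50.0, 70.7)]
        assert means[0] < means[1] < means[2]


class TestThermometerReading:
    def _scan(self, phantom, temperature):
        truth = sim.SessionGroundTruth(temperature_c=temperature)
        return sim.rasterize_phantom(
            phantom, sim.thermometer_sequence(), truth, seed=None, with_labels=True
        )

    def test_hot_phantom_capped_at_24p5(self, phantom):
        vol, labels = self._scan(phantom, 30.0)
        reading = read_thermometer(vol, labels, phantom.thermometer)
        assert reading.temperature == 24.5
        assert reading.capped

    def test_cold_phantom_capped_low(self, phantom):
        vol, labels = self._scan(phantom, 10.0)
        reading = read_thermometer(vol, labels, phantom.thermometer)
        assert reading.n_dark == 0
        assert reading.capped_low
        assert reading.temperature == 14.5

    def test_room_temperature_within_half_degree(self, phantom):
        vol, labels = self._scan(phantom, 20.0)
        reading = read_thermometer(vol, labels, phantom.thermometer)
        assert reading.n_dark == 6
        assert abs(reading.temperature - 20.0) <= 0.5
        assert not reading.capped

    def test_missing_element_label_rejected(self, phantom):
        vol, labels = self._scan(phantom, 20.0)
        labels.legend.pop(labels.id_of("thermo-3"))
        with pytest.raises(ValueError, match="thermo-3"):
            read_thermometer(vol, labels, phantom.thermometer)
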