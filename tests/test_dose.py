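import numpy as np
import pytest

from tfusnav import (HeadModel, ScalpMap, ScalpMesh, all_nuclei_doses,
                     assemble_scalp_map, nucleus_dose, smooth_scalp_map)
from tfusnav.solver import BeamGrid, BeamResult


def make_head(shape=(12, 12, 12), labels=None):
    labels = np.zeros(shape, np.int32) if labels is None else labels
    ones = np.ones(shape)
    return HeadModel(affine=np.eye(4), head_mask=np.ones(shape, bool),
                     porosity=ones, rho=1000 * ones, c=1500 * ones,
                     alpha=0 * ones, labels=labels)


def axis_grid(shape, origin=(0, 0, 0), spacing=1.0):
    return BeamGrid(origin=np.asarray(origin, float),
                    u=np.array([1.0, 0, 0]), v=np.array([0, 1.0, 0]),
                    w=np.array([0, 0, 1.0]), spacing=spacing, shape=shape)


def beam_with(intensity, origin=(0, 0, 0), spacing=1.0):
    return BeamResult(intensity=np.asarray(intensity, np.float32),
                      grid=axis_grid(intensity.shape, origin, spacing))


class TestNucleusDose:
    def test_uniform_intensity_counts_voxels(self):
        labels = np.zeros((12, 12, 12), np.int32)
        labels[2:7, 2:7, 2:6] = 10  # 100 voxels at 1 mm3
        head = make_head(labels=labels)
        beam = beam_with(np.ones((14, 14, 14)), origin=(-1, -1, -1))
        assert nucleus_dose(beam, head, 10) == pytest.approx(100.0)

    def test_nucleus_outside_beam_domain_is_zero(self):
        labels = np.zeros((12, 12, 12), np.int32)
        labels[2:4, 2:4, 2:4] = 10
        head = make_head(labels=labels)
        beam = beam_with(np.ones((5, 5, 5)), origin=(100, 100, 100))
        assert nucleus_dose(beam, head, 10) == 0.0

    def test_matches_explicit_per_voxel_loop(self):
        rng = np.random.default_rng(5)
        labels = np.zeros((12, 12, 12), np.int32)
        vox = rng.choice(12 ** 3, size=10, replace=False)
        labels.ravel()[vox] = 7
        head = make_head(labels=labels)
        inten = rng.uniform(0, 2, (16, 16, 16)).astype(np.float32)
        beam = beam_with(inten, origin=(-2.25, -1.5, -0.75), spacing=0.8)
        # independent oracle: explicit trilinear sum over the 10 voxels
        expected = 0.0
        for flat in vox:
            ijk = np.unravel_index(flat, (12, 12, 12))
            local = (np.asarray(ijk, float)
                     - np.asarray([-2.25, -1.5, -0.75])) / 0.8
            i0 = np.floor(local).astype(int)
            fr = local - i0
            acc = 0.0
            for di in (0, 1):
                for dj in (0, 1):
                    for dk in (0, 1):
                        idx = i0 + (di, dj, dk)
                        if np.all(idx >= 0) and np.all(idx < 16):
                            val = inten[tuple(idx)]
                        else:
                            val = 0.0
                        w = ((fr[0] if di else 1 - fr[0])
                             * (fr[1] if dj else 1 - fr[1])
                             * (fr[2] if dk else 1 - fr[2]))
                        acc += w * float(val)
            expected += acc
        assert nucleus_dose(beam, head, 7) == pytest.approx(expected, rel=1e-5)

    def test_absent_label_lists_available(self):
        labels = np.zeros((6, 6, 6), np.int32)
        labels[2, 2, 2] = 10
        head = make_head((6, 6, 6), labels)
        beam = beam_with(np.ones((6, 6, 6)))
        with pytest.raises(KeyError, match=r"\[10\]"):
            nucleus_dose(beam, head, 18)


class TestAllNucleiDoses:
    def test_two_disjoint_nuclei(self):
        labels = np.zeros((12, 12, 12), np.int32)
        labels[1:3, 1:6, 1:6] = 10   # 50 voxels
        labels[6:8, 1:8, 1:6] = 18   # 70 voxels
        head = make_head(labels=labels)
        beam = beam_with(np.ones((14, 14, 14)), origin=(-1, -1, -1))
        doses = all_nuclei_doses(beam, head)
        assert doses[10] == pytest.approx(50.0)
        assert doses[18] == pytest.approx(70.0)

    def test_consistent_with_single_label_calls(self):
        rng = np.random.default_rng(2)
        labels = np.zeros((10, 10, 10), np.int32)
        labels[2:4, 2:4, 2:4] = 3
        labels[6:8, 6:8, 6:8] = 4
        head = make_head((10, 10, 10), labels)
        beam = beam_with(rng.uniform(0, 1, (12, 12, 12)), origin=(-1, -1, -1))
        doses = all_nuclei_doses(beam, head)
        for lab in (3, 4):
            assert doses[lab] == nucleus_dose(beam, head, lab)


def toy_mesh():
    """5-face chain: adjacency 0-1, 1-2, 2-3, 3-4; areas [1,2,1,1,3]."""
    adj = [np.array([1]), np.array([0, 2]), np.array([1, 3]),
           np.array([2, 4]), np.array([3])]
    nf = 5
    return ScalpMesh(vertices=np.zeros((3, 3)),
                     faces=np.zeros((nf, 3), int),
                     face_centers=np.zeros((nf, 3)),
                     face_normals=np.tile([0, 0, 1.0], (nf, 1)),
                     face_areas=np.array([1.0, 2.0, 1.0, 1.0, 3.0]),
                     adjacency=adj)


def toy_map(raw):
    raw = np.asarray(raw, float)
    return ScalpMap(face_ids=np.arange(len(raw)), raw_dose=raw,
                    smoothed_dose=raw.copy(), nucleus_label=1)


class TestSmoothing:
    def test_hand_computed_one_iteration(self):
        # area-weighted mean of self + chain neighbors, worked by hand
        sm = smooth_scalp_map(toy_map([10, 0, 6, 0, 2]), toy_mesh(), 1)
        np.testing.assert_allclose(sm.smoothed_dose,
                                   [10 / 3, 4.0, 1.5, 2.4, 1.5])

    def test_zero_iterations_is_identity(self):
        m = toy_map([3, 1, 4, 1, 5])
        sm = smooth_scalp_map(m, toy_mesh(), 0)
        np.testing.assert_array_equal(sm.smoothed_dose, m.raw_dose)

    def test_constant_map_fixed_point(self):
        sm = smooth_scalp_map(toy_map([2, 2, 2, 2, 2]), toy_mesh(), 7)
        np.testing.assert_allclose(sm.smoothed_dose, 2.0)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            raw = rng.uniform(0, 10, 5)
            sm = smooth_scalp_map(toy_map(raw), toy_mesh(), 3)
            assert sm.smoothed_dose.min() >= raw.min() - 1e-12
            assert sm.smoothed_dose.max() <= raw.max() + 1e-12

    def test_max_nonincreasing_in_iterations(self):
        raw = [9, 0, 1, 0, 2]
        maxes = [smooth_scalp_map(toy_map(raw), toy_mesh(), k)
                 .smoothed_dose.max() for k in range(5)]
        assert all(a >= b - 1e-12 for a, b in zip(maxes, maxes[1:]))

    def test_excluded_faces_skipped(self):
        mesh = toy_mesh()
        mesh.valid = np.array([True, True, False, True, True])
        raw = np.array([10.0, 0.0, np.nan, 0.0, 2.0])
        sm = smooth_scalp_map(toy_map(raw), mesh, 1)
        assert np.isnan(sm.smoothed_dose[2])
        # face 1 averages only itself and face 0 (face 2 is excluded)
        assert sm.smoothed_dose[1] == pytest.approx((2 * 0 + 1 * 10) / 3)


class TestAssembleScalpMap:
    def _setup(self):
        labels = np.zeros((12, 12, 12), np.int32)
        labels[4:8, 4:8, 4:8] = 10
        head = make_head(labels=labels)
        rng = np.random.default_rng(4)
        mesh = toy_mesh()
        mesh.valid = np.array([True, True, True, False, True])
        lib = {fid: beam_with(rng.uniform(0, 1, (14, 14, 14)),
                              origin=(-1, -1, -1)) for fid in range(5)}
        return head, mesh, lib

    def test_map_matches_per_face_doses_and_peak(self):
        head, mesh, lib = self._setup()
        smap = assemble_scalp_map(lib, head, 10, mesh, smoothing_iterations=0)
        oracle = {fid: nucleus_dose(lib[fid], head, 10)
                  for fid in mesh.valid_face_ids()}
        for fid, dose in oracle.items():
            assert smap.raw_dose[fid] == pytest.approx(dose)
        assert np.isnan(smap.raw_dose[3])  # excluded face -> sentinel
        assert smap.peak_face(smoothed=False) == max(oracle, key=oracle.get)

    def test_order_independent(self):
        head, mesh, lib = self._setup()
        a = assemble_scalp_map(lib, head, 10, mesh)
        shuffled = {k: lib[k] for k in [4, 1, 0, 2, 3]}
        b = assemble_scalp_map(shuffled, head, 10, mesh)
        np.testing.assert_array_equal(a.raw_dose, b.raw_dose)
        np.testing.assert_array_equal(a.smoothed_dose, b.smoothed_dose)

    def test_missing_face_record(self):
        head, mesh, lib = self._setup()
        del lib[1]
        with pytest.raises(KeyError, match="face 1"):
            assemble_scalp_map(lib, head, 10, mesh)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        head, mesh, lib = self._setup()
        smap = assemble_scalp_map(lib, head, 10, mesh)
        path = tmp_path / "map.csv"
        smap.save_csv(path)
        back = ScalpMap.from_frame(pd.read_csv(path), 10)
        np.testing.assert_allclose(back.raw_dose, smap.raw_dose, rtol=1e-8)
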