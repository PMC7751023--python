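"""Volume handling: masking, change maps, spherical seeds, lesion overlap."""

import numpy as np
import pytest

from scnpls.exceptions import (
    AlignmentError,
    DegenerateMaskError,
    DimensionError,
    EmptySeedError,
)
from scnpls.gm_maps import (
    GMDataset,
    SeedSpec,
    build_gm_dataset,
    compute_change_dataset,
    extract_seed_means,
    lesion_seed_overlap,
    load_gm_dataset,
    read_seed_table,
    sphere_voxel_mask,
    write_gm_dataset,
    write_seed_table,
)

from conftest import make_gm


def brute_force_sphere(shape, affine, centre, radius):
    """Independent O(n^3) scan of voxel centres against the mm sphere."""
    hits = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                mm = affine @ np.array([i, j, k, 1.0])
                if np.sum((mm[:3] - np.asarray(centre)) ** 2) <= radius**2 + 1e-9:
                    hits[i, j, k] = True
    return hits


class TestMasking:
    def test_constant_image_full_mask(self):
        gm = make_gm(np.full((3, 4, 4, 4), 0.5))
        assert gm.n_voxels == 64
        assert np.all(gm.data == 0.5)

    def test_group_mean_rule(self):
        vols = np.full((2, 2, 2, 2), 0.2)
        vols[0, 0, 0, 0], vols[1, 0, 0, 0] = 0.4, 0.6  # mean 0.5 at one voxel
        gm = make_gm(vols)
        assert gm.n_voxels == 1
        np.testing.assert_allclose(gm.data[:, 0], [0.4, 0.6])

    def test_per_subject_threshold_intersection(self):
        vols = np.full((2, 2, 2, 2), 0.5)
        vols[0, 0, 0, 0] = 0.1  # drags subject 0 below threshold there
        gm = build_gm_dataset(vols, np.eye(4), per_subject_threshold=True)
        assert gm.n_voxels == 7

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateMaskError):
            make_gm(np.full((2, 2, 2, 2), 0.1))

    def test_shape_mismatch_raises(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.full((4, 4, 4), 0.5), np.eye(4)),
                 str(tmp_path / "a.nii.gz"))
        nib.save(nib.Nifti1Image(np.full((4, 4, 5), 0.5), np.eye(4)),
                 str(tmp_path / "b.nii.gz"))
        with pytest.raises(DimensionError):
            load_gm_dataset([tmp_path / "a.nii.gz", tmp_path / "b.nii.gz"])

    def test_roundtrip_bit_exact(self, tmp_path, rng):
        vols = 0.45 + 0.4 * rng.random((3, 5, 5, 5))
        gm = make_gm(vols)
        paths = write_gm_dataset(gm, tmp_path)
        re = load_gm_dataset(paths, mask_threshold=0.45,
                             subject_ids=gm.subject_ids)
        assert np.array_equal(re.mask, gm.mask)
        assert np.array_equal(re.data, gm.data)


class TestChange:
    def test_identity_gives_zero(self, rng):
        vols = 0.5 + 0.1 * rng.random((3, 4, 4, 4))
        a, b = make_gm(vols), make_gm(vols.copy(), timepoint="chronic")
        ch = compute_change_dataset(a, b)
        assert ch.timepoint == "change"
        np.testing.assert_array_equal(ch.data, 0.0)

    def test_uniform_offset(self):
        vols = np.full((2, 3, 3, 3), 0.6)
        a = make_gm(vols)
        b = make_gm(vols - 0.1, threshold=0.0)
        b = GMDataset(b.subject_ids, (vols - 0.1)[:, a.mask], a.mask,
                      a.affine, "chronic")
        ch = compute_change_dataset(a, b)
        np.testing.assert_allclose(ch.data, -0.1)

    def test_subject_mismatch_raises(self, rng):
        vols = 0.5 + 0.1 * rng.random((3, 4, 4, 4))
        a = make_gm(vols)
        b = make_gm(vols[:2], timepoint="chronic")
        with pytest.raises(AlignmentError):
            compute_change_dataset(a, b)

    def test_change_commutes_with_seed_extraction(self, rng, centred_seed):
        vols1 = 0.5 + 0.05 * rng.random((4, 16, 16, 16))
        vols2 = 0.5 + 0.05 * rng.random((4, 16, 16, 16))
        a, b = make_gm(vols1), make_gm(vols2, timepoint="chronic")
        b = GMDataset(b.subject_ids, vols2[:, a.mask], a.mask, a.affine, "chronic")
        via_change = extract_seed_means(compute_change_dataset(a, b), [centred_seed])
        direct = (extract_seed_means(b, [centred_seed]).values
                  - extract_seed_means(a, [centred_seed]).values)
        np.testing.assert_allclose(via_change.values, direct, atol=1e-12)


class TestSeeds:
    def test_constant_image_mean(self, centred_seed):
        gm = make_gm(np.full((2, 16, 16, 16), 0.7))
        sm = extract_seed_means(gm, [centred_seed])
        np.testing.assert_allclose(sm.values, 0.7)

    def test_sphere_count_1mm_grid(self, centred_seed):
        # 4-mm sphere fully inside a 1-mm grid: integer lattice points with
        # x^2+y^2+z^2 <= 16
        gm = make_gm(np.full((1, 17, 17, 17), 0.5), spacing=1.0)
        mask = sphere_voxel_mask(gm.mask.shape, gm.affine, centred_seed)
        assert mask.sum() == 257
        brute = brute_force_sphere(gm.mask.shape, gm.affine,
                                   centred_seed.centre_mm, 4.0)
        assert np.array_equal(mask, brute)

    def test_sphere_count_4mm_grid(self):
        seed = SeedSpec("c", "DAN", (8.0, 8.0, 8.0), 4.0)
        vols = np.full((1, 5, 5, 5), 0.0)
        vols[0, 2, 2, 2] = 1.0  # centre voxel
        gm = build_gm_dataset(vols, np.diag([4.0, 4, 4, 1]), mask_threshold=0.0)
        mask = sphere_voxel_mask(gm.mask.shape, gm.affine, seed)
        assert mask.sum() == 7  # centre + 6 face neighbours
        sm = extract_seed_means(gm, [seed])
        np.testing.assert_allclose(sm.values, 1.0 / 7.0)

    @pytest.mark.parametrize("spacing,radius", [(1.0, 2.5), (2.0, 5.0), (3.0, 4.0)])
    def test_sphere_matches_brute_force(self, spacing, radius):
        seed = SeedSpec("s", "SN", (5.0, 7.0, 3.0), radius)
        shape = (9, 9, 9)
        affine = np.diag([spacing, spacing, spacing, 1.0])
        mask = sphere_voxel_mask(shape, affine, seed)
        assert np.array_equal(
            mask, brute_force_sphere(shape, affine, seed.centre_mm, radius)
        )

    def test_linearity(self, rng, centred_seed):
        v1 = 0.5 + 0.1 * rng.random((3, 16, 16, 16))
        v2 = 0.5 + 0.1 * rng.random((3, 16, 16, 16))
        g1, g2 = make_gm(v1), make_gm(v2)
        combo = make_gm(2.0 * v1 + 3.0 * v2, threshold=0.0)
        combo = GMDataset(g1.subject_ids, (2 * v1 + 3 * v2)[:, g1.mask],
                          g1.mask, g1.affine)
        m = extract_seed_means
        np.testing.assert_allclose(
            m(combo, [centred_seed]).values,
            2 * m(g1, [centred_seed]).values + 3 * m(g2, [centred_seed]).values,
            atol=1e-12,
        )

    def test_empty_seed_raises_with_name(self):
        gm = make_gm(np.full((2, 8, 8, 8), 0.5))
        far = SeedSpec("nowhere", "DMN", (500.0, 500.0, 500.0), 4.0)
        with pytest.raises(EmptySeedError, match="nowhere"):
            extract_seed_means(gm, [far])

    def test_seed_table_roundtrip(self, tmp_path, centred_seed):
        write_seed_table([centred_seed], tmp_path / "seeds.tsv")
        back = read_seed_table(tmp_path / "seeds.tsv")
        assert back == [centred_seed]


class TestLesionOverlap:
    def _gm(self):
        return make_gm(np.full((2, 16, 16, 16), 0.5))

    def test_disjoint(self, centred_seed):
        gm = self._gm()
        lesion = np.zeros(gm.mask.shape, dtype=bool)
        lesion[0, 0, 0] = True
        rep = lesion_seed_overlap(lesion, [centred_seed], gm)
        assert rep.fraction_of_seed_map == 0.0

    def test_identical(self, centred_seed):
        gm = self._gm()
        conj = sphere_voxel_mask(gm.mask.shape, gm.affine, centred_seed)
        rep = lesion_seed_overlap(conj, [centred_seed], gm)
        assert rep.fraction_of_seed_map == 1.0
        assert rep.lesion_voxels == rep.seed_voxels

    def test_half_overlap(self, centred_seed):
        gm = self._gm()
        conj = sphere_voxel_mask(gm.mask.shape, gm.affine, centred_seed)
        idx = np.argwhere(conj)
        half = np.zeros_like(conj)
        half[tuple(idx[: len(idx) // 2].T)] = True
        rep = lesion_seed_overlap(half, [centred_seed], gm)
        assert rep.intersection_voxels == len(idx) // 2
        assert rep.fraction_of_seed_map == pytest.approx(
            (len(idx) // 2) / len(idx)
        )

    def test_grid_mismatch(self, centred_seed):
        gm = self._gm()
        with pytest.raises(DimensionError):
            lesion_seed_overlap(np.zeros((4, 4, 4), bool), [centred_seed], gm)
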