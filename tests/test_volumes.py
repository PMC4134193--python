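"""Container invariants, NIfTI round-trips and mask algebra."""

import numpy as np
import pytest

import nibabel as nib

from wmhseg import (BinaryMask, GridMismatchError, ImageVolume, apply_mask,
                    binarize_probability, label_components, mask_and,
                    read_volume, write_mask, write_volume)
from wmhseg.volumes import read_mask


def _vol(data, spacing=(1.0, 1.0, 1.0), **kw):
    return ImageVolume(np.asarray(data, float), np.diag(list(spacing) + [1.0]), **kw)


class TestIO:
    def test_write_read_roundtrip_identity(self, tmp_path, rng):
        vol = _vol(rng.normal(size=(8, 9, 5)), spacing=(0.8, 0.8, 6.0))
        path = tmp_path / "img.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.data, vol.data, rtol=1e-6)
        np.testing.assert_allclose(back.spacing, (0.8, 0.8, 6.0), atol=1e-6)

    def test_mask_roundtrip_bit_exact(self, tmp_path, rng):
        m = BinaryMask(rng.random((6, 6, 4)) > 0.5, np.eye(4))
        path = tmp_path / "m.nii.gz"
        write_mask(m, path)
        assert (read_mask(path).data == m.data).all()

    def test_4d_image_rejected_with_dimensionality(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 3), dtype=np.float32), np.eye(4))
        path = tmp_path / "bad.nii.gz"
        nib.save(img, path)
        with pytest.raises(ValueError, match="4-D"):
            read_volume(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_rank_and_finiteness_enforced(self):
        with pytest.raises(ValueError, match="3-D"):
            _vol(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="finite"):
            _vol(np.full((3, 3, 3), np.nan))


class TestBinarize:
    @pytest.mark.parametrize("p,expected", [(0.51, 1), (0.50, 0), (0.49, 0)])
    def test_strictly_over_half(self, p, expected):
        vol = _vol(np.full((2, 2, 2), p), modality="probability")
        assert binarize_probability(vol).data.all() == bool(expected)

    def test_all_zero_map_empty(self):
        assert binarize_probability(_vol(np.zeros((3, 3, 3)))).n_voxels == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            binarize_probability(_vol(np.full((2, 2, 2), 1.5)))


class TestMaskAlgebra:
    def test_and_matches_bruteforce_and_is_commutative(self, rng):
        aff = np.eye(4)
        a = BinaryMask(rng.random((5, 6, 4)) > 0.5, aff)
        b = BinaryMask(rng.random((5, 6, 4)) > 0.5, aff)
        got = mask_and(a, b).data
        brute = np.zeros_like(got)
        for idx in np.ndindex(a.shape):
            brute[idx] = a.data[idx] and b.data[idx]
        assert (got == brute).all()
        assert (mask_and(b, a).data == got).all()
        assert (mask_and(a, a).data == a.data).all()          # idempotent
        assert mask_and(a, a.complement()).n_voxels == 0

    def test_grid_mismatch_raises(self):
        a = BinaryMask(np.ones((3, 3, 3), bool), np.eye(4))
        b = BinaryMask(np.ones((3, 3, 3), bool), np.diag([2.0, 1, 1, 1]))
        with pytest.raises(GridMismatchError):
            mask_and(a, b)

    def test_apply_mask_preserves_in_mask_histogram(self, rng):
        vol = _vol(rng.integers(0, 50, size=(7, 7, 5)))
        m = BinaryMask(rng.random((7, 7, 5)) > 0.4, vol.affine)
        out = apply_mask(vol, m)
        naive = sorted(vol.data[idx] for idx in np.ndindex(vol.shape) if m.data[idx])
        assert sorted(out.valid_values()) == naive

    def test_apply_full_and_empty_mask(self, rng):
        vol = _vol(rng.normal(size=(4, 4, 4)))
        full = apply_mask(vol, BinaryMask.full(vol))
        assert (full.valid_values() == vol.data.ravel()).all()
        empty = apply_mask(vol, BinaryMask.empty(vol))
        assert empty.valid_values().size == 0


def _flood_fill_labels(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Independent BFS component extraction."""
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)
               and (connectivity == 26 or abs(i) + abs(j) + abs(k) == 1)]
    seen = set()
    comps = []
    for start in zip(*np.nonzero(mask)):
        if start in seen:
            continue
        comp, queue = set(), [start]
        seen.add(start)
        while queue:
            x, y, z = queue.pop()
            comp.add((x, y, z))
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb in seen:
                    continue
                if all(0 <= nb[d] < mask.shape[d] for d in range(3)) and mask[nb]:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return comps


class TestLabelComponents:
    def test_two_separated_cubes(self):
        m = np.zeros((10, 10, 6), bool)
        m[1:3, 1:3, 1:3] = True
        m[6:9, 6:9, 3:5] = True
        lab = label_components(BinaryMask(m, np.eye(4)))
        assert lab.n_labels == 2

    def test_single_voxel(self):
        m = np.zeros((4, 4, 4), bool)
        m[2, 2, 2] = True
        lab = label_components(BinaryMask(m, np.eye(4)))
        assert lab.n_labels == 1 and lab.label_sizes()[1] == 1

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_partition_matches_flood_fill(self, rng, connectivity):
        m = rng.random((10, 10, 5)) > 0.6
        lab = label_components(BinaryMask(m, np.eye(4)), connectivity)
        got = {frozenset(zip(*np.nonzero(lab.data == i)))
               for i in range(1, lab.n_labels + 1)}
        assert got == set(_flood_fill_labels(m, connectivity))
        # partition property: union of labels equals the mask
        assert ((lab.data > 0) == m).all()
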