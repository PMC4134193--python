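"""Candidate nomination threshold, junction band, junction-connected filter."""

import numpy as np
import pytest

from wmhseg import (BinaryMask, DetectionParams, ImageVolume, TissueStats,
                    junction_connected_filter, junction_map,
                    nominate_candidates)


def _vol(data, **kw):
    return ImageVolume(np.asarray(data, float), np.eye(4), **kw)


class TestNominate:
    def test_threshold_strictly_above_65(self):
        data = np.zeros((4, 4, 3))
        data[0, 0, 0], data[1, 1, 1], data[2, 2, 2] = 66.0, 65.0, 64.9
        cands = nominate_candidates(_vol(data), BinaryMask.full(_vol(data)))
        got = cands.mask().data
        assert got[0, 0, 0] and not got[1, 1, 1] and not got[2, 2, 2]

    def test_empty_wm_mask_gives_empty_set(self, rng):
        v = _vol(rng.uniform(0, 100, (5, 5, 3)))
        cands = nominate_candidates(v, BinaryMask.empty(v))
        assert cands.n_components == 0

    def test_threshold_monotonicity(self, rng):
        v = _vol(rng.uniform(0, 100, (8, 8, 4)))
        m = BinaryMask.full(v)
        low = nominate_candidates(v, m, DetectionParams(wmh_threshold=40)).mask().data
        high = nominate_candidates(v, m, DetectionParams(wmh_threshold=70)).mask().data
        assert not (high & ~low).any()

    def test_phantom_wmh_plateau_recovered(self, wmh_phantom):
        from wmhseg import apply_mask, normalize_to_range
        ph = wmh_phantom
        wm = BinaryMask(ph.truth["wm"].data & ph.truth["exclusion"].data,
                        ph.flair.affine)
        norm = normalize_to_range(apply_mask(ph.flair, wm), wm)
        cands = nominate_candidates(norm, wm)
        got = cands.mask().data
        truth = ph.truth["wmh"].data
        dice = 200 * (got & truth).sum() / (got.sum() + truth.sum())
        assert dice >= 85.0


class TestJunctionMap:
    STATS = TissueStats(gm_mean=60.0, gm_sd=10.0, wm_mean=100.0, wm_sd=8.0)

    @pytest.mark.parametrize("intensity,is_junction", [
        (80.0, True),    # inside [65, 96]
        (65.0, True),    # closed lower endpoint
        (96.0, True),    # closed upper endpoint
        (64.9, False),
        (100.0, False),
    ])
    def test_band_membership(self, intensity, is_junction):
        v = _vol(np.full((2, 2, 2), intensity))
        assert junction_map(v, self.STATS).data.all() == is_junction

    def test_empty_band_warns_and_returns_empty(self):
        stats = TissueStats(gm_mean=90.0, gm_sd=10.0, wm_mean=92.0, wm_sd=10.0)
        v = _vol(np.full((3, 3, 3), 90.0))
        with pytest.warns(RuntimeWarning, match="empty"):
            out = junction_map(v, stats)
        assert out.n_voxels == 0


def _toy_candidates(n_total, coords):
    """One in-plane line component of n_total voxels at z=1."""
    from wmhseg import label_components
    grid = np.zeros((12, 12, 3), bool)
    for c in coords:
        grid[c] = True
    assert grid.sum() == n_total
    labels = label_components(BinaryMask(grid, np.eye(4)))
    from wmhseg.wmh import WMHCandidateSet
    return WMHCandidateSet(labels)


class TestJunctionFilter:
    def _run(self, n_junction_connected, n_total=10):
        # candidate: a 10-voxel in-plane line at x=1..10, y=5.  Junction
        # voxels on the adjacent row y=6 at x=2..k-1 mark (via the in-plane
        # 8-neighborhood, including diagonals) candidates x=1..k: exactly
        # k junction-connected voxels.
        coords = [(1 + i, 5, 1) for i in range(n_total)]
        cands = _toy_candidates(n_total, coords)
        jmask = np.zeros((12, 12, 3), bool)
        for x in range(2, n_junction_connected):
            jmask[x, 6, 1] = True
        out = junction_connected_filter(cands, BinaryMask(jmask, np.eye(4)))
        return out.n_components

    def test_ninety_percent_connected_removed(self):
        assert self._run(9) == 0

    def test_exactly_eighty_percent_kept(self):
        assert self._run(8) == 1    # strict > 80% rule

    def test_unconnected_label_kept(self):
        assert self._run(0) == 1

    def test_junction_in_adjacent_slice_does_not_connect_in_2d(self):
        coords = [(1 + i, 5, 1) for i in range(10)]
        cands = _toy_candidates(10, coords)
        jmask = np.zeros((12, 12, 3), bool)
        jmask[1:11, 5, 2] = True   # all junction voxels one slice away
        out = junction_connected_filter(cands, BinaryMask(jmask, np.eye(4)),
                                        DetectionParams(neighborhood="8-2d"))
        assert out.n_components == 1
        out3d = junction_connected_filter(cands, BinaryMask(jmask, np.eye(4)),
                                          DetectionParams(neighborhood="26-3d"))
        assert out3d.n_components == 0

    def test_filter_output_subset_of_input(self, rng):
        from wmhseg import label_components
        grid = rng.random((10, 10, 4)) > 0.7
        cands_labels = label_components(BinaryMask(grid, np.eye(4)))
        from wmhseg.wmh import WMHCandidateSet
        cands = WMHCandidateSet(cands_labels)
        junction = BinaryMask(rng.random((10, 10, 4)) > 0.6, np.eye(4))
        out = junction_connected_filter(cands, junction)
        assert not (out.mask().data & ~cands.mask().data).any()

    def test_no_removals_on_blur_free_phantom(self):
        from conftest import small_spec
        from wmhseg import (apply_mask, fuse, generate_phantom, harmonize,
                            normalize_to_range, tissue_segment_gmm,
                            tissue_stats)
        ph = generate_phantom(small_spec(seed=31, junction_blur_vox=0.0))
        brain = ph.truth["brain"]
        fused = fuse(harmonize(ph.t1w, brain), harmonize(ph.flair, brain))
        gm_p, wm_p = tissue_segment_gmm(fused, brain, seed=0)
        wm = BinaryMask(ph.truth["wm"].data & ph.truth["exclusion"].data,
                        ph.flair.affine)
        norm = normalize_to_range(apply_mask(ph.flair, wm), wm)
        cands = nominate_candidates(norm, wm)
        assert cands.n_components > 0
        jmap = junction_map(fused, tissue_stats(fused, gm_p, wm_p))
        out = junction_connected_filter(cands, jmap)
        assert out.n_components == cands.n_components
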