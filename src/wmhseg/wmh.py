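"""Candidate WMH nomination and gray/white junction false-positive removal.

Candidates are in-mask voxels of the normalized ([0, 100]) FLAIR image with
intensity strictly above the detection threshold (default 65, the average
lowest bound of expert-demarcated WMHs; adjustable), grouped into
connected components.

Blurred gray/white junctions mimic WMHs.  The junction map marks fused-
image voxels whose intensity falls in the closed band

    [ I_avg,GM + 0.5 I_sd,GM ,  I_avg,WM - 0.5 I_sd,WM ]

A candidate voxel is *junction-connected* when it or any of its 8 in-plane
neighbors is a junction voxel; a candidate component is discarded when
strictly more than 80% of its voxels are junction-connected.  The
8-neighborhood is evaluated slice by slice in 2-D by default (a 26-voxel
3-D variant is available for sensitivity analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .tissue import TissueStats
from .volumes import BinaryMask, ImageVolume, LabelMap, check_same_grid, label_components

__all__ = [
    "DetectionParams",
    "WMHCandidateSet",
    "nominate_candidates",
    "junction_map",
    "junction_connected_filter",
]


@dataclass
class DetectionParams:
    """Tunable thresholds of the WMH nomination / junction-removal stages.

    wmh_threshold:
        normalized FLAIR intensity above which a voxel is nominated
        (strict >); default 65 on the [0, 100] scale.
    junction_fraction:
        fraction of junction-connected voxels above which a candidate
        component is discarded (strict >); default 0.8.
    junction_band_coefficient:
        SD multiplier defining the junction intensity band; default 0.5.
    neighborhood:
        ``"8-2d"`` (in-plane, slice-wise; default) or ``"26-3d"``.
    candidate_connectivity:
        3-D connectivity grouping candidate voxels into components
        (default 26).
    """

    wmh_threshold: float = 65.0
    junction_fraction: float = 0.8
    junction_band_coefficient: float = 0.5
    neighborhood: str = "8-2d"
    candidate_connectivity: int = 26

    def __post_init__(self) -> None:
        if not 0.0 <= self.wmh_threshold <= 100.0:
            raise ValueError("wmh_threshold must lie in [0,100]")
        if not 0.0 <= self.junction_fraction <= 1.0:
            raise ValueError("junction_fraction must lie in [0,1]")
        if self.neighborhood not in ("8-2d", "26-3d"):
            raise ValueError("neighborhood must be '8-2d' or '26-3d'")


@dataclass
class WMHCandidateSet:
    """Labeled candidate WMH components with per-label bookkeeping."""

    labels: LabelMap
    voxel_counts: np.ndarray = field(default=None)  # index by label id; [0] unused
    junction_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.voxel_counts is None:
            self.voxel_counts = self.labels.label_sizes()

    @property
    def n_components(self) -> int:
        return self.labels.n_labels

    def mask(self) -> BinaryMask:
        return self.labels.mask()


def nominate_candidates(norm_flair: ImageVolume, wm_mask: BinaryMask,
                        params: DetectionParams | None = None) -> WMHCandidateSet:
    """Select in-mask voxels strictly above the threshold and label them.

    An empty candidate set is a valid outcome (hemisphere without WMHs).
    """
    params = params or DetectionParams()
    check_same_grid(norm_flair, wm_mask)
    cand = (norm_flair.data > params.wmh_threshold) & wm_mask.data & norm_flair.valid_mask
    labels = label_components(BinaryMask(cand, norm_flair.affine.copy()),
                              connectivity=params.candidate_connectivity)
    return WMHCandidateSet(labels)


def junction_map(fused: ImageVolume, stats: TissueStats,
                 band_coefficient: float = 0.5) -> BinaryMask:
    """Binary map of the gray/white junction intensity band (closed interval).

    Bounds: [gm_mean + c*gm_sd, wm_mean - c*wm_sd].  When the band is
    empty (lower bound above upper bound) a warning is issued and an empty
    mask returned.
    """
    lo = stats.gm_mean + band_coefficient * stats.gm_sd
    hi = stats.wm_mean - band_coefficient * stats.wm_sd
    if lo > hi:
        warnings.warn(
            f"junction band is empty (lower {lo:.2f} > upper {hi:.2f}); "
            "returning empty map", RuntimeWarning)
        return BinaryMask.empty(fused)
    data = (fused.data >= lo) & (fused.data <= hi) & fused.valid_mask
    return BinaryMask(data, fused.affine.copy())


_STRUCT_2D = np.zeros((3, 3, 3), dtype=bool)
_STRUCT_2D[:, :, 1] = True  # in-plane 3x3 (axis 2 = slice axis)
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


def junction_connected_voxels(junction: BinaryMask, neighborhood: str = "8-2d") -> np.ndarray:
    """Boolean array: voxel or any neighbor is a junction voxel."""
    struct = _STRUCT_2D if neighborhood == "8-2d" else _STRUCT_3D
    return ndimage.binary_dilation(junction.data, structure=struct)


def junction_connected_filter(cands: WMHCandidateSet, junction: BinaryMask,
                              params: DetectionParams | None = None) -> WMHCandidateSet:
    """Discard candidate components dominated by junction-connected voxels.

    A component is removed iff its junction-connected voxel fraction is
    strictly greater than ``params.junction_fraction`` (a component at
    exactly the fraction survives).  Surviving components are relabeled
    contiguously; the output set is always a subset of the input.
    """
    params = params or DetectionParams()
    check_same_grid(cands.labels, junction)
    lbl = cands.labels.data
    n = cands.labels.n_labels
    if n == 0:
        return WMHCandidateSet(LabelMap(lbl.copy(), cands.labels.affine.copy(), 0),
                               junction_counts=np.zeros(1, dtype=np.int64))
    jc = junction_connected_voxels(junction, params.neighborhood)
    sizes = np.bincount(lbl.ravel(), minlength=n + 1)
    jcounts = np.bincount(lbl[jc].ravel(), minlength=n + 1)
    with np.errstate(invalid="ignore"):
        frac = np.where(sizes > 0, jcounts / np.maximum(sizes, 1), 0.0)
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    keep[1:] = frac[1:] <= params.junction_fraction
    old_ids = np.flatnonzero(keep)
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[old_ids] = np.arange(1, len(old_ids) + 1)
    new_lbl = remap[lbl]
    out_labels = LabelMap(new_lbl, cands.labels.affine.copy(), len(old_ids))
    kept_counts = np.concatenate([[0], jcounts[old_ids]]).astype(np.int64)
    return WMHCandidateSet(out_labels, junction_counts=kept_counts)
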