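"""Tissue probability maps, the cerebral white-matter search mask, and
gray/white intensity statistics.

The pipeline normally consumes subject-space gray/white probability maps
and an ex-brainstem-cerebellum-corpus-callosum exclusion mask produced by
external neuroimaging tools.  When those are not supplied,
:func:`tissue_segment_gmm` provides an atlas-free stand-in: a 3-class
(CSF/GM/WM) Gaussian mixture over in-brain intensities of the fused image,
with classes identified by ascending mean (the fused image is
T1w-dominant, so white matter is brightest).

:func:`tissue_stats` yields the per-tissue fused-intensity mean/SD that
parameterize the gray/white junction band (tissue membership is
probability > 0.5, consistent with the mask binarization convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .volumes import (BinaryMask, ImageVolume, binarize_probability,
                      check_same_grid, mask_and)

__all__ = ["TissueStats", "tissue_segment_gmm", "cerebral_wm_mask", "tissue_stats"]

#: voxels used to fit the mixture are capped at this count for speed;
#: posteriors are still evaluated at every in-brain voxel
_GMM_FIT_CAP = 100_000


@dataclass
class TissueStats:
    """Fused-image intensity mean/SD over gray and white matter."""

    gm_mean: float
    gm_sd: float
    wm_mean: float
    wm_sd: float

    def __post_init__(self) -> None:
        if self.gm_sd < 0 or self.wm_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.wm_mean <= self.gm_mean:
            warnings.warn(
                "white-matter mean does not exceed gray-matter mean; "
                "is the fused image T1w-dominant?", RuntimeWarning)


def tissue_segment_gmm(fused: ImageVolume, brain: BinaryMask,
                       n_classes: int = 3, seed: int = 0
                       ) -> tuple[ImageVolume, ImageVolume]:
    """Gaussian-mixture tissue posteriors (gray, white) from the fused image.

    Fits ``n_classes`` 1-D Gaussians to in-brain intensities and assigns
    components to CSF/GM/WM by ascending mean; the two returned probability
    volumes are the GM and WM posteriors (zero / invalid outside the brain).
    Posteriors sum to 1 in-brain across all classes.

    Raises if the brain mask is empty or if the fitted mixture leaves a
    class with no voxels at maximum-posterior assignment.
    """
    check_same_grid(fused, brain)
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    inb = brain.data & fused.valid_mask
    x = fused.data[inb].reshape(-1, 1)
    if x.size == 0:
        raise ValueError("brain mask is empty")
    rng = np.random.default_rng(seed)
    fit_x = x if len(x) <= _GMM_FIT_CAP else x[rng.choice(len(x), _GMM_FIT_CAP, replace=False)]
    # tied (shared) variance: with per-class variances a tight WM fit can
    # hand bright WMH voxels to a broader neighboring class; a shared
    # variance lets the brightest class claim every bright voxel
    gmm = GaussianMixture(n_components=n_classes, covariance_type="tied",
                          n_init=3, random_state=seed, reg_covar=1e-4)
    gmm.fit(fit_x)
    order = np.argsort(gmm.means_.ravel())
    post = gmm.predict_proba(x)[:, order]  # columns: ascending mean
    occupancy = np.bincount(post.argmax(axis=1), minlength=n_classes)
    if (occupancy == 0).any():
        raise RuntimeError(
            f"degenerate mixture fit: class occupancy {occupancy.tolist()}")

    def as_volume(col: int) -> ImageVolume:
        data = np.zeros(fused.shape)
        data[inb] = post[:, col]
        return ImageVolume(data, fused.affine.copy(), modality="probability",
                           valid=inb.copy())

    # brightest class is WM, next-brightest GM (T1w-dominant fusion)
    return as_volume(n_classes - 2), as_volume(n_classes - 1)


def cerebral_wm_mask(wm_prob: ImageVolume, exclusion: BinaryMask) -> BinaryMask:
    """White-matter search region: (WM probability > 0.5) AND exclusion mask.

    ``exclusion`` is the subject-space ex-brainstem-cerebellum-corpus-
    callosum mask (1 where segmentation is allowed).
    """
    return mask_and(binarize_probability(wm_prob, 0.5), exclusion)


def tissue_stats(fused: ImageVolume, gm_prob: ImageVolume,
                 wm_prob: ImageVolume) -> TissueStats:
    """Mean/SD of fused intensities over GM and WM (probability > 0.5).

    Sample (n-1) standard deviations.  Raises when a tissue has no
    qualifying voxels.
    """
    check_same_grid(fused, gm_prob)
    check_same_grid(fused, wm_prob)
    out = []
    for name, prob in (("gray matter", gm_prob), ("white matter", wm_prob)):
        sel = (prob.data > 0.5) & prob.valid_mask & fused.valid_mask
        vals = fused.data[sel]
        if vals.size == 0:
            raise ValueError(f"no voxels with {name} probability > 0.5")
        out.append((float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0))
    (gm_mean, gm_sd), (wm_mean, wm_sd) = out
    return TissueStats(gm_mean, gm_sd, wm_mean, wm_sd)
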