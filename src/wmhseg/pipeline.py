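"""End-to-end per-hemisphere WMH segmentation.

Stage order: rigid-register T1w (and DWI, when given) to FLAIR -> fuse
harmonized T1w/FLAIR (k = 0.8) -> tissue probability maps (supplied or
GMM stand-in) -> cerebral white-matter search mask (WM > 0.5 AND exclusion
mask) -> mask + normalize FLAIR to [0, 100] -> nominate candidates
(> 65) -> junction-map filtering -> DWI infarct detection (peak + 19) and
infarct subtraction with the 80% per-label rule.  The infarct stages are
skipped gracefully when no DWI is given (hemisphere with WMHs only).

After candidate nomination the stages only ever remove voxels, so
candidates ⊇ junction-filtered set ⊇ final WMH mask.  Every intermediate
mask is kept on the result (and written to disk when an output directory
is given) for audit, together with a run manifest embedding the resolved
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import delta_vol, overlap_metrics, volume_ml
from .fusion import FusionParams, fuse, harmonize, normalize_to_range
from .infarct import InfarctParams, brain_mask_fallback, infarct_segment, subtract_infarcts
from .registration import RigidTransform, resample, rigid_register
from .tissue import cerebral_wm_mask, tissue_segment_gmm, tissue_stats
from .volumes import (BinaryMask, ImageVolume, apply_mask, check_same_grid,
                      write_mask, write_volume)
from .wmh import (DetectionParams, WMHCandidateSet, junction_connected_filter,
                  junction_map, nominate_candidates)

__all__ = ["PipelineConfig", "SegmentationResult", "run_pipeline"]

log = logging.getLogger("wmhseg")


@dataclass
class PipelineConfig:
    """Resolved parameters of a segmentation run (all paper-adjustable)."""

    fusion_k: float = 0.8
    wmh_threshold: float = 65.0
    junction_fraction: float = 0.8
    junction_band_coefficient: float = 0.5
    junction_neighborhood: str = "8-2d"
    candidate_connectivity: int = 26
    peak_offset: float = 19.0
    label_overlap_fraction: float = 0.8
    histogram_bins: int = 101
    normalization_mode: str = "minmax"
    register: bool = True
    registration_bins: int = 32
    gmm_classes: int = 3
    gmm_seed: int = 0

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            wmh_threshold=self.wmh_threshold,
            junction_fraction=self.junction_fraction,
            junction_band_coefficient=self.junction_band_coefficient,
            neighborhood=self.junction_neighborhood,
            candidate_connectivity=self.candidate_connectivity,
        )

    def infarct_params(self) -> InfarctParams:
        return InfarctParams(
            peak_offset=self.peak_offset,
            label_overlap_fraction=self.label_overlap_fraction,
            histogram_bins=self.histogram_bins,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SegmentationResult:
    """Final masks, audit intermediates and volumes of one hemisphere run."""

    wmh_mask: BinaryMask
    infarct_mask: BinaryMask
    removed_mask: BinaryMask
    candidates: WMHCandidateSet
    post_junction: WMHCandidateSet
    junction: BinaryMask
    wm_mask: BinaryMask
    brain_mask: BinaryMask
    fused: ImageVolume
    norm_flair: ImageVolume
    tissue_stats: object
    transforms: dict[str, RigidTransform] = field(default_factory=dict)
    volumes_ml: dict[str, float] = field(default_factory=dict)
    evaluation: dict | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)


def _maybe_register(moving: ImageVolume, fixed: ImageVolume, cfg: PipelineConfig,
                    name: str, transforms: dict) -> ImageVolume:
    if cfg.register:
        log.info("registering %s to FLAIR", name)
        t = rigid_register(moving, fixed, bins=cfg.registration_bins)
        transforms[name] = t
        return resample(moving, t, fixed, "linear")
    check_same_grid(moving, fixed)
    transforms[name] = RigidTransform()
    return moving


def run_pipeline(t1: ImageVolume, flair: ImageVolume, dwi: ImageVolume | None = None,
                 *, gm_prob: ImageVolume | None = None,
                 wm_prob: ImageVolume | None = None,
                 exclusion_mask: BinaryMask | None = None,
                 brain_mask: BinaryMask | None = None,
                 reference_wmh: BinaryMask | None = None,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> SegmentationResult:
    """Run the full segmentation for one hemisphere.

    Tissue probability maps and the exclusion/brain masks are consumed as
    subject-space inputs when supplied; otherwise the built-in stand-ins
    run (GMM tissue classifier, Otsu brain mask, full-volume exclusion)
    with a prominent log notice.  When ``reference_wmh`` is given the
    result carries per-hemisphere agreement metrics against it.
    """
    cfg = config or PipelineConfig()
    transforms: dict[str, RigidTransform] = {}
    stage = "registration"
    try:
        t1r = _maybe_register(t1, flair, cfg, "T1w", transforms)

        stage = "brain mask"
        if brain_mask is None:
            log.warning("no brain mask supplied; using Otsu fallback on FLAIR")
            brain_mask = brain_mask_fallback(flair)
        check_same_grid(brain_mask, flair)

        stage = "fusion"
        fused = fuse(harmonize(t1r, brain_mask), harmonize(flair, brain_mask),
                     FusionParams(k=cfg.fusion_k))

        stage = "tissue maps"
        if gm_prob is None or wm_prob is None:
            log.warning("no tissue probability maps supplied; "
                        "running built-in GMM tissue classifier")
            gm_prob, wm_prob = tissue_segment_gmm(fused, brain_mask,
                                                  n_classes=cfg.gmm_classes,
                                                  seed=cfg.gmm_seed)
        stage = "white-matter mask"
        if exclusion_mask is None:
            log.warning("no exclusion mask supplied; searching the whole volume")
            exclusion_mask = BinaryMask.full(flair)
        wm_mask = cerebral_wm_mask(wm_prob, exclusion_mask)

        stage = "normalization"
        norm_flair = normalize_to_range(apply_mask(flair, wm_mask), wm_mask,
                                        mode=cfg.normalization_mode)

        stage = "candidate nomination"
        det = cfg.detection_params()
        candidates = nominate_candidates(norm_flair, wm_mask, det)

        stage = "junction filtering"
        stats = tissue_stats(fused, gm_prob, wm_prob)
        junction = junction_map(fused, stats, cfg.junction_band_coefficient)
        post_junction = junction_connected_filter(candidates, junction, det)

        stage = "infarct detection"
        if dwi is not None:
            dwir = _maybe_register(dwi, flair, cfg, "DWI", transforms)
            dwi_norm = normalize_to_range(apply_mask(dwir, brain_mask), brain_mask,
                                          mode=cfg.normalization_mode)
            infarcts = infarct_segment(dwi_norm, brain_mask, cfg.infarct_params(),
                                       connectivity=cfg.candidate_connectivity)
            final, removed = subtract_infarcts(post_junction, infarcts,
                                               cfg.infarct_params())
            infarct_mask = infarcts.mask()
        else:
            final = post_junction.mask()
            removed = BinaryMask.empty(flair)
            infarct_mask = BinaryMask.empty(flair)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    volumes = {
        "wmh_ml": volume_ml(final),
        "infarct_ml": volume_ml(infarct_mask),
        "candidate_ml": volume_ml(candidates.mask()),
        "removed_by_infarct_ml": volume_ml(removed),
    }
    evaluation = None
    if reference_wmh is not None:
        si, sens, spec = overlap_metrics(final, reference_wmh, brain_mask)
        semi = volume_ml(reference_wmh)
        evaluation = {
            "si_pct": si, "sen_pct": sens, "spe_pct": spec,
            "semi_auto_ml": semi, "auto_ml": volumes["wmh_ml"],
            "delta_vol_pct": delta_vol(semi, volumes["wmh_ml"]) if semi > 0 else None,
        }

    result = SegmentationResult(
        wmh_mask=final, infarct_mask=infarct_mask, removed_mask=removed,
        candidates=candidates, post_junction=post_junction, junction=junction,
        wm_mask=wm_mask, brain_mask=brain_mask, fused=fused,
        norm_flair=norm_flair, tissue_stats=stats, transforms=transforms,
        volumes_ml=volumes, evaluation=evaluation, config=cfg,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: SegmentationResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mask(result.wmh_mask, out_dir / "wmh_final.nii.gz")
    write_mask(result.infarct_mask, out_dir / "infarct.nii.gz")
    write_mask(result.removed_mask, out_dir / "removed_by_infarct.nii.gz")
    write_mask(result.candidates.mask(), out_dir / "wmh_candidates.nii.gz")
    write_mask(result.post_junction.mask(), out_dir / "wmh_post_junction.nii.gz")
    write_mask(result.junction, out_dir / "junction_map.nii.gz")
    write_mask(result.wm_mask, out_dir / "cerebral_wm_mask.nii.gz")
    write_mask(result.brain_mask, out_dir / "brain_mask.nii.gz")
    write_volume(result.fused, out_dir / "fused.nii.gz")
    write_volume(result.norm_flair, out_dir / "flair_normalized.nii.gz")
    manifest = {
        "software": {"name": "wmhseg", "version": __version__},
        "config": result.config.to_dict(),
        "volumes_ml": result.volumes_ml,
        "transforms": {k: t.to_dict() for k, t in result.transforms.items()},
        "evaluation": result.evaluation,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
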