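"""Deterministic multimodal digital phantoms with ground truth.

The generator builds co-registered T1w / FLAIR / DWI volumes of an
ellipsoidal "brain" with a cortical gray-matter shell, deep white matter,
CSF-filled ventricles, a cerebellum-like inferior lobe and a midline
corpus-callosum block (both excluded from the WMH search region by the
ground-truth exclusion mask).  Optional features:

* WMH lesions — ellipsoids in deep white matter, FLAIR-hyperintense and
  mildly T1-hypointense;
* acute infarcts — a DWI-bright core surrounded by a peri-infarct edema
  ring whose DWI intensity sits *between* background and core while its
  FLAIR intensity stays hyperintense, reproducing the structure that makes
  naive infarct subtraction leave a spurious WMH crescent;
* gray/white junction blur — an in-plane Gaussian kernel applied to all
  modalities, creating the intermediate-intensity band the junction filter
  targets;
* known rigid misalignment of T1w and/or DWI, returned as ground-truth
  transforms for registration testing.

Everything is deterministic given the seed.  The per-hemisphere cohort
tables that accompany the method (printed per-hemisphere volumes and
agreement metrics for a derivation and a validation cohort) are packaged
as TSVs and exposed through :func:`fixture_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .evaluation import HemisphereRecord
from .registration import RigidTransform, resample
from .volumes import BinaryMask, ImageVolume

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "fixture_tables",
           "load_cohort_table"]

#: per-tissue mean intensities, arbitrary scanner-like units
DEFAULT_INTENSITIES = {
    "T1w":   {"csf": 30, "gm": 60, "wm": 100, "wmh": 95, "infarct": 96, "edema": 94},
    "FLAIR": {"csf": 10, "gm": 55, "wm": 40, "wmh": 80, "infarct": 82, "edema": 76},
    "DWI":   {"csf": 5, "gm": 41, "wm": 44, "wmh": 45, "infarct": 85, "edema": 50},
}


@dataclass
class Lesion:
    """Ellipsoidal lesion: center offset from brain center (mm) + radii (mm)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]


@dataclass
class Infarct(Lesion):
    """Infarct core with an in-plane peri-infarct edema ring (width in mm)."""

    edema_width: float = 0.9


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of a synthetic multimodal phantom.

    Defaults reflect the emulated acquisition: 128x128 in-plane matrix at
    0.9 mm pitch and 24 slices at 6 mm pitch (5 mm thickness + 1 mm gap).
    ``junction_blur_vox`` is the in-plane Gaussian sigma (voxels) applied
    to every modality; ``noise_sd`` is additive Gaussian noise in
    intensity units.  ``misalign`` maps modality name ("T1w"/"DWI") to a
    (rotation_deg_z, tx_mm, ty_mm, tz_mm) misalignment injected into that
    modality and returned as ground truth.
    """

    shape: tuple[int, int, int] = (128, 128, 24)
    spacing: tuple[float, float, float] = (0.9, 0.9, 6.0)
    brain_radii: tuple[float, float, float] = (48.0, 54.0, 58.0)
    gm_thickness: float = 4.0
    ventricle_radii: tuple[float, float, float] = (8.0, 14.0, 12.0)
    ventricle_offset: float = 11.0
    cerebellum_center: tuple[float, float, float] = (0.0, 38.0, -46.0)
    cerebellum_radii: tuple[float, float, float] = (28.0, 20.0, 16.0)
    callosum_halfwidth: float = 3.0
    wmh_lesions: list[Lesion] = field(default_factory=lambda: [
        Lesion(center=(-26.0, -14.0, 6.0), radii=(7.0, 7.0, 7.0)),
        Lesion(center=(24.0, 18.0, 0.0), radii=(6.0, 8.0, 7.0)),
    ])
    infarcts: list[Infarct] = field(default_factory=list)
    intensities: dict = field(default_factory=lambda: {
        m: dict(v) for m, v in DEFAULT_INTENSITIES.items()})
    noise_sd: float = 2.0
    noise_model: str = "gaussian"       # or "rician"
    junction_blur_vox: float = 0.8
    misalign: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def wmh_only(cls, **kw) -> "PhantomSpec":
        return cls(**kw)

    @classmethod
    def with_infarct(cls, **kw) -> "PhantomSpec":
        spec = cls(**kw)
        if not spec.infarcts:
            spec.infarcts = [Infarct(center=(18.0, -26.0, 0.0),
                                     radii=(13.5, 13.5, 8.0),
                                     edema_width=0.9)]
        return spec


@dataclass
class Phantom:
    """Generated volumes, ground-truth masks and injected transforms."""

    t1w: ImageVolume
    flair: ImageVolume
    dwi: ImageVolume
    truth: dict[str, BinaryMask]
    transforms: dict[str, RigidTransform]
    spec: PhantomSpec


def _affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.diag(list(spec.spacing) + [1.0])
    # center the world origin in the volume
    aff[:3, 3] = -(np.asarray(spec.shape) - 1) / 2.0 * np.asarray(spec.spacing)
    return aff


def _world_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    aff = _affine(spec)
    axes = [aff[i, i] * np.arange(spec.shape[i]) + aff[i, 3] for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, radii) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the phantom described by ``spec`` (deterministic per seed).

    Raises ``ValueError`` when a WMH lesion or infarct (with its edema
    ring) extends outside deep white matter.
    """
    spec = spec or PhantomSpec()
    aff = _affine(spec)
    coords = _world_coords(spec)

    brain = _ellipsoid(coords, (0, 0, 0), spec.brain_radii)
    inner = _ellipsoid(coords, (0, 0, 0),
                       tuple(r - spec.gm_thickness for r in spec.brain_radii))
    vent = (_ellipsoid(coords, (-spec.ventricle_offset, 4.0, 2.0), spec.ventricle_radii)
            | _ellipsoid(coords, (spec.ventricle_offset, 4.0, 2.0), spec.ventricle_radii))
    cereb = _ellipsoid(coords, spec.cerebellum_center, spec.cerebellum_radii) & brain
    x, y, z = coords
    callosum = (np.abs(x) <= spec.callosum_halfwidth) & (np.abs(y) <= 26.0) \
        & (z >= 0.0) & (z <= 12.0) & inner
    gm = brain & ~inner & ~cereb
    wm_parenchyma = inner & ~vent & ~cereb
    csf = vent & brain

    wmh = np.zeros(spec.shape, dtype=bool)
    for les in spec.wmh_lesions:
        m = _ellipsoid(coords, les.center, les.radii)
        if not m.any() or (m & ~wm_parenchyma).any():
            raise ValueError(f"WMH lesion at {les.center} extends outside white matter")
        wmh |= m
    core = np.zeros(spec.shape, dtype=bool)
    edema = np.zeros(spec.shape, dtype=bool)
    for inf in spec.infarcts:
        c = _ellipsoid(coords, inf.center, inf.radii)
        rx, ry, rz = inf.radii
        outer = _ellipsoid(coords, inf.center,
                           (rx + inf.edema_width, ry + inf.edema_width, rz))
        ring = outer & ~c
        if not c.any() or (outer & ~wm_parenchyma).any():
            raise ValueError(f"infarct at {inf.center} extends outside white matter")
        core |= c
        edema |= ring
    edema &= ~core
    wmh &= ~(core | edema)

    # tissue painting order: later entries overwrite earlier ones
    regions = [("gm", gm), ("wm", wm_parenchyma), ("csf", csf),
               ("wm", cereb), ("wmh", wmh), ("edema", edema), ("infarct", core)]

    volumes = {}
    rng = np.random.default_rng(spec.seed)
    sigma = (spec.junction_blur_vox, spec.junction_blur_vox, 0.0)
    for modality in ("T1w", "FLAIR", "DWI"):
        levels = spec.intensities[modality]
        img = np.zeros(spec.shape, dtype=np.float64)
        for name, mask in regions:
            img[mask] = levels[name]
        if spec.junction_blur_vox > 0:
            img = ndimage.gaussian_filter(img, sigma=sigma)
        if spec.noise_sd > 0:
            noise = rng.normal(0.0, spec.noise_sd, size=spec.shape)
            if spec.noise_model == "rician":
                q = rng.normal(0.0, spec.noise_sd, size=spec.shape)
                img = np.sqrt((img + noise) ** 2 + q ** 2)
            else:
                img = img + noise
        volumes[modality] = ImageVolume(img, aff.copy(), modality=modality)

    transforms: dict[str, RigidTransform] = {}
    center = np.zeros(3)  # world origin is the volume center
    for modality, (rot_deg, tx, ty, tz) in spec.misalign.items():
        t = RigidTransform(rotation=np.array([0.0, 0.0, np.deg2rad(rot_deg)]),
                           translation=np.array([tx, ty, tz]), center=center)
        moved = resample(volumes[modality], t.inverse(), volumes[modality], "linear")
        # fill out-of-view voxels with background so the volume stays dense
        data = np.where(moved.valid_mask, moved.data, 0.0)
        volumes[modality] = ImageVolume(data, aff.copy(), modality=modality)
        transforms[modality] = t

    truth = {name: BinaryMask(arr.copy(), aff.copy()) for name, arr in [
        ("brain", brain),
        ("gm", gm),
        ("wm", wm_parenchyma | wmh | core | edema),
        ("exclusion", brain & ~cereb & ~callosum),
        ("wmh", wmh),
        ("infarct", core),
        ("edema", edema),
    ]}
    return Phantom(volumes["T1w"], volumes["FLAIR"], volumes["DWI"],
                   truth, transforms, spec)


def load_cohort_table(which: str) -> pd.DataFrame:
    """Load a packaged cohort table ('derivation' or 'validation')."""
    if which not in ("derivation", "validation"):
        raise ValueError("which must be 'derivation' or 'validation'")
    ref = resources.files("wmhseg.data").joinpath(f"{which}_cohort.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"patient": str})


def fixture_tables() -> tuple[list[HemisphereRecord], list[HemisphereRecord]]:
    """Packaged per-hemisphere cohort records (derivation, validation)."""
    out = []
    for which in ("derivation", "validation"):
        df = load_cohort_table(which)
        recs = [HemisphereRecord(
            patient=row.patient, side=row.side, group=row.group,
            semi_auto_ml=row.semi_auto_ml, auto_ml=row.auto_ml,
            si_pct=row.si_pct, sen_pct=row.sen_pct, spe_pct=row.spe_pct,
            delta_vol_pct=row.delta_vol_pct,
            demar=getattr(row, "demar", None),
        ) for row in df.itertuples()]
        out.append(recs)
    return out[0], out[1]
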