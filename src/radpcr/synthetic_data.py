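"""Fully synthetic phantom cohort: lesion volumes, masks and covariates.

Each subject gets one (or, when bilateral, two) phantom subtraction-MRI
volumes: a low-amplitude noise background plus an ellipsoidal lesion filled
with a class-parameterized texture.  The texture has three class-tunable
ingredients — a radial intensity profile (flat vs centre-weighted), a rim
ridge near the lesion boundary, and a stationary Gaussian random field whose
correlation length differs between classes — so planted signal survives the
per-patch min-max normalization applied downstream.  Covariates follow the
configured per-class prevalences (TNBC, bilateral cancer), truncated-normal
age, and Poisson relative counts.

Everything is deterministic given the config's ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._seeds import derive_rng
from .errors import RadpcrError
from .imaging_io import LesionMask, VolumeImage, write_mask, write_volume

__all__ = [
    "TextureParams",
    "CovariateParams",
    "SyntheticCohortConfig",
    "SyntheticSubject",
    "generate_lesion_volume",
    "generate_lesion_volume_with_geometry",
    "generate_covariates",
    "generate_cohort_arrays",
    "generate_cohort",
]


@dataclass
class TextureParams:
    """Per-class lesion appearance parameters (mm units where physical)."""

    contrast: float = 1.0  # mean lesion intensity above background
    texture_sd: float = 0.3  # GRF amplitude
    corr_length_mm: float = 1.5  # GRF correlation length
    noise_sd: float = 0.05  # voxel-wise white noise inside the lesion
    rim_amplitude: float = 0.0  # ridge height near the boundary
    rim_width_mm: float = 2.0
    center_gradient: float = 0.0  # 0 = flat profile; >0 = centre-weighted


@dataclass
class CovariateParams:
    """Per-class covariate distributions."""

    tnbc_prevalence: float = 0.14
    bbc_prevalence: float = 0.172
    age_mean: float = 38.0
    age_sd: float = 11.0
    mbc_prevalence: float = 0.02
    # Poisson rates for relative counts
    fdr_bc: float = 0.5
    fdr_oc: float = 0.1
    sdr_bc: float = 0.5
    sdr_oc: float = 0.05
    tdr_bc: float = 0.4
    tdr_oc: float = 0.05


def _default_carrier_texture() -> TextureParams:
    return TextureParams(
        contrast=1.0,
        texture_sd=0.3,
        corr_length_mm=2.5,
        noise_sd=0.05,
        rim_amplitude=0.8,
        rim_width_mm=2.0,
        center_gradient=0.0,
    )


def _default_control_texture() -> TextureParams:
    return TextureParams(
        contrast=1.0,
        texture_sd=0.3,
        corr_length_mm=1.0,
        noise_sd=0.05,
        rim_amplitude=0.0,
        rim_width_mm=2.0,
        center_gradient=1.5,
    )


def _default_carrier_covariates() -> CovariateParams:
    return CovariateParams(
        tnbc_prevalence=0.80,
        bbc_prevalence=0.441,
        age_mean=36.8,
        age_sd=7.0,
        mbc_prevalence=0.05,
        fdr_bc=1.0,
        fdr_oc=0.3,
        sdr_bc=0.8,
        sdr_oc=0.2,
        tdr_bc=0.5,
        tdr_oc=0.1,
    )


@dataclass
class SyntheticCohortConfig:
    """Cohort-level generation settings; defaults emulate the study cohort."""

    n_carriers: int = 16
    n_controls: int = 25
    volume_shape: tuple[int, int, int] = (16, 128, 128)  # (slice, row, column)
    spacing: tuple[float, float, float] = (3.7, 0.75, 0.75)
    semi_axes_mm: tuple[float, float] = (6.0, 12.0)  # in-plane range
    semi_axis_z_mm: tuple[float, float] = (3.7, 7.4)
    background_sd: float = 0.02
    boundary_margin_voxels: int = 33  # keeps default 65x65 windows inside
    bilateral_second_volume: bool = True
    carrier_texture: TextureParams = field(default_factory=_default_carrier_texture)
    control_texture: TextureParams = field(default_factory=_default_control_texture)
    carrier_covariates: CovariateParams = field(default_factory=_default_carrier_covariates)
    control_covariates: CovariateParams = field(default_factory=CovariateParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_carriers < 1 or self.n_controls < 1:
            raise ValueError("need >= 1 subject per class")
        for name, pair in (
            ("carrier_covariates", self.carrier_covariates),
            ("control_covariates", self.control_covariates),
        ):
            for f in ("tnbc_prevalence", "bbc_prevalence", "mbc_prevalence"):
                v = getattr(pair, f)
                if not (0 <= v <= 1):
                    raise ValueError(f"{name}.{f} must be in [0, 1], got {v}")
        for tex in (self.carrier_texture, self.control_texture):
            if tex.corr_length_mm <= 0:
                raise ValueError("correlation lengths must be > 0")

    def texture(self, label: int) -> TextureParams:
        return self.carrier_texture if label == 1 else self.control_texture

    def covariates(self, label: int) -> CovariateParams:
        return self.carrier_covariates if label == 1 else self.control_covariates

    def null_effect(self) -> "SyntheticCohortConfig":
        """Copy with all class differences removed (texture and covariates)."""
        cfg = dataclasses.replace(
            self,
            carrier_texture=dataclasses.replace(self.control_texture),
            carrier_covariates=dataclasses.replace(self.control_covariates),
        )
        return cfg


def reduced_scale_config(seed: int = 0, null: bool = False) -> SyntheticCohortConfig:
    """Desk-scale cohort preset: full 16+25 subjects but smaller volumes,
    suitable for 33x33 patches at ~100 samples/image on one CPU.

    ``null=True`` removes every class difference (texture and covariates)."""
    cfg = SyntheticCohortConfig(
        volume_shape=(12, 96, 96),
        boundary_margin_voxels=17,
        semi_axes_mm=(6.0, 10.0),
        bilateral_second_volume=False,
        rng_seed=seed,
    )
    return cfg.null_effect() if null else cfg


@dataclass
class SyntheticSubject:
    subject_id: str
    label: int
    record: dict
    volume_paths: list[str] = field(default_factory=list)
    mask_paths: list[str] = field(default_factory=list)
    texture: TextureParams | None = None


def generate_lesion_volume(
    label: int, cfg: SyntheticCohortConfig, rng_seed: int
) -> tuple[VolumeImage, LesionMask]:
    """One phantom volume with an ellipsoidal textured lesion and exact mask."""
    vol, mask, _ = generate_lesion_volume_with_geometry(label, cfg, rng_seed)
    return vol, mask


def generate_lesion_volume_with_geometry(
    label: int, cfg: SyntheticCohortConfig, rng_seed: int
) -> tuple[VolumeImage, LesionMask, dict]:
    """As :func:`generate_lesion_volume`, also returning the ellipsoid geometry
    (center voxel coordinates and per-axis semi-axes in voxel units)."""
    rng = np.random.default_rng(rng_seed)
    tex = cfg.texture(label)
    shape = cfg.volume_shape
    spacing = np.asarray(cfg.spacing, dtype=float)

    # semi-axes in mm -> voxel units per axis
    a_z = rng.uniform(*cfg.semi_axis_z_mm)
    a_r = rng.uniform(*cfg.semi_axes_mm)
    a_c = rng.uniform(*cfg.semi_axes_mm)
    semi_vox = np.array([a_z, a_r, a_c]) / spacing

    margin = np.array([0.0, cfg.boundary_margin_voxels, cfg.boundary_margin_voxels])
    lo = np.ceil(semi_vox + margin) + 1
    hi = np.array(shape) - lo - 1
    if np.any(hi < lo):
        raise RadpcrError(
            f"lesion (semi-axes {semi_vox} vox + margin {margin}) does not fit "
            f"inside volume of shape {shape}"
        )
    center = np.array([rng.uniform(l, h) for l, h in zip(lo, hi)])

    zz, rr, cc = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    # normalized ellipsoid radius: <= 1 inside the lesion
    r2 = (
        ((zz - center[0]) / semi_vox[0]) ** 2
        + ((rr - center[1]) / semi_vox[1]) ** 2
        + ((cc - center[2]) / semi_vox[2]) ** 2
    )
    inside = r2 <= 1.0
    if not inside.any():
        raise RadpcrError("degenerate lesion: no voxels inside the ellipsoid")
    r = np.sqrt(np.clip(r2, 0.0, None))

    voxels = rng.normal(0.0, cfg.background_sd, size=shape)

    # radial profile: flat (gradient 0) or centre-weighted
    profile = np.where(inside, (1.0 - np.clip(r, 0, 1) ** 2) ** (tex.center_gradient / 2.0), 0.0)
    # rim ridge near the boundary, width in mm via the mean in-plane semi-axis
    mean_semi_mm = 0.5 * (a_r + a_c)
    if tex.rim_amplitude != 0.0:
        dist_mm = (1.0 - np.clip(r, 0, 1)) * mean_semi_mm
        rim = tex.rim_amplitude * np.exp(-((dist_mm / tex.rim_width_mm) ** 2))
    else:
        rim = 0.0

    # stationary GRF: smoothed white noise, unit-variance, scaled
    if tex.texture_sd > 0:
        white = rng.normal(size=shape)
        sigma_vox = tex.corr_length_mm / spacing
        grf = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
        sd = grf.std()
        grf = grf / sd if sd > 0 else grf
    else:
        grf = 0.0

    lesion = tex.contrast * (profile + rim) + tex.texture_sd * grf
    if tex.noise_sd > 0:
        lesion = lesion + rng.normal(0.0, tex.noise_sd, size=shape)
    voxels = np.where(inside, lesion, voxels)

    vol = VolumeImage(voxels.astype(np.float64), tuple(cfg.spacing))
    mask = LesionMask(inside.astype(np.uint8), tuple(cfg.spacing))
    geometry = {"center": center.tolist(), "semi_axes_vox": semi_vox.tolist()}
    return vol, mask, geometry


def generate_covariates(label: int, cfg: SyntheticCohortConfig, rng_seed: int) -> dict:
    """Draw one subject's covariate record for the given class."""
    rng = np.random.default_rng(rng_seed)
    cov = cfg.covariates(label)
    age = float(np.clip(rng.normal(cov.age_mean, cov.age_sd), 18.0, 90.0))
    return {
        "Age": round(age, 1),
        "BBC": int(rng.random() < cov.bbc_prevalence),
        "FDR.BC": int(rng.poisson(cov.fdr_bc)),
        "FDR.OC": int(rng.poisson(cov.fdr_oc)),
        "SDR.BC": int(rng.poisson(cov.sdr_bc)),
        "SDR.OC": int(rng.poisson(cov.sdr_oc)),
        "TDR.BC": int(rng.poisson(cov.tdr_bc)),
        "TDR.OC": int(rng.poisson(cov.tdr_oc)),
        "MBC": int(rng.random() < cov.mbc_prevalence),
        "TNBC": int(rng.random() < cov.tnbc_prevalence),
        "label": int(label),
    }


def generate_cohort_arrays(
    cfg: SyntheticCohortConfig,
) -> list[tuple[SyntheticSubject, list[tuple[str, VolumeImage, LesionMask]]]]:
    """In-memory cohort: (subject, [(image_id, volume, mask), ...]) pairs."""
    out = []
    specs = [(1, i) for i in range(cfg.n_carriers)] + [
        (0, i) for i in range(cfg.n_controls)
    ]
    for label, i in specs:
        sid = f"{'carrier' if label else 'control'}_{i:03d}"
        record = generate_covariates(
            label, cfg, derive_rng(cfg.rng_seed, "cov", sid).integers(2**31)
        )
        n_vols = 2 if (cfg.bilateral_second_volume and record["BBC"] == 1) else 1
        images = []
        for v in range(n_vols):
            image_id = f"{sid}_img{v}"
            seed = derive_rng(cfg.rng_seed, "vol", image_id).integers(2**31)
            vol, mask = generate_lesion_volume(label, cfg, int(seed))
            images.append((image_id, vol, mask))
        subj = SyntheticSubject(
            subject_id=sid, label=label, record=record, texture=cfg.texture(label)
        )
        out.append((subj, images))
    return out


def generate_cohort(cfg: SyntheticCohortConfig, out_dir: str) -> list[SyntheticSubject]:
    """Write a cohort to ``out_dir``: MetaImage volumes/masks, covariates.tsv,
    and a manifest.json carrying ground-truth labels and texture parameters."""
    os.makedirs(out_dir, exist_ok=True)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)

    subjects: list[SyntheticSubject] = []
    rows = []
    for subj, images in generate_cohort_arrays(cfg):
        for image_id, vol, mask in images:
            vpath = os.path.join(img_dir, f"{image_id}.mhd")
            mpath = os.path.join(img_dir, f"{image_id}_mask.mhd")
            write_volume(vol, vpath)
            write_mask(mask, mpath)
            subj.volume_paths.append(vpath)
            subj.mask_paths.append(mpath)
        rows.append({"subject_id": subj.subject_id, **subj.record})
        subjects.append(subj)

    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(out_dir, "covariates.tsv"), sep="\t", index=False)

    manifest = {
        "config": _cfg_to_dict(cfg),
        "subjects": [
            {
                "subject_id": s.subject_id,
                "label": s.label,
                "volumes": [os.path.relpath(p, out_dir) for p in s.volume_paths],
                "masks": [os.path.relpath(p, out_dir) for p in s.mask_paths],
                "texture": dataclasses.asdict(s.texture) if s.texture else None,
            }
            for s in subjects
        ],
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return subjects


def _cfg_to_dict(cfg: SyntheticCohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("volume_shape", "spacing", "semi_axes_mm", "semi_axis_z_mm"):
        d[key] = list(d[key])
    return d
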