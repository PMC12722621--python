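"""Synthetic 3D head phantoms with separable disease signals.

Each phantom is a small T1-like head: an ellipsoidal brain with a gray-matter
rim and white-matter core, a dark central ventricle cavity, two lateralized
hippocampus-like inclusions, and a bright spherical skull shell. Three effect
channels distinguish the patient class from controls:

* ``atrophy_effect`` — shape: brain (and hippocampus) radii shrink by the
  given fraction while the ventricle cavity grows by it, mimicking the
  volumetric signature of neurodegeneration;
* ``texture_effect`` — texture: the gray-white intensity gap shrinks, leaving
  volumes unchanged;
* ``shortcut_effect`` — an explicit contour artifact: intensities in a
  one-voxel shell just inside the brain-mask boundary are amplified, a
  controllable stand-in for the sharp edge that skull-stripping introduces.

All geometry is evaluated on a continuous coordinate grid with sigmoidal
edges so sub-voxel radius changes are expressed even on coarse grids, and a
small random rigid jitter per image prevents the downstream classifier from
keying on a fixed template.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "SubjectRecord",
    "HeadVolume",
    "BrainMask",
    "PhantomImage",
    "PhantomCohort",
    "make_head_phantom",
    "inject_contour_shortcut",
    "generate_cohort",
    "load_cohort",
    "STRUCTURE_LABELS",
]

# integer codes of the structure-label field returned alongside each phantom
STRUCTURE_LABELS = {
    "background": 0,
    "white_matter": 1,
    "gray_matter": 2,
    "ventricle": 3,
    "hippocampus": 4,
    "skull": 5,
}

# tissue intensity modes before noise (control class, white matter = 1)
_WM_INTENSITY = 1.0
_GM_INTENSITY = 0.7
_VENTRICLE_INTENSITY = 0.15
_SKULL_INTENSITY = 1.3

# base geometry as fractions of the grid half-width
_BRAIN_SEMIAXES = (0.66, 0.61, 0.57)
_VENTRICLE_SEMIAXES = (0.20, 0.24, 0.16)
_HIPPO_RADIUS = 0.10
_HIPPO_OFFSET = (0.28, -0.16, -0.20)  # mirrored in x for the second one
_SKULL_INNER = 0.68
_SKULL_OUTER = 0.80
_WM_CORE_FRACTION = 0.80  # white core radius as a fraction of brain radius
_EDGE_WIDTH = 0.035  # sigmoid edge width in grid-half-width units


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generator settings; with the seed it fully determines
    every volume, mask and subject record."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 1.0
    n_subjects_per_class: int = 50
    images_per_subject: int = 1
    atrophy_effect: float = 0.1
    texture_effect: float = 0.0
    shortcut_effect: float = 0.0
    noise_sd: float = 0.02
    n_sites: int = 2
    site_offset_sd: float = 0.01
    seed: int = 0
    age_mean: float = 74.0
    age_sd: float = 6.0
    age_offset: float = 2.0  # patient mean age minus control mean age

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3:
            raise ValueError("grid_shape must have three axes")
        for n in self.grid_shape:
            if n % 16 != 0:
                raise ValueError(
                    f"grid_shape {self.grid_shape} must be divisible by 16 "
                    "per axis (four stride-2 halvings)"
                )
        for name in ("atrophy_effect", "texture_effect", "shortcut_effect",
                     "noise_sd", "site_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects_per_class < 1 or self.images_per_subject < 1:
            raise ValueError("subject and image counts must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    class_label: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    site_id: str

    def __post_init__(self) -> None:
        if self.class_label not in ("patient", "control"):
            raise ValueError(f"bad class label {self.class_label!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"bad sex {self.sex!r}")


@dataclass
class HeadVolume:
    """A 3D non-negative scalar field with voxel spacing; the unit of all
    image processing."""

    intensities: np.ndarray
    voxel_size_mm: float = 1.0
    space_tag: str = "aligned"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be 3D")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def copy_with(self, intensities: np.ndarray) -> "HeadVolume":
        return HeadVolume(intensities, self.voxel_size_mm, self.space_tag)


@dataclass
class BrainMask:
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]


@dataclass
class PhantomImage:
    """One generated image with its provenance and structure labels."""

    image_id: str
    subject: SubjectRecord
    volume: HeadVolume
    mask: BrainMask
    labels: np.ndarray  # integer structure-label field, same grid


@dataclass
class PhantomCohort:
    config: PhantomConfig
    subjects: list[SubjectRecord]
    images: list[PhantomImage]

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": im.subject.subject_id,
                "image_id": im.image_id,
                "class": im.subject.class_label,
                "age": im.subject.age,
                "sex": im.subject.sex,
                "site": im.subject.site_id,
            }
            for im in self.images
        ]
        return pd.DataFrame(rows)


def _subject_rng(seed: int, subject_id: str, image_index: int) -> np.random.Generator:
    # stable across runs: hash the subject id with crc32, not Python hash()
    key = zlib.crc32(subject_id.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, image_index)))


def _rotation_matrix(rng: np.random.Generator, max_angle_rad: float) -> np.ndarray:
    angles = rng.uniform(-max_angle_rad, max_angle_rad, size=3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _soft_inside(rho: np.ndarray, width: float = _EDGE_WIDTH) -> np.ndarray:
    """Smooth indicator of rho <= 1 (rho = normalized ellipsoidal radius)."""
    return 1.0 / (1.0 + np.exp((rho - 1.0) / width))


def _ellipsoid_rho(coords: np.ndarray, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    d = (coords - center[:, None, None, None]) / semiaxes[:, None, None, None]
    return np.sqrt((d ** 2).sum(axis=0))


def make_head_phantom(
    config: PhantomConfig,
    subject: SubjectRecord,
    rng: np.random.Generator,
    image_index: int = 0,
    site_offset: float = 0.0,
) -> tuple[HeadVolume, BrainMask, np.ndarray]:
    """Render one head phantom for ``subject``.

    Returns the intensity volume, the brain mask (skull excluded) and an
    integer structure-label field (see :data:`STRUCTURE_LABELS`). The
    patient class gets the configured atrophy / texture / contour-shortcut
    effects; controls are drawn from the no-effect distribution.
    """
    shape = config.grid_shape
    half = min(shape) / 2.0
    is_patient = subject.class_label == "patient"

    # per-image rigid jitter + radius jitter, applied before class effects
    rot = _rotation_matrix(rng, np.deg2rad(4.0))
    shift = rng.uniform(-0.03, 0.03, size=3) * half
    radius_jitter = 1.0 + rng.uniform(-0.03, 0.03)

    atrophy = config.atrophy_effect if is_patient else 0.0
    texture = config.texture_effect if is_patient else 0.0
    shortcut = config.shortcut_effect if is_patient else 0.0

    brain_ax = np.array(_BRAIN_SEMIAXES) * half * radius_jitter * (1.0 - atrophy)
    vent_ax = np.array(_VENTRICLE_SEMIAXES) * half * radius_jitter * (1.0 + atrophy)
    hippo_r = _HIPPO_RADIUS * half * radius_jitter * (1.0 - atrophy)
    skull_inner = _SKULL_INNER * half * radius_jitter
    skull_outer = _SKULL_OUTER * half * radius_jitter

    margin = 1.0  # background voxels required on every face
    if skull_outer + np.abs(shift).max() >= half - margin:
        raise ValueError(
            f"grid {shape} too small to contain the skull shell "
            f"(outer radius {skull_outer:.1f} voxels)"
        )
    if np.any(vent_ax >= brain_ax * _WM_CORE_FRACTION):
        raise ValueError("ventricle does not fit inside the white-matter core")

    center = np.array([(n - 1) / 2.0 for n in shape]) + shift
    idx = np.indices(shape, dtype=np.float64)
    centered = idx - center[:, None, None, None]
    coords = np.einsum("ij,jxyz->ixyz", rot.T, centered) + center[:, None, None, None]

    gray = _GM_INTENSITY + (_WM_INTENSITY - _GM_INTENSITY) * texture

    rho_brain = _ellipsoid_rho(coords, center, brain_ax)
    rho_core = _ellipsoid_rho(coords, center, brain_ax * _WM_CORE_FRACTION)
    rho_vent = _ellipsoid_rho(coords, center, vent_ax)
    hippo_c1 = center + np.array(_HIPPO_OFFSET) * half
    hippo_c2 = center + np.array(_HIPPO_OFFSET) * np.array([-1.0, 1.0, 1.0]) * half
    rho_h1 = _ellipsoid_rho(coords, hippo_c1, np.full(3, hippo_r))
    rho_h2 = _ellipsoid_rho(coords, hippo_c2, np.full(3, hippo_r))
    r_sphere = np.sqrt((centered ** 2).sum(axis=0))

    w_brain = _soft_inside(rho_brain)
    w_core = _soft_inside(rho_core)
    w_vent = _soft_inside(rho_vent)
    w_hippo = np.maximum(_soft_inside(rho_h1), _soft_inside(rho_h2))
    # radial band indicator so mid-shell weight reaches ~1 even on coarse grids
    skull_mid = 0.5 * (skull_inner + skull_outer)
    skull_halfwidth = 0.5 * (skull_outer - skull_inner)
    w_skull = _soft_inside(np.abs(r_sphere - skull_mid) / skull_halfwidth, width=0.25)

    # paint compartments innermost-last by alpha compositing
    img = np.zeros(shape)
    img = img * (1 - w_skull) + _SKULL_INTENSITY * w_skull
    img = img * (1 - w_brain) + gray * w_brain
    img = img * (1 - w_core) + _WM_INTENSITY * w_core
    img = img * (1 - w_hippo) + gray * w_hippo
    img = img * (1 - w_vent) + _VENTRICLE_INTENSITY * w_vent

    mask = rho_brain <= 1.0
    labels = np.zeros(shape, dtype=np.int8)
    labels[w_skull > 0.5] = STRUCTURE_LABELS["skull"]
    labels[mask] = STRUCTURE_LABELS["gray_matter"]
    labels[mask & (rho_core <= 1.0)] = STRUCTURE_LABELS["white_matter"]
    labels[mask & ((rho_h1 <= 1.0) | (rho_h2 <= 1.0))] = STRUCTURE_LABELS["hippocampus"]
    labels[mask & (rho_vent <= 1.0)] = STRUCTURE_LABELS["ventricle"]

    # site offset shifts tissue (non-background) intensities only
    head = img > 0.02
    img = np.where(head, img + site_offset, img)
    img = img + rng.normal(0.0, config.noise_sd, size=shape)
    img = np.maximum(img, 0.0)

    volume = HeadVolume(img, config.voxel_size_mm, "aligned")
    brain_mask = BrainMask(mask)
    if shortcut > 0.0:
        volume = inject_contour_shortcut(volume, brain_mask, shortcut)
    return volume, brain_mask, labels


def inject_contour_shortcut(
    volume: HeadVolume, mask: BrainMask, amplitude: float
) -> HeadVolume:
    """Scale intensities in the one-voxel shell just inside the mask boundary
    by ``(1 + amplitude)``; all other voxels are unchanged."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    m = mask.mask
    if not m.any():
        raise ValueError("empty mask: no boundary shell to modify")
    shell = m & ~ndimage.binary_erosion(m)
    out = volume.intensities.copy()
    out[shell] *= 1.0 + amplitude
    return volume.copy_with(out)


def _draw_subjects(config: PhantomConfig) -> list[SubjectRecord]:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0xC0F0,)))
    subjects: list[SubjectRecord] = []
    for class_label, prefix in (("control", "C"), ("patient", "P")):
        mean_age = config.age_mean + (config.age_offset if class_label == "patient" else 0.0)
        for i in range(config.n_subjects_per_class):
            age = float(np.clip(rng.normal(mean_age, config.age_sd), 40.0, 100.0))
            sex = "M" if rng.random() < 0.5 else "F"
            site = f"site{rng.integers(config.n_sites)}"
            subjects.append(
                SubjectRecord(f"{prefix}{i:04d}", class_label, age, sex, site)
            )
    return subjects


def generate_cohort(config: PhantomConfig, out_dir: Optional[Path | str] = None) -> PhantomCohort:
    """Generate the full phantom cohort; identical config + seed gives a
    bit-identical cohort. If ``out_dir`` is given, volumes and masks are
    written as NIfTI and the cohort table as TSV."""
    subjects = _draw_subjects(config)
    site_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0x517E,)))
    site_offsets = {
        f"site{k}": float(site_rng.normal(0.0, config.site_offset_sd))
        for k in range(config.n_sites)
    }
    images: list[PhantomImage] = []
    for subject in subjects:
        for j in range(config.images_per_subject):
            rng = _subject_rng(config.seed, subject.subject_id, j)
            vol, mask, labels = make_head_phantom(
                config, subject, rng, j, site_offsets[subject.site_id]
            )
            images.append(
                PhantomImage(f"{subject.subject_id}_img{j}", subject, vol, mask, labels)
            )
    cohort = PhantomCohort(config, subjects, images)
    if out_dir is not None:
        save_cohort(cohort, Path(out_dir))
    return cohort


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return aff


def save_cohort(cohort: PhantomCohort, out_dir: Path) -> pd.DataFrame:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(cohort.config.voxel_size_mm)
    rows = []
    for im in cohort.images:
        vol_path = out_dir / f"{im.image_id}.nii.gz"
        mask_path = out_dir / f"{im.image_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(im.volume.intensities.astype(np.float32), aff), vol_path)
        nib.save(nib.Nifti1Image(im.mask.mask.astype(np.uint8), aff), mask_path)
        rows.append(
            {
                "subject_id": im.subject.subject_id,
                "image_id": im.image_id,
                "class": im.subject.class_label,
                "age": im.subject.age,
                "sex": im.subject.sex,
                "site": im.subject.site_id,
                "volume_path": vol_path.name,
                "mask_path": mask_path.name,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    return table


def load_cohort(cohort_dir: Path | str, config: Optional[PhantomConfig] = None) -> PhantomCohort:
    """Read a cohort written by :func:`save_cohort` (or any user-supplied
    directory with the same TSV layout). Structure labels are not stored on
    disk; loaded images carry an all-zero label field."""
    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "cohort.tsv", sep="\t")
    subjects: dict[str, SubjectRecord] = {}
    images: list[PhantomImage] = []
    for _, row in table.iterrows():
        sid = row["subject_id"]
        if sid not in subjects:
            subjects[sid] = SubjectRecord(
                sid, row["class"], float(row["age"]), row["sex"], row["site"]
            )
        vol_img = nib.load(cohort_dir / row["volume_path"])
        mask_img = nib.load(cohort_dir / row["mask_path"])
        voxel = float(vol_img.header.get_zooms()[0])
        vol = HeadVolume(np.asarray(vol_img.dataobj, dtype=np.float64), voxel, "aligned")
        mask = BrainMask(np.asarray(mask_img.dataobj) > 0)
        labels = np.zeros(vol.shape, dtype=np.int8)
        images.append(PhantomImage(row["image_id"], subjects[sid], vol, mask, labels))
    cfg = config or PhantomConfig(grid_shape=images[0].volume.shape)
    return PhantomCohort(cfg, list(subjects.values()), images)
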