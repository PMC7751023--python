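"""Grey-matter probability volumes as subject x voxel matrices.

This module turns per-subject volumetric grey-matter (GM) probability maps
into the matrix view the covariance analysis works on: one row per subject,
one column per in-mask voxel.  It also implements spherical-seed mean
extraction (the per-network regions of interest), longitudinal change maps
(chronic minus sub-acute), and the lesion/seed overlap check used to verify
that seed regions are not driven by infarcted tissue.

Conventions
-----------
* Voxel indices are 0-based; world coordinates are MNI millimetres; the two
  are related only through the volume affine.
* The analysis mask is defined on the group-mean GM image (mean GM >=
  threshold), so every subject shares one voxel set.  Per-subject
  thresholding (intersection of subject masks) is available as an option.
* In-mask voxels are ordered by C-order linear index of the 3D grid; this
  ordering is stable and round-trips through NIfTI.
* Sphere membership uses the Euclidean mm distance from the seed centre to
  the voxel centre, with a closed boundary (distance <= radius).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DataError,
    DegenerateMaskError,
    DimensionError,
    EmptySeedError,
)

NETWORKS = ("DAN", "ECN", "SN", "DMN", "LN", "MN")


@dataclasses.dataclass(frozen=True)
class SeedSpec:
    """A spherical seed region: a named point in MNI mm space plus a radius."""

    name: str
    network: str
    centre_mm: tuple[float, float, float]
    radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise DataError(f"seed {self.name!r}: radius must be positive")


@dataclasses.dataclass
class GMDataset:
    """Subjects x in-mask-voxels view of a set of GM probability volumes.

    ``data[i, j]`` is subject ``i``'s GM value at the j-th in-mask voxel
    (C-order over the grid).  ``timepoint`` is one of ``subacute``,
    ``chronic`` or ``change``; change maps may hold values in [-1, 1],
    probability maps in [0, 1].
    """

    subject_ids: list[str]
    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    timepoint: str = "subacute"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError("data must be 2D (subjects x voxels)")
        if self.data.shape[0] != len(self.subject_ids):
            raise DimensionError("row count does not match subject_ids")
        if self.data.shape[1] != int(self.mask.sum()):
            raise DimensionError("column count does not match mask voxel count")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise DimensionError("affine must be an invertible 4x4 matrix")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def voxel_coords_mm(self) -> np.ndarray:
        """mm coordinates of in-mask voxel centres, (n_voxels, 3)."""
        idx = np.argwhere(self.mask)  # argwhere follows C order
        homo = np.c_[idx, np.ones(len(idx))]
        return (homo @ self.affine.T)[:, :3]

    def unmask(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an in-mask vector back onto the 3D grid."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_voxels,):
            raise DimensionError("vector length does not match mask voxel count")
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = vector
        return vol

    def to_volumes(self) -> np.ndarray:
        """(n_subjects, *grid) array with zeros outside the mask."""
        out = np.zeros((self.n_subjects,) + self.mask.shape)
        out[:, self.mask] = self.data
        return out


@dataclasses.dataclass
class SeedMatrix:
    """Subjects x seeds table of mean GM (or mean dGM) values."""

    subject_ids: list[str]
    seed_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.seed_names)):
            raise DimensionError("seed matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise DataError("seed means contain non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.seed_names)


def build_gm_dataset(
    volumes: np.ndarray,
    affine: np.ndarray,
    subject_ids: Sequence[str] | None = None,
    mask_threshold: float = 0.45,
    per_subject_threshold: bool = False,
    timepoint: str = "subacute",
) -> GMDataset:
    """Mask and vectorize a (n_subjects, X, Y, Z) stack of GM volumes.

    The default mask keeps voxels whose group-mean GM is at or above
    ``mask_threshold`` (one shared voxel set, as covariance analysis needs);
    ``per_subject_threshold=True`` instead intersects per-subject masks.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise DimensionError("expected a 4D (subjects, x, y, z) array")
    if not 0.0 <= mask_threshold <= 1.0:
        raise DataError("mask_threshold must lie in [0, 1]")
    n = volumes.shape[0]
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
    if len(subject_ids) != n:
        raise DimensionError("subject_ids length does not match volume count")
    if per_subject_threshold:
        mask = np.all(volumes >= mask_threshold, axis=0)
    else:
        mask = volumes.mean(axis=0) >= mask_threshold
    if not mask.any():
        raise DegenerateMaskError(
            f"mask at threshold {mask_threshold} selects no voxels"
        )
    return GMDataset(
        subject_ids=list(subject_ids),
        data=volumes[:, mask],
        mask=mask,
        affine=np.asarray(affine, dtype=float),
        timepoint=timepoint,
    )


def load_gm_dataset(
    paths: Sequence[str | Path],
    mask_threshold: float = 0.45,
    subject_ids: Sequence[str] | None = None,
    per_subject_threshold: bool = False,
    timepoint: str = "subacute",
) -> GMDataset:
    """Load per-subject NIfTI GM maps and vectorize them under a common mask.

    All volumes must share grid shape and affine.
    """
    if len(paths) == 0:
        raise DataError("no input volumes given")
    imgs = [nib.load(str(p)) for p in paths]
    shape = imgs[0].shape
    affine = imgs[0].affine
    for p, img in zip(paths, imgs):
        if img.shape != shape:
            raise DimensionError(f"{p}: grid shape {img.shape} != {shape}")
        if not np.allclose(img.affine, affine, atol=1e-4):
            raise DimensionError(f"{p}: affine differs from first volume")
    volumes = np.stack([np.asarray(img.get_fdata(), dtype=float) for img in imgs])
    if subject_ids is None:
        subject_ids = [Path(p).name.split(".")[0] for p in paths]
    return build_gm_dataset(
        volumes,
        affine,
        subject_ids=subject_ids,
        mask_threshold=mask_threshold,
        per_subject_threshold=per_subject_threshold,
        timepoint=timepoint,
    )


def write_gm_dataset(gm: GMDataset, out_dir: str | Path, prefix: str = "gm") -> list[Path]:
    """Write one NIfTI volume per subject plus the mask; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    vols = gm.to_volumes()
    for sid, vol in zip(gm.subject_ids, vols):
        p = out_dir / f"{prefix}_{sid}.nii.gz"
        nib.save(nib.Nifti1Image(vol, gm.affine), str(p))
        paths.append(p)
    nib.save(
        nib.Nifti1Image(gm.mask.astype(np.uint8), gm.affine),
        str(out_dir / f"{prefix}_mask.nii.gz"),
    )
    return paths


def compute_change_dataset(subacute: GMDataset, chronic: GMDataset) -> GMDataset:
    """Chronic-minus-sub-acute GM change maps on the shared mask."""
    if subacute.subject_ids != chronic.subject_ids:
        raise AlignmentError("subject sets/order differ between timepoints")
    if subacute.mask.shape != chronic.mask.shape or not np.array_equal(
        subacute.mask, chronic.mask
    ):
        raise DimensionError("timepoints must share one analysis mask")
    if not np.allclose(subacute.affine, chronic.affine, atol=1e-4):
        raise DimensionError("timepoints must share one affine")
    return GMDataset(
        subject_ids=list(subacute.subject_ids),
        data=chronic.data - subacute.data,
        mask=subacute.mask.copy(),
        affine=subacute.affine.copy(),
        timepoint="change",
    )


def sphere_voxel_mask(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    seed: SeedSpec,
) -> np.ndarray:
    """Boolean grid of voxels whose centre lies within the seed sphere."""
    affine = np.asarray(affine, dtype=float)
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    mm = grid @ affine[:3, :3].T + affine[:3, 3]
    d2 = ((mm - np.asarray(seed.centre_mm)) ** 2).sum(axis=1)
    return (d2 <= seed.radius_mm**2 + 1e-9).reshape(shape)


def seed_conjunction_mask(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    seeds: Iterable[SeedSpec],
) -> np.ndarray:
    """Union of all seed spheres on the grid."""
    out = np.zeros(shape, dtype=bool)
    for seed in seeds:
        out |= sphere_voxel_mask(shape, affine, seed)
    return out


def extract_seed_means(gm: GMDataset, seeds: Sequence[SeedSpec]) -> SeedMatrix:
    """Mean GM (or mean dGM) over each seed sphere, per subject.

    Only in-mask voxels enter the mean; a seed whose sphere contains no
    in-mask voxel raises :class:`EmptySeedError` naming the seed.
    """
    coords = gm.voxel_coords_mm()
    values = np.empty((gm.n_subjects, len(seeds)))
    for s, seed in enumerate(seeds):
        d2 = ((coords - np.asarray(seed.centre_mm)) ** 2).sum(axis=1)
        inside = d2 <= seed.radius_mm**2 + 1e-9
        if not inside.any():
            raise EmptySeedError(
                f"seed {seed.name!r} at {seed.centre_mm} has no in-mask voxels"
            )
        values[:, s] = gm.data[:, inside].mean(axis=1)
    return SeedMatrix(
        subject_ids=list(gm.subject_ids),
        seed_names=[s.name for s in seeds],
        values=values,
    )


@dataclasses.dataclass(frozen=True)
class OverlapReport:
    """Voxel-count overlap between a lesion map and the seed conjunction map."""

    seed_voxels: int
    lesion_voxels: int
    intersection_voxels: int

    @property
    def fraction_of_seed_map(self) -> float:
        if self.seed_voxels == 0:
            return 0.0
        return self.intersection_voxels / self.seed_voxels


def lesion_seed_overlap(
    group_lesion_mask: np.ndarray,
    seeds: Sequence[SeedSpec],
    gm: GMDataset,
) -> OverlapReport:
    """Overlap of the group lesion map with the union of all seed spheres."""
    lesion = np.asarray(group_lesion_mask, dtype=bool)
    if lesion.shape != gm.mask.shape:
        raise DimensionError("lesion mask grid does not match GM grid")
    conj = seed_conjunction_mask(gm.mask.shape, gm.affine, seeds)
    inter = lesion & conj
    return OverlapReport(
        seed_voxels=int(conj.sum()),
        lesion_voxels=int(lesion.sum()),
        intersection_voxels=int(inter.sum()),
    )


def read_seed_table(path: str | Path) -> list[SeedSpec]:
    """Read a seed TSV with columns name, network, x_mm, y_mm, z_mm, radius_mm."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "network", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"seed table missing columns: {sorted(missing)}")
    seeds = []
    for _, row in df.iterrows():
        seeds.append(
            SeedSpec(
                name=str(row["name"]),
                network=str(row["network"]),
                centre_mm=(float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])),
                radius_mm=float(row.get("radius_mm", 4.0)),
            )
        )
    return seeds


def write_seed_table(seeds: Sequence[SeedSpec], path: str | Path) -> None:
    rows = [
        {
            "name": s.name,
            "network": s.network,
            "x_mm": s.centre_mm[0],
            "y_mm": s.centre_mm[1],
            "z_mm": s.centre_mm[2],
            "radius_mm": s.radius_mm,
        }
        for s in seeds
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_seed_table() -> list[SeedSpec]:
    """The 12 default seeds (2 per canonical network), 4-mm radius.

    Coordinates are placeholder peak foci taken from the source literature
    for each network; replace with a study-specific seed TSV for real use.
    """
    from importlib import resources

    with resources.files("scnpls.data").joinpath("seeds_default.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        SeedSpec(
            name=str(r["name"]),
            network=str(r["network"]),
            centre_mm=(float(r["x_mm"]), float(r["y_mm"]), float(r["z_mm"])),
            radius_mm=float(r["radius_mm"]),
        )
        for _, r in df.iterrows()
    ]
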