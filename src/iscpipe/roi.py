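"""Spherical ROI definitions at MNI coordinates and ROI time-series extraction.

A region of interest is a sphere of given diameter (default 6 mm)
centered on an MNI millimeter coordinate.  Masks are built on an
explicit grid whose affine maps voxel indices to MNI mm -- the affine is
authoritative, no axis-orientation guessing.  A voxel belongs to the
mask when its *center* lies within the radius (inclusive boundary);
spatial reduction to a time series is the unweighted mean over mask
voxels.

The package ships a 16-region stress-processing ROI table
(``data/stress_rois_16.csv``): bilateral insula, basal ganglia and
amygdala plus left superior/inferior frontal gyrus, precuneus, putamen,
thalamus and bilateral parahippocampal gyrus, as used a priori in the
emulated study.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import DataFormatError, GeometryError

__all__ = [
    "RoiSpec",
    "GridSpec",
    "VoxelMask",
    "load_roi_table",
    "default_roi_table",
    "build_sphere_mask",
    "extract_timeseries",
    "mask_to_nifti",
]

DEFAULT_DIAMETER_MM = 6.0


@dataclass(frozen=True)
class RoiSpec:
    """One spherical ROI: label, MNI center (mm), diameter (mm)."""

    label: str
    mni_xyz: tuple[float, float, float]
    diameter: float = DEFAULT_DIAMETER_MM
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise DataFormatError(f"ROI '{self.label}': diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def key(self) -> str:
        """Unique identifier: anatomical labels may repeat across coordinates."""
        x, y, z = self.mni_xyz
        return f"{self.label} [{x:g}, {y:g}, {z:g}]"


@dataclass(frozen=True)
class GridSpec:
    """Sampling grid: shape plus the voxel-index -> MNI-mm affine (4x4)."""

    dims: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GeometryError("affine must be invertible")
        object.__setattr__(self, "affine", aff)

    @classmethod
    def isotropic(
        cls, dims: tuple[int, int, int], voxel_size: float, origin_mm=(0.0, 0.0, 0.0)
    ) -> "GridSpec":
        """Axis-aligned grid with cubic voxels; origin = mm coordinate of voxel (0,0,0)."""
        if voxel_size <= 0:
            raise GeometryError("voxel_size must be > 0")
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
        aff[:3, 3] = origin_mm
        return cls(dims=tuple(dims), affine=aff)

    def voxel_centers_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz_mm) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class VoxelMask:
    """Voxel indices belonging to one ROI on a specific grid."""

    indices: np.ndarray  # (n_voxels, 3) integer
    grid: GridSpec
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise GeometryError("indices must be (n, 3)")
        if self.indices.shape[0] == 0:
            raise GeometryError(f"mask '{self.label}' is empty")
        dims = np.asarray(self.grid.dims)
        if np.any(self.indices < 0) or np.any(self.indices >= dims):
            raise GeometryError(f"mask '{self.label}' has out-of-grid voxels")

    def __len__(self) -> int:
        return self.indices.shape[0]


def load_roi_table(path: str | Path) -> list[RoiSpec]:
    """Read an ROI table CSV: columns label, x, y, z, optional diameter, note.

    Lines starting with ``#`` are comments.  Anatomical labels may repeat
    (bilateral structures, multiple insular foci), but an exact duplicate
    of (label, x, y, z) raises a format error naming the label.
    """
    path = Path(path)
    rois: list[RoiSpec] = []
    seen: set[tuple] = set()
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(
            (line for line in fh if not line.lstrip().startswith("#"))
        )]
    if not rows:
        raise DataFormatError(f"no ROI rows in {path}")
    required = {"label", "x", "y", "z"}
    if not required.issubset(rows[0].keys()):
        raise DataFormatError(f"ROI table must have columns {sorted(required)}")
    for row in rows:
        label = row["label"].strip()
        try:
            xyz = tuple(float(row[c]) for c in ("x", "y", "z"))
        except (TypeError, ValueError) as exc:
            raise DataFormatError(
                f"non-numeric coordinate for ROI '{label}'"
            ) from exc
        diameter = float(row.get("diameter") or DEFAULT_DIAMETER_MM)
        ident = (label, *xyz)
        if ident in seen:
            raise DataFormatError(f"duplicate ROI row for label '{label}' at {xyz}")
        seen.add(ident)
        rois.append(
            RoiSpec(
                label=label, mni_xyz=xyz, diameter=diameter,
                source_note=(row.get("note") or "").strip(),
            )
        )
    return rois


def default_roi_table() -> list[RoiSpec]:
    """The shipped 16-region stress-processing ROI set."""
    with resources.as_file(
        resources.files("iscpipe.data") / "stress_rois_16.csv"
    ) as p:
        return load_roi_table(p)


def build_sphere_mask(
    center_mm, radius_mm: float, grid: GridSpec, label: str = ""
) -> VoxelMask:
    """All voxels whose center lies within ``radius_mm`` of ``center_mm``
    (Euclidean distance, inclusive boundary)."""
    if radius_mm <= 0:
        raise GeometryError("radius must be > 0")
    center_mm = np.asarray(center_mm, dtype=float)
    # candidate bounding box in voxel space around the center
    center_vox = grid.mm_to_voxel(center_mm)[0]
    # conservative per-axis half-extent: radius / smallest singular value
    svals = np.linalg.svd(grid.affine[:3, :3], compute_uv=False)
    halo = int(np.ceil(radius_mm / svals.min())) + 1
    lo = np.maximum(np.floor(center_vox).astype(int) - halo, 0)
    hi = np.minimum(np.ceil(center_vox).astype(int) + halo, np.asarray(grid.dims) - 1)
    if np.any(lo > hi):
        raise GeometryError(
            f"sphere at {tuple(center_mm)} lies outside the grid"
        )
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    centers = grid.voxel_centers_mm(ijk)
    dist = np.linalg.norm(centers - center_mm, axis=1)
    inside = dist <= radius_mm + 1e-9  # inclusive boundary, tolerant to fp
    if not np.any(inside):
        raise GeometryError(
            f"empty mask: no voxel center within {radius_mm} mm of {tuple(center_mm)}"
        )
    return VoxelMask(indices=ijk[inside], grid=grid, label=label)


def extract_timeseries(volume4d: np.ndarray, mask: VoxelMask) -> np.ndarray:
    """ROI time series: unweighted mean over mask voxels at each time point.

    ``volume4d`` is (X, Y, Z, T) on the mask's grid.  NaN voxels are
    ignored per time point; a time point with no finite voxel yields NaN
    with a warning.
    """
    vol = np.asarray(volume4d, dtype=float)
    if vol.ndim != 4:
        raise GeometryError("volume must be 4-D (X, Y, Z, T)")
    if vol.shape[:3] != tuple(mask.grid.dims):
        raise GeometryError(
            f"volume grid {vol.shape[:3]} does not match mask grid {mask.grid.dims}"
        )
    i, j, k = mask.indices.T
    voxels = vol[i, j, k, :]  # (n_voxels, T)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        series = np.nanmean(voxels, axis=0)
    if np.any(np.isnan(series)):
        warnings.warn(
            f"ROI '{mask.label}': {int(np.isnan(series).sum())} all-NaN time points",
            stacklevel=2,
        )
    return series


def grid_from_image(img) -> GridSpec:
    """GridSpec for a loaded NIfTI image (first three dims + its affine)."""
    return GridSpec(dims=tuple(img.shape[:3]), affine=np.asarray(img.affine))


def mask_to_nifti(mask: VoxelMask):
    """Binary NIfTI image of the mask (for visual inspection)."""
    import nibabel as nib

    vol = np.zeros(mask.grid.dims, dtype=np.uint8)
    i, j, k = mask.indices.T
    vol[i, j, k] = 1
    return nib.Nifti1Image(vol, mask.grid.affine)
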