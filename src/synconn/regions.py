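"""Region catalog, sphere ROIs, and time-series extraction.

The analysis operates on 14 syntax-related regions grouped into three
networks (I: 6 regions, II: 4, III: 4).  Each region is a 6-mm-radius
sphere centred on an MNI-millimetre coordinate; the per-volume signal of
a region is the unweighted mean over the voxels whose centres fall
inside the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NETWORK_LABELS = ("I", "II", "III")
DEFAULT_SPHERE_RADIUS_MM = 6.0

REGION_TABLE_COLUMNS = ["name", "ba", "side", "x", "y", "z", "network"]


@dataclass(frozen=True)
class RegionDefinition:
    """One named region: MNI centre plus its network assignment."""

    name: str
    brodmann: str
    side: str  # L, R, or M (medial)
    mni: tuple[float, float, float]
    network: str  # I, II, or III

    def __post_init__(self) -> None:
        if self.side not in ("L", "R", "M"):
            raise ValueError(f"region {self.name!r}: side must be L/R/M, got {self.side!r}")
        if self.network not in NETWORK_LABELS:
            raise ValueError(
                f"region {self.name!r}: unknown network label {self.network!r} "
                f"(expected one of {NETWORK_LABELS})"
            )
        if len(self.mni) != 3 or not np.all(np.isfinite(self.mni)):
            raise ValueError(f"region {self.name!r}: non-finite MNI coordinate {self.mni}")


class RegionCatalog:
    """Ordered collection of regions; the order fixes every matrix axis."""

    def __init__(self, regions: Sequence[RegionDefinition]):
        regions = list(regions)
        if not regions:
            raise ValueError("no regions")
        names = [r.name for r in regions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes}")
        self.regions: list[RegionDefinition] = regions

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, key: int | str) -> RegionDefinition:
        if isinstance(key, str):
            return self.regions[self.index(key)]
        return self.regions[key]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def networks(self) -> np.ndarray:
        return np.array([r.network for r in self.regions])

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"region {name!r} not in catalog") from None

    def network_sizes(self) -> dict[str, int]:
        nets = self.networks
        return {lab: int(np.sum(nets == lab)) for lab in NETWORK_LABELS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "ba": [r.brodmann for r in self.regions],
                "side": [r.side for r in self.regions],
                "x": [r.mni[0] for r in self.regions],
                "y": [r.mni[1] for r in self.regions],
                "z": [r.mni[2] for r in self.regions],
                "network": self.networks,
            }
        )


def load_region_catalog(table: str | pd.DataFrame) -> RegionCatalog:
    """Build a catalog from a region table (CSV path or DataFrame).

    The table needs columns name, ba, side, x, y, z, network; row order
    is preserved and becomes the axis order of every connectivity matrix.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, dtype={"ba": str})
    missing = [c for c in REGION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"region table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("no regions")
    regions = []
    for _, row in df.iterrows():
        try:
            mni = (float(row["x"]), float(row["y"]), float(row["z"]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"region {row['name']!r}: non-numeric coordinate") from exc
        ba = "" if pd.isna(row["ba"]) else str(row["ba"])
        regions.append(
            RegionDefinition(
                name=str(row["name"]),
                brodmann=ba,
                side=str(row["side"]),
                mni=mni,
                network=str(row["network"]),
            )
        )
    return RegionCatalog(regions)


def load_default_catalog() -> RegionCatalog:
    """The packaged 14-region / three-network catalog."""
    with resources.as_file(
        resources.files("synconn.data").joinpath("syntax_regions.csv")
    ) as path:
        return load_region_catalog(str(path))


# ---------------------------------------------------------------------------
# Voxel grids and sphere masks


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D sampling grid: shape plus a 4x4 voxel-to-MNI affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine spatial part is singular")
        object.__setattr__(self, "affine", affine)
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError("grid shape must be 3 positive integers")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @classmethod
    def isotropic(
        cls, shape: tuple[int, int, int], voxel_size_mm: float, origin_mni=(0.0, 0.0, 0.0)
    ) -> "VoxelGrid":
        """Axis-aligned grid with cubic voxels; voxel (0,0,0) sits at origin_mni."""
        affine = np.eye(4)
        affine[:3, :3] *= voxel_size_mm
        affine[:3, 3] = origin_mni
        return cls(shape=shape, affine=affine)


def voxel_to_mni(voxel: Iterable[float], grid: VoxelGrid) -> np.ndarray:
    v = np.append(np.asarray(voxel, dtype=float), 1.0)
    return (grid.affine @ v)[:3]


def mni_to_voxel(coord: Iterable[float], grid: VoxelGrid) -> tuple[int, int, int]:
    """Nearest voxel index for an MNI coordinate; errors if outside the grid."""
    c = np.append(np.asarray(coord, dtype=float), 1.0)
    v = np.linalg.solve(grid.affine, c)[:3]
    idx = np.rint(v).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
        raise ValueError(
            f"MNI coordinate {tuple(np.asarray(coord, float))} maps to voxel "
            f"{tuple(idx)} outside grid shape {grid.shape}"
        )
    return tuple(int(i) for i in idx)


@dataclass(frozen=True)
class SphereMask:
    """Set of voxels whose centres lie within radius_mm of an MNI centre."""

    center_mni: tuple[float, float, float]
    radius_mm: float
    voxel_indices: np.ndarray = field(repr=False)  # (n, 3) int array

    def __len__(self) -> int:
        return len(self.voxel_indices)


def build_sphere_mask(
    center_mni: Iterable[float], radius_mm: float, grid: VoxelGrid
) -> SphereMask:
    """All grid voxels whose centres are within ``radius_mm`` (Euclidean, mm).

    Inclusion is ``distance <= radius``; a radius-0 sphere centred on a
    voxel centre therefore contains exactly that voxel.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    center = np.asarray(center_mni, dtype=float)
    inv = np.linalg.inv(grid.affine)
    # Candidate voxels: bounding box of the MNI cube center +/- radius,
    # mapped through the inverse affine (covers oblique affines too).
    corners = center + radius_mm * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    vox_corners = (inv[:3, :3] @ corners.T).T + inv[:3, 3]
    lo = np.maximum(np.floor(vox_corners.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(vox_corners.max(axis=0)).astype(int), np.array(grid.shape) - 1)
    if np.any(lo > hi):
        raise ValueError(f"sphere at {tuple(center)} lies entirely outside the grid")
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = (grid.affine[:3, :3] @ vox.T).T + grid.affine[:3, 3]
    keep = np.linalg.norm(centers - center, axis=1) <= radius_mm + 1e-9
    vox = vox[keep]
    if len(vox) == 0:
        raise ValueError(f"sphere at {tuple(center)} contains no voxel centres")
    return SphereMask(
        center_mni=tuple(center), radius_mm=float(radius_mm), voxel_indices=vox
    )


def extract_roi_series(volume4d, mask: SphereMask) -> np.ndarray:
    """Per-volume mean over the mask voxels.

    ``volume4d`` is a 4-D array (x, y, z, t) or a nibabel spatial image;
    returns a 1-D array of length t.
    """
    data = np.asarray(
        volume4d.get_fdata() if hasattr(volume4d, "get_fdata") else volume4d
    )
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    if len(mask) == 0:
        raise ValueError("empty mask")
    idx = mask.voxel_indices
    if np.any(idx < 0) or np.any(idx >= np.asarray(data.shape[:3])):
        raise ValueError("mask voxels fall outside the volume")
    return data[idx[:, 0], idx[:, 1], idx[:, 2], :].mean(axis=0)


def extract_catalog_series(
    volume4d,
    catalog: RegionCatalog,
    grid: VoxelGrid,
    radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
) -> pd.DataFrame:
    """Extract every catalog region's sphere-mean series from one 4-D run."""
    series = {
        region.name: extract_roi_series(
            volume4d, build_sphere_mask(region.mni, radius_mm, grid)
        )
        for region in catalog
    }
    return pd.DataFrame(series, columns=catalog.names)
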