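"""Spatial connectivity statistics around tumour-infiltrated cortex.

Covers the volumetric half of the pipeline: snapping electrode coordinates to
the nearest grey-matter/tumour voxel (with a 10-mm-spacing tie-break),
building parenchyma-masked spherical seeds, whole-brain seed-based Pearson
connectivity with Fisher z transform and masked Gaussian smoothing, nearest-
voxel projection onto a spherical surface, and the per-voxel tumour-network
connectivity statistic with Bonferroni family-wise error control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.stats as sst
from scipy.spatial import cKDTree

from .errors import DegenerateInputError
from .surface import SurfaceMap, SurfaceMesh

R_CLIP = 1.0 - 1e-7
TARGET_SPACING_MM = 10.0  # centre-to-centre electrode spacing of the strips


def world_coords(ijk: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Voxel indices (n, 3) -> world mm coordinates via the volume affine."""
    ijk = np.atleast_2d(ijk)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def snap_electrode_to_cortex(
    coord_mm,
    mask: np.ndarray,
    affine: np.ndarray,
    snapped_neighbours_mm=None,
    max_dist_mm: float = 20.0,
    tie_tol_mm: float = 1e-6,
) -> tuple:
    """Nearest mask voxel to a world coordinate, with a spacing tie-break.

    Among voxels equidistant from the coordinate (ties at voxel precision),
    the one whose distances to the already-snapped neighbouring electrodes
    are closest to the nominal 10-mm strip spacing (minimum sum of
    |d - 10 mm|) is chosen.  Coordinates farther than ``max_dist_mm`` from
    the mask still snap, with a warning.
    """
    ijk = np.argwhere(np.asarray(mask, dtype=bool))
    if not len(ijk):
        raise DegenerateInputError("cannot snap to an empty mask")
    coord_mm = np.asarray(coord_mm, dtype=float)
    xyz = world_coords(ijk, affine)
    d = np.linalg.norm(xyz - coord_mm, axis=1)
    dmin = d.min()
    if dmin > max_dist_mm:
        warnings.warn(
            f"electrode at {tuple(np.round(coord_mm, 1))} is {dmin:.1f} mm from the "
            f"nearest mask voxel (bound {max_dist_mm} mm)",
            stacklevel=2,
        )
    ties = np.flatnonzero(d <= dmin + tie_tol_mm)
    if len(ties) > 1 and snapped_neighbours_mm is not None and len(snapped_neighbours_mm):
        neigh = np.atleast_2d(np.asarray(snapped_neighbours_mm, dtype=float))
        cost = np.abs(
            np.linalg.norm(xyz[ties][:, None, :] - neigh[None, :, :], axis=2)
            - TARGET_SPACING_MM
        ).sum(axis=1)
        best = ties[np.argmin(cost)]
    else:
        best = ties[0]
    return tuple(int(v) for v in ijk[best])


@dataclass
class SeedSphere:
    """A parenchyma-masked spherical seed around one electrode voxel."""

    centre_mm: np.ndarray
    radius_mm: float
    voxels: np.ndarray  # (n, 3) int indices

    def __post_init__(self) -> None:
        if not len(self.voxels):
            raise DegenerateInputError("seed sphere contains no parenchyma voxels")


def make_seed(centre_voxel, radius_mm: float, parenchyma_mask: np.ndarray,
              affine: np.ndarray) -> SeedSphere:
    """Voxels whose centres lie within ``radius_mm`` of the seed centre,
    intersected with the parenchyma mask."""
    if radius_mm <= 0:
        raise ValueError("seed radius must be positive")
    parenchyma_mask = np.asarray(parenchyma_mask, dtype=bool)
    centre_mm = world_coords(np.asarray(centre_voxel, dtype=float), affine)[0]
    ijk = np.argwhere(parenchyma_mask)
    if not len(ijk):
        raise DegenerateInputError("parenchyma mask is empty")
    d = np.linalg.norm(world_coords(ijk, affine) - centre_mm, axis=1)
    inside = ijk[d <= radius_mm]
    return SeedSphere(centre_mm=centre_mm, radius_mm=float(radius_mm), voxels=inside)


@dataclass
class ConnectivityMap:
    """Voxelwise Fisher-z connectivity from one seed, on the BOLD grid."""

    data: np.ndarray  # 3-D, NaN outside parenchyma
    affine: np.ndarray
    parenchyma: np.ndarray
    zero_variance: np.ndarray  # voxels whose r was defined as 0
    provenance: dict = field(default_factory=dict)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped to 1 - 1e-7 so the map stays finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _masked_gaussian_smooth(data: np.ndarray, mask: np.ndarray, sigma_vox) -> np.ndarray:
    """Gaussian smoothing whose support is restricted to ``mask``."""
    filled = np.where(mask, data, 0.0)
    num = ndi.gaussian_filter(filled, sigma_vox)
    den = ndi.gaussian_filter(mask.astype(float), sigma_vox)
    out = np.full_like(data, np.nan)
    inside = mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return out


def seed_fc_map(
    bold: np.ndarray,
    seed: SeedSphere,
    parenchyma_mask: np.ndarray,
    affine: np.ndarray,
    fwhm_mm: float = 5.0,
) -> ConnectivityMap:
    """Seed-based functional connectivity: Pearson r of the seed-mean time
    series with every parenchyma voxel, Fisher z transformed, then Gaussian
    smoothed (FWHM in mm) over the parenchyma only.

    Zero-variance voxels get r = 0 and are flagged.
    """
    if bold.ndim != 4:
        raise ValueError("bold must be 4-D (x, y, z, t)")
    n_t = bold.shape[-1]
    if n_t < 3:
        raise ValueError("need at least 3 time points")
    parenchyma_mask = np.asarray(parenchyma_mask, dtype=bool)

    seed_ts = bold[tuple(seed.voxels.T)].mean(axis=0)
    seed_sd = seed_ts.std()
    if seed_sd == 0:
        raise DegenerateInputError("seed mean time series has zero variance")
    seed_z = (seed_ts - seed_ts.mean()) / seed_sd

    vox = bold[parenchyma_mask]
    sd = vox.std(axis=1)
    zero_var = sd == 0
    sd_safe = np.where(zero_var, 1.0, sd)
    vox_z = (vox - vox.mean(axis=1, keepdims=True)) / sd_safe[:, None]
    r = vox_z @ seed_z / n_t
    r[zero_var] = 0.0

    zmap = np.full(bold.shape[:3], np.nan)
    zmap[parenchyma_mask] = fisher_z(r)
    zv = np.zeros(bold.shape[:3], dtype=bool)
    zv[parenchyma_mask] = zero_var

    if fwhm_mm > 0:
        voxel_sizes = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / voxel_sizes
        zmap = _masked_gaussian_smooth(zmap, parenchyma_mask, sigma_vox)

    return ConnectivityMap(
        data=zmap,
        affine=affine,
        parenchyma=parenchyma_mask,
        zero_variance=zv,
        provenance={"n_seed_voxels": len(seed.voxels), "fwhm_mm": fwhm_mm},
    )


def volume_to_surface(
    cmap: ConnectivityMap,
    mesh: SurfaceMesh,
    vertex_coords_mm: np.ndarray | None = None,
    max_dist_mm: float = 3.0,
) -> SurfaceMap:
    """Sample the volume at each vertex's nearest in-parenchyma voxel.

    ``vertex_coords_mm`` maps mesh vertices into the volume's world frame
    (defaults to the mesh's own coordinates).  Vertices with no parenchyma
    voxel within ``max_dist_mm`` are masked invalid.
    """
    coords = np.asarray(
        vertex_coords_mm if vertex_coords_mm is not None else mesh.vertices, dtype=float
    )
    if coords.shape != (mesh.n_vertices, 3):
        raise ValueError("vertex coordinate array must be (n_vertices, 3)")
    ijk = np.argwhere(cmap.parenchyma)
    tree = cKDTree(world_coords(ijk, cmap.affine))
    dist, idx = tree.query(coords)
    valid = dist <= max_dist_mm
    if not valid.any():
        raise DegenerateInputError("no vertex lies within range of the parenchyma")
    values = np.full(mesh.n_vertices, np.nan)
    values[valid] = cmap.data[tuple(ijk[idx[valid]].T)]
    # smoothing support can still leave NaNs at isolated voxels
    valid &= np.isfinite(values)
    return SurfaceMap(values=values, valid=valid)


@dataclass
class TumourNetworkResult:
    """Per-voxel tumour-network correlations with FWER thresholding."""

    voxels: np.ndarray            # (n, 3) tested tumour voxels
    r: np.ndarray
    p: np.ndarray
    survivors: np.ndarray         # boolean over tested voxels
    n_overlap_excluded: int
    alpha_fwer: float
    mean_connectivity: float | None

    @property
    def n_survivors(self) -> int:
        return int(self.survivors.sum())


def pearson_p_exact(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the exact t transform t = r sqrt((n-2)/(1-r^2))."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * sst.t.sf(np.abs(t), df=n - 2)


def tumour_network_connectivity(
    bold: np.ndarray,
    tumour_mask: np.ndarray,
    network_mask: np.ndarray,
    alpha_fwer: float = 0.05,
) -> TumourNetworkResult:
    """Correlate every non-overlapping tumour voxel with the network mean
    time series; keep voxels surviving Bonferroni FWER control.

    Voxels where tumour and network masks overlap are excluded and their
    count reported (it enters later models as a covariate).  The summary
    statistic is the mean r over surviving voxels (absent when none survive).
    """
    tumour_mask = np.asarray(tumour_mask, dtype=bool)
    network_mask = np.asarray(network_mask, dtype=bool)
    n_t = bold.shape[-1]
    if n_t < 4:
        raise ValueError("need at least 4 time points")
    if not network_mask.any():
        raise DegenerateInputError("network mask is empty")
    overlap = tumour_mask & network_mask
    tested_mask = tumour_mask & ~network_mask
    n_overlap = int(overlap.sum())
    if not tested_mask.any():
        raise DegenerateInputError(
            f"all {n_overlap} tumour voxels overlap the network mask; nothing to test"
        )

    ref = bold[network_mask].mean(axis=0)
    ref_sd = ref.std()
    if ref_sd == 0:
        raise DegenerateInputError("network reference time series has zero variance")
    ref_z = (ref - ref.mean()) / ref_sd

    vox = bold[tested_mask]
    sd = vox.std(axis=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    vox_z = (vox - vox.mean(axis=1, keepdims=True)) / sd_safe[:, None]
    r = vox_z @ ref_z / n_t
    r[sd == 0] = 0.0

    p = pearson_p_exact(r, n_t)
    m = len(r)
    survivors = p < alpha_fwer / m
    mean_conn = float(r[survivors].mean()) if survivors.any() else None
    return TumourNetworkResult(
        voxels=np.argwhere(tested_mask),
        r=r,
        p=p,
        survivors=survivors,
        n_overlap_excluded=n_overlap,
        alpha_fwer=alpha_fwer,
        mean_connectivity=mean_conn,
    )
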