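"""Voxel-wise functional connectivity density (FCD) mapping.

For every in-mask voxel i the total FCD is the sum of Pearson correlations
r(i, j) over all other in-mask voxels j with r(i, j) strictly above the
threshold (default 0.25) — a weighted degree/strength, not a binary count.
Local FCD restricts the sum to voxels within ``local_radius_mm`` (default
3 mm: on a 3 mm isotropic grid, the seed's 6 face neighbours), distant FCD
to voxels beyond ``distant_radius_mm`` (default 25 mm).  The band between
the two radii is deliberately assigned to neither map (no overlap between
the indices); its sum is kept as the ``gap`` map so the decomposition
local + gap + distant = total can always be verified.

Only positive suprathreshold correlations contribute, and the seed's own
r = 1 self-correlation is always excluded.  The all-pairs correlation is
computed in voxel blocks with a bounded working set — the full N x N
matrix is never materialized — and the result is independent of block
size.  ``naive_fcd`` is a deliberately simple all-pairs reference
implementation used for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .images import BoldImage, FcdPipeError

FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


@dataclass
class FcdMaps:
    """Per-subject triple of 3D FCD maps plus the gap-band remainder."""

    total: np.ndarray
    local: np.ndarray
    distant: np.ndarray
    gap: np.ndarray
    brain_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    r_threshold: float = 0.25
    local_radius_mm: float = 3.0
    distant_radius_mm: float = 25.0
    normalized: bool = False
    smoothed_fwhm_mm: float | None = None

    MAP_NAMES = ("total", "local", "distant")

    def map(self, name: str) -> np.ndarray:
        if name not in self.MAP_NAMES + ("gap",):
            raise FcdPipeError(f"unknown map {name!r}")
        return getattr(self, name)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit L2 norm, so that X @ X.T is the
    exact Pearson correlation matrix."""
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    return x / norms


class FcdGeometry:
    """Precomputed distance classification for one (mask, radii) geometry.

    Voxel-pair distance classes depend only on the mask, the voxel size and
    the two radii, so they can be computed once and shared across subjects
    of a cohort.  Stored per block, as float masks in the requested dtype
    (1.0 inside the local sphere / the <= distant-radius "near" ball), for
    direct use in einsum accumulation.
    """

    def __init__(self, mask, voxel_size_mm, local_radius_mm=3.0,
                 distant_radius_mm=25.0, block_size=512, dtype=np.float64):
        self.mask = np.asarray(mask, bool)
        self.voxel_size_mm = tuple(
            np.broadcast_to(np.atleast_1d(np.asarray(voxel_size_mm, float)), (3,))
        )
        self.local_radius_mm = float(local_radius_mm)
        self.distant_radius_mm = float(distant_radius_mm)
        self.block_size = int(block_size)
        self.dtype = np.dtype(dtype)
        coords = (np.argwhere(self.mask) * np.asarray(self.voxel_size_mm))
        self.n = len(coords)
        lr2 = local_radius_mm**2 + 1e-9
        dr2 = distant_radius_mm**2 + 1e-9
        sq = np.einsum("ij,ij->i", coords, coords)
        self.blocks = []
        for start in range(0, self.n, self.block_size):
            stop = min(start + self.block_size, self.n)
            d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (coords[start:stop] @ coords.T)
            self.blocks.append((
                start, stop,
                (d2 <= lr2).astype(self.dtype),
                (d2 <= dr2).astype(self.dtype),
            ))

    def matches(self, bold: BoldImage, local_radius_mm, distant_radius_mm,
                block_size, dtype) -> bool:
        return (
            np.array_equal(self.mask, bold.brain_mask)
            and self.voxel_size_mm == tuple(bold.voxel_size_mm)
            and self.local_radius_mm == local_radius_mm
            and self.distant_radius_mm == distant_radius_mm
            and self.block_size == block_size
            and self.dtype == np.dtype(dtype)
        )


def compute_fcd(
    bold: BoldImage,
    r_threshold: float = 0.25,
    local_radius_mm: float = 3.0,
    distant_radius_mm: float = 25.0,
    block_size: int = 512,
    dtype=np.float64,
    geometry: FcdGeometry | None = None,
) -> FcdMaps:
    """Compute unnormalized total/local/distant (and gap) FCD maps.

    ``geometry`` may hold the precomputed distance classification for this
    exact (mask, voxel size, radii, block size, dtype) combination —
    results are identical with or without it.  Raises if any in-mask voxel
    has zero temporal variance (its correlation is undefined; remove it
    from the mask).
    """
    if local_radius_mm >= distant_radius_mm:
        raise FcdPipeError("local_radius_mm must be smaller than distant_radius_mm")
    mask = bold.brain_mask
    n = int(mask.sum())
    if n < 2:
        raise FcdPipeError("need at least 2 in-mask voxels")
    if bold.n_volumes < 3:
        raise FcdPipeError("need at least 3 time points")
    x = bold.data[mask]
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = np.argwhere(mask)[sd == 0]
        raise FcdPipeError(
            f"{len(bad)} in-mask voxel(s) have zero temporal variance "
            f"(first: {tuple(bad[0])}); correlation is undefined there — "
            "remove them from the brain mask"
        )
    x = _standardize_rows(x).astype(dtype, copy=False)

    if geometry is None:
        geometry = FcdGeometry(
            mask, bold.voxel_size_mm, local_radius_mm, distant_radius_mm,
            block_size, dtype,
        )
    elif not geometry.matches(bold, local_radius_mm, distant_radius_mm,
                              block_size, dtype):
        raise FcdPipeError("supplied FcdGeometry does not match this computation")

    total = np.zeros(n, dtype=np.float64)
    local = np.zeros(n, dtype=np.float64)
    near = np.zeros(n, dtype=np.float64)

    thr = np.dtype(dtype).type(r_threshold)
    for start, stop, local_m, near_m in geometry.blocks:
        r = x[start:stop] @ x.T  # (b, n) exact correlations
        r *= r > thr  # zero sub-threshold entries in place
        total[start:stop] = np.einsum("ij->i", r)
        local[start:stop] = np.einsum("ij,ij->i", r, local_m)
        near[start:stop] = np.einsum("ij,ij->i", r, near_m)
    # the seed's own r = 1 lies inside every distance class; remove it
    if 1.0 > r_threshold:
        total -= 1.0
        local -= 1.0
        near -= 1.0
    gap = near - local
    distant = total - near
    # guard against negative rounding residue (maps are sums of positives)
    for arr in (total, local, gap, distant):
        np.maximum(arr, 0.0, out=arr)

    def to3d(v):
        out = np.zeros(mask.shape)
        out[mask] = v
        return out

    return FcdMaps(
        total=to3d(total), local=to3d(local), distant=to3d(distant), gap=to3d(gap),
        brain_mask=mask.copy(), voxel_size_mm=bold.voxel_size_mm,
        r_threshold=r_threshold, local_radius_mm=local_radius_mm,
        distant_radius_mm=distant_radius_mm,
    )


def naive_fcd(
    bold: BoldImage,
    r_threshold: float = 0.25,
    local_radius_mm: float = 3.0,
    distant_radius_mm: float = 25.0,
) -> FcdMaps:
    """All-pairs reference implementation (materializes the full N x N
    correlation and distance matrices).  For cross-checks on small grids."""
    mask = bold.brain_mask
    x = bold.data[mask]
    r = np.corrcoef(x)
    np.fill_diagonal(r, 0.0)
    w = np.where(r > r_threshold, r, 0.0)
    coords = np.argwhere(mask) * np.asarray(bold.voxel_size_mm)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))

    def to3d(v):
        out = np.zeros(mask.shape)
        out[mask] = v
        return out

    return FcdMaps(
        total=to3d(w.sum(1)),
        local=to3d((w * (d <= local_radius_mm)).sum(1) - np.diag(w)),
        distant=to3d((w * (d > distant_radius_mm)).sum(1)),
        gap=to3d((w * ((d > local_radius_mm) & (d <= distant_radius_mm))).sum(1)),
        brain_mask=mask.copy(), voxel_size_mm=bold.voxel_size_mm,
        r_threshold=r_threshold, local_radius_mm=local_radius_mm,
        distant_radius_mm=distant_radius_mm,
    )


def local_sphere_offsets(radius_mm: float = 3.0, voxel_size_mm: float = 3.0):
    """Voxel offsets within the local sphere (center-to-center distance
    <= radius).  At the default 3 mm radius on a 3 mm isotropic grid this
    is the seed plus its 6 face neighbours: 7 voxels."""
    reach = int(np.floor(radius_mm / voxel_size_mm))
    offs = []
    for dx in range(-reach, reach + 1):
        for dy in range(-reach, reach + 1):
            for dz in range(-reach, reach + 1):
                d = voxel_size_mm * np.sqrt(dx * dx + dy * dy + dz * dz)
                if d <= radius_mm + 1e-12:
                    offs.append((dx, dy, dz))
    return offs


def normalize_fcd(maps: FcdMaps, per_map: bool = True) -> FcdMaps:
    """Divide each map by its own in-mask mean (``per_map=True``, default)
    or divide all maps by the total map's in-mask mean.  After per-map
    normalization every map has in-mask mean exactly 1."""
    mask = maps.brain_mask
    out = {}
    total_mean = maps.total[mask].mean()
    for name in maps.MAP_NAMES + ("gap",):
        m = maps.map(name)
        divisor = m[mask].mean() if per_map else total_mean
        if divisor <= 0:
            raise FcdPipeError(
                f"in-mask mean of {name} map is {divisor}; nothing to normalize "
                "(no suprathreshold connectivity anywhere)"
            )
        out[name] = m / divisor
    return replace(maps, normalized=True, **out)


def smooth_map(
    map3d: np.ndarray,
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm,
) -> np.ndarray:
    """Masked 3D Gaussian smoothing with the stated full width at half
    maximum (sigma = FWHM / sqrt(8 ln 2) per axis, in voxels).

    Values outside the mask are excluded, and the result is renormalized by
    the smoothed mask so edge voxels are not attenuated.  ``fwhm_mm = 0``
    is the identity (inside the mask).
    """
    if fwhm_mm < 0:
        raise FcdPipeError("fwhm_mm must be >= 0")
    mask = np.asarray(mask, bool)
    if fwhm_mm == 0:
        return np.where(mask, map3d, 0.0)
    voxel = np.broadcast_to(np.atleast_1d(np.asarray(voxel_size_mm, float)), (3,))
    sigma_vox = (fwhm_mm / FWHM_PER_SIGMA) / voxel
    num = ndimage.gaussian_filter(np.where(mask, map3d, 0.0), sigma_vox)
    den = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    out = np.zeros_like(num)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def smooth_fcd_maps(maps: FcdMaps, fwhm_mm: float = 8.0) -> FcdMaps:
    """Apply masked Gaussian smoothing to all maps (group-analysis stage)."""
    out = {
        name: smooth_map(maps.map(name), maps.brain_mask, fwhm_mm, maps.voxel_size_mm)
        for name in maps.MAP_NAMES + ("gap",)
    }
    return replace(maps, smoothed_fwhm_mm=fwhm_mm, **out)
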