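"""Trabecular bone morphometry: IsoData binarization, cylindrical VOIs and
model-free BV/TV, Tb.Th, Tb.Sp measurement.

The three standard metrics are

* **BV/TV** — bone volume fraction: foreground voxels / total voxels in the
  volume of interest, by direct voxel counting.
* **Tb.Th** — trabecular thickness: mean *local thickness* of the bone
  (foreground) phase.
* **Tb.Sp** — trabecular separation: mean local thickness of the marrow
  (background) phase.

Local thickness follows the largest-inscribed-sphere definition of
Hildebrand & Rüegsegger: the thickness at a point of a phase is the diameter
of the largest sphere that contains the point and fits entirely within the
phase.  It is computed from the exact Euclidean distance transform via a
distance-ridge reduction followed by sphere painting, and is defined for
isotropic grids only; anisotropic stacks must be resampled first (see
:func:`measure_stack`, which does this automatically).
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
from scipy import ndimage

from .core import VoxelVolume

__all__ = [
    "CylindricalVOI",
    "MorphometryResult",
    "isodata_threshold",
    "voxelize_voi",
    "position_voi_from_body_mask",
    "bvtv",
    "local_thickness_map",
    "tbth_tbsp",
    "measure_stack",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CylindricalVOI:
    """Cylindrical volume of interest.

    ``center`` is in physical (z, y, x) mm coordinates; ``axis`` is a unit
    vector (default: slice normal, i.e. the z axis).  The conventional VOI
    for a vertebral centrum is 15 mm in diameter and 5 mm in height.
    """

    center: tuple[float, float, float]
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    diameter_mm: float = 15.0
    height_mm: float = 5.0
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.height_mm <= 0:
            raise ValueError("VOI diameter and height must be positive")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("VOI axis must be a nonzero vector")
        self.axis = tuple(a / n)
        self.center = tuple(float(c) for c in self.center)


@dataclass
class MorphometryResult:
    """BV/TV, Tb.Th and Tb.Sp for one VOI, with provenance."""

    bvtv: float
    tbth_mm: float
    tbth_sd_mm: float
    tbsp_mm: float
    tbsp_sd_mm: float
    threshold_used: float
    voi: CylindricalVOI
    n_foreground: int
    n_total: int
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# IsoData threshold
# ---------------------------------------------------------------------------

def isodata_threshold(volume, mask=None, max_iter: int = 256) -> float:
    """IsoData (iterative intermeans) global threshold of an 8-bit region.

    Starting from the mean intensity of the region, iterate
    ``t <- (mean of values <= t) + (mean of values > t)) / 2`` to a fixed
    point and return the converged (fractional) threshold.  Voxels strictly
    above the returned threshold are foreground.
    """
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    if mask is not None:
        m = mask.data if isinstance(mask, VoxelVolume) else np.asarray(mask)
        data = data[m.astype(bool)]
    data = np.clip(np.rint(np.asarray(data, dtype=np.float64)), 0, 255).astype(np.int64)
    if data.size == 0:
        raise ValueError("empty region")
    hist = np.bincount(data.ravel(), minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: region is constant")
    csum = np.cumsum(hist)
    cmoment = np.cumsum(hist * levels)
    total, total_m = csum[-1], cmoment[-1]

    def intermeans(t: float) -> float:
        k = min(int(np.floor(t)), 254)
        k = max(k, 0)
        n_lo = csum[k]
        if n_lo == 0 or n_lo == total:  # cannot happen for t strictly inside
            raise ValueError("degenerate histogram: one-sided split")
        mu_lo = cmoment[k] / n_lo
        mu_hi = (total_m - cmoment[k]) / (total - n_lo)
        return 0.5 * (mu_lo + mu_hi)

    t = total_m / total  # region mean
    for _ in range(max_iter):
        t_new = intermeans(t)
        if np.floor(t_new) == np.floor(t) or abs(t_new - t) < 1e-9:
            return float(t_new)
        t = t_new
    return float(t)


# ---------------------------------------------------------------------------
# VOI geometry
# ---------------------------------------------------------------------------

def voxelize_voi(voi: CylindricalVOI, grid: VoxelVolume) -> np.ndarray:
    """Boolean mask of grid voxels whose centres lie strictly inside the VOI."""
    zc = grid.voxel_centers(0)
    yc = grid.voxel_centers(1)
    xc = grid.voxel_centers(2)
    dz = zc - voi.center[0]
    dy = yc - voi.center[1]
    dx = xc - voi.center[2]
    az, ay, ax = voi.axis
    # axial coordinate and squared radial distance for every voxel centre
    t = dz[:, None, None] * az + dy[None, :, None] * ay + dx[None, None, :] * ax
    r2 = (
        dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
        - t ** 2
    )
    mask = (np.abs(t) < voi.height_mm / 2.0) & (r2 < (voi.diameter_mm / 2.0) ** 2)
    if not mask.any():
        raise ValueError("VOI does not intersect the grid")
    return mask


def position_voi_from_body_mask(
    body_mask: VoxelVolume,
    diameter_mm: float = 15.0,
    height_mm: float = 5.0,
    offset_mm: float = 5.0,
    anterior_margin_mm: float = 5.0,
) -> tuple[CylindricalVOI, CylindricalVOI]:
    """Place the two standard centrum VOIs from the vertebral body mask.

    Axial construction (on the mid-stack axial mask): line A is the
    centreline of the short (anterior-posterior, y) axis of the body
    cross-section, i.e. the A-P line through the body centroid; the tangent
    point P lies on A, ``anterior_margin_mm`` interior to A's intersection
    with the anterior edge of the body (anterior = low y).  Each VOI is a
    cylinder of ``diameter_mm`` tangent at P from the interior side.  The two
    VOIs are centred ``offset_mm`` above and below the cranio-caudal (z)
    midline of the mask.

    If a cylinder does not fit inside the mask a warning is emitted and the
    returned VOIs carry ``clipped=True``.
    """
    m = body_mask.require_binary()
    if not m.any():
        raise ValueError("empty body mask")
    zc = body_mask.voxel_centers(0)
    yc = body_mask.voxel_centers(1)
    xc = body_mask.voxel_centers(2)
    z_idx = np.where(m.any(axis=(1, 2)))[0]
    z_mid_mm = 0.5 * (zc[z_idx[0]] + zc[z_idx[-1]])
    axial = m[(z_idx[0] + z_idx[-1]) // 2]
    ys, xs = np.nonzero(axial)
    x0_mm = float(np.mean(xc[xs]))  # line A: x = x0
    # anterior edge along line A: smallest-y body voxel on the column nearest x0
    col = np.argmin(np.abs(xc[None, xs] - x0_mm), axis=1)
    col_x = xs[col[0]]
    col_ys = ys[xs == col_x]
    y_ant_mm = float(yc[col_ys.min()])
    y_post_mm = float(yc[col_ys.max()])
    p_y = y_ant_mm + anterior_margin_mm
    center_y = p_y + diameter_mm / 2.0  # tangent at P, interior (posterior) side

    clipped = center_y + diameter_mm / 2.0 > y_post_mm
    vois = []
    for sign in (+1.0, -1.0):
        cz = z_mid_mm + sign * offset_mm
        z_lo, z_hi = cz - height_mm / 2.0, cz + height_mm / 2.0
        clip = clipped or z_lo < zc[z_idx[0]] or z_hi > zc[z_idx[-1]]
        vois.append(
            CylindricalVOI(
                center=(cz, center_y, x0_mm),
                diameter_mm=diameter_mm,
                height_mm=height_mm,
                clipped=bool(clip),
            )
        )
    if any(v.clipped for v in vois):
        warnings.warn("VOI does not fit inside the body mask; flagged as clipped")
    return tuple(vois)


# ---------------------------------------------------------------------------
# BV/TV
# ---------------------------------------------------------------------------

def bvtv(binary: VoxelVolume, mask=None) -> float:
    """Bone volume fraction by voxel counting: foreground-in-mask / mask."""
    b = binary.require_binary()
    if mask is None:
        m = np.ones_like(b, dtype=bool)
    else:
        m = (mask.data if isinstance(mask, VoxelVolume) else np.asarray(mask)).astype(bool)
    n_total = int(m.sum())
    if n_total == 0:
        raise ValueError("empty mask")
    return float(int((b & m).sum()) / n_total)


# ---------------------------------------------------------------------------
# local thickness
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=8)
def _containment_tables(r2max: int) -> np.ndarray:
    """Digital sphere containment templates for the distance-ridge test.

    A centre ``c`` with squared distance-transform value ``R2`` covers the
    lattice points ``v`` with ``|v - c|^2 <= R2 - 1`` (the strict-inequality
    cover rule on integer squared distances).  ``table[cls, R2]`` is the
    smallest squared radius a 26-neighbour at offset class ``cls``
    (``|o|^2 = cls + 1``) must have for its digital sphere to contain all of
    ``c``'s — i.e. ``1 + max |p + o|^2`` over ``|p|^2 <= R2 - 1``.  Because
    digital spheres are finite point sets this prunes far more than the
    Euclidean bound while remaining exactly lossless.
    """
    r = int(np.ceil(np.sqrt(max(r2max, 1)))) + 1
    g = np.arange(-r, r + 1)
    pz, py, px = np.meshgrid(g, g, g, indexing="ij")
    p2 = (pz * pz + py * py + px * px).ravel()
    sel = p2 <= r2max - 1
    pz, py, px, p2 = pz.ravel()[sel], py.ravel()[sel], px.ravel()[sel], p2[sel]
    order = np.argsort(p2, kind="stable")
    pz, py, px, p2 = pz[order], py[order], px[order], p2[order]
    table = np.zeros((3, r2max + 1), dtype=np.int64)
    for cls, o in enumerate([(0, 0, 1), (0, 1, 1), (1, 1, 1)]):
        q2 = (pz + o[0]) ** 2 + (py + o[1]) ** 2 + (px + o[2]) ** 2
        running = np.maximum.accumulate(q2)
        # for each R2, the largest index with p2 <= R2 - 1
        idx = np.searchsorted(p2, np.arange(r2max + 1) - 1, side="right") - 1
        m = np.where(idx >= 0, running[np.clip(idx, 0, None)], 0)
        table[cls] = m + 1
    return table


@numba.njit(cache=True)
def _ridge_mask(d2, table):  # pragma: no cover - jitted
    """Distance ridge: keep voxels whose digital sphere is not contained in
    a 26-neighbour's digital sphere (containment is exact, so pruning never
    changes the painted map; containment implies a strictly larger radius,
    so no mutual pruning can occur)."""
    nz, ny, nx = d2.shape
    keep = np.zeros(d2.shape, dtype=numba.boolean)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                r2 = d2[z, y, x]
                if r2 <= 0:
                    continue
                redundant = False
                for dz in (-1, 0, 1):
                    zz = z + dz
                    if zz < 0 or zz >= nz:
                        continue
                    for dy in (-1, 0, 1):
                        yy = y + dy
                        if yy < 0 or yy >= ny:
                            continue
                        for dx in (-1, 0, 1):
                            if dz == 0 and dy == 0 and dx == 0:
                                continue
                            xx = x + dx
                            if xx < 0 or xx >= nx:
                                continue
                            cls = dz * dz + dy * dy + dx * dx - 1
                            if d2[zz, yy, xx] >= table[cls, r2]:
                                redundant = True
                                break
                        if redundant:
                            break
                    if redundant:
                        break
                if not redundant:
                    keep[z, y, x] = True
    return keep


@numba.njit(cache=True)
def _paint_spheres(out, cz, cy, cx, r2arr):  # pragma: no cover - jitted
    """Assign to every voxel the diameter of the largest covering sphere.

    A centre c with squared distance-transform value R2 covers lattice
    points v with |v - c|^2 <= R2 - 1 (the strict rule |v - c| < r in exact
    integer arithmetic); the assigned diameter is 2*sqrt(R2) - 1 voxels, so
    a slab t voxels thick maps to t and an isolated voxel to 1.
    """
    nz, ny, nx = out.shape
    for i in range(cz.shape[0]):
        r2 = r2arr[i]
        diam = np.float32(2.0 * np.sqrt(float(r2)) - 1.0)
        rint = int(np.floor(np.sqrt(float(r2 - 1)) + 1e-9))
        z0, y0, x0 = cz[i], cy[i], cx[i]
        for dz in range(-rint, rint + 1):
            z = z0 + dz
            if z < 0 or z >= nz:
                continue
            for dy in range(-rint, rint + 1):
                y = y0 + dy
                if y < 0 or y >= ny:
                    continue
                rem = r2 - 1 - dz * dz - dy * dy
                if rem < 0:
                    continue
                for dx in range(-rint, rint + 1):
                    x = x0 + dx
                    if x < 0 or x >= nx:
                        continue
                    if dx * dx <= rem and out[z, y, x] < diam:
                        out[z, y, x] = diam


def _local_thickness_voxels(binary: np.ndarray) -> np.ndarray:
    """Local thickness map in voxel units for a boolean array.

    Array borders behave as if the phase continued beyond them (the distance
    transform only sees background voxels inside the array).
    """
    fg = np.ascontiguousarray(binary.astype(bool))
    if not fg.any():
        raise ValueError("phase is empty: no foreground voxels")
    dist = ndimage.distance_transform_edt(fg)
    if not (~fg).any():
        # no background anywhere: thickness is unbounded; report grid diameter
        diam = float(np.linalg.norm(fg.shape))
        return np.full(fg.shape, 2 * diam - 1, dtype=np.float32)
    d2 = np.rint(dist * dist).astype(np.int64)
    keep = _ridge_mask(d2, _containment_tables(int(d2.max())))
    cz, cy, cx = np.nonzero(keep)
    order = np.argsort(d2[cz, cy, cx])[::-1]  # large spheres first
    cz, cy, cx = cz[order], cy[order], cx[order]
    out = np.zeros(fg.shape, dtype=np.float32)
    _paint_spheres(
        out,
        cz.astype(np.int64),
        cy.astype(np.int64),
        cx.astype(np.int64),
        d2[cz, cy, cx],
    )
    out[~fg] = 0.0
    return out


def local_thickness_map(binary: VoxelVolume) -> VoxelVolume:
    """Largest-inscribed-sphere thickness map (mm) of the foreground phase.

    Requires an isotropic grid; anisotropic stacks must be resampled first
    (the sphere model has no meaning on anisotropic voxels).
    """
    if not binary.is_isotropic:
        raise ValueError(
            "local thickness requires isotropic voxels; resample the stack "
            f"first (voxel_size={binary.voxel_size})"
        )
    b = binary.require_binary()
    out = _local_thickness_voxels(b) * binary.voxel_size[0]
    return binary.with_data(out)


def tbth_tbsp(binary: VoxelVolume, mask=None, phases=("bone", "marrow"), _crop_margin: int = 32):
    """Mean +/- sd local thickness of the bone phase (Tb.Th) and of the
    marrow/background phase (Tb.Sp), over the masked region, in mm.

    Returns ``((tbth_mean, tbth_sd), (tbsp_mean, tbsp_sd))``.  The sd is
    taken over voxels of the phase, not over individual trabeculae.
    ``phases`` selects which phases to measure (the marrow phase dominates
    the cost); a skipped phase reports NaN.
    """
    b = binary.require_binary()
    if mask is None:
        m = np.ones_like(b, dtype=bool)
    else:
        m = (mask.data if isinstance(mask, VoxelVolume) else np.asarray(mask)).astype(bool)
    results = []
    for name, phase in (("bone", b), ("marrow", ~b)):
        if name not in phases:
            results.append((float("nan"), float("nan")))
            continue
        if not (phase & m).any():
            raise ValueError("empty phase inside mask")
        vals = _phase_thickness_in_mask(phase, m, _crop_margin) * binary.voxel_size[0]
        results.append((float(vals.mean()), float(vals.std())))
    return tuple(results)


def _phase_thickness_in_mask(phase: np.ndarray, m: np.ndarray, margin: int = 32) -> np.ndarray:
    """Thickness values (voxel units) of phase voxels inside the mask.

    The map is computed on the mask bounding box plus an adaptive margin
    (grown to three times the largest sphere radius seen in the mask, at
    which point every sphere realising a masked voxel's thickness lies
    entirely inside the crop).  Crop borders that cut through the volume are
    padded with background, so truncation can only shrink spheres near the
    crop border, never inflate values inside the mask.
    """
    idx = [np.nonzero(m.any(axis=ax))[0] for ax in ((1, 2), (0, 2), (0, 1))]
    if not all(len(i) for i in idx):
        raise ValueError("empty mask")
    for _ in range(4):
        sl = tuple(
            slice(max(0, i[0] - margin), min(n, i[-1] + 1 + margin))
            for i, n in zip(idx, phase.shape)
        )
        whole = all(s.start == 0 and s.stop == n for s, n in zip(sl, phase.shape))
        sub = phase[sl]
        # an inscribed sphere containing a masked voxel lies entirely in that
        # voxel's connected component, so other components (e.g. the space
        # outside the cortical shell when measuring marrow) are irrelevant
        labels, n_lab = ndimage.label(sub, structure=np.ones((3, 3, 3), bool))
        if n_lab > 1:
            wanted = np.unique(labels[sub & m[sl]])
            sub = np.isin(labels, wanted[wanted > 0])
        if whole:
            tmap = _local_thickness_voxels(sub)
        else:
            pad = [
                (int(s.start > 0), int(s.stop < n))
                for s, n in zip(sl, phase.shape)
            ]
            padded = np.pad(sub, pad, mode="constant", constant_values=False)
            tmap = _local_thickness_voxels(padded)[
                tuple(slice(p[0], padded.shape[a] - p[1]) for a, p in enumerate(pad))
            ]
        sel = sub & m[sl]
        rmax = int(np.ceil(tmap[sel].max() / 2.0)) + 1
        if whole or 3 * rmax + 2 <= margin:
            return tmap[sel]
        margin = 3 * rmax + 2
    return tmap[sel]


# ---------------------------------------------------------------------------
# composite measurement
# ---------------------------------------------------------------------------

def measure_stack(
    volume: VoxelVolume,
    voi: CylindricalVOI,
    threshold: str | float = "isodata",
    per_slice: bool = False,
    phases=("bone", "marrow"),
) -> MorphometryResult:
    """Binarize a grayscale stack inside a cylindrical VOI and measure
    BV/TV, Tb.Th and Tb.Sp.

    One global IsoData threshold is derived per VOI (``threshold='isodata'``,
    the default); ``per_slice=True`` thresholds each axial slice separately;
    a numeric ``threshold`` is used as-is.  Anisotropic stacks (e.g. MDCT
    with thick slices) are resampled to isotropic voxels by linear
    interpolation before thickness measurement.
    """
    resampled = False
    if not volume.is_isotropic:
        pitch = min(volume.voxel_size)
        zoom = [v / pitch for v in volume.voxel_size]
        data = ndimage.zoom(volume.data.astype(np.float32), zoom, order=1)
        volume = VoxelVolume(data, (pitch,) * 3, volume.origin)
        resampled = True
    mask = voxelize_voi(voi, volume)
    # the whole (resampled) stack is binarized; the VOI only scopes the
    # threshold estimation and the statistics, so trabeculae and marrow
    # spaces are not truncated at the VOI wall
    if isinstance(threshold, str):
        if threshold != "isodata":
            raise ValueError(f"unknown threshold policy {threshold!r}")
        if per_slice:
            binary = np.zeros(volume.shape, dtype=np.uint8)
            thr_used = []
            for z in range(volume.shape[0]):
                if not mask[z].any():
                    continue
                t = isodata_threshold(volume.data[z], mask[z])
                binary[z] = volume.data[z] > t
                thr_used.append(t)
            thr = float(np.mean(thr_used))
        else:
            thr = isodata_threshold(volume, mask)
            binary = (volume.data > thr).astype(np.uint8)
    else:
        thr = float(threshold)
        binary = (volume.data > thr).astype(np.uint8)
    bvol = volume.with_data(binary)
    frac = bvtv(bvol, mask)
    (tbth, tbth_sd), (tbsp, tbsp_sd) = tbth_tbsp(bvol, mask, phases=phases)
    return MorphometryResult(
        bvtv=frac,
        tbth_mm=tbth,
        tbth_sd_mm=tbth_sd,
        tbsp_mm=tbsp,
        tbsp_sd_mm=tbsp_sd,
        threshold_used=thr,
        voi=voi,
        n_foreground=int((binary.astype(bool) & mask).sum()),
        n_total=int(mask.sum()),
        meta={
            "mode": "3d",
            "per_slice_threshold": per_slice,
            "resampled_isotropic": resampled,
            "voxel_size_mm": volume.voxel_size,
        },
    )
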