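"""Voxel grids, NCI field evaluation, interaction-point selection and integration.

For one fragment pair the workflow is: build an axis-aligned uniform grid
around both fragments, evaluate the promolecular density of each fragment and
of their union on the grid, keep the voxels that look like an interfragment
noncovalent contact (low rho, low reduced gradient s, meaningful density from
*both* fragments), classify each kept voxel by sign(lambda2)*rho against the
+-0.02 a.u. thresholds and integrate the density over each class:

    attractive :  sign(lambda2)*rho < -0.02
    vdW        : -0.02 <= sign(lambda2)*rho <= +0.02   (ties go to vdW)
    repulsive  :  sign(lambda2)*rho > +0.02

The three integrals partition the total exactly.  Defaults (spacing 0.1 bohr,
margin 2 angstrom, rho < 0.05 a.u., s < 1.0, fragment share >= 0.05) follow
common practice for promolecular NCI integration; only the +-0.02 thresholds
are part of the classification definition itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .promolecular import (
    BOHR_PER_ANGSTROM,
    RDG_PREFACTOR,
    AtomicDensityModel,
    default_density_table,
    evaluate_field_many,
)

__all__ = [
    "NCIParams",
    "GridSpec",
    "NCIGrid",
    "PairIntegrals",
    "build_pair_grid",
    "evaluate_nci_fields",
    "select_interaction_points",
    "classify_and_integrate",
    "pair_integrals",
    "connected_components",
    "write_cube",
    "read_cube",
]

#: voxels with less density than this are treated as vacuum
DENSITY_FLOOR = 1e-10
#: voxels closer than this to a nucleus are excluded from NCI masks
NUCLEUS_EXCLUSION_BOHR = 1e-3
#: evaluation chunk (voxels) to bound peak memory
_CHUNK = 262_144


@dataclass(frozen=True)
class NCIParams:
    """Tunable parameters of the NCI integration for one fragment pair."""

    spacing: float = 0.1          # bohr
    margin: float = 2.0           # angstrom, padding around the pair bounding box
    rho_cut: float = 0.05         # a.u., upper density bound of the NCI region
    s_cut: float = 1.0            # reduced-gradient bound
    frag_fraction: float = 0.05   # minimum density share of the minor fragment
    thresholds: tuple[float, float] = (-0.02, 0.02)  # sign(lambda2)*rho class bounds
    prefilter_distance: float = 12.0  # angstrom; skip pairs farther than this
    #: subvoxel quadrature resolution (bohr) near mask boundaries; the voxel
    #: spacing controls scan coverage while integrals are always resolved to
    #: this fixed resolution, making them insensitive to the nominal spacing.
    #: None integrates on bare voxel centers.
    refine_resolution: float | None = 0.025

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.margin <= 0:
            raise ValueError("spacing and margin must be positive")
        if not (0.0 < self.frag_fraction < 0.5):
            raise ValueError("frag_fraction must be in (0, 0.5)")
        lo, hi = self.thresholds
        if not lo < hi:
            raise ValueError("thresholds must be increasing")
        if self.refine_resolution is not None and self.refine_resolution <= 0:
            raise ValueError("refine_resolution must be positive or None")

    @property
    def refine_factor(self) -> int:
        """Subvoxel samples per axis: ceil(spacing / refine_resolution)."""
        if self.refine_resolution is None:
            return 1
        return max(1, int(np.ceil(self.spacing / self.refine_resolution)))


@dataclass(frozen=True)
class GridSpec:
    """Uniform isotropic voxel grid: origin (bohr), spacing (bohr), shape."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(n < 2 for n in self.shape):
            raise ValueError(f"grid shape must be >= 2 per axis, got {self.shape}")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def points_chunk(self, start: int, stop: int) -> np.ndarray:
        """Cartesian coordinates (angstrom) of flat voxel indices [start, stop)."""
        idx = np.arange(start, stop)
        nx, ny, nz = self.shape
        iz = idx % nz
        iy = (idx // nz) % ny
        ix = idx // (ny * nz)
        pts = np.stack([ix, iy, iz], axis=1) * self.spacing + np.asarray(self.origin)
        return pts / BOHR_PER_ANGSTROM

    def points(self) -> np.ndarray:
        return self.points_chunk(0, self.n_voxels)


@dataclass
class NCIGrid:
    """Per-voxel NCI fields on a grid (flat arrays in C order over the shape)."""

    spec: GridSpec
    rho_total: np.ndarray
    rho_fragA: np.ndarray
    rho_fragB: np.ndarray
    s: np.ndarray
    lambda2: np.ndarray
    signed_rho: np.ndarray
    near_nucleus: np.ndarray  # bool; voxels inside the nuclear exclusion radius


@dataclass(frozen=True)
class PairIntegrals:
    """The three NCI density integrals (electrons) for one pair in one frame."""

    frame_index: int
    pair: tuple[str, str]
    attractive: float
    vdw: float
    repulsive: float
    total: float

    def __post_init__(self) -> None:
        for name in ("attractive", "vdw", "repulsive", "total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} integral must be >= 0")
        parts = self.attractive + self.vdw + self.repulsive
        scale = max(self.total, 1.0)
        if abs(parts - self.total) > 1e-12 * scale:
            raise ValueError("attractive + vdw + repulsive must equal total")


def _atom_array(fragment) -> tuple[list[str], np.ndarray]:
    """Accept a Fragment-like object or a list of (element, xyz) pairs."""
    if hasattr(fragment, "elements"):
        return list(fragment.elements), np.asarray(fragment.coords, dtype=float)
    elements = [el for el, _ in fragment]
    coords = np.asarray([xyz for _, xyz in fragment], dtype=float)
    return elements, coords


def _atoms_list(fragment) -> list[tuple[str, np.ndarray]]:
    elements, coords = _atom_array(fragment)
    return list(zip(elements, coords))


def build_pair_grid(fragmentA, fragmentB, spacing: float = 0.1, margin: float = 2.0) -> GridSpec:
    """Axis-aligned bounding box of both fragments plus ``margin`` (angstrom).

    ``spacing`` is in bohr.  Every atom lies at least ``margin`` inside the box
    and the shape is the smallest one achieving that at the given spacing.
    """
    if spacing <= 0 or margin <= 0:
        raise ValueError("spacing and margin must be positive")
    _, ca = _atom_array(fragmentA)
    _, cb = _atom_array(fragmentB)
    if ca.size == 0 or cb.size == 0:
        raise ValueError("both fragments must contain atoms")
    coords = np.vstack([ca, cb]) * BOHR_PER_ANGSTROM
    lo = coords.min(axis=0) - margin * BOHR_PER_ANGSTROM
    hi = coords.max(axis=0) + margin * BOHR_PER_ANGSTROM
    shape = tuple(int(max(2, np.ceil((h - l) / spacing) + 1)) for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(lo), spacing=spacing, shape=shape)


def _near_nucleus_mask(points_ang: np.ndarray, coords_ang: np.ndarray) -> np.ndarray:
    cutoff = NUCLEUS_EXCLUSION_BOHR / BOHR_PER_ANGSTROM
    near = np.zeros(points_ang.shape[0], dtype=bool)
    for c in coords_ang:
        d2 = np.einsum("ij,ij->i", points_ang - c, points_ang - c)
        near |= d2 < cutoff**2
    return near


def evaluate_nci_fields(
    spec: GridSpec,
    fragmentA,
    fragmentB,
    *,
    table: dict[str, AtomicDensityModel] | None = None,
    floor: float = DENSITY_FLOOR,
) -> NCIGrid:
    """Fill all per-voxel NCI fields for a fragment pair on ``spec``.

    Voxels with rho below ``floor`` are masked out of s (set to +inf).
    """
    table = table or default_density_table()
    atoms_a = _atoms_list(fragmentA)
    atoms_b = _atoms_list(fragmentB)
    if not atoms_a or not atoms_b:
        raise ValueError("both fragments must contain atoms")
    all_coords = np.asarray([xyz for _, xyz in atoms_a + atoms_b], dtype=float)

    n = spec.n_voxels
    rho_a = np.empty(n)
    rho_b = np.empty(n)
    lam2 = np.empty(n)
    grad_sq = np.empty(n)
    near = np.empty(n, dtype=bool)

    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        pts = spec.points_chunk(start, stop)
        ra, ga, ha = evaluate_field_many(atoms_a, pts, table=table, cusp_check=False)
        rb, gb, hb = evaluate_field_many(atoms_b, pts, table=table, cusp_check=False)
        rho_a[start:stop] = ra
        rho_b[start:stop] = rb
        g = ga + gb
        grad_sq[start:stop] = np.einsum("ij,ij->i", g, g)
        lam2[start:stop] = np.linalg.eigvalsh(ha + hb)[:, 1]
        near[start:stop] = _near_nucleus_mask(pts, all_coords)

    rho_tot = rho_a + rho_b
    s = np.full(n, np.inf)
    ok = rho_tot >= floor
    s[ok] = np.sqrt(grad_sq[ok]) / (RDG_PREFACTOR * rho_tot[ok] ** (4.0 / 3.0))
    signed = np.where(lam2 < 0, -1.0, 1.0) * rho_tot
    return NCIGrid(spec=spec, rho_total=rho_tot, rho_fragA=rho_a, rho_fragB=rho_b,
                   s=s, lambda2=lam2, signed_rho=signed, near_nucleus=near)


def select_interaction_points(
    grid: NCIGrid,
    rho_cut: float = 0.05,
    s_cut: float = 1.0,
    frag_fraction: float = 0.05,
    *,
    floor: float = DENSITY_FLOOR,
) -> np.ndarray:
    """Boolean voxel mask of interfragment NCI points.

    True iff floor < rho_total < rho_cut, s < s_cut and the minor fragment
    contributes at least ``frag_fraction`` of the total density.
    """
    if not (0.0 < frag_fraction < 0.5):
        raise ValueError("frag_fraction must be in (0, 0.5)")
    if rho_cut <= 0 or s_cut <= 0:
        raise ValueError("rho_cut and s_cut must be positive")
    rho = grid.rho_total
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_share = np.minimum(grid.rho_fragA, grid.rho_fragB) / np.maximum(rho, floor)
    mask = (
        (rho > floor)
        & (rho < rho_cut)
        & (grid.s < s_cut)
        & (minor_share >= frag_fraction)
        & ~grid.near_nucleus
    )
    return mask


def classify_and_integrate(
    grid: NCIGrid,
    mask: np.ndarray,
    thresholds: tuple[float, float] = (-0.02, 0.02),
    *,
    frame_index: int = -1,
    pair: tuple[str, str] = ("A", "B"),
) -> PairIntegrals:
    """Integrate rho over the masked voxels, split by sign(lambda2)*rho class.

    An empty mask yields all-zero integrals.  Values exactly at a threshold
    are assigned to the vdW class so the three classes partition the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.rho_total.shape:
        raise ValueError("mask shape does not match grid")
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must be increasing")
    sr = grid.signed_rho[mask]
    rho = grid.rho_total[mask]
    dv = grid.spec.voxel_volume
    attractive = float(rho[sr < lo].sum() * dv)
    vdw = float(rho[(sr >= lo) & (sr <= hi)].sum() * dv)
    repulsive = float(rho[sr > hi].sum() * dv)
    return PairIntegrals(
        frame_index=frame_index,
        pair=pair,
        attractive=attractive,
        vdw=vdw,
        repulsive=repulsive,
        total=attractive + vdw + repulsive,
    )


def pair_integrals(
    fragmentA,
    fragmentB,
    params: NCIParams = NCIParams(),
    *,
    table: dict[str, AtomicDensityModel] | None = None,
    frame_index: int = -1,
    pair: tuple[str, str] | None = None,
) -> PairIntegrals:
    """NCI integrals for one fragment pair: the production fast path.

    Two-phase quadrature.  Phase 1 scans the voxel grid (density and gradient
    only, chunked) and keeps the voxels passing the interaction-point
    selection.  Phase 2 re-integrates the kept voxels plus a one-voxel
    dilation shell at subvoxel resolution (``params.refine_resolution``):
    every candidate voxel is subdivided, the full selection is re-applied per
    subpoint, and the Hessian is evaluated only on subpoints that pass.  The
    nominal spacing therefore controls scan coverage while the integrals are
    resolved to a fixed fine resolution, making them insensitive to the
    nominal spacing.  With ``refine_resolution=None`` (factor 1) the result is
    identical to evaluate_nci_fields + select_interaction_points +
    classify_and_integrate on bare voxel centers.
    """
    table = table or default_density_table()
    atoms_a = _atoms_list(fragmentA)
    atoms_b = _atoms_list(fragmentB)
    all_coords = np.asarray([xyz for _, xyz in atoms_a + atoms_b], dtype=float)
    spec = build_pair_grid(fragmentA, fragmentB, spacing=params.spacing, margin=params.margin)

    def fields(points_ang: np.ndarray):
        ra, ga, _ = evaluate_field_many(atoms_a, points_ang, table=table,
                                        want_hessian=False, cusp_check=False)
        rb, gb, _ = evaluate_field_many(atoms_b, points_ang, table=table,
                                        want_hessian=False, cusp_check=False)
        rho = ra + rb
        g = ga + gb
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.sqrt(np.einsum("ij,ij->i", g, g)) / (
                RDG_PREFACTOR * np.maximum(rho, DENSITY_FLOOR) ** (4.0 / 3.0)
            )
            minor = np.minimum(ra, rb) / np.maximum(rho, DENSITY_FLOOR)
        keep = (
            (rho > DENSITY_FLOOR)
            & (rho < params.rho_cut)
            & (s < params.s_cut)
            & (minor >= params.frag_fraction)
        )
        if keep.any():
            keep[keep] &= ~_near_nucleus_mask(points_ang[keep], all_coords)
        return rho, keep

    # phase 1: voxel-level scan
    n = spec.n_voxels
    voxel_idx: list[np.ndarray] = []
    voxel_rho: list[np.ndarray] = []
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        rho, keep = fields(spec.points_chunk(start, stop))
        if keep.any():
            voxel_idx.append(np.nonzero(keep)[0] + start)
            voxel_rho.append(rho[keep])

    pair_ids = pair or ("A", "B")
    if not voxel_idx:
        return PairIntegrals(frame_index, pair_ids, 0.0, 0.0, 0.0, 0.0)

    k = params.refine_factor
    if k == 1:
        pts = _flat_points(spec, np.concatenate(voxel_idx))
        rho = np.concatenate(voxel_rho)
        dv = spec.voxel_volume
    else:
        # phase 2: dilate by one voxel and re-sample at subvoxel resolution
        flat = _dilate_flat(np.concatenate(voxel_idx), spec.shape)
        centers_b = _flat_points(spec, flat) * BOHR_PER_ANGSTROM
        off = ((np.arange(k) + 0.5) / k - 0.5) * spec.spacing
        sub = np.stack(np.meshgrid(off, off, off, indexing="ij"), axis=-1).reshape(-1, 3)
        pts_list: list[np.ndarray] = []
        rho_list: list[np.ndarray] = []
        batch = max(1, _CHUNK // (k**3))
        for start in range(0, len(centers_b), batch):
            c = centers_b[start : start + batch]
            p = (c[:, None, :] + sub[None, :, :]).reshape(-1, 3) / BOHR_PER_ANGSTROM
            rho, keep = fields(p)
            if keep.any():
                pts_list.append(p[keep])
                rho_list.append(rho[keep])
        if not pts_list:
            return PairIntegrals(frame_index, pair_ids, 0.0, 0.0, 0.0, 0.0)
        pts = np.vstack(pts_list)
        rho = np.concatenate(rho_list)
        dv = (spec.spacing / k) ** 3

    # classification: Hessian only on the points that passed selection
    lam2 = np.empty(len(pts))
    for start in range(0, len(pts), _CHUNK):
        stop = min(start + _CHUNK, len(pts))
        _, _, ha = evaluate_field_many(atoms_a, pts[start:stop], table=table, cusp_check=False)
        _, _, hb = evaluate_field_many(atoms_b, pts[start:stop], table=table, cusp_check=False)
        lam2[start:stop] = np.linalg.eigvalsh(ha + hb)[:, 1]
    signed = np.where(lam2 < 0, -1.0, 1.0) * rho
    lo, hi = params.thresholds
    attractive = float(rho[signed < lo].sum() * dv)
    vdw = float(rho[(signed >= lo) & (signed <= hi)].sum() * dv)
    repulsive = float(rho[signed > hi].sum() * dv)
    return PairIntegrals(frame_index, pair_ids, attractive, vdw, repulsive,
                         attractive + vdw + repulsive)


def _flat_points(spec: GridSpec, flat: np.ndarray) -> np.ndarray:
    """Cartesian coordinates (angstrom) of arbitrary flat voxel indices."""
    nx, ny, nz = spec.shape
    iz = flat % nz
    iy = (flat // nz) % ny
    ix = flat // (ny * nz)
    pts = np.stack([ix, iy, iz], axis=1) * spec.spacing + np.asarray(spec.origin)
    return pts / BOHR_PER_ANGSTROM


def _dilate_flat(flat: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """26-connected one-voxel dilation of a flat voxel index set."""
    nx, ny, nz = shape
    iz = flat % nz
    iy = (flat // nz) % ny
    ix = flat // (ny * nz)
    out = []
    for dx in (-1, 0, 1):
        jx = ix + dx
        okx = (jx >= 0) & (jx < nx)
        for dy in (-1, 0, 1):
            jy = iy + dy
            oky = okx & (jy >= 0) & (jy < ny)
            for dz in (-1, 0, 1):
                jz = iz + dz
                ok = oky & (jz >= 0) & (jz < nz)
                out.append((jx[ok] * ny + jy[ok]) * nz + jz[ok])
    return np.unique(np.concatenate(out))


def connected_components(grid: NCIGrid, mask: np.ndarray) -> np.ndarray:
    """Optional diagnostic: label 26-connected basins of a voxel mask."""
    from scipy import ndimage

    labels, _ = ndimage.label(mask.reshape(grid.spec.shape), structure=np.ones((3, 3, 3)))
    return labels


# ---------------------------------------------------------------------------
# Gaussian cube export (values in atomic units, z fastest as in the format)

def write_cube(spec: GridSpec, values: np.ndarray, atoms, path, comment: str = "ncitraj field") -> None:
    """Write a scalar grid field to a Gaussian cube file.

    ``atoms`` are (element, xyz angstrom) pairs or a Fragment; coordinates and
    voxel vectors are stored in bohr per the format.
    """
    from .fragments_io import ELEMENT_NUMBERS

    elements, coords = _atom_array(atoms)
    coords_b = coords * BOHR_PER_ANGSTROM
    vals = np.asarray(values, dtype=float).reshape(spec.shape)
    nx, ny, nz = spec.shape
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("promolecular NCI field (a.u.)\n")
        ox, oy, oz = spec.origin
        fh.write(f"{len(elements):5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}\n")
        fh.write(f"{nx:5d} {spec.spacing:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {spec.spacing:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {spec.spacing:12.6f}\n")
        for el, (x, y, z) in zip(elements, coords_b):
            zn = ELEMENT_NUMBERS.get(el.capitalize(), 0)
            fh.write(f"{zn:5d} {float(zn):12.6f} {x:12.6f} {y:12.6f} {z:12.6f}\n")
        flat = vals.reshape(nx * ny, nz)
        for line in flat:
            for i in range(0, nz, 6):
                fh.write("".join(f"{v:13.5E}" for v in line[i : i + 6]) + "\n")


def read_cube(path) -> tuple[GridSpec, np.ndarray, list[tuple[int, np.ndarray]]]:
    """Read a cube file written by :func:`write_cube` (orthogonal axes only)."""
    with open(path) as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        natoms = int(parts[0])
        origin = tuple(float(x) for x in parts[1:4])
        axes = []
        shape = []
        for _ in range(3):
            parts = fh.readline().split()
            shape.append(int(parts[0]))
            axes.append([float(x) for x in parts[1:4]])
        spacing = axes[0][0]
        if not (
            np.allclose(axes[0], [spacing, 0, 0])
            and np.allclose(axes[1], [0, spacing, 0])
            and np.allclose(axes[2], [0, 0, spacing])
        ):
            raise ValueError("only isotropic orthogonal cube grids are supported")
        atoms = []
        for _ in range(natoms):
            parts = fh.readline().split()
            atoms.append((int(parts[0]), np.array([float(x) for x in parts[2:5]])))
        data = np.array(fh.read().split(), dtype=float)
    spec = GridSpec(origin=origin, spacing=spacing, shape=tuple(shape))
    return spec, data.reshape(spec.shape), atoms
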