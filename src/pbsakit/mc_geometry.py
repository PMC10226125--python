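"""Monte-Carlo probe-sampling estimators for molecular surface area and volume.

A spherical probe of radius ``r_p`` defines three quantities for a set of vdW
spheres:

* **ASA** — accessible surface area: the area of the locus of probe centres in
  contact with the solute, i.e. the union boundary of the probe-inflated
  spheres.  Estimated by drawing points uniformly on each atom's inflated
  sphere and counting the fraction not buried inside any other inflated
  sphere (per-atom stratified sampling).
* **PCAV** — probe-centred accessible volume: the volume available to the
  probe *centre* (outside every inflated sphere).  The *molecular* PCAV volume
  is ``cell_volume − pore_volume``, mirroring the subtraction of pore volume
  from the total cell volume used when a porous-material code is pointed at a
  solute.
* **POAV** — probe-occupiable accessible volume: the volume any part of the
  probe can occupy (outside every vdW sphere and within ``r_p`` of some
  probe-centred-accessible location).  Its molecular volume is smaller than
  PCAV's and bounds the vdW volume from above.

For ``r_p → 0`` all three collapse onto the vdW surface/volume.

All sampling is done in structure-local coordinates (relative to the cell's
minimum corner) with a counter-based Philox generator whose per-atom
substreams are keyed by ``(seed, stream, atom index)``, so estimates are
bit-reproducible and independent of iteration order, and rigid translations
of structure-plus-cell by exactly representable shifts leave results
bit-identical.

The probe-occupiable membership test asks whether the nearest
probe-centred-accessible point lies within ``r_p`` of the sample point.  That
nearest point sits on the boundary of the inflated-sphere union, which
decomposes into faces (single spheres), edges (pairwise intersection circles)
and vertices (triple intersections); each stratum's nearest-point candidate is
closed-form, so the membership test is evaluated exactly (no reachability /
percolation analysis is performed — interior voids count as pore).  The
deterministic :func:`grid_oracle` recomputes the same quantities by lattice
counting plus a Euclidean distance transform and serves as an independent
cross-check in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ResolutionError
from .structure_io import MolecularStructure, check_cell

__all__ = [
    "ProbeSpec",
    "SurfVolResult",
    "mc_asa",
    "mc_pore_volume",
    "molecular_volume",
    "surf_vol",
    "grid_oracle",
]

_VOL_CHUNK = 200_000


@dataclass(frozen=True)
class ProbeSpec:
    """Probe radius (Å), number of MC samples and RNG seed."""

    probe_radius: float = 1.4
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.probe_radius < 0:
            raise GeometryError("probe radius must be >= 0")
        if self.n_samples < 1:
            raise GeometryError("n_samples must be >= 1")


@dataclass(frozen=True)
class SurfVolResult:
    """ASA plus the three volume definitions with MC standard errors."""

    asa: float
    asa_stderr: float
    pcav_molecular_volume: float
    pcav_stderr: float
    poav_molecular_volume: float
    poav_stderr: float
    vdw_volume: float
    vdw_stderr: float
    n_samples: int
    seed: int


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    """Counter-based Philox generator for substream (seed, stream, index)."""
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, stream, index])))


def _local(structure: MolecularStructure):
    """Centers shifted to cell-local coordinates, plus the cell extent."""
    centers = structure.centers - structure.cell_min
    extent = structure.cell_max - structure.cell_min
    return centers, extent


def mc_asa(structure: MolecularStructure, probe: ProbeSpec) -> tuple[float, float]:
    """Monte-Carlo accessible surface area.

    Each atom's probe-inflated sphere receives an equal share of the sample
    budget; a surface point is accessible iff it lies outside every *other*
    inflated sphere.  Returns ``(area, stderr)`` in Å²; the stderr combines
    per-atom binomial variances.
    """
    if np.any(structure.radii <= 0):
        raise GeometryError("radii unassigned; call assign_radii first")
    centers, _ = _local(structure)
    inflated = structure.radii + probe.probe_radius
    n_atoms = structure.n_atoms
    n_per_atom = max(1, math.ceil(probe.n_samples / n_atoms))

    total = 0.0
    var = 0.0
    for i in range(n_atoms):
        rng = _rng(probe.seed, 0, i)
        # uniform points on the unit sphere
        u = rng.standard_normal((n_per_atom, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = centers[i] + inflated[i] * u
        accessible = np.ones(n_per_atom, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 >= inflated[j] ** 2
        p = accessible.mean()
        sphere_area = 4.0 * math.pi * inflated[i] ** 2
        total += sphere_area * p
        var += sphere_area**2 * p * (1.0 - p) / n_per_atom
    return float(total), float(math.sqrt(var))


_GEOM_TOL = 1e-9


def _union_vertices(centers, inflated) -> np.ndarray:
    """Accessible triple-intersection vertices of the inflated-sphere union.

    A vertex is a point lying on three inflated spheres simultaneously and
    outside every other one; together with the sphere surfaces (faces) and the
    pairwise intersection circles (edges) they stratify the boundary of the
    probe-centred-accessible region.
    """
    n = len(centers)
    verts = []
    for i in range(n):
        for j in range(i + 1, n):
            d_ij = np.linalg.norm(centers[j] - centers[i])
            if not (abs(inflated[i] - inflated[j]) < d_ij < inflated[i] + inflated[j]):
                continue
            ex = (centers[j] - centers[i]) / d_ij
            for k in range(j + 1, n):
                rel = centers[k] - centers[i]
                iv = float(ex @ rel)
                ey = rel - iv * ex
                jv = float(np.linalg.norm(ey))
                if jv < 1e-12:
                    continue
                ey = ey / jv
                ez = np.cross(ex, ey)
                x = (d_ij**2 + inflated[i] ** 2 - inflated[j] ** 2) / (2 * d_ij)
                y = (inflated[i] ** 2 - inflated[k] ** 2 + iv**2 + jv**2 - 2 * iv * x) / (
                    2 * jv
                )
                z2 = inflated[i] ** 2 - x * x - y * y
                if z2 <= 0:
                    continue
                z = math.sqrt(z2)
                base = centers[i] + x * ex + y * ey
                verts.append(base + z * ez)
                verts.append(base - z * ez)
    if not verts:
        return np.zeros((0, 3))
    verts = np.asarray(verts)
    keep = np.ones(len(verts), dtype=bool)
    for a in range(len(centers)):
        d2 = np.sum((verts - centers[a]) ** 2, axis=1)
        keep &= d2 >= (inflated[a] - _GEOM_TOL) ** 2
    return verts[keep]


def _poav_mask(pts, outside_vdw, centers, inflated, r_p, vertices) -> np.ndarray:
    """Probe-occupiable membership for points already outside the vdW spheres.

    A point x (outside vdW, inside some inflated sphere) is occupiable iff the
    nearest probe-centred-accessible point lies within r_p.  That nearest
    point sits on the boundary of the inflated-sphere union, which decomposes
    into faces (single-sphere surfaces), edges (pairwise intersection circles)
    and vertices (triple intersections); the candidate nearest point on each
    stratum is closed-form, so the test is exact up to the _GEOM_TOL slack on
    boundary classification.
    """
    n_pts = len(pts)
    ok = np.zeros(n_pts, dtype=bool)
    idx = np.flatnonzero(outside_vdw)
    if idx.size == 0:
        return ok
    sub = pts[idx]
    n_atoms = len(centers)

    def accessible(cands):
        # cands: (m, k, 3) candidate probe centres for m points
        acc = np.ones(cands.shape[:2], dtype=bool)
        for a in range(n_atoms):
            d2 = np.sum((cands - centers[a]) ** 2, axis=2)
            acc &= d2 >= (inflated[a] - _GEOM_TOL) ** 2
        return acc.any(axis=1)

    # face candidates: radial projection of x onto each inflated sphere
    diff = sub[:, None, :] - centers[None, :, :]  # (m, n_atoms, 3)
    dist = np.linalg.norm(diff, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = diff / dist[:, :, None]
    unit = np.nan_to_num(unit)
    surf = centers[None, :, :] + inflated[None, :, None] * unit
    near = np.abs(dist - inflated[None, :]) <= r_p + _GEOM_TOL
    acc = np.ones(surf.shape[:2], dtype=bool)
    for a in range(n_atoms):
        d2 = np.sum((surf - centers[a]) ** 2, axis=2)
        acc &= d2 >= (inflated[a] - _GEOM_TOL) ** 2
    found = (near & acc).any(axis=1)

    # edge candidates: nearest point on each pairwise intersection circle
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            cij = centers[j] - centers[i]
            d = float(np.linalg.norm(cij))
            ri, rj = inflated[i], inflated[j]
            if not (abs(ri - rj) < d < ri + rj):
                continue
            u = cij / d
            a_off = (d * d + ri * ri - rj * rj) / (2.0 * d)
            rho = math.sqrt(max(ri * ri - a_off * a_off, 0.0))
            ccen = centers[i] + a_off * u
            v = sub - ccen
            v_perp = v - (v @ u)[:, None] * u
            norm = np.linalg.norm(v_perp, axis=1)
            good = (norm > 1e-12) & ~found
            if not good.any():
                continue
            y = ccen + rho * v_perp[good] / norm[good, None]
            near = np.linalg.norm(y - sub[good], axis=1) <= r_p + _GEOM_TOL
            acc = np.ones(len(y), dtype=bool)
            for a in range(n_atoms):
                d2 = np.sum((y - centers[a]) ** 2, axis=1)
                acc &= d2 >= (inflated[a] - _GEOM_TOL) ** 2
            upd = np.zeros(len(sub), dtype=bool)
            upd[good] = near & acc
            found |= upd

    # vertex candidates: any accessible triple-intersection point within r_p
    if len(vertices) and not found.all():
        todo = np.flatnonzero(~found)
        d2 = np.sum((sub[todo, None, :] - vertices[None, :, :]) ** 2, axis=2)
        found[todo] = d2.min(axis=1) <= (r_p + _GEOM_TOL) ** 2
    ok[idx] = found
    return ok


def _volume_masks(structure, probe, n, seed_stream=1):
    """Draw n uniform cell points; return per-point indicator masks.

    Masks (pcav, poav, outside_vdw) are nested: pcav ⊆ poav ⊆ outside_vdw,
    which enforces the volume ordering sample-by-sample.
    """
    check_cell(structure, probe.probe_radius)
    centers, extent = _local(structure)
    inflated = structure.radii + probe.probe_radius
    rng = _rng(probe.seed, seed_stream)
    vertices = _union_vertices(centers, inflated) if probe.probe_radius > 0 else None
    pcav_hits = 0
    poav_hits = 0
    vdw_out_hits = 0
    drawn = 0
    while drawn < n:
        m = min(_VOL_CHUNK, n - drawn)
        pts = rng.random((m, 3)) * extent
        d2 = np.sum((pts[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        outside_vdw = np.all(d2 >= structure.radii[None, :] ** 2, axis=1)
        pcav = np.all(d2 >= inflated[None, :] ** 2, axis=1)
        if probe.probe_radius == 0.0:
            poav = pcav
        else:
            poav = pcav | _poav_mask(
                pts, outside_vdw & ~pcav, centers, inflated, probe.probe_radius, vertices
            )
        pcav_hits += int(pcav.sum())
        poav_hits += int(poav.sum())
        vdw_out_hits += int(outside_vdw.sum())
        drawn += m
    return pcav_hits, poav_hits, vdw_out_hits, drawn


def _binomial(hits, n, volume):
    p = hits / n
    return volume * p, volume * math.sqrt(p * (1.0 - p) / n)


def mc_pore_volume(
    structure: MolecularStructure, probe: ProbeSpec, mode: str = "probe_centered"
) -> tuple[float, float]:
    """Monte-Carlo pore (accessible) volume of the sampling cell, Å³.

    ``probe_centered``: a point counts iff its distance to every atom centre is
    at least ``r_i + r_p``.  ``probe_occupiable``: a point counts iff it lies
    outside every vdW sphere and within ``r_p`` of some probe-centred-
    accessible location.  Interior voids count as pore in both modes (no
    reachability analysis).  Returns ``(volume, stderr)``.
    """
    if mode not in ("probe_centered", "probe_occupiable"):
        raise GeometryError(f"unknown volume mode {mode!r}")
    pcav, poav, _, n = _volume_masks(structure, probe, probe.n_samples)
    hits = pcav if mode == "probe_centered" else poav
    return _binomial(hits, n, structure.cell_volume)


def molecular_volume(
    structure: MolecularStructure, probe: ProbeSpec, mode: str = "probe_centered"
) -> tuple[float, float]:
    """Molecular volume = cell volume − pore volume (same stderr), Å³.

    The subtraction removes the cell-size dependence: this is the quantity fed
    to the binding-energy estimators in place of a solvent-accessible volume.
    """
    pore, err = mc_pore_volume(structure, probe, mode)
    return structure.cell_volume - pore, err


def surf_vol(structure: MolecularStructure, probe: ProbeSpec) -> SurfVolResult:
    """ASA, PCAV/POAV molecular volumes and vdW volume in one pass.

    All three volume indicators share the same sample points, so the ordering
    ``vdw ≤ POAV ≤ PCAV`` (molecular volumes) holds deterministically.
    """
    asa, asa_err = mc_asa(structure, probe)
    pcav, poav, vdw_out, n = _volume_masks(structure, probe, probe.n_samples)
    v = structure.cell_volume
    pcav_pore, pcav_err = _binomial(pcav, n, v)
    poav_pore, poav_err = _binomial(poav, n, v)
    vdw_pore, vdw_err = _binomial(vdw_out, n, v)
    return SurfVolResult(
        asa=asa,
        asa_stderr=asa_err,
        pcav_molecular_volume=v - pcav_pore,
        pcav_stderr=pcav_err,
        poav_molecular_volume=v - poav_pore,
        poav_stderr=poav_err,
        vdw_volume=v - vdw_pore,
        vdw_stderr=vdw_err,
        n_samples=probe.n_samples,
        seed=probe.seed,
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def grid_oracle(
    structure: MolecularStructure,
    probe: ProbeSpec,
    resolution: float = 0.05,
    quadrature_points: int = 20_000,
) -> SurfVolResult:
    """Deterministic lattice/quadrature reference for ASA, PCAV, POAV and vdW volume.

    Volumes by voxel counting on a lattice of the given spacing; the
    probe-occupiable region is computed *exactly* (up to voxelisation) as the
    set of outside-vdW voxels whose Euclidean distance to the probe-centred-
    accessible region is at most ``r_p`` (via a distance transform).  Area by
    fixed Fibonacci-spiral quadrature on each inflated sphere.  Intended for
    validation; cost grows as (cell/resolution)³.
    """
    if resolution <= 0:
        raise ResolutionError("resolution must be positive")
    check_cell(structure, probe.probe_radius)
    centers, extent = _local(structure)
    radii = structure.radii
    inflated = radii + probe.probe_radius
    shape = tuple(int(math.floor(e / resolution)) for e in extent)
    min_r = radii.min()
    if (4.0 / 3.0) * math.pi * min_r**3 / resolution**3 < 10:
        raise ResolutionError(
            f"resolution {resolution} Å too coarse: smallest atom (r={min_r:.2f}) "
            "would contain fewer than 10 lattice points"
        )

    # voxel centres at (i + 0.5) * res
    inside_vdw = np.zeros(shape, dtype=bool)
    inside_inflated = np.zeros(shape, dtype=bool)
    axes = [
        (np.arange(s, dtype=float) + 0.5) * resolution for s in shape
    ]
    for c, r_v, r_i in zip(centers, radii, inflated):
        _fill_sphere(inside_vdw, axes, c, r_v, resolution)
        _fill_sphere(inside_inflated, axes, c, r_i, resolution)
    pcav_region = ~inside_inflated
    if probe.probe_radius == 0.0:
        poav_region = pcav_region
    else:
        dist = ndimage.distance_transform_edt(~pcav_region, sampling=resolution)
        # the EDT measures distance to accessible *voxel centres*, which sit on
        # average half a voxel inside the continuum region; correct the
        # threshold by half the lattice spacing to remove that one-sided bias
        poav_region = (~inside_vdw) & (dist <= probe.probe_radius + 0.5 * resolution)

    voxel = resolution**3
    n_vox = float(np.prod(shape))
    cell_v = n_vox * voxel
    pcav_mol = cell_v - pcav_region.sum() * voxel
    poav_mol = cell_v - poav_region.sum() * voxel
    vdw_vol = inside_vdw.sum() * voxel

    # ASA by deterministic spherical quadrature per atom
    u = _fibonacci_sphere(quadrature_points)
    area = 0.0
    for i in range(structure.n_atoms):
        pts = centers[i] + inflated[i] * u
        acc = np.ones(quadrature_points, dtype=bool)
        for j in range(structure.n_atoms):
            if j == i:
                continue
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            acc &= d2 >= inflated[j] ** 2
        area += 4.0 * math.pi * inflated[i] ** 2 * acc.mean()

    return SurfVolResult(
        asa=float(area),
        asa_stderr=0.0,
        pcav_molecular_volume=float(pcav_mol),
        pcav_stderr=0.0,
        poav_molecular_volume=float(poav_mol),
        poav_stderr=0.0,
        vdw_volume=float(vdw_vol),
        vdw_stderr=0.0,
        n_samples=int(n_vox),
        seed=probe.seed,
    )


def _fill_sphere(mask, axes, center, radius, resolution):
    """Mark voxels whose centre lies inside the sphere, touching only its bbox."""
    slices = []
    local_axes = []
    for d in range(3):
        ax = axes[d]
        i0 = max(0, int((center[d] - radius) / resolution) - 1)
        i1 = min(len(ax), int((center[d] + radius) / resolution) + 2)
        slices.append(slice(i0, i1))
        local_axes.append(ax[i0:i1] - center[d])
    dx2 = local_axes[0][:, None, None] ** 2
    dy2 = local_axes[1][None, :, None] ** 2
    dz2 = local_axes[2][None, None, :] ** 2
    mask[tuple(slices)] |= (dx2 + dy2 + dz2) <= radius**2
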