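"""Shrake-Rupley solvent-accessible surface area with periodic boundaries.

The contact-area analyses of nanotube hydration all reduce to one geometric
kernel: per-atom SASA. Each atom's sphere is inflated by the probe radius
and covered with a deterministic quasi-uniform point set (golden-spiral
lattice); the accessible fraction is the share of points not buried inside
any neighbour's inflated sphere, and the area is that fraction times
``4 pi (r_i + probe)^2``.

Orthorhombic periodic boxes are honoured: neighbour search uses a periodic
k-d tree and point burial tests use minimum-image displacements.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError

__all__ = ["sphere_points", "sasa", "contact_area_coords"]


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    if n < 1:
        raise ValidationError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _min_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return disp
    return disp - box * np.round(disp / box)


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    box: np.ndarray | None = None,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in A^2.

    Parameters
    ----------
    coords : (n, 3) array, Angstrom
    radii : (n,) array, Angstrom (> 0)
    probe_radius : float
        Solvent probe radius (water: 1.4 A). >= 0.
    n_points : int
        Test points per atom (quadrature resolution).
    box : (3,) array or None
        Orthorhombic periodic box lengths; None for an isolated cluster.
    subset : index array or None
        Compute areas only for these atoms (all atoms still occlude). The
        returned array then has ``len(subset)`` entries in subset order.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("coords must be (n, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValidationError("coords contain NaN/inf")
    if radii.shape != (coords.shape[0],):
        raise ValidationError("radii must be (n,)")
    if np.any(radii <= 0):
        raise ValidationError("radii must be > 0")
    if probe_radius < 0:
        raise ValidationError("probe_radius must be >= 0")
    n = coords.shape[0]
    inflated = radii + probe_radius
    unit = sphere_points(n_points)

    if box is not None:
        box = np.asarray(box, dtype=float)
        wrapped = np.mod(coords, box)
        tree = cKDTree(wrapped, boxsize=box)
    else:
        wrapped = coords
        tree = cKDTree(wrapped)

    targets = np.arange(n) if subset is None else np.asarray(subset, dtype=int)
    areas = np.empty(targets.size, dtype=float)
    for out_i, i in enumerate(targets):
        ri = inflated[i]
        neigh = tree.query_ball_point(wrapped[i], r=ri + inflated.max())
        neigh = [j for j in neigh if j != i]
        if neigh:
            dvec = _min_image(wrapped[neigh] - wrapped[i], box)
            dist = np.linalg.norm(dvec, axis=1)
            if np.any((dist < 1e-9)):
                warnings.warn(f"coincident atoms at index {i}; SASA ill-defined there")
            keep = dist < ri + inflated[neigh]
            dvec, rj = dvec[keep], inflated[np.asarray(neigh)[keep]]
        else:
            dvec = np.empty((0, 3))
            rj = np.empty(0)
        if dvec.shape[0] == 0:
            areas[out_i] = 4.0 * np.pi * ri * ri
            continue
        pts = unit * ri  # relative to atom centre
        # buried if |pts - dvec_j| < rj for any neighbour j
        d2 = ((pts[:, None, :] - dvec[None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < (rj * rj)[None, :]).any(axis=1)
        frac = 1.0 - buried.mean()
        areas[out_i] = frac * 4.0 * np.pi * ri * ri
    return areas


def contact_area_coords(
    coords: np.ndarray,
    radii: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    box: np.ndarray | None = None,
) -> float:
    """Contact area between two disjoint atom groups, in A^2.

    Defined as half the solvent-accessible area lost on union formation,
    ``(SASA_A + SASA_B - SASA_{A u B}) / 2``, each term computed with only
    the named groups present. Atoms without cross-group neighbours
    contribute identically to both sides and are skipped exactly.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValidationError("groups overlap")
    if group_a.size == 0 or group_b.size == 0:
        raise ValidationError("empty group")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    inflated = radii + probe_radius

    ca, cb = coords[group_a], coords[group_b]
    ra, rb = inflated[group_a], inflated[group_b]
    if box is not None:
        box = np.asarray(box, dtype=float)
        ta = cKDTree(np.mod(ca, box), boxsize=box)
        tb = cKDTree(np.mod(cb, box), boxsize=box)
    else:
        ta, tb = cKDTree(ca), cKDTree(cb)
    pairs = ta.query_ball_tree(tb, r=ra.max() + rb.max())
    touched_a = [ia for ia, js in enumerate(pairs) if js]
    touched_b = sorted({j for js in pairs for j in js})
    if not touched_a:
        return 0.0

    union_idx = np.concatenate([group_a, group_b])
    ucoords, uradii = coords[union_idx], radii[union_idx]
    sub_a = np.asarray(touched_a, dtype=int)
    sub_b = np.asarray(touched_b, dtype=int)

    a_alone = sasa(ca, radii[group_a], probe_radius, n_points, box, subset=sub_a)
    b_alone = sasa(cb, radii[group_b], probe_radius, n_points, box, subset=sub_b)
    a_union = sasa(ucoords, uradii, probe_radius, n_points, box, subset=sub_a)
    b_union = sasa(
        ucoords, uradii, probe_radius, n_points, box, subset=sub_b + group_a.size
    )
    lost = (a_alone.sum() - a_union.sum()) + (b_alone.sum() - b_union.sum())
    return float(max(lost, 0.0) / 2.0)
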