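"""Low-level 3-D geometry: internal coordinates, rigid transforms, superposition.

All coordinates are in angstroms, all angles in degrees unless noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "angle_deg",
    "dihedral_deg",
    "place_atom",
    "random_rotation",
    "apply_rigid",
    "kabsch_superpose",
    "GeometryError",
]


class GeometryError(ValueError):
    """Degenerate geometry (collinear frame, too few points, ...)."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-10):
        raise GeometryError("zero-length vector in geometric construction")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float | np.ndarray:
    """Angle a-b-c at vertex b. Broadcasts over leading axes."""
    u = _unit(np.asarray(a, float) - b)
    v = _unit(np.asarray(c, float) - b)
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def dihedral_deg(a, b, c, d) -> float | np.ndarray:
    """Signed torsion a-b-c-d in (-180, 180]. Broadcasts over leading axes."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def place_atom(a, b, c, bond: float, angle: float, dihedral) -> np.ndarray:
    """Place atom d from internal coordinates relative to the a-b-c frame (NeRF).

    d is bonded to c at `bond` angstroms, with angle b-c-d = `angle` and
    torsion a-b-c-d = `dihedral` (degrees).  `dihedral` may be an array, in
    which case one position per torsion value is returned (shape (..., 3)).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    dihedral = np.asarray(dihedral, float)
    ang = np.radians(angle)
    tor = np.radians(dihedral)

    bc = c - b
    if np.linalg.norm(bc) < 1e-10 or np.linalg.norm(b - a) < 1e-10:
        raise GeometryError("coincident frame atoms")
    bc_u = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    if np.linalg.norm(n) < 1e-8:
        raise GeometryError("collinear frame atoms a, b, c")
    n_u = n / np.linalg.norm(n)
    m_u = np.cross(n_u, bc_u)

    d_local = np.stack(
        [
            -bond * np.cos(ang) * np.ones_like(tor),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ],
        axis=-1,
    )
    frame = np.stack([bc_u, m_u, n_u], axis=0)  # rows are basis vectors
    return c + d_local @ frame


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (Haar measure, via quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation) -> np.ndarray:
    """Apply x -> R x + t row-wise."""
    return np.asarray(coords, float) @ np.asarray(rotation, float).T + np.asarray(
        translation, float
    )


def kabsch_superpose(
    ref_coords: np.ndarray,
    mob_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mob_coords`` onto ``ref_coords``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``apply_rigid(mob_coords, rotation, translation)`` best fits the reference.
    The rotation is always proper (determinant +1): reflections are excluded by
    flipping the sign of the smallest singular direction when needed.

    Parameters
    ----------
    ref_coords, mob_coords : (N, 3) arrays, N >= 3, not all collinear.
    weights : optional non-negative per-point weights.
    """
    ref = np.asarray(ref_coords, float)
    mob = np.asarray(mob_coords, float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError("coordinate arrays must both have shape (N, 3)")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError(f"superposition needs at least 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm_ref = w @ ref
    cm_mob = w @ mob
    x = mob - cm_mob
    y = ref - cm_ref
    # collinearity check on the reference point cloud
    sv = np.linalg.svd(y * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) point set")

    h = (x * w[:, None]).T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cm_ref - rot @ cm_mob
    resid = apply_rigid(mob, rot, trans) - ref
    rmsd = float(np.sqrt(np.sum(w * np.sum(resid**2, axis=1))))
    return rot, trans, rmsd
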