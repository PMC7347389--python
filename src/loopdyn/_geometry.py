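"""Internal geometry helpers: superposition, dihedrals, rotations."""

from __future__ import annotations

import numpy as np


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation matrix mapping centered `mobile` onto centered `target`.

    Both inputs are (n, 3) and are assumed already centered on their centroids.
    Returns R such that mobile @ R.T best matches target (proper rotation,
    reflections excluded).
    """
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(mobile: np.ndarray, target: np.ndarray,
              fit_idx: np.ndarray | None = None) -> np.ndarray:
    """Superpose a full coordinate frame onto a target using a subset of atoms.

    Parameters
    ----------
    mobile, target : (n, 3) arrays with matching atom order.
    fit_idx : indices of the atoms used to determine the transform
        (default: all atoms). The transform is applied to every atom.
    """
    if fit_idx is None:
        fit_idx = np.arange(len(mobile))
    mob_fit = mobile[fit_idx]
    tar_fit = target[fit_idx]
    mob_c = mob_fit.mean(axis=0)
    tar_c = tar_fit.mean(axis=0)
    rot = kabsch_rotation(mob_fit - mob_c, tar_fit - tar_c)
    return (mobile - mob_c) @ rot.T + tar_c


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two matched coordinate sets, in the input units."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float | np.ndarray:
    """Signed dihedral angle (degrees, in (-180, 180]) for four points.

    Accepts single points (3,) or stacked frames (n, 3); IUPAC sign
    convention (positive = clockwise looking from p1 to p2).
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 so the range is (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    if np.ndim(ang) == 0:
        return float(ang)
    return ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis by `angle_deg` degrees."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer(axis, axis)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a fourth atom D given three atoms A-B-C, the C-D bond length,
    the B-C-D angle and the A-B-C-D dihedral (degrees, IUPAC convention)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        -bond * np.sin(ang) * np.sin(dih),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local
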