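"""Low-level vector geometry shared by the annotation modules.

All coordinates are in Å. Torsion angles follow the IUPAC sign
convention and are reported in degrees in (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "angle",
    "place_atom",
    "fit_plane",
    "random_rotation",
    "wrap180",
]


def wrap180(x: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees into (-180, 180]."""
    w = -((-np.asarray(x) + 180.0) % 360.0 - 180.0)
    return float(w) if np.ndim(x) == 0 else w


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention.

    Positive when, looking from p1 towards p2, the far bond p2->p3 is
    rotated clockwise relative to the near bond p1->p0.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, theta: float, phi: float) -> np.ndarray:
    """Place atom D from internal coordinates (natural extension frame).

    ``bond`` is the C-D distance, ``theta`` the B-C-D angle in degrees and
    ``phi`` the A-B-C-D torsion in degrees; returns the position of D.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    th = np.radians(180.0 - theta)
    ph = np.radians(phi)
    d_local = np.array(
        [
            bond * np.cos(th),
            bond * np.sin(th) * np.cos(ph),
            bond * np.sin(th) * np.sin(ph),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit plane through points; returns (centroid, unit normal)."""
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[-1]
    return centroid, normal / np.linalg.norm(normal)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (via QR of a Gaussian)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
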