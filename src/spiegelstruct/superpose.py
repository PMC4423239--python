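"""Rigid-body superposition (Kabsch), RMSD and per-base rotation angles.

Reflections are never applied: the optimal rotation is constrained to
det(R) = +1, so superposing a structure onto its mirror image reports
the honest (large) residual instead of silently inverting chirality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ResidueRecord, StructureModel
from .pairing import BASE_RING_ATOMS

__all__ = ["Superposition", "kabsch", "superpose", "superpose_models", "rmsd", "base_rotation"]

# selections exclude solvent and ions by default; altloc-A conformers only
_EXCLUDED_KINDS = ("water", "metal_ion")


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, orthonormal, det +1
    translation: np.ndarray  # Å
    rmsd: float  # Å
    n_atoms: int
    mapping: list[tuple] | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares proper rotation + translation mapping moving -> fixed."""
    a = np.asarray(moving, float)
    b = np.asarray(fixed, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 paired atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise ValueError("degenerate (colinear) point set: rotation underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cb - rot @ ca
    moved = a @ rot.T + trans
    value = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=value, n_atoms=len(a))


def rmsd(a: np.ndarray, b: np.ndarray, superposed: bool = True) -> float:
    """RMSD between paired point sets, after optimal superposition by default."""
    if superposed:
        return kabsch(a, b).rmsd
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _atom_map(model: StructureModel, chain_map: dict[str, str] | None, atom_filter):
    out = {}
    for chain in model.chains:
        role = chain.name if chain_map is None else chain_map.get(chain.name)
        if role is None and chain_map is not None:
            continue
        for res in chain.residues:
            if res.kind in _EXCLUDED_KINDS:
                continue
            for atom in res.atoms:
                if atom.element in ("H", "D"):
                    continue
                if atom.altloc not in ("", "A"):
                    continue
                if atom_filter is not None and not atom_filter(res, atom):
                    continue
                out[(role, res.author_number, res.insertion_code, atom.name)] = atom.position
    return out


def superpose_models(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_map_a: dict[str, str] | None = None,
    chain_map_b: dict[str, str] | None = None,
    atom_filter=None,
) -> Superposition:
    """Superpose B onto A, pairing atoms by (chain role, residue, atom name).

    ``chain_map_*`` rename chains onto shared roles so distinct copies of
    a complex can be compared; unmatched atoms are dropped. Waters, ions,
    hydrogens and non-A altlocs are excluded.
    """
    map_a = _atom_map(model_a, chain_map_a, atom_filter)
    map_b = _atom_map(model_b, chain_map_b, atom_filter)
    shared = sorted(set(map_a) & set(map_b))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared atoms; cannot superpose")
    fixed = np.array([map_a[k] for k in shared])
    moving = np.array([map_b[k] for k in shared])
    sup = kabsch(moving, fixed)
    sup.mapping = shared
    return sup


def superpose(a: np.ndarray, b: np.ndarray) -> Superposition:
    """Optimal proper rotation superposing point set b onto point set a."""
    return kabsch(b, a)


def base_rotation(
    res_a: ResidueRecord,
    res_b: ResidueRecord,
    context: Superposition | None = None,
) -> float:
    """Rotation angle (degrees, [0, 180]) between two conformers of a base.

    ``context`` is the superposition aligning everything around the
    target residue (e.g. the helical stem); the base ring atoms of the
    second conformer are brought into that frame, both rings are centred
    on their centroids, and the angle of the optimal proper rotation
    between them is returned.
    """
    ring = BASE_RING_ATOMS["purine"] if res_a.atom("N9") else BASE_RING_ATOMS["pyrimidine"]
    shared = [n for n in ring if res_a.atom(n) and res_b.atom(n)]
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared ring atoms; need >= 4")
    pts_a = res_a.positions(shared)
    pts_b = res_b.positions(shared)
    if context is not None:
        pts_b = context.apply(pts_b)
    sup = kabsch(pts_b - pts_b.mean(axis=0), pts_a - pts_a.mean(axis=0))
    cos_theta = (np.trace(sup.rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))
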