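"""Solvent-accessible surface area, buried interface area and footprints.

SASA uses the Shrake-Rupley method with a deterministic golden-spiral
point lattice (no RNG): for each atom, test points on the expanded
sphere of radius r_atom + probe are discarded when they fall inside any
neighbour's expanded sphere; the accessible fraction times the expanded
sphere area is the atom's SASA. Buried surface area of a complex A:B is
the two-sided sum SASA(A) + SASA(B) - SASA(AB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import StructureModel

__all__ = [
    "VDW_RADII",
    "SasaResult",
    "InterfaceReport",
    "sasa",
    "buried_surface",
    "footprint_overlap",
    "sphere_points",
]

# per-element van der Waals radii (Å); a published standard set
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "H": 1.20,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "MG": 1.73,
    "CA": 2.31,
    "K": 2.75,
    "NA": 2.27,
    "ZN": 1.39,
}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960
FOOTPRINT_DSASA_MIN = 1.0  # Å²
CONTACT_CUTOFF = 4.0  # Å heavy-atom contact distance


def _canonical_frame(pos: np.ndarray) -> np.ndarray:
    """Deterministic molecule frame: covariance eigenvectors (descending),
    each oriented by the sign of the third moment along it.

    The frame co-rotates (and co-reflects) with the atom set, so the test
    lattice is expressed in molecule coordinates and the computed area is
    exactly invariant under global rotation, translation and mirroring
    (up to eigenvector degeneracy in exactly symmetric inputs).
    """
    rel = pos - pos.mean(axis=0)
    if len(rel) < 2:
        return np.eye(3)
    cov = rel.T @ rel
    w, v = np.linalg.eigh(cov)
    frame = v[:, ::-1]  # descending eigenvalue order
    for k in range(3):
        s = float(np.sum((rel @ frame[:, k]) ** 3))
        if s < 0 or (s == 0 and frame[np.argmax(np.abs(frame[:, k])), k] < 0):
            frame[:, k] = -frame[:, k]
    return frame


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class SasaResult:
    atom_areas: np.ndarray  # Å², aligned with atom_keys
    atom_keys: list[tuple[str, int, str]]  # (chain, residue number, atom name)
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())

    def per_residue(self) -> dict[tuple[str, int], float]:
        out: dict[tuple[str, int], float] = {}
        for (chain, num, _), a in zip(self.atom_keys, self.atom_areas):
            key = (chain, num)
            out[key] = out.get(key, 0.0) + float(a)
        return out


def _gather(model: StructureModel, include_het: bool, selection=None):
    keys, pos, radii = [], [], []
    unknown = set()
    for chain in model.chains:
        for res in chain.residues:
            if not include_het and res.kind in ("water", "metal_ion"):
                continue
            if selection is not None and not selection(chain, res):
                continue
            for atom in res.atoms:
                if atom.element in ("H", "D"):
                    continue
                r = VDW_RADII.get(atom.element.upper())
                if r is None:
                    unknown.add(atom.element)
                    r = DEFAULT_RADIUS
                keys.append((chain.name, res.author_number, atom.name))
                pos.append(atom.position)
                radii.append(r)
    if unknown:
        import warnings

        warnings.warn(f"unknown element(s) {sorted(unknown)}; default radius used", stacklevel=3)
    return keys, np.array(pos, float), np.array(radii, float)


def sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    include_het: bool = False,
    selection=None,
    frame: np.ndarray | None = None,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Deterministic for a fixed lattice size; waters/ions are excluded
    unless ``include_het`` is set. ``selection(chain, residue) -> bool``
    restricts the atom set (the excluded atoms do not occlude).
    ``frame`` overrides the canonical lattice orientation — interface
    calculations pass one shared frame so that component and complex
    areas use identical quadrature.
    """
    if not 1.0 <= probe <= 2.0:
        raise ValueError("probe radius must be within [1.0, 2.0] Å")
    keys, pos, radii = _gather(model, include_het, selection)
    if len(keys) == 0:
        return SasaResult(np.zeros(0), [], probe, n_points)
    if frame is None:
        frame = _canonical_frame(pos)
    lattice = sphere_points(n_points) @ frame.T
    expanded = radii + probe
    tree = cKDTree(pos)
    max_reach = 2.0 * expanded.max()
    areas = np.zeros(len(keys))
    for i in range(len(keys)):
        pts = pos[i] + expanded[i] * lattice
        neighbours = [j for j in tree.query_ball_point(pos[i], max_reach) if j != i]
        if neighbours:
            nb_pos = pos[neighbours]
            nb_r2 = (expanded[neighbours]) ** 2
            d2 = ((pts[:, None, :] - nb_pos[None, :, :]) ** 2).sum(axis=2)
            accessible = ~(d2 < nb_r2[None, :]).any(axis=1)
        else:
            accessible = np.ones(len(pts), bool)
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return SasaResult(areas, keys, probe, n_points)


@dataclass
class InterfaceReport:
    bsa_total: float  # Å², SASA(A) + SASA(B) - SASA(AB)
    footprint_a: dict[tuple[str, int], float]  # residue -> buried area Å²
    footprint_b: dict[tuple[str, int], float]
    contacts: list[tuple[tuple[str, int, str], tuple[str, int, str], float]] = field(default_factory=list)


def buried_surface(
    model: StructureModel,
    selection_a,
    selection_b,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> InterfaceReport:
    """Two-sided buried surface area between two disjoint selections.

    Selections are chain-name collections or ``(chain, residue) -> bool``
    predicates. Waters and ions are always excluded. Footprints list the
    residues losing at least 1 Å² of SASA on complexation, plus any
    residue with a heavy-atom contact within the contact cutoff.
    """
    sel_a = _as_predicate(selection_a)
    sel_b = _as_predicate(selection_b)

    def overlap(chain, res):
        return sel_a(chain, res) and sel_b(chain, res)

    if any(overlap(c, r) for c in model.chains for r in c.residues):
        raise ValueError("selections overlap")

    def union(chain, res):
        return sel_a(chain, res) or sel_b(chain, res)

    # one lattice frame from the union so the three areas share quadrature
    _, union_pos, _ = _gather(model, False, union)
    frame = _canonical_frame(union_pos)
    s_a = sasa(model, probe, n_points, selection=sel_a, frame=frame)
    s_b = sasa(model, probe, n_points, selection=sel_b, frame=frame)
    s_ab = sasa(model, probe, n_points, selection=union, frame=frame)
    # aligned per-atom differences summed in canonical key order: exactly
    # zero for non-contacting chains and exactly symmetric in (a, b)
    ab_areas = dict(zip(s_ab.atom_keys, s_ab.atom_areas))
    alone = {}
    for part in (s_a, s_b):
        alone.update(zip(part.atom_keys, part.atom_areas))
    bsa = float(sum(float(alone[k]) - float(ab_areas[k]) for k in sorted(alone)))

    res_ab = s_ab.per_residue()
    foot_a = _footprint(s_a.per_residue(), res_ab)
    foot_b = _footprint(s_b.per_residue(), res_ab)

    contacts = _contacts(model, sel_a, sel_b, contact_cutoff)
    for (ka, kb, _) in contacts:
        foot_a.setdefault((ka[0], ka[1]), 0.0)
        foot_b.setdefault((kb[0], kb[1]), 0.0)
    return InterfaceReport(bsa_total=float(bsa), footprint_a=foot_a, footprint_b=foot_b, contacts=contacts)


def _as_predicate(selection):
    if callable(selection):
        return selection
    names = set(selection) if not isinstance(selection, str) else {selection}

    def pred(chain, res):
        return chain.name in names and res.kind not in ("water", "metal_ion")

    return pred


def _footprint(before: dict, after: dict) -> dict:
    out = {}
    for key, area in before.items():
        delta = area - after.get(key, 0.0)
        if delta >= FOOTPRINT_DSASA_MIN:
            out[key] = round(float(delta), 2)
    return out


def _contacts(model, sel_a, sel_b, cutoff):
    entries_a, entries_b = [], []
    for chain in model.chains:
        for res in chain.residues:
            for target, sel in ((entries_a, sel_a), (entries_b, sel_b)):
                if sel(chain, res):
                    for atom in res.atoms:
                        if atom.element not in ("H", "D"):
                            target.append(((chain.name, res.author_number, atom.name), atom.position))
    if not entries_a or not entries_b:
        return []
    pos_a = np.array([p for _, p in entries_a])
    pos_b = np.array([p for _, p in entries_b])
    tree_b = cKDTree(pos_b)
    out = []
    for i, hits in enumerate(tree_b.query_ball_point(pos_a, cutoff)):
        for j in hits:
            d = float(np.linalg.norm(pos_a[i] - pos_b[j]))
            out.append((entries_a[i][0], entries_b[j][0], d))
    return sorted(out, key=lambda t: t[2])


def footprint_overlap(fp_a, fp_b) -> dict:
    """Intersection/Jaccard overlap of two residue footprints (same numbering)."""
    a, b = set(fp_a), set(fp_b)
    inter = a & b
    union = a | b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "intersection": sorted(inter),
        "n_intersection": len(inter),
        "jaccard": (len(inter) / len(union)) if union else 1.0,
    }
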