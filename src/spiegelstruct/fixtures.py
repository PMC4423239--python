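"""Synthetic structural and kinetic fixtures.

Every input the test-suite needs is generated here, with no downloads:
idealised nucleic-acid geometries in both D and L chirality, stacked
G-tetrads with an optional channel ion, metal coordination polyhedra,
random atom clusters for surface-area checks, and noisy sensorgram sets.

Nucleotide geometry starts from the chemical-component-dictionary ideal
coordinates shipped with biotite (natural D-nucleotides). Bases are kept
rigid; the glycosidic torsion is set by rotating the base about the
C1'-N bond, Watson-Crick pairs and Hoogsteen G-tetrads are assembled by
least-squares placement of rigid nucleotides against canonical
hydrogen-bond distance targets, and L-chirality builds are exact mirror
images (z -> -z) of the D builds.

All randomised fixtures take a mandatory seed and are byte-deterministic
for a given parameter set.
"""

from __future__ import annotations

from functools import lru_cache

import biotite.structure.info as _ccd_info
import numpy as np
from scipy.optimize import least_squares

from .geometry import dihedral, place_atom
from .model import AtomRecord, Chain, ResidueRecord, StructureModel, mirror_structure
from .spr import KineticModel, Sensorgram, simulate_sensorgram

__all__ = [
    "make_nucleotide",
    "make_sugar_ring",
    "make_base_pair",
    "make_duplex",
    "make_tetrad_stack",
    "make_ion_site",
    "make_sphere_cluster",
    "make_sensorgram_set",
]

A_FORM_TWIST = 32.7  # deg per bp, right-handed for the D build
A_FORM_RISE = 2.81  # Å per bp

COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A", "T": "A"}

# canonical Watson-Crick donor/acceptor heavy-atom distance targets (Å)
_WC_TARGETS = {
    ("G", "C"): [("O6", "N4", 2.91), ("N1", "N3", 2.95), ("N2", "O2", 2.86)],
    ("A", "U"): [("N6", "O4", 2.95), ("N1", "N3", 2.82)],
    ("A", "T"): [("N6", "O4", 2.95), ("N1", "N3", 2.82)],
}
_C1C1_WC = 10.4  # Å, canonical C1'-C1' separation in a WC pair

_BASE_RING = {
    "purine": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "pyrimidine": ("N1", "C2", "N3", "C4", "C5", "C6"),
}


def _ccd_name(base: str, deoxy: bool) -> str:
    base = base.upper()
    if base not in "ACGUT":
        raise ValueError(f"unknown base {base!r}")
    return ("D" + base) if deoxy else base


@lru_cache(maxsize=None)
def _template_arrays(ccd: str):
    res = _ccd_info.residue(ccd)
    keep = [
        i
        for i in range(res.array_length())
        if res.element[i] not in ("H", "D") and res.atom_name[i] != "OP3"
    ]
    names = tuple(res.atom_name[i] for i in keep)
    coords = np.array([res.coord[i] for i in keep], float)
    elements = tuple(res.element[i] for i in keep)
    return names, elements, coords


def _glycosidic_atoms(names) -> tuple[str, str]:
    """(glycosidic N, chi-defining ring carbon)."""
    return ("N9", "C4") if "N9" in names else ("N1", "C2")


def _base_atom_mask(names) -> np.ndarray:
    return np.array([("'" not in n) and (n not in ("P", "OP1", "OP2")) for n in names])


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _rz(angle_deg: float) -> np.ndarray:
    return _rotation_about_axis(np.array([0.0, 0.0, 1.0]), angle_deg)


def _internal(coords, idx, a, b, c, d):
    """(bond c-d, angle b-c-d, torsion a-b-c-d) measured on a template."""
    pa, pb, pc, pd = (coords[idx[x]] for x in (a, b, c, d))
    from .geometry import angle as _angle

    return (
        float(np.linalg.norm(pd - pc)),
        _angle(pb, pc, pd),
        dihedral(pa, pb, pc, pd),
    )


def _kabsch_transform(src: np.ndarray, dst: np.ndarray):
    """Proper-rotation least-squares transform mapping src points to dst."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, dc - rot @ sc


@lru_cache(maxsize=None)
def _built_nucleotide(base: str, deoxy: bool, chi: float, pucker: float, amplitude: float):
    """Build a D-nucleotide with prescribed sugar pucker and glycosidic chi.

    The five-membered ring is chained from the Altona-Sundaralingam
    endocyclic torsions for the requested phase; exocyclic backbone atoms
    and the glycosidic attachment reuse internal coordinates measured on
    the CCD ideal-coordinate template, and the rigid CCD base is grafted
    on at the exact requested chi.
    """
    t_names, t_elements, t_coords = _template_arrays(_ccd_name(base, deoxy))
    t_idx = {n: i for i, n in enumerate(t_names)}
    n_gly, c_chi = _glycosidic_atoms(t_names)

    ring = make_sugar_ring(pucker, amplitude)
    pos = {a.name: a.position for a in ring.atoms}

    def add(name, a, b, c, torsion=None):
        if name not in t_idx:
            return
        bond, theta, t_phi = _internal(t_coords, t_idx, a, b, c, name)
        pos[name] = place_atom(pos[a], pos[b], pos[c], bond, theta, t_phi if torsion is None else torsion)

    add("O2'", "O4'", "C1'", "C2'")
    add("O3'", "O4'", "C4'", "C3'")
    add("C5'", "C2'", "C3'", "C4'")
    add("O5'", "C3'", "C4'", "C5'")
    add("P", "C4'", "C5'", "O5'")
    add("OP1", "C5'", "O5'", "P")
    add("OP2", "C5'", "O5'", "P")

    # glycosidic N from the template's anomeric torsion, neighbours at chi
    add(n_gly, "C4'", "O4'", "C1'")
    bond_a, theta_a, _ = _internal(t_coords, t_idx, "O4'", "C1'", n_gly, c_chi)
    pos[c_chi] = place_atom(pos["O4'"], pos["C1'"], pos[n_gly], bond_a, theta_a, chi)
    other = {"N9": "C8", "N1": "C6"}[n_gly]
    bond_b, theta_b, tau_b = _internal(t_coords, t_idx, "O4'", "C1'", n_gly, other)
    _, _, tau_a = _internal(t_coords, t_idx, "O4'", "C1'", n_gly, c_chi)
    pos[other] = place_atom(pos["O4'"], pos["C1'"], pos[n_gly], bond_b, theta_b, chi + (tau_b - tau_a))

    # graft the rigid base onto the three anchors
    base_mask = _base_atom_mask(t_names)
    anchors = (n_gly, c_chi, other)
    src = np.array([t_coords[t_idx[a]] for a in anchors])
    dst = np.array([pos[a] for a in anchors])
    rot, shift = _kabsch_transform(src, dst)
    for i, name in enumerate(t_names):
        if base_mask[i] and name not in anchors:
            pos[name] = rot @ t_coords[i] + shift

    names = tuple(n for n in t_names if n in pos)
    elements = tuple(t_elements[t_idx[n]] for n in names)
    coords = np.array([pos[n] for n in names])
    return names, elements, coords, base_mask_for(names)


def base_mask_for(names) -> np.ndarray:
    return _base_atom_mask(names)


@lru_cache(maxsize=None)
def _canonical_nucleotide(base: str, deoxy: bool, chi: float | None,
                          pucker: float = 18.0, amplitude: float = 38.0):
    """Nucleotide template with the base plane in z=0.

    The base centroid sits at the origin with the glycosidic N on the -x
    axis and the sugar on the +z side. Default geometry is C3'-endo,
    anti (chi defaults to -160 degrees when not given).
    """
    chi = -160.0 if chi is None else chi
    names, elements, coords, base_mask = _built_nucleotide(base, deoxy, chi, pucker, amplitude)
    coords = coords.copy()
    idx = {n: i for i, n in enumerate(names)}
    n_gly, _ = _glycosidic_atoms(names)

    # canonical frame: base plane -> z=0, sugar above it
    base_pts = coords[base_mask]
    centroid = base_pts.mean(axis=0)
    coords -= centroid
    _, _, vt = np.linalg.svd(coords[base_mask])
    normal = vt[-1]
    if np.dot(normal, coords[idx["C1'"]]) < 0:
        normal = -normal
    zax = normal
    xax = -coords[idx[n_gly]]
    xax = xax - np.dot(xax, zax) * zax
    xax /= np.linalg.norm(xax)
    yax = np.cross(zax, xax)
    frame = np.column_stack([xax, yax, zax])
    coords = coords @ frame
    coords.setflags(write=False)
    return names, elements, coords


def _residue_from_arrays(name, names, elements, coords, number, kind) -> ResidueRecord:
    atoms = [
        AtomRecord(n, e, np.array(c, float)) for n, e, c in zip(names, elements, coords)
    ]
    return ResidueRecord(name=name, author_number=number, kind=kind, chirality="D", atoms=atoms)


def make_nucleotide(
    base: str,
    deoxy: bool = False,
    chi: float = -160.0,
    number: int = 1,
    pucker: float = 18.0,
    amplitude: float = 38.0,
) -> ResidueRecord:
    """A single idealised (D) nucleotide with the given glycosidic chi and
    sugar pseudorotation phase (default C3'-endo, anti)."""
    names, elements, coords = _canonical_nucleotide(base.upper(), deoxy, chi, pucker, amplitude)
    kind = "deoxyribonucleotide" if deoxy else "ribonucleotide"
    return _residue_from_arrays(_ccd_name(base, deoxy), names, elements, coords, number, kind)


def make_sugar_ring(phase_deg: float, amplitude_deg: float = 38.0) -> ResidueRecord:
    """A bare five-membered furanose ring with prescribed pucker.

    Ring atoms are chained from the Altona-Sundaralingam endocyclic
    torsions nu_j = amplitude * cos(P + 144 deg * (j - 2)); bond lengths
    and angles are idealised, so the realised phase matches the request
    to within a fraction of a degree (closure is approximate).
    """
    nu = [
        amplitude_deg * np.cos(np.radians(phase_deg + 144.0 * (j - 2)))
        for j in range(5)
    ]
    # chain C3'-C4'-O4'-C1'-C2' using nu4 (C3'C4'O4'C1') and nu0 (C4'O4'C1'C2')
    c3 = np.zeros(3)
    c4 = np.array([1.52, 0.0, 0.0])
    o4 = place_atom(np.array([1.0, 1.0, 0.0]), c3, c4, 1.45, 104.0, 0.0)
    c1 = place_atom(c3, c4, o4, 1.41, 109.0, nu[4])
    c2 = place_atom(c4, o4, c1, 1.53, 106.0, nu[0])
    atoms = [
        AtomRecord(n, "O" if n.startswith("O") else "C", p)
        for n, p in (("C1'", c1), ("C2'", c2), ("C3'", c3), ("C4'", c4), ("O4'", o4))
    ]
    return ResidueRecord(name="RIB", author_number=1, kind="ribonucleotide", atoms=atoms)


def _apply(coords: np.ndarray, theta: float, tx: float, ty: float) -> np.ndarray:
    return coords @ _rz(theta).T + np.array([tx, ty, 0.0])


@lru_cache(maxsize=None)
def _wc_pair_pose(b1: str, b2: str, deoxy1: bool, deoxy2: bool, chi: float):
    """In-plane pose (theta, tx, ty) of the flipped partner nucleotide."""
    if (b1, b2) in _WC_TARGETS:
        targets = _WC_TARGETS[(b1, b2)]
        swap = False
    elif (b2, b1) in _WC_TARGETS:
        targets = [(a2, a1, d) for a1, a2, d in _WC_TARGETS[(b2, b1)]]
        swap = True
    else:
        raise ValueError(f"no Watson-Crick geometry for {b1}-{b2}")
    del swap
    n1, _, c1 = _canonical_nucleotide(b1, deoxy1, chi)
    n2, _, c2 = _canonical_nucleotide(b2, deoxy2, chi)
    i1 = {n: i for i, n in enumerate(n1)}
    i2 = {n: i for i, n in enumerate(n2)}
    flip = c2 @ np.diag([1.0, -1.0, -1.0])  # 180 deg about x: antiparallel partner

    def residuals(x):
        theta, tx, ty = x
        p2 = _apply(flip, theta, tx, ty)
        res = [
            np.linalg.norm(c1[i1[a1]] - p2[i2[a2]]) - d for a1, a2, d in targets
        ]
        res.append(0.3 * (np.linalg.norm(c1[i1["C1'"]] - p2[i2["C1'"]]) - _C1C1_WC))
        return res

    best = None
    for theta0 in (0.0, 60.0, 120.0, 180.0, 240.0, 300.0):
        sol = least_squares(residuals, [theta0, 9.0, 0.0], method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    return tuple(best.x)


def make_base_pair(
    b1: str,
    b2: str | None = None,
    deoxy1: bool = False,
    deoxy2: bool = False,
    chi: float = -160.0,
) -> StructureModel:
    """A coplanar canonical Watson-Crick pair (two single-residue chains)."""
    b1 = b1.upper()
    b2 = COMPLEMENT[b1] if b2 is None else b2.upper()
    theta, tx, ty = _wc_pair_pose(b1, b2, deoxy1, deoxy2, chi)
    n1, e1, c1 = _canonical_nucleotide(b1, deoxy1, chi)
    n2, e2, c2 = _canonical_nucleotide(b2, deoxy2, chi)
    p2 = _apply(c2 @ np.diag([1.0, -1.0, -1.0]), theta, tx, ty)
    # shared pair frame: C1'-C1' midpoint at the origin, C1'->C1' along +x
    c1a = c1[list(n1).index("C1'")]
    c1b = p2[list(n2).index("C1'")]
    align = _rz(-np.degrees(np.arctan2((c1b - c1a)[1], (c1b - c1a)[0])))
    c1 = c1 @ align.T
    p2 = p2 @ align.T
    mid = 0.5 * (c1[list(n1).index("C1'")] + p2[list(n2).index("C1'")])
    kind1 = "deoxyribonucleotide" if deoxy1 else "ribonucleotide"
    kind2 = "deoxyribonucleotide" if deoxy2 else "ribonucleotide"
    ra = _residue_from_arrays(_ccd_name(b1, deoxy1), n1, e1, c1 - mid, 1, kind1)
    rb = _residue_from_arrays(_ccd_name(b2, deoxy2), n2, e2, p2 - mid, 1, kind2)
    return StructureModel([Chain("A", [ra]), Chain("B", [rb])], identifier=f"{b1}-{b2} pair")


def make_duplex(
    n_bp: int,
    sequence: str | None = None,
    chirality: str = "D",
    twist: float = A_FORM_TWIST,
    rise: float = A_FORM_RISE,
    chi: float = -160.0,
) -> StructureModel:
    """An idealised A-form double helix.

    The D build uses right-handed twist (+32.7 deg/bp, 2.81 Å rise); the
    L build is its exact mirror image and is therefore left-handed.
    Strand A is ``sequence`` 5'->3', strand B its reverse complement,
    both numbered 1..n_bp in their own 5'->3' order.
    """
    if n_bp < 2:
        raise ValueError("a duplex needs at least 2 base pairs")
    if chirality not in ("D", "L"):
        raise ValueError("chirality must be 'D' or 'L'")
    if sequence is None:
        sequence = ("GCGC" * ((n_bp + 3) // 4))[:n_bp]
    sequence = sequence.upper()
    if len(sequence) != n_bp:
        raise ValueError("sequence length must equal n_bp")

    strand_a: list[ResidueRecord] = []
    strand_b: list[ResidueRecord] = []
    for k, base in enumerate(sequence):
        pair = make_base_pair(base, chi=chi)
        rot = _rz(k * twist)
        shift = np.array([0.0, 0.0, k * rise])
        for src, dst in ((pair.chains[0].residues[0], strand_a), (pair.chains[1].residues[0], strand_b)):
            atoms = [
                AtomRecord(a.name, a.element, rot @ a.position + shift, a.occupancy, a.altloc, a.b_factor)
                for a in src.atoms
            ]
            dst.append(ResidueRecord(src.name, 0, kind=src.kind, chirality="D", atoms=atoms))
    strand_b.reverse()  # antiparallel: strand B 5'->3' runs against strand A
    for i, r in enumerate(strand_a, start=1):
        r.author_number = i
    for i, r in enumerate(strand_b, start=1):
        r.author_number = i
    model = StructureModel(
        [Chain("A", strand_a), Chain("B", strand_b)],
        identifier=f"ideal A-form duplex ({chirality})",
    )
    if chirality == "L":
        model = mirror_structure(model)
        model.identifier = "ideal A-form duplex (L)"
    return model


@lru_cache(maxsize=None)
def _tetrad_pose(o6_radius: float, chi: float):
    """In-plane pose of one guanine such that 90 deg copies form a Hoogsteen
    cycle with O6 at the given axis radius.

    The two Hoogsteen contacts (N1->O6, N2->N7) share a common length that
    floats inside the physical band [2.6, 3.2] Å with a weak preference
    for 2.9 Å, because a prescribed channel radius and a fixed hydrogen-
    bond length cannot in general be satisfied simultaneously.
    """
    names, _, coords = _canonical_nucleotide("G", False, chi)
    idx = {n: i for i, n in enumerate(names)}
    r90 = _rz(90.0)

    def residuals(x):
        theta, tx, ty, h = x
        g0 = _apply(coords, theta, tx, ty)
        g1 = g0 @ r90.T
        return [
            10.0 * (np.linalg.norm(g0[idx["N1"]] - g1[idx["O6"]]) - h),
            10.0 * (np.linalg.norm(g0[idx["N2"]] - g1[idx["N7"]]) - h),
            10.0 * (np.linalg.norm(g0[idx["O6"]][:2]) - o6_radius),
            0.2 * (h - 2.9),
            # keep the base pointing outward (O6 on the inner channel rim),
            # excluding degenerate poses that fold the base across the axis
            0.2 * (np.linalg.norm(g0[idx["N9"]][:2]) - (o6_radius + 4.3)),
        ]

    lower = [-720.0, -20.0, -20.0, 2.6]
    upper = [720.0, 20.0, 20.0, 3.2]
    best = None
    for theta0 in np.arange(0.0, 360.0, 45.0):
        sol = least_squares(
            residuals, [theta0, 4.0, 0.0, 2.9], method="trf", bounds=(lower, upper)
        )
        if best is None or sol.cost < best.cost:
            best = sol
    return tuple(best.x[:3])


def make_tetrad_stack(
    n_tetrads: int = 2,
    twist: float = 45.0,
    rise: float = 2.9,
    ion: str | None = "CA",
    ion_distance: float = 2.48,
    chi: float = -120.0,
) -> StructureModel:
    """Stacked canonical G-tetrads with an optional channel ion.

    Each tetrad is a C4-symmetric Hoogsteen cycle of four guanosines;
    consecutive tetrads are related by ``twist`` degrees about the common
    axis and ``rise`` Å along it. With two tetrads the ion sits midway on
    the axis and the guanine O6 radius is chosen so every ion-O6 distance
    equals ``ion_distance``; with one tetrad the ion lies in-plane.
    """
    if n_tetrads < 1:
        raise ValueError("need at least one tetrad")
    half_rise = rise / 2.0 if n_tetrads >= 2 else 0.0
    if ion is not None:
        if ion_distance <= half_rise:
            raise ValueError("ion distance too short for the requested rise")
        o6_radius = float(np.sqrt(ion_distance**2 - half_rise**2))
    else:
        o6_radius = 2.9  # typical channel radius when no ion constrains it
    theta, tx, ty = _tetrad_pose(o6_radius, chi)
    names, elements, coords = _canonical_nucleotide("G", False, chi)
    g0 = _apply(coords, theta, tx, ty)

    residues: list[ResidueRecord] = []
    num = 1
    for t in range(n_tetrads):
        rot_t = _rz(t * twist)
        shift = np.array([0.0, 0.0, t * rise])
        for q in range(4):
            pts = g0 @ _rz(90.0 * q).T @ rot_t.T + shift
            residues.append(_residue_from_arrays("G", names, elements, pts, num, "ribonucleotide"))
            num += 1
    chains = [Chain("Q", residues)]
    if ion is not None:
        ion = ion.upper()
        z_ion = rise * (min(n_tetrads, 2) - 1) / 2.0
        ion_atom = AtomRecord(ion, ion.capitalize(), np.array([0.0, 0.0, z_ion]))
        chains.append(
            Chain("I", [ResidueRecord(ion, 1, kind="metal_ion", atoms=[ion_atom])])
        )
    return StructureModel(chains, identifier=f"{n_tetrads}-tetrad stack")


# unit-vector ligand polyhedra for coordination numbers 4-9
def _polyhedron(cn: int) -> np.ndarray:
    s3 = 1.0 / np.sqrt(3.0)
    if cn == 4:
        return np.array([[s3, s3, s3], [s3, -s3, -s3], [-s3, s3, -s3], [-s3, -s3, s3]])
    if cn == 5:  # trigonal bipyramid
        eq = [[np.cos(a), np.sin(a), 0.0] for a in np.radians([0, 120, 240])]
        return np.array(eq + [[0, 0, 1.0], [0, 0, -1.0]])
    if cn == 6:  # octahedron
        return np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
        )
    if cn == 7:  # pentagonal bipyramid
        eq = [[np.cos(a), np.sin(a), 0.0] for a in np.radians(np.arange(0, 360, 72))]
        return np.array(eq + [[0, 0, 1.0], [0, 0, -1.0]])
    if cn == 8:  # square antiprism
        h = 1.0 / np.sqrt(2.0)
        top = [[h * np.cos(a), h * np.sin(a), h] for a in np.radians([0, 90, 180, 270])]
        bot = [[h * np.cos(a), h * np.sin(a), -h] for a in np.radians([45, 135, 225, 315])]
        return np.array(top + bot)
    if cn == 9:  # tricapped trigonal prism
        h = 0.65
        r = np.sqrt(1 - h * h)
        top = [[r * np.cos(a), r * np.sin(a), h] for a in np.radians([0, 120, 240])]
        bot = [[r * np.cos(a), r * np.sin(a), -h] for a in np.radians([0, 120, 240])]
        caps = [[np.cos(a), np.sin(a), 0.0] for a in np.radians([60, 180, 300])]
        return np.array(top + bot + caps)
    raise ValueError("coordination number must be between 4 and 9")


def make_ion_site(
    species: str = "MG",
    cn: int = 6,
    mean_distance: float = 2.08,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> StructureModel:
    """A metal ion at the origin with water-oxygen ligands on a regular
    polyhedron; ligand distances are drawn N(mean_distance, jitter_sd)."""
    if not 4 <= cn <= 9:
        raise ValueError("coordination number must be between 4 and 9")
    rng = np.random.default_rng(seed)
    dirs = _polyhedron(cn)
    dists = mean_distance + (rng.normal(0.0, jitter_sd, cn) if jitter_sd > 0 else np.zeros(cn))
    species = species.upper()
    ion = ResidueRecord(
        species, 1, kind="metal_ion",
        atoms=[AtomRecord(species, species.capitalize(), np.zeros(3))],
    )
    waters = [
        ResidueRecord("HOH", i + 1, kind="water", atoms=[AtomRecord("O", "O", d * u)])
        for i, (u, d) in enumerate(zip(dirs, dists))
    ]
    return StructureModel(
        [Chain("I", [ion]), Chain("W", waters)],
        identifier=f"{species} site CN{cn}",
    )


def make_sphere_cluster(
    n_atoms: int = 20, seed: int = 0, box: float = 6.0, elements=("C", "N", "O")
) -> StructureModel:
    """A seeded random atom cluster (single residue) for surface-area checks."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-box / 2, box / 2, size=(n_atoms, 3))
    elems = [elements[i % len(elements)] for i in range(n_atoms)]
    atoms = [AtomRecord(f"{e}{i+1}", e, p) for i, (e, p) in enumerate(zip(elems, pos))]
    res = ResidueRecord("CLU", 1, kind="other", atoms=atoms)
    return StructureModel([Chain("X", [res])], identifier=f"cluster n={n_atoms} seed={seed}")


def make_sensorgram_set(
    model: KineticModel,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_assoc: float = 240.0,
    t_dissoc: float = 240.0,
    dt: float = 1.0,
) -> list[Sensorgram]:
    """Simulated concentration series with seeded additive Gaussian noise."""
    rng = np.random.default_rng(seed)
    out = []
    for conc in np.asarray(concentrations, float):
        s = simulate_sensorgram(model, conc, t_assoc, t_dissoc, dt)
        response = s.response
        if noise_sd > 0:
            response = response + rng.normal(0.0, noise_sd, response.size)
        out.append(Sensorgram(s.times, response, conc, s.t_assoc, s.t_end))
    return out
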