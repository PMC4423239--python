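"""Hydrogen bonds, base pairing, stacking, G-tetrads and quadruplexes.

All detection is distance/angle based on heavy atoms only (crystal
structures at 1.8-2.0 Å carry no hydrogens) and is therefore invariant
under mirror reflection of the whole structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .geometry import fit_plane
from .model import AtomRecord, ResidueRecord, StructureModel

__all__ = [
    "HBond",
    "BasePair",
    "Tetrad",
    "Quadruplex",
    "detect_hbonds",
    "detect_base_pairs",
    "detect_tetrads",
    "assemble_quadruplex",
    "detect_stacking",
    "helix_handedness",
]

HBOND_CUTOFF = 3.5  # Å, heavy-atom donor-acceptor default
COPLANARITY_MAX = 30.0  # deg, base-pair normal angle
PAIR_MAX_PLANE_OFFSET = 1.8  # Å, partner centroid distance from the base plane
STACK_DISTANCE = (2.8, 4.5)  # Å, ring-centroid window
STACK_NORMAL_MAX = 30.0  # deg
STACK_MIN_OFFSET = 1.5  # Å along the mean normal, excludes coplanar neighbours
TETRAD_CUTOFF = 3.5  # Å for the N1->O6 and N2->N7 Hoogsteen contacts

# donor/acceptor roles for nucleobase, sugar and generic atoms
_BASE_DONORS = {
    "G": {"N1", "N2"},
    "A": {"N6"},
    "C": {"N4"},
    "U": {"N3"},
    "T": {"N3"},
    "I": {"N1"},
}
_BASE_ACCEPTORS = {
    "G": {"O6", "N7", "N3"},
    "A": {"N1", "N3", "N7"},
    "C": {"O2", "N3"},
    "U": {"O2", "O4"},
    "T": {"O2", "O4"},
    "I": {"O6", "N7", "N3"},
}
_SUGAR_DONORS = {"O2'"}
_SUGAR_ACCEPTORS = {"O2'", "O3'", "O4'", "O5'", "OP1", "OP2", "OP3"}

BASE_RING_ATOMS = {
    "purine": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "pyrimidine": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

_WC_PATTERNS = {
    frozenset({"G", "C"}): {frozenset({"O6", "N4"}), frozenset({"N1", "N3"}), frozenset({"N2", "O2"})},
    frozenset({"A", "U"}): {frozenset({"N6", "O4"}), frozenset({"N1", "N3"})},
    frozenset({"A", "T"}): {frozenset({"N6", "O4"}), frozenset({"N1", "N3"})},
}


def _base_letter(res: ResidueRecord) -> str:
    return res.name.lstrip("D")[:1]


def _roles(res: ResidueRecord, atom: AtomRecord) -> tuple[bool, bool]:
    """(is_donor, is_acceptor) for a heavy atom, by residue context."""
    if res.kind == "water":
        return True, True
    if res.is_nucleotide:
        b = _base_letter(res)
        if atom.name in _BASE_DONORS.get(b, set()) or atom.name in _SUGAR_DONORS:
            donor = True
        else:
            donor = False
        acceptor = atom.name in _BASE_ACCEPTORS.get(b, set()) or atom.name in _SUGAR_ACCEPTORS
        return donor, acceptor
    if res.kind == "protein":
        if atom.element == "N":
            return True, atom.name in ("ND1", "NE2", "N")  # His/backbone N can accept
        if atom.element == "O":
            return atom.name in ("OG", "OG1", "OH"), True
        return False, False
    # generic fallback for 'other' residues
    return atom.element in ("N", "O"), atom.element in ("N", "O")


@dataclass(frozen=True)
class AtomRef:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str

    def __str__(self) -> str:
        return f"{self.chain}/{self.residue_name}{self.residue_number}/{self.atom_name}"


@dataclass
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float


@dataclass
class BasePair:
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    pair_class: str  # watson_crick | non_watson_crick | other
    hbonds: list[HBond] = field(default_factory=list)
    bases: tuple[str, str] = ("", "")


@dataclass
class Tetrad:
    guanines: tuple[tuple[str, int], ...]  # cyclic donor->acceptor order
    mean_hbond_distance: float
    centroid: np.ndarray
    normal: np.ndarray


@dataclass
class Quadruplex:
    tetrads: list[Tetrad]
    twist_angles: list[float]
    rises: list[float]
    strand_orientation: str
    channel_ions: list[AtomRef] = field(default_factory=list)


def _flatten(model: StructureModel, selection=None):
    """(chain, residue, atom) triples; selection is a chain-name set or a
    predicate over (chain, residue)."""
    for chain in model.chains:
        for res in chain.residues:
            if selection is not None:
                if callable(selection):
                    if not selection(chain, res):
                        continue
                elif chain.name not in selection:
                    continue
            for atom in res.atoms:
                yield chain, res, atom


def _covalently_linked(c1, r1, a1, c2, r2, a2) -> bool:
    """Conservative exclusion of bonded pairs between adjacent residues."""
    if c1.name != c2.name:
        return False
    if abs(r1.author_number - r2.author_number) != 1:
        return False
    pair = {a1.name, a2.name}
    return pair in ({"O3'", "P"}, {"C", "N"})


def detect_hbonds(model: StructureModel, cutoff: float = HBOND_CUTOFF, selection=None) -> list[HBond]:
    """All donor-acceptor heavy-atom pairs within ``cutoff`` Å.

    Pairs within the same residue and covalently bonded inter-residue
    pairs (O3'-P, peptide C-N) are excluded. Symmetric in atom order:
    an atom that can both donate and accept yields one bond per role
    pairing, deduplicated on the atom pair.
    """
    if not 2.4 <= cutoff <= 4.0:
        raise ValueError("h-bond cutoff must be within [2.4, 4.0] Å")
    entries = list(_flatten(model, selection))
    if not entries:
        return []
    coords = np.array([a.position for _, _, a in entries])
    tree = cKDTree(coords)
    seen = set()
    out: list[HBond] = []
    for i, j in tree.query_pairs(cutoff):
        c1, r1, a1 = entries[i]
        c2, r2, a2 = entries[j]
        if r1 is r2 or _covalently_linked(c1, r1, a1, c2, r2, a2):
            continue
        d1, ac1 = _roles(r1, a1)
        d2, ac2 = _roles(r2, a2)
        dist = float(np.linalg.norm(a1.position - a2.position))
        if dist < 2.0:  # closer than any plausible h-bond: clash or covalent
            continue
        for (dn_c, dn_r, dn_a), (ac_c, ac_r, ac_a), ok in (
            ((c1, r1, a1), (c2, r2, a2), d1 and ac2),
            ((c2, r2, a2), (c1, r1, a1), d2 and ac1),
        ):
            if not ok:
                continue
            key = frozenset({(dn_c.name, dn_r.author_number, dn_a.name, dn_a.altloc),
                             (ac_c.name, ac_r.author_number, ac_a.name, ac_a.altloc)})
            if key in seen:
                continue
            seen.add(key)
            out.append(
                HBond(
                    donor=AtomRef(dn_c.name, dn_r.author_number, dn_r.name, dn_a.name),
                    acceptor=AtomRef(ac_c.name, ac_r.author_number, ac_r.name, ac_a.name),
                    distance=dist,
                )
            )
            break  # one record per atom pair
    out.sort(key=lambda h: (h.donor.chain, h.donor.residue_number, h.acceptor.chain,
                            h.acceptor.residue_number, h.donor.atom_name, h.acceptor.atom_name))
    return out


def base_frame(res: ResidueRecord) -> tuple[np.ndarray, np.ndarray] | None:
    """(centroid, unit normal) of the base ring, or None if incomplete."""
    ring = BASE_RING_ATOMS["purine"] if res.atom("N9") else BASE_RING_ATOMS["pyrimidine"]
    pts = res.positions(ring)
    if pts is None:
        return None
    return fit_plane(pts)


def _base_atom_names(res: ResidueRecord) -> set[str]:
    ring = BASE_RING_ATOMS["purine"] if res.atom("N9") else BASE_RING_ATOMS["pyrimidine"]
    extra = {"O2", "O4", "O6", "N2", "N4", "N6", "N7"}
    return set(ring) | extra


def detect_base_pairs(model: StructureModel, selection=None, cutoff: float = HBOND_CUTOFF) -> list[BasePair]:
    """Base pairs: >= 2 inter-base hydrogen bonds and near-coplanar rings.

    Canonical A-U/A-T and G-C hydrogen-bonding patterns are classed
    watson_crick; every other base-base pairing (including G-U wobble
    and purine-purine pairs) is non_watson_crick.
    """
    hbonds = detect_hbonds(model, cutoff, selection)
    residues: dict[tuple[str, int], ResidueRecord] = {}
    for chain in model.chains:
        for res in chain.residues:
            if res.is_nucleotide:
                residues[(chain.name, res.author_number)] = res

    grouped: dict[tuple, list[HBond]] = {}
    for hb in hbonds:
        ka = (hb.donor.chain, hb.donor.residue_number)
        kb = (hb.acceptor.chain, hb.acceptor.residue_number)
        if ka == kb or ka not in residues or kb not in residues:
            continue
        ra, rb = residues[ka], residues[kb]
        if hb.donor.atom_name not in _base_atom_names(ra):
            continue
        if hb.acceptor.atom_name not in _base_atom_names(rb):
            continue
        key = tuple(sorted([ka, kb]))
        grouped.setdefault(key, []).append(hb)

    pairs: list[BasePair] = []
    for (ka, kb), bonds in sorted(grouped.items()):
        if len(bonds) < 2:
            continue
        ra, rb = residues[ka], residues[kb]
        fa, fb = base_frame(ra), base_frame(rb)
        if fa is None or fb is None:
            continue
        cosang = abs(float(np.dot(fa[1], fb[1])))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > COPLANARITY_MAX:
            continue
        # the partner base must lie in-plane, not stacked above/below
        offset = max(
            abs(float(np.dot(fb[0] - fa[0], fa[1]))),
            abs(float(np.dot(fa[0] - fb[0], fb[1]))),
        )
        if offset > PAIR_MAX_PLANE_OFFSET:
            continue
        letters = frozenset({_base_letter(ra), _base_letter(rb)})
        pattern = {
            frozenset({hb.donor.atom_name, hb.acceptor.atom_name}) for hb in bonds
        }
        wc = letters in _WC_PATTERNS and len(pattern & _WC_PATTERNS[letters]) >= 2
        pairs.append(
            BasePair(
                residue_a=ka,
                residue_b=kb,
                pair_class="watson_crick" if wc else "non_watson_crick",
                hbonds=bonds,
                bases=(_base_letter(ra), _base_letter(rb)),
            )
        )
    return pairs


def detect_tetrads(model: StructureModel, selection=None, cutoff: float = TETRAD_CUTOFF) -> list[Tetrad]:
    """Directed Hoogsteen 4-cycles of guanines.

    An edge Gi -> Gj exists when N1(i)...O6(j) <= cutoff and
    N2(i)...N7(j) <= cutoff. Tetrads are directed 4-cycles; when cycles
    share guanines, tetrads are accepted greedily by mean hydrogen-bond
    distance.
    """
    guanines: list[tuple[str, ResidueRecord]] = []
    for chain in model.chains:
        for res in chain.residues:
            if selection is not None:
                if callable(selection):
                    if not selection(chain, res):
                        continue
                elif chain.name not in selection:
                    continue
            if res.is_nucleotide and _base_letter(res) == "G":
                if all(res.atom(n) for n in ("N1", "N2", "O6", "N7")):
                    guanines.append((chain.name, res))
    g = nx.DiGraph()
    dist: dict[tuple[int, int], float] = {}
    for i, (_, ri) in enumerate(guanines):
        for j, (_, rj) in enumerate(guanines):
            if i == j:
                continue
            d1 = np.linalg.norm(ri.atom("N1").position - rj.atom("O6").position)
            d2 = np.linalg.norm(ri.atom("N2").position - rj.atom("N7").position)
            if d1 <= cutoff and d2 <= cutoff:
                g.add_edge(i, j)
                dist[(i, j)] = float((d1 + d2) / 2.0)

    candidates = []
    seen_sets = set()
    for cycle in nx.simple_cycles(g, length_bound=4):
        if len(cycle) != 4:
            continue
        key = frozenset(cycle)
        if key in seen_sets:
            continue
        seen_sets.add(key)
        edges = list(zip(cycle, cycle[1:] + cycle[:1]))
        mean_d = float(np.mean([dist[e] for e in edges]))
        candidates.append((mean_d, cycle))
    candidates.sort(key=lambda c: c[0])

    used: set[int] = set()
    tetrads: list[Tetrad] = []
    for mean_d, cycle in candidates:
        if used & set(cycle):
            continue
        used |= set(cycle)
        pts = np.vstack([
            guanines[i][1].positions(BASE_RING_ATOMS["purine"]) for i in cycle
        ])
        centroid, normal = fit_plane(pts)
        tetrads.append(
            Tetrad(
                guanines=tuple((guanines[i][0], guanines[i][1].author_number) for i in cycle),
                mean_hbond_distance=mean_d,
                centroid=centroid,
                normal=normal,
            )
        )
    return tetrads


def _c1_positions(model: StructureModel, tetrad: Tetrad) -> np.ndarray:
    pts = []
    for chain_name, num in tetrad.guanines:
        res = model.chain(chain_name).residue(num)
        pts.append(res.atom("C1'").position)
    return np.array(pts)


def _fold_quarter(delta: float) -> float:
    """Fold an angular offset into [0, 90] given 4-fold near-symmetry."""
    d = abs((delta + 180.0) % 360.0 - 180.0)
    return min(d, abs(180.0 - d)) if d > 90.0 else d


def assemble_quadruplex(
    model: StructureModel,
    tetrads: list[Tetrad],
    rise_window: tuple[float, float] = STACK_DISTANCE,
    normal_max: float = COPLANARITY_MAX,
) -> Quadruplex:
    """Stack tetrads into a quadruplex and measure inter-tetrad twist.

    Consecutive tetrads must have centroid separation inside the
    stacking window and near-parallel normals. Twist is the mean angular
    offset, about the stacking axis, between C1' positions of one tetrad
    and their nearest counterparts in the next (folded into [0, 90]).
    """
    if len(tetrads) < 2:
        return Quadruplex(tetrads=list(tetrads), twist_angles=[], rises=[],
                          strand_orientation="n/a")
    # order along the consensus normal
    axis = tetrads[0].normal
    order = sorted(tetrads, key=lambda t: float(np.dot(t.centroid, axis)))
    stacked = [order[0]]
    twists: list[float] = []
    rises: list[float] = []
    for t in order[1:]:
        prev = stacked[-1]
        sep = float(np.linalg.norm(t.centroid - prev.centroid))
        cosang = abs(float(np.dot(t.normal, prev.normal)))
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        if not (rise_window[0] <= sep <= rise_window[1]) or ang > normal_max:
            continue
        ax = t.centroid - prev.centroid
        ax = ax / np.linalg.norm(ax)
        centre = 0.5 * (t.centroid + prev.centroid)
        e1 = np.cross(ax, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(ax, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(ax, e1)

        def angles(tet):
            p = _c1_positions(model, tet) - centre
            return np.degrees(np.arctan2(p @ e2, p @ e1))

        a_prev, a_next = angles(prev), angles(t)
        deltas = [min(_fold_quarter(b - a) for b in a_next) for a in a_prev]
        twists.append(float(np.mean(deltas)))
        rises.append(sep)
        stacked.append(t)

    orientation = _strand_orientation(model, stacked)
    ions = _channel_ions(model, stacked)
    return Quadruplex(tetrads=stacked, twist_angles=twists, rises=rises,
                      strand_orientation=orientation, channel_ions=ions)


def _strand_orientation(model: StructureModel, tetrads: list[Tetrad]) -> str:
    """Consensus of glycosidic-bond (C1'->N9) directions projected on the axis."""
    if not tetrads:
        return "n/a"
    axis = tetrads[0].normal
    signs = []
    for tet in tetrads:
        for chain_name, num in tet.guanines:
            res = model.chain(chain_name).residue(num)
            c1, n9 = res.atom("C1'"), res.atom("N9")
            if c1 is None or n9 is None:
                continue
            v = n9.position - c1.position
            # project into the tetrad plane and take the circulation sense
            r = c1.position - tet.centroid
            signs.append(np.sign(np.dot(np.cross(r, v), axis)))
    if not signs:
        return "n/a"
    pos = sum(1 for s in signs if s > 0)
    neg = len(signs) - pos
    if pos == 0 or neg == 0:
        return "parallel"
    return "antiparallel" if abs(pos - neg) == 0 else "mixed"


def _channel_ions(model: StructureModel, tetrads: list[Tetrad], radius: float = 3.5) -> list:
    ions = []
    for chain, res, atom in model.metal_ions():
        for a, b in zip(tetrads, tetrads[1:] or tetrads):
            centre = 0.5 * (a.centroid + b.centroid)
            if np.linalg.norm(atom.position - centre) <= radius:
                ions.append(AtomRef(chain.name, res.author_number, res.name, atom.name))
                break
    return ions


def detect_stacking(model: StructureModel, selection=None) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Base-on-base stacking: centroid distance in the stacking window,
    near-parallel normals, and a non-trivial offset along the mean normal
    (to exclude coplanar hydrogen-bonded neighbours)."""
    frames = []
    for chain in model.chains:
        for res in chain.residues:
            if selection is not None:
                if callable(selection):
                    if not selection(chain, res):
                        continue
                elif chain.name not in selection:
                    continue
            if not res.is_nucleotide:
                continue
            f = base_frame(res)
            if f is not None:
                frames.append(((chain.name, res.author_number), f[0], f[1]))
    out = []
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            (ki, ci, ni), (kj, cj, nj) = frames[i], frames[j]
            sep = float(np.linalg.norm(ci - cj))
            if not (STACK_DISTANCE[0] <= sep <= STACK_DISTANCE[1]):
                continue
            cosang = abs(float(np.dot(ni, nj)))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > STACK_NORMAL_MAX:
                continue
            mean_n = ni if np.dot(ni, nj) >= 0 else -nj
            if abs(float(np.dot(ci - cj, mean_n))) < STACK_MIN_OFFSET:
                continue
            out.append(tuple(sorted([ki, kj])))
    return sorted(set(out))


def stacked_on_tetrad(model: StructureModel, tetrad: Tetrad, key: tuple[str, int]) -> bool:
    """True when the given residue stacks on any guanine of the tetrad."""
    stacked = detect_stacking(model)
    tet_keys = set(tetrad.guanines)
    return any(key in pair and (set(pair) - {key}) & tet_keys for pair in stacked)


def helix_handedness(model: StructureModel, chain_name: str, atom_name: str = "C1'") -> str:
    """'right' or 'left' from the sense of angular progression along the
    principal axis of the chain's marker atoms."""
    chain = model.chain(chain_name)
    pts = np.array([
        r.atom(atom_name).position for r in chain.residues if r.atom(atom_name) is not None
    ])
    if len(pts) < 4:
        raise ValueError("need at least 4 marker atoms to call handedness")
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid)
    axis = vt[0]
    z = (pts - centroid) @ axis
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    theta = np.unwrap(np.arctan2((pts - centroid) @ e2, (pts - centroid) @ e1))
    slope = np.polyfit(z, theta, 1)[0]
    return "right" if slope > 0 else "left"
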