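"""Hierarchical coordinate model for mirror-image aptamer:protein complexes.

The model wraps the content of PDB/mmCIF files (read and written through
gemmi) in a small chain/residue/atom hierarchy that carries two extra
annotations the downstream analyses need and the file formats do not
provide: the polymer *kind* of every residue (protein, ribonucleotide,
deoxyribonucleotide, water, metal ion, other) and the sugar *chirality*
(D for natural nucleotides, L for Spiegelmer nucleotides).

Chirality is geometric, not nomenclatural: deposited L-nucleotides often
carry standard residue names, so the flag is derived from the improper
configuration of the sugar ring (see :func:`detect_chirality`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "Chain",
    "StructureModel",
    "MixedSequence",
    "read_structure",
    "write_structure",
    "mirror_structure",
    "detect_chirality",
    "parse_mixed_sequence",
    "structure_summary",
]

# Residue-name lookup used when the file carries no entity information.
RIBO_NAMES = {"A", "C", "G", "U", "I"}
DEOXY_NAMES = {"DA", "DC", "DG", "DT", "DU", "DI"}
WATER_NAMES = {"HOH", "WAT", "DOD"}
METAL_NAMES = {"CA", "MG", "K", "NA", "ZN", "MN", "FE", "SR", "RB", "CS", "LI", "BA", "CD", "NI", "CU", "CO"}
PROTEIN_NAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

SUGAR_RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")

# Sign of the improper configuration at C4' (C3', C5', O4' triple product)
# for a natural D-ribose; calibrated against the CCD ideal-coordinate
# nucleotide templates (see tests). D-sugars give a negative volume.
_D_SUGAR_SIGN = -1.0


@dataclass
class AtomRecord:
    """A single atom: PDB-convention name, element, position in Å."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1] for atom {self.name}")


@dataclass
class ResidueRecord:
    """A residue with author numbering, polymer kind and chirality tag."""

    name: str
    author_number: int
    insertion_code: str = ""
    kind: str = "other"  # protein | ribonucleotide | deoxyribonucleotide | water | metal_ion | other
    chirality: str = "not_applicable"  # L | D | not_applicable
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def positions(self, names) -> np.ndarray | None:
        """Stacked positions for the named atoms, or None if any is missing."""
        out = []
        for n in names:
            a = self.atom(n)
            if a is None:
                return None
            out.append(a.position)
        return np.array(out)

    @property
    def is_nucleotide(self) -> bool:
        return self.kind in ("ribonucleotide", "deoxyribonucleotide")

    @property
    def key(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)

    def label(self) -> str:
        prefix = "d" if self.kind == "deoxyribonucleotide" else ""
        base = self.name.lstrip("D") if self.is_nucleotide else self.name
        return f"{prefix}{base}{self.author_number}"


@dataclass
class Chain:
    name: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def residue(self, number: int, icode: str = "") -> ResidueRecord | None:
        for r in self.residues:
            if r.author_number == number and r.insertion_code == icode:
                return r
        return None

    @property
    def n_nucleotides(self) -> int:
        return sum(r.is_nucleotide for r in self.residues)

    @property
    def n_protein_residues(self) -> int:
        return sum(r.kind == "protein" for r in self.residues)


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)
    identifier: str = ""
    source_format: str = "PDB"

    def chain(self, name: str) -> Chain | None:
        for c in self.chains:
            if c.name == name:
                return c
        return None

    def residues(self):
        for c in self.chains:
            yield from c.residues

    def atoms(self):
        for r in self.residues():
            yield from r.atoms

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms()])

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def nucleic_chains(self, min_length: int = 2) -> list[Chain]:
        """Chains selected by content: mostly nucleotides, at least min_length."""
        return [c for c in self.chains if c.n_nucleotides >= max(min_length, c.n_protein_residues + 1)]

    def protein_chains(self, min_length: int = 10) -> list[Chain]:
        return [c for c in self.chains if c.n_protein_residues >= max(min_length, c.n_nucleotides + 1)]

    def metal_ions(self) -> list[tuple[Chain, ResidueRecord, AtomRecord]]:
        out = []
        for c in self.chains:
            for r in c.residues:
                if r.kind == "metal_ion":
                    for a in r.atoms:
                        out.append((c, r, a))
        return out

    def copy(self) -> "StructureModel":
        chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [
                    AtomRecord(a.name, a.element, a.position.copy(), a.occupancy, a.altloc, a.b_factor)
                    for a in r.atoms
                ]
                residues.append(
                    ResidueRecord(r.name, r.author_number, r.insertion_code, r.kind, r.chirality, atoms)
                )
            chains.append(Chain(c.name, residues))
        return StructureModel(chains, self.identifier, self.source_format)


@dataclass
class MixedSequence:
    """An ordered mixed ribo/deoxyribo sequence, e.g. a Spiegelmer sequence."""

    nucleotides: list[tuple[str, bool]]  # (base letter, is_deoxy)

    @property
    def length(self) -> int:
        return len(self.nucleotides)

    @property
    def deoxy_positions(self) -> list[int]:
        """1-based positions carrying a deoxyribose."""
        return [i + 1 for i, (_, d) in enumerate(self.nucleotides) if d]

    def __str__(self) -> str:
        return "".join(f"(d{b})" if d else b for b, d in self.nucleotides)


def classify_residue_kind(name: str, atom_names: set[str], entity_kind: str | None = None) -> str:
    """Residue-kind typing.

    Precedence: polymer entity record (mmCIF) > residue-name table >
    O2' heuristic for otherwise-nucleotide-looking residues. Deposited
    mirror-image nucleotides may carry nonstandard names, so naming alone
    is not trusted when the sugar ring is present.
    """
    name = name.strip().upper()
    if entity_kind in ("ribonucleotide", "deoxyribonucleotide", "protein"):
        return entity_kind
    if name in WATER_NAMES:
        return "water"
    if name in METAL_NAMES and len(atom_names) == 1:
        return "metal_ion"
    if name in PROTEIN_NAMES:
        return "protein"
    has_ring = all(a in atom_names for a in SUGAR_RING_ATOMS)
    if name in RIBO_NAMES or name in DEOXY_NAMES or has_ring:
        if "O2'" in atom_names:
            return "ribonucleotide"
        if has_ring or name in DEOXY_NAMES:
            return "deoxyribonucleotide"
        return "ribonucleotide"
    if {"N", "CA", "C", "O"} <= atom_names:
        return "protein"
    return "other"


def _entity_kind(subchain: str, structure: gemmi.Structure) -> str | None:
    for ent in structure.entities:
        if subchain in ent.subchains:
            pt = ent.polymer_type
            if pt == gemmi.PolymerType.PeptideL or pt == gemmi.PolymerType.PeptideD:
                return "protein"
            if pt == gemmi.PolymerType.Rna:
                return "ribonucleotide"
            if pt == gemmi.PolymerType.Dna:
                return "deoxyribonucleotide"
    return None


def read_structure(path, fmt: str = "auto", keep_altlocs: bool = False) -> StructureModel:
    """Read a PDB or mmCIF file (gzip-transparent) into a StructureModel.

    By default only the highest-occupancy conformer of each alternate-
    location group is kept; pass ``keep_altlocs=True`` to retain all.
    Unknown residue names are typed ``other`` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()

    source = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        residues = []
        for res in ch:
            atoms = []
            # altloc policy: group by name, keep the highest-occupancy conformer
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                chosen = group if keep_altlocs else [max(group, key=lambda a: a.occ)]
                for at in chosen:
                    atoms.append(
                        AtomRecord(
                            name=name,
                            element=at.element.name,
                            position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=min(max(at.occ, 0.0), 1.0),
                            altloc=at.altloc if at.altloc != "\x00" else "",
                            b_factor=at.b_iso,
                        )
                    )
            atom_names = {a.name for a in atoms}
            kind = classify_residue_kind(res.name, atom_names, _entity_kind(res.subchain, st))
            if kind == "other" and res.name.strip().upper() not in WATER_NAMES:
                warnings.warn(f"unknown residue name {res.name!r}; typed as 'other'", stacklevel=2)
            rr = ResidueRecord(
                name=res.name.strip(),
                author_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                kind=kind,
                atoms=atoms,
            )
            if rr.is_nucleotide:
                rr.chirality = detect_chirality(rr)
            residues.append(rr)
        chains.append(Chain(ch.name, residues))
    return StructureModel(chains=chains, identifier=st.name or path.stem, source_format=source)


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.identifier
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.name)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
            gr.het_flag = "H" if res.kind in ("water", "metal_ion", "other") else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc or "\x00"
                ga.b_iso = atom.b_factor
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path, fmt: str = "auto") -> None:
    """Write the model as PDB or mmCIF (chosen from the extension by default)."""
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def mirror_structure(model: StructureModel) -> StructureModel:
    """Reflect the structure through the XY plane: (x, y, z) -> (x, y, -z).

    All interatomic distances are preserved exactly, every torsion angle
    is negated, and every sugar chirality flag flips L <-> D.
    """
    out = model.copy()
    for atom in out.atoms():
        atom.position[2] = -atom.position[2]
    for res in out.residues():
        if res.chirality == "L":
            res.chirality = "D"
        elif res.chirality == "D":
            res.chirality = "L"
    return out


def detect_chirality(residue: ResidueRecord) -> str:
    """Geometric sugar chirality of a nucleotide: 'D', 'L' or 'not_applicable'.

    Uses the sign of the improper (out-of-plane) configuration at C4'
    (triple product of the C4'->C3', C4'->C5', C4'->O4' bond vectors),
    which is positive for natural D-sugars and negative for their mirror
    images. Falls back to the equivalent improper at C1' (O4', C2',
    glycosidic N) when C5' is absent.
    """
    pts = residue.positions(("C4'", "C3'", "C5'", "O4'"))
    if pts is not None:
        c4, c3, c5, o4 = pts
        vol = np.dot(np.cross(c3 - c4, c5 - c4), o4 - c4)
    else:
        n_gly = residue.atom("N9") or residue.atom("N1")
        pts = residue.positions(("C1'", "O4'", "C2'"))
        if pts is None or n_gly is None:
            warnings.warn(
                f"residue {residue.name}{residue.author_number}: incomplete sugar, chirality undetermined",
                stacklevel=2,
            )
            return "not_applicable"
        c1, o4, c2 = pts
        # the C1' improper has the opposite sense from the C4' one
        vol = -np.dot(np.cross(o4 - c1, c2 - c1), n_gly.position - c1)
    if abs(vol) < 1e-9:
        return "not_applicable"
    return "D" if vol * _D_SUGAR_SIGN > 0 else "L"


def parse_mixed_sequence(text: str) -> MixedSequence:
    """Parse mixed ribo/deoxyribo sequence notation, e.g. "GCGAUG(dU)GG...".

    Plain letters are ribonucleotides; parenthesised d-prefixed letters,
    e.g. "(dU)", are deoxyribonucleotides. 5'/3' end decorations and
    whitespace/hyphens are ignored.
    """
    s = text.replace("5'-", "").replace("-3'", "").replace("5′-", "").replace("-3′", "")
    s = s.replace("5'", "").replace("3'", "").replace("5′", "").replace("3′", "")
    nts: list[tuple[str, bool]] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch in " -\t\n":
            i += 1
            continue
        if ch == "(":
            j = s.find(")", i)
            if j < 0:
                raise ValueError(f"unbalanced parenthesis at offset {i}")
            token = s[i + 1 : j].strip()
            if len(token) != 2 or token[0] not in "dD" or token[1].upper() not in "ACGUT":
                raise ValueError(f"illegal deoxy token {token!r} at offset {i}")
            nts.append((token[1].upper(), True))
            i = j + 1
        elif ch == ")":
            raise ValueError(f"unbalanced parenthesis at offset {i}")
        elif ch.upper() in "ACGUT":
            nts.append((ch.upper(), False))
            i += 1
        else:
            raise ValueError(f"illegal character {ch!r} at offset {i}")
    return MixedSequence(nts)


def structure_summary(model: StructureModel) -> dict:
    """JSON-serialisable summary of chain contents."""
    return {
        "identifier": model.identifier,
        "source_format": model.source_format,
        "n_atoms": model.n_atoms,
        "chains": [
            {
                "name": c.name,
                "n_residues": len(c.residues),
                "n_nucleotides": c.n_nucleotides,
                "n_protein_residues": c.n_protein_residues,
                "kinds": sorted({r.kind for r in c.residues}),
                "chiralities": sorted({r.chirality for r in c.residues if r.is_nucleotide}),
            }
            for c in model.chains
        ],
    }


def summary_json(model: StructureModel) -> str:
    return json.dumps(structure_summary(model), indent=2)
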