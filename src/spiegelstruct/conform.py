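"""Nucleotide conformational annotation: glycosidic torsion and sugar pucker.

Mirror-image (L) nucleotides are always evaluated after reflecting the
residue into the natural D frame, so the standard syn/anti and
pseudorotation vocabulary applies unchanged; the reflection negates all
torsions, which leaves the syn/anti call invariant (the boundary is
symmetric in chi) and leaves the pucker name invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import dihedral, wrap180
from .model import Chain, ResidueRecord, StructureModel

__all__ = [
    "TorsionProfile",
    "glycosidic_chi",
    "classify_glycosidic",
    "pseudorotation",
    "pucker_name_from_phase",
    "annotate_structure",
    "MissingAtomError",
]

SYN_BOUNDARY = 90.0  # |chi| <= 90 deg -> syn
AMBIGUITY_MARGIN = 5.0  # deg; calls closer than this to an edge are flagged

# endocyclic torsion definitions nu0..nu4 (atom quadruples)
NU_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

# canonical envelope names on the 18-degree pseudorotation wheel
PUCKER_WHEEL = (
    (18.0, "3'-endo"),
    (54.0, "4'-exo"),
    (90.0, "O4'-endo"),
    (126.0, "1'-exo"),
    (162.0, "2'-endo"),
    (198.0, "3'-exo"),
    (234.0, "4'-endo"),
    (270.0, "O4'-exo"),
    (306.0, "1'-endo"),
    (342.0, "2'-exo"),
)

MIN_AMPLITUDE = 5.0  # deg; below this the ring is effectively planar


class MissingAtomError(ValueError):
    """A torsion-defining atom is absent from the residue."""


def _d_frame_positions(residue: ResidueRecord, names) -> np.ndarray:
    """Positions of the named atoms, mirrored to the D frame for L residues."""
    pts = residue.positions(names)
    if pts is None:
        missing = [n for n in names if residue.atom(n) is None]
        raise MissingAtomError(
            f"residue {residue.name}{residue.author_number}: missing atom(s) {missing}"
        )
    if residue.chirality == "L":
        pts = pts * np.array([1.0, 1.0, -1.0])
    return pts


def glycosidic_chi(residue: ResidueRecord, frame: str = "mirrored-to-D") -> float:
    """Glycosidic torsion chi in degrees, IUPAC convention.

    Purines: O4'-C1'-N9-C4; pyrimidines: O4'-C1'-N1-C2. L residues are
    evaluated in the mirrored-to-D frame unless ``frame='as-deposited'``.
    """
    purine = residue.atom("N9") is not None
    names = ("O4'", "C1'", "N9", "C4") if purine else ("O4'", "C1'", "N1", "C2")
    if frame == "as-deposited":
        pts = residue.positions(names)
        if pts is None:
            missing = [n for n in names if residue.atom(n) is None]
            raise MissingAtomError(
                f"residue {residue.name}{residue.author_number}: missing atom(s) {missing}"
            )
    else:
        pts = _d_frame_positions(residue, names)
    return dihedral(*pts)


def classify_glycosidic(chi: float) -> str:
    """'syn' iff |chi| <= 90 degrees, else 'anti'; invariant under chi -> -chi."""
    if not np.isfinite(chi):
        raise ValueError("chi must be finite")
    return "syn" if abs(wrap180(chi)) <= SYN_BOUNDARY else "anti"


def pseudorotation(residue: ResidueRecord) -> tuple[float, float, str]:
    """Altona-Sundaralingam pseudorotation of the sugar ring.

    Returns (phase P in [0, 360), amplitude in degrees, pucker name).
    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72)),
    with 180 degrees added when nu2 < 0. Rings with amplitude below
    5 degrees are named "planar/indeterminate".
    """
    ring = ("C1'", "C2'", "C3'", "C4'", "O4'")
    pos = {n: p for n, p in zip(ring, _d_frame_positions(residue, ring))}
    nu = [dihedral(*(pos[a] for a in quad)) for quad in NU_ATOMS]
    denom = 2.0 * nu[2] * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    p = np.degrees(np.arctan(((nu[4] + nu[1]) - (nu[3] + nu[0])) / denom)) if denom != 0 else 90.0
    if nu[2] < 0:
        p += 180.0
    p %= 360.0
    amplitude = abs(nu[2] / np.cos(np.radians(p))) if abs(np.cos(np.radians(p))) > 1e-9 else abs(
        (nu[4] + nu[1] - nu[3] - nu[0]) / (2 * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0))))
    )
    if amplitude < MIN_AMPLITUDE:
        return p, amplitude, "planar/indeterminate"
    return p, amplitude, pucker_name_from_phase(p)


def pucker_name_from_phase(phase: float) -> str:
    """Nearest canonical envelope on the pseudorotation wheel."""
    phase %= 360.0
    diffs = [min(abs(phase - c), 360.0 - abs(phase - c)) for c, _ in PUCKER_WHEEL]
    return PUCKER_WHEEL[int(np.argmin(diffs))][1]


def _near_boundary_chi(chi: float) -> bool:
    return abs(abs(wrap180(chi)) - SYN_BOUNDARY) < AMBIGUITY_MARGIN


def _near_boundary_pucker(phase: float) -> bool:
    # sector edges sit halfway between wheel centres, at multiples of 36 deg
    return float(np.min(np.abs((phase % 36.0) - np.array([0.0, 36.0])))) < AMBIGUITY_MARGIN


@dataclass
class TorsionProfile:
    chain: str
    number: int
    base: str
    deoxy: bool
    chirality: str
    chi: float
    glycosidic_class: str
    phase_P: float
    amplitude: float
    pucker_name: str
    ambiguous_chi: bool
    ambiguous_pucker: bool
    frame: str = "mirrored-to-D"


def annotate_residue(residue: ResidueRecord, chain_name: str = "") -> TorsionProfile:
    chi = glycosidic_chi(residue)
    p, amp, pucker = pseudorotation(residue)
    return TorsionProfile(
        chain=chain_name,
        number=residue.author_number,
        base=residue.name.lstrip("D"),
        deoxy=residue.kind == "deoxyribonucleotide",
        chirality=residue.chirality,
        chi=chi,
        glycosidic_class=classify_glycosidic(chi),
        phase_P=p,
        amplitude=amp,
        pucker_name=pucker,
        ambiguous_chi=_near_boundary_chi(chi),
        ambiguous_pucker=_near_boundary_pucker(p),
    )


def annotate_structure(model: StructureModel, chains: list[str] | None = None) -> pd.DataFrame:
    """Per-nucleotide conformational table for the selected chains."""
    rows = []
    for chain in model.chains:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain.residues:
            if not res.is_nucleotide:
                continue
            try:
                rows.append(annotate_residue(res, chain.name).__dict__)
            except MissingAtomError:
                continue
    return pd.DataFrame(rows)


def annotate_chain(chain: Chain) -> pd.DataFrame:
    return annotate_structure(StructureModel([chain]))
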