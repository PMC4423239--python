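"""Published aptamer sequences and reference residue sets.

These strings are inputs to the analyses (mixed L-RNA/L-DNA notation:
plain letters are L-ribonucleotides, parenthesised (dX) tokens are
L-deoxyribonucleotides). NOX-D20 is the 40-nt C5a-binding Spiegelmer
with six ribo-to-deoxyribo exchanges; NOX-D19 is its 44-nt all-L-RNA
predecessor.
"""

from .model import MixedSequence, parse_mixed_sequence

NOX_D20_NOTATION = "5'-GCGAUG(dU)GGUGGU(dG)(dA)AGGGUUGUUGGG(dU)G(dU)CGACGCA(dC)GC-3'"
NOX_D19_NOTATION = "5'-GCCUGAUGUGGUGGUGAAGGGUUGUUGGGUGUCGACGCACAGGC-3'"


def nox_d20() -> MixedSequence:
    return parse_mixed_sequence(NOX_D20_NOTATION)


def nox_d19() -> MixedSequence:
    return parse_mixed_sequence(NOX_D19_NOTATION)


# mouse C5a residues contacting the aptamer (author numbering of the
# C5 precursor), assembled from the published interface description
MC5A_CONTACT_RESIDUES = frozenset(
    {688, 695, 696, 697, 701, 704, 705, 708, 710, 713, 721, 723}
)

# aptamer nucleotides forming the two stacked G-tetrads (chain positions 1-40)
TETRAD_1 = frozenset({17, 19, 25, 27})
TETRAD_2 = frozenset({18, 22, 26, 32})

# guanosines in the syn glycosidic conformation
SYN_GUANOSINES = frozenset({8, 14, 17, 25})

# sugar puckers deviating from the common 3'-endo / 2'-endo pair
PUCKER_EXCEPTIONS = {7: "4'-exo", 9: "2'-exo", 14: "4'-exo", 25: "4'-exo", 26: "2'-exo"}
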