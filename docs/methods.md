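# Methods

This note documents the models and conventions behind `spiegelstruct`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the design choices made where the design was genuinely open.

## Coordinate model and chirality

Structures are read and written through gemmi (PDB and mmCIF, gzip
transparent) into a plain chain/residue/atom hierarchy. Two annotations
are attached on reading:

**Residue kind** (protein / ribonucleotide / deoxyribonucleotide / water /
metal ion / other) is typed with the precedence *mmCIF polymer entity >
residue-name table > O2′ heuristic*. The heuristic matters because
deposited mirror-image nucleotides may carry nonstandard names: any
residue with a complete C1′–C4′/O4′ sugar ring is treated as a
nucleotide, deoxy when O2′ is absent.

**Sugar chirality** is geometric, never name-based: the sign of the
improper volume at C4′ (triple product of the C4′→C3′, C4′→C5′, C4′→O4′
bonds) is negative for natural D-sugars — the sign convention is
calibrated against the CCD ideal-coordinate nucleotide templates, which
serve as an external D reference in the tests. A C1′-based improper is
the fallback when C5′ is missing. Mirroring a structure flips every
verdict L↔D.

**Mirror transform.** The mirror operation negates the z coordinate of
every atom. Any reflection plane is equivalent up to rotation; the
z-plane is the convention used when mirror-image models are built for
phasing, and it makes the operation an exact involution and an exact
isometry (bit-identical distances), which the tests assert.

**Alternate locations.** By default only the highest-occupancy conformer
of each altloc group is kept (`keep_altlocs=True` retains all). This
matters for conformational work: a nucleotide alternating between syn
and anti in the deposited model should be annotated from its dominant
conformer unless the user asks for both.

## Conformational annotation

All descriptors for L-residues are computed after reflecting the residue
into the D frame. Reflection negates torsions, so syn/anti (symmetric
boundary) and pucker names are unchanged, and the standard nomenclature
applies to mirror-image sugars without inventing an L-vocabulary.

* **Glycosidic χ**: O4′–C1′–N9–C4 (purines), O4′–C1′–N1–C2
  (pyrimidines), IUPAC sign, (−180°, 180°].
* **syn/anti**: syn iff |χ| ≤ 90°. The published structure descriptions
  give verdicts, not boundaries; the conventional bisection reproduces
  all of them. Calls within 5° of the boundary carry an `ambiguous_chi`
  flag rather than a silent verdict.
* **Pseudorotation**: Altona–Sundaralingam from the five endocyclic
  torsions, `tan P = ((ν₄+ν₁) − (ν₃+ν₀)) / (2ν₂(sin36°+sin72°))`, +180°
  when ν₂ < 0; amplitude ν_max = ν₂/cos P. Pucker names are the ten
  envelope positions on the 18° wheel (3′-endo ≈ 18°, 4′-exo ≈ 54°, …,
  2′-exo ≈ 342°), assigned by nearest centre; amplitudes below 5° are
  "planar/indeterminate", and phases within 5° of a 36° sector edge are
  flagged `ambiguous_pucker`.

## Base pairing, stacking and quadruplexes

Deposited structures at 1.8–2.0 Å carry no hydrogens, so all hydrogen
bonding is heavy-atom donor–acceptor geometry with a 3.5 Å default
cutoff (configurable within [2.4, 4.0] Å). Donor/acceptor roles come
from a per-base atom table (sugar O2′ donates; phosphate and sugar
oxygens accept; waters do both), with an element-based fallback for
non-standard residues. Everything is distance-based, hence exactly
mirror-invariant.

A **base pair** needs ≥ 2 inter-base hydrogen bonds, ring normals within
30°, and each base centroid within 1.8 Å of the partner's base plane.
The third criterion is what separates in-plane pairing from stacking
(parallel planes 3–4 Å apart would otherwise satisfy the first two);
1.8 Å tolerates the propeller twist of real pairs. Canonical A-U/A-T and
G-C hydrogen-bond patterns class as Watson–Crick; everything else
(including G-U wobble) is non-Watson–Crick.

**Stacking**: ring-centroid separation in [2.8, 4.5] Å, normals within
30°, and a ≥ 1.5 Å offset along the mean normal to exclude coplanar
hydrogen-bonded neighbours.

**G-tetrads** are directed 4-cycles in the graph with an edge Gi→Gj when
N1(i)…O6(j) ≤ 3.5 Å *and* N2(i)…N7(j) ≤ 3.5 Å (the Hoogsteen pattern).
Cycles sharing guanines are disambiguated greedily by mean hydrogen-bond
distance. Tetrads stack into a quadruplex when mean-plane centroids are
2.8–4.5 Å apart with normals within 30°. The **inter-tetrad twist** is
the mean angular offset about the stacking axis between C1′ positions of
one tetrad and their nearest counterparts in the next, folded into
[0°, 90°]; C1′ atoms are used because they sit farthest from the axis and
are numerically stable. Published twist values for quadruplexes rarely
state their metric, so comparisons against them carry a ±10° tolerance.
Strand orientation is the consensus circulation sense of the glycosidic
C1′→N9 vectors about the axis (parallel / antiparallel / mixed).

## Ion sites

A coordination sphere collects all O/N atoms within the cutoff
(default 3.0 Å — covers K–O at 2.81 Å with margin while excluding the
second shell; configurable within [2.0, 3.5] Å), classed as water,
phosphate O, base O, sugar O, base N, or protein O/N. The species score
is the z-score of the observed mean ligand distance against survey
statistics:

| species | μ (Å) | σ (Å) | plausible CN |
|---------|-------|-------|--------------|
| Mg²⁺    | 2.08  | 0.06  | 5–6          |
| Ca²⁺    | 2.43  | 0.11  | 6–8          |
| K⁺      | 2.81  | 0.10  | 6–9          |
| Na⁺     | 2.38  | 0.10  | 5–6          |

The assignment is the argmin among CN-compatible species, but the
verdict becomes **"ambiguous"** whenever any species — CN-compatible or
not — scores within one z-unit of the best. Na⁺ is kept in the table
deliberately: Ca²⁺ and Na⁺ overlap so strongly in distance that geometry
alone cannot separate them, and the classifier must say so rather than
fake certainty; resolving that ambiguity requires anomalous-scattering
evidence, which is out of scope. Ions are attributed to a polymer chain
when that chain provides ≥ 2 non-water ligands; a colinearity helper
reports the maximum deviation of ion triples from their best-fit line.
Because the printed distance summaries of deposited sites may be either
per-site means or per-bond extremes, the ion report emits both.

## Surface areas

SASA is Shrake–Rupley with a deterministic golden-spiral lattice
(default 960 points, probe 1.4 Å, radii C 1.70 / N 1.55 / O 1.52 /
P 1.80 / S 1.80 Å with a config override). The lattice is expressed in a
canonical molecule frame (covariance eigenvectors oriented by
third-moment sign), which makes the computed area *exactly* invariant
under global rotation, translation and mirroring — not merely to
quadrature error — except for inputs whose inertia tensor is exactly
degenerate, where the value is still deterministic per input. Buried
surface area is the two-sided sum SASA(A) + SASA(B) − SASA(AB), with all
three areas computed on one shared lattice frame and differenced
per-atom in canonical order, so separated chains give exactly zero and
the operation is exactly symmetric. Waters, ions and non-A altlocs are
excluded from interface work by default. Footprints collect residues
losing ≥ 1 Å² of SASA or having any heavy-atom contact ≤ 4.0 Å; footprint
sets compare by intersection and Jaccard index. Since the exact radii
behind published buried-area figures are typically unstated, reproduction
comparisons for those carry a ±5% tolerance.

## Superposition

Kabsch via SVD with the determinant correction, proper rotations only: a
structure superposed on its mirror image reports the honest residual
instead of silently reflecting. Atom pairing is by (chain role, residue
number, insertion code, atom name); waters, ions, hydrogens and non-A
altlocs are excluded, and unmatched atoms are dropped. Published r.m.s.d.
values rarely state their exact atom selection, so reproductions carry
±0.1 Å. Per-base rotation between two conformers is the rotation angle
of the optimal proper rotation mapping centred base-ring atoms after a
context superposition (everything except the target residue) has aligned
the frames.

## SPR kinetics

The 1:1 Langmuir model with mass-transport limitation uses the standard
two-compartment quasi-steady-state form

    dR/dt = ka·Cs·(Rmax − R) − kd·R,
    Cs = (kt·C + kd·R) / (kt + ka·(Rmax − R)),

stated explicitly because vendor software does not document its exact
variant; the dissociation phase uses C = 0 and the model reduces to
plain Langmuir as kt → ∞ (the tests check the closed form to < 0.1 RU at
kt = 10¹²). Integration is LSODA with absolute tolerance 10⁻⁶ RU — the
equation is mildly stiff at high ka·Rmax. Protocol defaults mirror a
direct-binding assay: 240 s association, 240 s dissociation, a two-fold
dilution series from 500 nM (14 concentrations plus a blank), and
kt = 1×10⁷ RU M⁻¹s⁻¹ fixed by default (optionally floated). Fitting is
global nonlinear least squares on log₁₀ parameters sharing ka, kd, Rmax
across all curves; non-convergence is flagged on the result, never
raised; Kd is reported as kd/ka exactly. The competitive format
pre-equilibrates the analyte with a solution competitor via the stable
depletion quadratic `A_free = ((A−B−Kd) + √((A−B−Kd)² + 4·Kd·A))/2`
(evaluated in its cancellation-free branch) and reads the signal at the
end of dissociation, normalised to the no-competitor trace. Divalent-ion
conditions are represented purely as multiplicative ka factors
(`scale_ka`), the channel through which such titrations act; no
mechanistic ion-binding model is implied. Experimentally measured
affinities are not computable outputs and serve only as plausible
simulation parameters.

## Synthetic fixtures

The generators build every geometry the analyses consume, with no
downloads. Bases are rigid CCD ideal-coordinate templates; sugars are
rebuilt at a prescribed pseudorotation phase by chaining the
Altona–Sundaralingam torsions (closure is approximate, realised phase
within ~1.5° of the request); exocyclic atoms reuse internal coordinates
measured from the templates; χ is set exactly by construction.

* **Duplexes**: Watson–Crick pairs are assembled by least-squares
  placement of the rigid partner against canonical donor–acceptor
  distance targets (G-C 2.91/2.95/2.86 Å; A-U 2.95/2.82 Å; C1′–C1′
  10.4 Å), then stacked helicoidally at 2.81 Å rise and +32.7°/bp for
  the D build; the L build is the exact mirror, hence left-handed with
  −32.7°/bp. The placement is simplified fibre geometry (zero base-pair
  displacement and inclination), which preserves everything the
  annotations measure — pairing pattern, coplanarity, stacking,
  handedness, puckers, χ — but is not a refined A-RNA model. The default
  sequence alternates G/C on one strand; with mixed purine/pyrimidine
  strands the centroid of a purine following a pyrimidine can jump
  across the helix axis in this simplified geometry, which real
  inclined base pairs avoid.
* **G-tetrad stacks**: one guanosine pose is solved so that its 90°
  copies close the Hoogsteen cycle; the two Hoogsteen contacts share a
  common length floating in [2.6, 3.2] Å (weak preference 2.9 Å) because
  a prescribed channel radius and a fixed hydrogen-bond length cannot
  generally hold simultaneously. With a channel ion the O6 radius is
  chosen so all eight ion–O6 distances equal the request (default
  2.48 Å, realised within ~0.01 Å); the default rise is 2.9 Å so that
  this is geometrically feasible.
* **Ion sites**: regular polyhedra (tetrahedron through tricapped
  trigonal prism, CN 4–9) of water oxygens at seeded Gaussian-jittered
  distances.
* **Sensorgram sets**: simulator output plus seeded additive Gaussian
  noise per time point; drift and bulk refractive-index jumps are not
  modelled (double-referencing removes them in practice).

All fixtures are byte-deterministic given their parameters and seed.
Passing tests on these fixtures demonstrates correctness of the
*algorithms* under ideal and mildly noisy geometry; they do not
demonstrate robustness to crystallographic disorder, missing atoms, or
modelling error in real deposited coordinates, which is why the pipeline
also runs against user-supplied copies of the deposited entries.

## Deposited-structure pipeline

Chains are selected by content (a ≥ 30-nt nucleic chain is an aptamer; a
≥ 40-residue protein chain is a protein), never by hard-coded
identifiers; aptamer–protein complexes are paired by interface contact
counts, and "complex A" is the pairing with the most modelled protein
residues. Descriptor comparisons (buried area 1,791 Å² ± 5%, r.m.s.d.
1.29/0.25/0.43 Å ± 0.1, tetrad/syn/pucker sets, twist 45° ± 10°,
base-30 rotation 65° ± 10°, stem Mg 2.08 Å ± 0.03, four ions per aptamer
chain, channel CN 8) run only when local copies of the deposited entries
are supplied; the package performs no downloads, and descriptor
mismatches never change the process exit status (only hard errors do).

## Problem sizes

The shipped tests and the acceptance script use 8-bp duplexes, 2-tetrad
stacks, 20-atom SASA clusters with a 10⁴-point independent quadrature
oracle, 1,000-ring pucker sweeps, 100 ion-site draws per species, and 20
noisy SPR replicates over 4-concentration series at 2 s sampling — sizes
chosen so the whole suite completes in well under a minute while leaving
every statistical check comfortably powered.

## Known limitations

* Base-pair classification is WC vs non-WC only (no full 12-family
  taxonomy); backbone suite rotamers (α–ζ) are not named.
* The inter-tetrad twist metric assumes approximate 4-fold symmetry when
  folding angular offsets; highly irregular quadruplexes would need a
  per-guanine correspondence instead.
* Ion identity from geometry cannot separate Ca²⁺ from Na⁺; the
  classifier reports this rather than hiding it.
* The SASA canonical frame loses exact rotation invariance for inputs
  with an exactly degenerate inertia tensor (it remains deterministic).
* Crystallographic phasing, refinement, density maps and experimental
  affinity tables are entirely out of scope.
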