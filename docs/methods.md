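# Methods

`crossbeta` quantifies the structural anatomy of amyloid spine segments:
steric-zipper interface metrics (buried surface area, shape
complementarity, hydrogen bonds, atomic solvation energy, zipper class,
dry/wet labeling), β-sheet geometry (planarity, backbone torsions,
registry, strand tilt), and simulated cross-β fiber diffraction with
radial-profile analysis of powder/fiber images.  This note records the
models, conventions, and numerical choices behind each number the package
prints.

## Coordinate models and symmetry

Structures are read from PDB or mmCIF via gemmi; atoms are held in
Cartesian Å, and fractional coordinates appear only at the symmetry
boundary.  Alternate conformers are reduced to the highest-occupancy one
(all metrics are defined on a single model); waters are parsed, flagged,
and excluded from strand grouping and from all area and shape
computations — their presence is what distinguishes a wet interface, but
the printed burial and Sc values describe peptide–peptide contact.
Hydrogens are accepted when present, never required.

`expand_symmetry` tiles the asymmetric unit over every space-group
operator and lattice translation in a requested ± range; each copy carries
its generating (operator, translation) tag and preserves internal
distances to numerical precision.  `build_assembly` groups strand copies
into β-sheets: two strands join the same sheet when their directions are
aligned (|cos| ≥ 0.65) and the median nearest-Cα spacing falls in the
cross-β stacking window (4.0–6.0 Å, centered on the ~4.7–4.8 Å rise).
Strands in a sheet are ordered along the stacking direction, taken as the
leading principal axis of the strand centroids.  The fiber axis of a
crystal model defaults to the shortest cell axis — the ~4.7–4.8 Å axis in
cross-β cells — and is overridable.

## The idealized builders

The synthetic generator is first-class: it provides the study conditions
under which every analyzer is closed against known ground truth.

**Strands.**  Backbones (N, Cα, C, O, and Cβ except glycine) are placed by
natural-extension (NeRF) geometry with standard bond lengths and angles,
reproducing requested (φ, ψ) exactly.  Ideal β torsions default to
(−119°, 113°) for parallel and (−139°, 135°) for antiparallel sheets.  One
internal coordinate is relaxed: the peptide ω is tuned within a few
degrees of planarity (≈ 181.5° antiparallel, ≈ 183.5° parallel) so the
per-residue screw twist is exactly 180°.  This produces the Pauling
two-fold repeat, making the Cα trace of an ideal strand exactly planar —
the same trade between peptide planarity and strand twist seen in real
sheets.  The Cβ is placed with L-chirality (improper N–C–Cα–Cβ = −122.6°);
side chains beyond Cβ are not built.  Where interface metrics need
side-chain bulk, an enlarged Cβ radius (3.5 Å, roughly the
volume-equivalent radius of an average side chain) substitutes for
rotamers; tests that need real side-chain detail require deposited models.

**Sheets.**  Strand *i* is translated i·rise along the stacking axis
(defaults 4.8 Å parallel / 4.7 Å antiparallel); antiparallel sheets flip
alternate strands.  Two orientation conventions are offered, because two
idealizations are genuinely in tension:

* default (pleat in-plane): the Cα zigzag lies in the sheet plane, so a
  flat sheet has exactly zero planarity RMSD — the clean reference for
  curvature measurements;
* `pleat_out_of_plane`: the strand is rotated 90° about its axis so
  carbonyls point along the stacking direction and adjacent strands form
  proper backbone hydrogen-bond ladders (N···O ≈ 2.8 Å).  Antiparallel
  flips are then about the sheet normal so facing carbonyls pair up.

Registry shift is applied as an along-strand stagger such that
same-direction neighbors (adjacent strands for parallel sheets, strands
i and i+2 for antiparallel) are offset by exactly the requested number of
residues; the antiparallel stagger advances in two-strand blocks, which
preserves H-bond alignment in every other strand interface — the
alternating strong/weak ladder characteristic of out-of-register sheets.
The declared fiber axis is the strand-accumulation direction, which for a
staggered sheet leans away from the stacking normal; out-of-register
sheets therefore show a nonzero strand tilt that grows with the shift.
Curvature adds a sinusoidal out-of-plane displacement A·cos(2πt) along the
strand (t ∈ (0,1) at residue midpoints); the cosine phase is orthogonal to
both the constant and linear trends a fitted plane can absorb, so the
planarity RMSD of a densely sampled curved sheet is A/√2 exactly.

**Zippers.**  The eight steric-zipper classes are encoded as three binary
descriptors — strand orientation within sheets (parallel: classes 1–4),
face-to-face vs face-to-back mating, and up-up vs up-down strand sense —
with face-to-face = {1,3,5,7} and up-up = {1,2,5,6}.  The published
schematic the classes come from is not numbered numerically; this table
follows the steric-zipper literature's convention and is the package's
fixed definition.  Sheet B is generated like sheet A, rotated 180° about
the strand axis for face-to-face classes and about the sheet normal for
up-down classes, then translated by the intersheet distance (sheet
normal) and lateral offset (stacking axis; a half-rise offset
interdigitates the Cβ rows).

**Ring images.**  Azimuthally uniform Gaussian rings are drawn at the
pixel radii of requested d-spacings on a flat detector (Cu Kα 1.5418 Å
default); Gaussian noise is the only randomness in the package and is
controlled by an explicit seed.  Rings beyond the λ/2 limit or off the
detector are rejected.

## Sheet geometry metrics

*Planarity* fits one least-squares plane (SVD) through the Cα atoms of all
strands of a sheet and reports the RMS perpendicular distance; the atom
selection is configurable, Cα being the convention.  *Backbone torsions*
follow the IUPAC sign convention, reported in (−180°, 180°] with ties at
±180 reported as +180; terminal residues have undefined φ or ψ.
Ramachandran regions (favored / allowed / outlier) use polygonal
approximations of published general, glycine, and proline contour levels,
bundled as data.  The polygons are coarse but preserve the feature the
analysis turns on: the positive-ψ bridge near (−100°, +110°) is allowed
for glycine and an outlier for every residue type with a Cβ.

*Registry* determines orientation from dot products of consecutive strand
directions, then reports the modal residue-index offset of the nearest Cα
on the closest same-direction strand after projecting out the stacking
direction (the component of the adjacent-strand centroid vector
perpendicular to the strand axis).  Projecting along the exact lattice
repeat would always return zero for a periodic stack, so "directly above"
is deliberately referred to the H-bond stacking direction; this reproduces
the textbook picture in which residue X of strand one sits above residue
X±shift of strand three.  Evidence pairs are listed.  *Strand tilt* is the
angle between the mean strand direction and the plane normal to the
declared fiber axis: zero for in-register sheets, increasing with
registry shift.

## Interface metrics

**SASA** is Shrake–Rupley sampling with a deterministic Fibonacci-lattice
point set (default 960 points/atom, probe 1.4 Å, standard van der Waals
radii bundled as data).  Determinism makes every downstream report
bit-reproducible; doubling the density moves totals by < 0.5%.

**Buried area** is SASA(A) + SASA(B) − SASA(A∪B), restricted to central
strands (edge strands trimmed when a sheet has more than two) and divided
by 2 × (central strands per sheet): a per-strand, per-sheet-side
convention under which an 11-residue strand burying 24 Å²/residue buries
264 Å²/strand.  Sheets are built 2k+1 strands wide (default k = 4) so the
central strands see the repeating fibril environment.  Clashing sheets
(interatomic distance < 1 Å) are rejected.

**Shape complementarity** follows the Lawrence–Colman statistic evaluated
on van der Waals dot surfaces: for a surface point x on A with nearest
point x′ on B's surface, s(x) = −(n̂(x)·n̂(x′))·exp(−w·d²) with w = 0.5 Å⁻²
and a 1.5 Å interface band; Sc is the median of s over the interface
points of both surfaces.  Snugly conforming closed surfaces in exact vdW
contact score above 0.95.  The dot surface is an approximation to the
solvent-excluded surface of the original statistic; on knobby synthetic
interfaces it reads lower than a smooth-surface implementation would, a
known limitation recorded here rather than hidden.

**Hydrogen bonds** default to the heavy-atom criterion (deposited peptide
structures carry no hydrogens): donor N — or hydroxyl O — to acceptor N/O
at ≤ 3.5 Å with every covalent antecedent–donor–acceptor angle ≥ 90°;
bonds are listed once, labeled backbone–backbone or side-chain.  The
cutoffs sit at the center of the conventional 3.2–3.6 Å range and are
configurable.

**Solvation energy** is ΔG = Σ σ(class)·[ASA(reference) − ASA(assembly)]
per central strand, with the five-class atomic solvation parameters
σ = {C +16, N/O −6, O⁻ −24, N⁺ +…−50, S +21} cal·mol⁻¹·Å⁻² (the
Eisenberg–McLachlan set, bundled as data).  The sign convention makes
apolar burial positive (stabilizing).  Two reference states are
supported: each strand in isolation (default; includes the intra-sheet
ladder burial) and each strand within its isolated sheet.  The zipper
panel uses the sheet reference, because only it isolates the solvation
gain stored in the inter-sheet interface — the quantity that separates a
mated zipper from an unmated sheet stack by orders of magnitude.  The
exact protocol behind published per-strand solvation energies for these
structures is uncited, so numerical reproduction of those values is not
claimed; the ordering (zipper ≫ unmated stack) is.

**Dry/wet.**  An interface is called dry when it buries at least
15 Å²/residue — midway between typical zipper burial (~20 Å²/residue and
above) and loose hydrated crystal contacts (~10 Å²/residue).  A pair of
sheets whose burial falls below the threshold is not classified as a
zipper.

**Classification** computes the three class descriptors geometrically:
orientation from the registry report; face identity from the parity of
residues whose Cβ points toward the interface, voted over the even-ranked
strand sub-lattice along the common fiber axis (antiparallel sheets
present alternating faces per sub-lattice, so both sheets must be read on
matching sub-lattices); up/down by comparing strand directions rank-by-
rank along the fiber axis (rank pairing is robust to half-rise lateral
offsets).  Ambiguous descriptors return "none" with logged diagnostics.

## Fiber diffraction

Structure factors are computed by direct summation over the symmetry-
expanded unit cell, F(hkl) = Σ f_j(s)·occ_j·exp(−B_j s²/4)·exp(2πi h·x_j),
with International Tables four-Gaussian X-ray form factors (gemmi's
tables).  X-ray factors are the default because the comparison patterns
for these fibrils are X-ray fiber patterns; a Mott–Bethe electron option
exists.  Atoms with B = 0 receive a configurable default of 15 Å².

A fiber pattern maps each reflection to (R, Z) — the components of the
scattering vector perpendicular and parallel to the fiber axis — and
accumulates Gaussian smearing (σ = 0.005 Å⁻¹ default, representing
orientational disorder; peak centers are verified stable under ±20%
changes).  Patterns are normalized to max 1 and mirror-symmetric in ±Z by
construction.  Builder assemblies are diffracted by wrapping their exact
strand-repeat translation in a padded P1 pseudo-cell (one strand per cell
for parallel, two for antiparallel sheets), which makes the simulated
stack effectively infinite along the fiber axis; an in-register sheet
with rise 4.7 Å then shows meridional orders at 4.70 and 2.35 Å by
lattice geometry.  Profiles are extracted along the meridian (R ≤ band),
equator (|Z| ≤ band), or radially (powder average); peaks are local maxima
above a prominence threshold, reported at full precision and rounded to
0.1 Å only in formatted reports.

Radial profiles of 2D images average pixel intensity in annuli about the
beam center (1-pixel bins, fractional centers rounded half away from
zero) and convert radius to Bragg spacing via
d = λ / (2 sin(½ arctan(r·pixel/distance))).  Zero-pixel bins are flagged
NaN; total intensity is conserved across binning.

No helical (Fourier–Bessel) layer-line formalism is used: the assemblies
here are translational stacks, not helices.

## Pipeline and reproducibility

`analyze_structure` composes reading → symmetry expansion → sheet
grouping → geometry → interface metrics (→ optional diffraction) into one
report row; `survey` maps it over many inputs, isolating per-file
failures, and writes CSV/JSON plus the planarity scatter (id vs RMSD Å)
as CSV and PNG.  All sampling uses deterministic point sets, so reports
are byte-identical across reruns; every row carries a hash of the full
configuration, and changing any cutoff changes the hash.  The CLI
(`crossbeta analyze|survey|build|fiber|profile`) is a thin layer over
these functions with exit codes 0/1/2 for success/input error/computation
error.

## Problem sizes and defaults

Synthetic panels use sheets of 7–9 strands (metrics read from central
strands; convergence in sheet width is part of the test suite), 960-point
SASA sampling, 21-strand stacks for diffraction, and 256-px detector
images.  These sizes are converged for the quantities reported: widening
sheets or densifying sampling moves headline numbers by well under the
tolerances quoted with them.

## What the synthetic data does and does not show

The builders emulate the geometry the analysis assumes — ideal strands,
exact registry, clean class geometry, noiseless coordinates — so passing
closures demonstrate that the analyzers invert the generators and that
the numerical machinery (areas, torsions, structure factors, profiles)
is correct against closed forms and brute-force oracles.  They do not
demonstrate side-chain packing realism: synthetic interfaces carry Cβ-only
bulk, so absolute burial and Sc values on synthetic zippers are not
comparable to values computed on deposited, fully side-chained models.
The printed-value checks against the two deposited hIAPP spine structures
exercise exactly that gap and require the published coordinate files
(placed under `data/deposited/`), which are not distributed with the
package.

## Known limitations

* Sc on dot surfaces reads low on strongly knobby interfaces relative to
  solvent-excluded-surface implementations.
* The out-of-register builder idealizes stagger as rigid translation; real
  out-of-register sheets relax H-bond geometry with strand tilt, which the
  builder represents only through the declared fiber axis.
* Ramachandran polygons are coarse approximations; region labels near
  contour boundaries (±few degrees) should not be over-read.
* The solvation-energy scale depends on the chosen σ set and reference
  state; only orderings, closed-form checks, and sign conventions are
  guaranteed.
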