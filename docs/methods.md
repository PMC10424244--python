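# Methods

## Scope and model

`lnptools` prepares and characterizes model bilayers of DSPC, cholesterol
and an ionizable aminolipid with a titratable amine head.  It covers the
*system construction* problem (replacing phospholipids by the aminolipid in
an existing bilayer) and the *trajectory characterization* problem (density
profiles, orientational order, lateral structure, partitioning,
aggregation).  It does not integrate equations of motion: the molecular
dynamics stages of the original insertion protocol are replaced by a
deterministic steepest-descent relaxer with an explicit contract (cavities
cleared, no steric clashes), which is what the downstream steps actually
require.  Force-field parametrization, electrostatics and thermostats are
out of scope.

## Data model

A `MolecularSystem` holds an atom table (ids, names, elements, residues,
positions in Angstrom), a bond list, a molecule list carrying
species / protonation / leaflet labels, and an orthorhombic box.  PDB is
the reference interchange format (ATOM/HETATM/CONECT/CRYST1, multi-model
files for trajectories), read and written through MDAnalysis; inputs
without CONECT records can carry molecule grouping in a sidecar CSV.
Leaflets are assigned from the head-reference atom of each lipid
(phosphorus for DSPC, hydroxyl oxygen for cholesterol, titratable nitrogen
for the aminolipid) relative to the midplane, the mean z of all DSPC
phosphorus atoms.  Molecules whose head lies within a 5-A band of the
midplane are labeled `core`; the band width is a package convention — the
field has no standard label for midplane-dwelling lipids, but the neutral
aminolipid population needs one.

## Composition planning

Per leaflet of N lipids: `n_chol = round(0.40 N)`, `n_l5 = round(f N)` for
a requested aminolipid fraction f, remainder DSPC.  Protonation labels are
drawn with a round-half-up protonated count (default fraction 0.5,
emulating the near-even charge split of an ionizable lipid near its
apparent pKa) and balanced across leaflets to within one molecule, the
excess going to the upper leaflet.  Selection of replaced lipids is uniform
without replacement per leaflet; every random choice is driven by a
user-supplied seed, and per-stage seeds are derived as
`SHA-256(master ":" stage) mod 2^31` so replicates are independent but
reproducible.

## Grid potentials

Each selected site gets a scalar field on a regular lattice with node
spacing 0.8 A.  The field is a smoothed indicator of the template's
bounding cylinder (radius and length padded by 1 A), axis along the site
lipid's head-to-tail direction with the tail end toward the membrane core:
1 strictly inside, and outside the surface a shifted-truncated Gaussian
`(exp(-d^2/2 sigma^2) - e^-2) / (1 - e^-2)` with `sigma = 3 A` (half the
6-A smoothing length), reaching exactly zero at d = 6 A.  The plain
Gaussian never vanishes, which would violate the requirement that the
field be zero one smoothing length outside the cylinder; the shifted form
keeps the Gaussian scale while making the support compact.  Energy of an
atom is `k * V(x)` with V evaluated by trilinear interpolation; forces use
the analytic gradient of the trilinear form, so the force field is exactly
consistent with the interpolated energy.

## Relaxation

The relaxer minimizes grid energy plus a purely repulsive soft-sphere pair
term `eps (sigma_ij / r)^12`, truncated and shifted at a 9-A cutoff, with
`sigma_ij` the sum of per-element radii (about half the van der Waals
contact distance).  Molecules move as rigid bodies (translation only):
this preserves intramolecular geometry without bonded force terms, and it
means intramolecular pairs can be excluded from the energy.  Descent steps
are capped at 0.3 A of maximum molecular displacement with backtracking
halving, so the total energy is non-increasing at every accepted step.

Inside a cylinder the field is flat and the gradient vanishes; an atom
trapped there feels no grid force.  Such atoms (field >= 0.5 and grid
force below the convergence tolerance) are walked out along the cylinder's
outward radial direction.  Moving within the plateau leaves the energy
unchanged and the walk connects to the smoothed shoulder where ordinary
descent takes over, so monotonicity is preserved.  Lipids selected for
replacement are fully exempt (no forces felt or exerted) before
replacement; after replacement the inserted lipids are exempt only from
the grid term, so they still repel their neighbours during the staged
removal.

Grid removal follows the linear eight-stage schedule with force-constant
multipliers [1, 6/7, 5/7, 4/7, 3/7, 2/7, 1/7, 0] — the first stage at the
original constant, the last with the grids gone — with a short relaxation
per stage.

## Ring-piercing repair

Rings are the 5- and 6-cycles of the bond graph (networkx cycle basis).  A
bond pierces a ring when its minimum-image segment crosses the ring's
best-fit plane (SVD) and the crossing point falls inside the ring polygon
projected onto that plane (shapely).  Repair translates the two bond atoms
along the ring normal, toward the side of the nearer endpoint, in 0.3-A
increments until clear.  Once a chain has picked an exit side of a ring,
its other bonds follow the same side — otherwise clearing one bond can push
its chain neighbour back through the ring and the repair ping-pongs.
Detection re-runs until no violation remains; the workflow then alternates
a clash relaxation with re-detection, because repair can nudge atoms into
contact and relaxation can in principle re-thread a ring.

## Analysis conventions

- All z coordinates are midplane-centered per frame, absorbing drift.
- Density slices are 1.4 A wide with a bin center at z = 0, so
  mirror-symmetric populations produce mirror-symmetric profiles; the
  profile maximum is scaled to one.
- Crossing angles use the signed cosine of the angle between unit tail
  axes (first to last heavy atom of the designated unbranched tail) for
  pairs whose tail midpoints are within 10 A in-plane (minimum image);
  25 bins over [-1, 1], normalized to a probability distribution.
- The lateral RDF uses per-molecule heavy-atom centroids, x-y distances
  only, both leaflets pooled (stacked cross-leaflet molecules therefore
  contribute density near r = 0), normalized by 2 pi r dr rho with the
  bulk density from the instantaneous box area; frames are averaged with
  equal weight, and for identical groups the self-molecule is excluded
  (bulk density (N-1)/A).
- The orientation angle is measured against +z for upper-leaflet and -z
  for lower-leaflet molecules (core molecules against +z), so an upright
  lipid scores ~0 in both leaflets; the order parameter is the
  second-Legendre average `S = <(3 cos^2 theta - 1)/2>`, which reproduces
  the expected range (1 ordered, ~0 disordered, -0.5 in-plane).
- Cholesterol is *surface* when its hydroxyl oxygen is within 10 A in z
  of the bulk-water boundary on its side of the bilayer (the innermost
  water-oxygen z); the partition coefficient is core/surface, the
  direction consistent with a small coefficient when nearly all
  cholesterol sits at the surface.  Fixtures without explicit water can
  supply boundary planes directly.  z-distance (not 3-D distance to the
  nearest water molecule) is used; for a flat solvated bilayer the two
  are nearly identical and the z form is robust to sparse water models.
- DBSCAN runs on a precomputed minimum-image distance matrix
  (scikit-learn backend) with eps 5 A and minimum 50 points, the point
  count including the point itself; inputs default to aminolipid head
  nitrogens but any coordinate set can be clustered.
- The analysis window defaults to the trailing third of the frames,
  mirroring production protocols that analyse the last portion of a run;
  replicate helpers return mean and standard deviation across replicates.

## Synthetic fixtures

The generator emulates the *geometry* of a DSPC/cholesterol/aminolipid
bilayer, not its thermodynamics: coarse placeholder lipids (8-11 atoms)
with correctly named reference atoms on a square lattice (8-A spacing,
roughly the DSPC area per lipid; phosphate planes at +/-20 A; box height
90 A, matching the conventional simulation cell), per-molecule tilt drawn
from a wrapped-normal model (standard deviation `1/sqrt(kappa)` radians;
kappa -> infinity gives exact tilt), optional water slabs or configured
boundary planes, planted Gaussian z-peaks as single-nitrogen markers,
planted isotropic midplane aggregates, and trajectories as independent
Gaussian jitter around the base structure.  Tilted neighbours occasionally
touch; the generator de-clashes with rigid translations, which leave the
planted tilt angles untouched.  Cholesterol placeholders carry a standing
six-membered ring so the ring-piercing machinery is exercised.

What passing tests on these fixtures demonstrates: the estimators recover
known planted structure (peak positions, order, partitioning, aggregates)
and the construction workflow satisfies its structural contracts at scale.
What they do not demonstrate: agreement with all-atom simulation values of
order parameters or partition coefficients, which depend on real lipid
interactions and microsecond sampling the fixtures deliberately do not
model.

## Problem sizes and numerical choices

The acceptance-scale conversion uses a 500-lipid bilayer (250 per leaflet,
60:40 DSPC:cholesterol) across aminolipid fractions 0.10-0.50, three seeds
each; the package's own test problems are chosen so a full run fits
comfortably on a single CPU.  Relaxation defaults: 120 steps for the
cavity stage, 25 per removal stage, force tolerance 0.05, neighbour lists
refreshed every 5 steps with a drift-covering skin.  Clash acceptance is a
1.2-A minimum interatomic distance; fixture generation enforces 1.5 A.
Statistical tests use fixed seeds and tolerance bands of at least four
standard errors of the statistic under test.

## Known limitations

- Translation-only relaxation cannot reorient or deform molecules; badly
  tilted inserts are not annealed, only de-clashed.
- The rigid template seeds every inserted aminolipid with the same
  conformer (up to rotation); conformational diversity must come from
  downstream simulation.
- Ring repair moves the piercing bond's atoms only, which can stretch its
  chain bonds; the subsequent clash relaxation does not restore ideal bond
  lengths.
- The PDB reader follows MDAnalysis conventions (fixed-width columns,
  1-based serials); exotic PDB dialects are not supported, and boxes are
  orthorhombic only.
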