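# Methods

This note documents the models and conventions implemented in
`gpcrprofile`, the parameters that matter, the design choices made where
the design was genuinely open, what the synthetic generators emulate, and
the limitations of both.

## Coordinate model and I/O

Structures are parsed with gemmi (fixed-column PDB and mmCIF) into a flat
residue → heavy-atoms/hydrogens model.  Author residue numbering is kept
verbatim — all residue references in the structural literature (L386,
R199, …) use author numbers, so no renumbering is ever applied.  Alternate
conformations are reduced at read time to a single conformer per atom: the
highest occupancy wins, ties broken by altloc identifier order.  This keeps
every distance metric single-valued and deterministic.  Hydrogens are kept
and flagged when present, but all static-model criteria work heavy-atom
only, because deposited models rarely include them.

Trajectories are multi-model PDB files over a fixed topology; each MODEL
is one frame and a frame with a deviating atom count is an error naming the
frame.  Binary trajectory formats are deliberately not parsed here — the
adapter entry point `trajectory_from_arrays` accepts per-frame coordinate
arrays from any reader (MDAnalysis, mdtraj), keeping the core free of heavy
optional dependencies.  Trajectories are assumed pre-imaged (molecules
whole, no periodic wrapping); the analysis applies no periodic imaging.

Waters are residues named HOH/WAT/TIP3/SOL; the position of a water is its
oxygen atom.  Scalar fields are written as OpenDX grids (z fastest-varying)
and round-trip through an independent parser to 1e-6.

## Generic numbering

Ballesteros–Weinstein maps are anchor-driven: each TM segment gets one
anchor (`t.50` at the segment's most conserved position) and every other
residue in the segment range is labelled by plain sequence offset.  Bulges
and deletions (x.451-style insertion labels) are not handled; that is a
documented limitation, acceptable because offset labels are exact on the
receptors this package targets.  Intracellular-loop residues carry
free-text tags in the same map.  Because the map is strictly bijective
(needed so label→residue→label is the identity), loop tags embed the
sequence number (`ICL2.208`) instead of sharing one `ICL2` tag among
several residues.

CGN labels for Gα are never computed — the numbering is not
offset-derivable — and always come from an explicit table.  The packaged
Gα_i1 table covers the α5 helix and wavy hook (340–354).  Published work is
inconsistent about whether H5.24 is G352 or G353; the canonical common-Gα
assignment (C351 = H5.23, G352 = H5.24, L353 = H5.25, F354 = H5.26) is used
throughout and the table file carries a comment flagging the discrepancy.

## Geometry

Rigid superposition is the Kabsch SVD fit restricted to proper rotations
(the smallest singular direction is flipped when the optimal orthogonal
matrix has determinant −1), minimising RMSD over rotations + translations.
It is cross-checked in the tests against an independent quaternion
(Horn-method) oracle to 1e-9.  Atom pairing for two-structure RMSD is by
(chain, residue number, atom name) intersection; fewer than 3 surviving
pairs is an error.

Helix axes are estimated from the Cα trace via second differences: for an
ideal helix the second difference of consecutive Cα positions is purely
radial (the axial rise cancels), so the axis is the normal of the plane
spanned by those vectors (smallest principal component of the
second-difference cloud, lags 1–6 pooled).  This is exact for an ideal
helix of any length; a plain PCA of the Cα points is biased by several
degrees for short helices because the spiral is anisotropic.  Near-straight
traces fall back to point-cloud PCA.  Under 0.2 Å coordinate noise the
axis is typically recovered within ~2°.

The receptor bundle axis is the leading principal component of all TM Cα
positions, oriented extracellular → intracellular by an explicit reference
point.  This fitted axis is approximate (helices differ in length, so the
cloud is not symmetric); every displacement metric therefore accepts an
explicit `axis` argument for use when the membrane normal is known — the
synthetic ledger supplies it, and on real structures the membrane normal
from OPM-style annotations can be passed the same way.  "Downward"
displacements (toward the cytoplasm) are positive by this convention, and
the convention is stated in every report.

## Activation hallmarks

All inter-residue distances are minimum heavy-atom distances.  Cutoffs,
each configurable:

| quantity | default | rationale |
|---|---|---|
| direct-contact rule (3.46–7.53 and vdW contacts) | ≤ 4.5 Å | standard heavy-atom contact distance for hydrophobic/vdW interactions |
| hydrogen bond (static, no hydrogens) | ≤ 3.5 Å donor/acceptor | standard heavy-atom D–A criterion |
| salt bridge | ≤ 4.0 Å charged-group N/O | standard literature value |

TM6 outward movement: after superposing the active structure on the
inactive one over a core Cα set (default: all shared TM1–TM4 positions),
the probe Cα (default 6.30, the intracellular end of TM6) displacement is
projected into the plane orthogonal to the bundle axis.  TM7 downward
displacement: mean signed displacement of the 7.49–7.53 Cα along the axis,
intracellular-positive.  Which atoms published structure papers used for
their quoted TM6/TM7 numbers is generally unstated, so these definitions
are decisions; they recover purely translational plants exactly and should
be compared tolerantly against literature values.

The hallmark report also lists the residues lining the 3.46–7.53 gap
(heavy atoms within 6 Å of the midpoint of the closest 3.46/7.53 atom
pair) — the cavity that is hydrated in NPxxL receptors.

## Interface contacts

Contacts are tabulated at residue-pair granularity across the
receptor/Gα chain pair: a pair is a hydrogen bond if any donor/acceptor
heavy-atom pair (template table: backbone N donor except proline, backbone
O and C-terminal OXT acceptors, standard side-chain N/O/S roles, His and
Ser/Thr/Tyr in both roles) is within 3.5 Å; otherwise it is a vdW contact
if any heavy-atom pair is within 4.5 Å.  No pair is double-counted.  Each
record keeps the minimal distance and its atom pair as evidence, plus a
salt-bridge note for ionic pairs within 4.0 Å.  Without hydrogens there is
no angle term; this is a documented divergence from the trajectory
criterion below and errs on the permissive side.

The α5 insertion angle is the angle between the α5 helix axis and the
receptor bundle axis, folded into [0°, 90°]; smaller values mean a more
vertical (deeper, narrower) insertion.  Pocket composition lists the
receptor residues (as BW labels) within the contact cutoff of named Gα
positions (default H5.20/H5.25, the conserved leucines that anchor the α5
tip in the receptor's hydrophobic pocket).

## Trajectory statistics

Hydrogen-bond occupancy uses the classic geometric criterion pinned to the
defaults of the widely used MD tooling: donor–acceptor distance ≤ 0.35 nm
AND hydrogen–donor–acceptor angle ≤ 30°.  When the topology has no
hydrogens the distance term alone applies (flagged by the criterion
object).  A residue pair is bonded in a frame if *any* qualifying
donor(-H)/acceptor combination passes; occupancy is the bonded-frame
fraction.  Whether published per-pair probabilities mean "any atom
combination" or one named pair is usually unstated; any-combination is the
default here.

The water-density estimator evaluates the Heaviside double sum exactly (no
binning approximation): each frame is first superposed on frame 0 over the
fit selection (by default all receptor Cα), then every water oxygen within
r = 1 Å of a grid point increments that point.  Division by T·V_r gives a
local number density in waters/Å³.  Two properties worth stating plainly:
one water contributes to every grid point within r (overlapping spheres) —
the field is a local density, not a partition, and does not sum to the
water count; and grid points within r of the box boundary undercount, so
evaluation regions should be inset by r.  The default grid spacing is
0.4 Å.  Bulk density defaults to the literature value 0.0334 waters/Å³ and
can be overridden or estimated from a user-chosen bulk shell; high-density
regions are 26-connected components of points with ρ ≥ k·bulk (default
k = 2), sorted by peak ratio.

## Assay models

Luminescence counts are normalised per well to the pre-stimulus baseline,
then divided by the mean vehicle ratio, so vehicle-treated wells read 1.0.
The concentration–response model is the 3-parameter logistic with Hill
slope fixed at 1 (fixing the slope is what makes the fit 3-parametric);
the span top − bottom is reported as Emax and −log10 EC50 as pEC50.
Zero-concentration (vehicle) points cannot enter a log-concentration model,
so they are included at a pseudo-concentration 3 log units below the lowest
nonzero dose, anchoring the fitted bottom at the vehicle response.  Fits
use bounded least squares with a deterministic 5-point multi-start; EC50
estimates outside the sampled concentration span are flagged extrapolated,
and flat data are flagged degenerate rather than raising.  Weighting is
uniform; the exact zero-dose handling and weighting of commercial fitting
software are not public, so these are documented decisions.

Saturation binding fits `total = Bmax·L/(Kd+L) + ns·L` jointly (total and
nonspecific in one model, Kd parametrised on a log scale).  A measured
nonspecific column can instead be subtracted pointwise before a
2-parameter specific fit, but the joint fit is the default.

## Synthetic data: what it emulates, and what it does not

The generators produce, deterministically per seed:

* **Helix bundles** — seven ideal vertical helices (rise 1.5 Å/residue,
  Cα radius 2.3 Å, 96°/residue so 15 residues make exactly 4 turns and
  helix-axis estimates are exact) on a 10 Å ring, author-numbered like an
  endothelin-type receptor (R199 = 3.50, L386 = 7.53, …), with real
  amino-acid atom templates at the probed positions so donor/acceptor
  tables apply.  Side chains point radially outward, and planted pair
  distances are realised in free space below the intracellular mouth with
  companion atoms parked on perpendicular rakes, so each planted value is
  the *strict* minimum over the relevant atom sets.  Active/inactive pairs
  plant TM6 lateral and TM7 axial displacements as rigid sub-helix
  translations, which core superposition recovers exactly.
* **Complexes** — a bundle plus a Gα_i1 α5 helix (real 340–354 sequence,
  C-terminus-first insertion, side chains truncated to Cβ except at
  planted residues) with 4 planted hydrogen bonds and 6 planted vdW
  contacts mirroring a receptor–G_i interface: Gα D341/N347/D350 to
  receptor R6.30/ICL2/ICL1, the C-terminal carboxylate to S8.47, and the
  H5.20/H5.25 leucines in the V3.54/M5.61/M5.65/V6.33/V6.37/V7.56 pocket.
* **Hydration trajectories** — waters i.i.d. uniform per frame at a stated
  number density (default 0.0334 waters/Å³, ambient liquid water), with an
  optional spherical hotspot at a multiplied density and a static 3-atom
  anchor chain for superposition selections.  Defaults: 12 Å box, T = 50
  frames for the unbiasedness check (sampling error well under the 5%
  band); hotspot detection uses T = 200 so that 2×-bulk threshold
  crossings from shot noise (per-point expected count ≈ 28) are negligible.
* **Hydrogen-bond trajectories** — an Arg/Asp pair placed within criterion
  in exactly round(p·T) frames (seeded permutation), so occupancy is exact
  by construction.
* **Assay tables** — concentration–response data on a 0 / 6×10⁻⁶ M
  ten-point half-log-style design with pEC50 = 8.0, bottom 1.0, top 3.0
  (fold-change units) and Gaussian noise σ = 0.05, 3 replicates;
  saturation binding on the eight-point 2–200 pM design with Kd = 60 pM,
  Bmax = 1000 counts, ns·200 pM = 10% of Bmax, noise 2% of Bmax (the
  Poisson level for a few thousand γ-counts) and 6 replicates (duplicate
  wells in three experiments).

Construction is verified: after planting, every planted quantity is
recomputed with plain numpy and generation fails loudly if plants
interfere or are infeasible.  Every generator emits a ground-truth ledger;
tests consume the ledger, never eyeballed values.

What the synthetic data does *not* emulate: real backbone geometry
(φ/ψ-correct backbones, rotamers), bulges and non-ideal helices, water
structure (hydrogen-bond networks, excluded volume — waters here are an
ideal gas), correlated MD dynamics, and heteroscedastic assay noise.
Passing tests therefore demonstrate that the *estimators and metrics* are
implemented correctly (exact oracles, exact planted recovery, unbiasedness
under the stated sampling), not that any biological conclusion about a real
receptor follows; on real data the conventions documented above (axis
choice, cutoffs, heavy-atom-only hydrogen bonds) dominate the error budget.

## Numerical choices and degenerate inputs

Superposition requires ≥ 3 non-collinear points; degenerate point sets
raise.  Altloc ties, contact-record ordering and cluster ordering are all
deterministic.  The dose–response optimiser's multi-start is seeded and
bounded; parameter bounds stay open for flat data so degeneracy is flagged,
not raised.  Grid dimensions round with a 1e-9 epsilon so exact multiples
of the spacing are kept.  Reports contain no timestamps; re-running any
stage with identical inputs and seeds is byte-identical.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
desk scale: bundles of ~900 atoms, complexes of ~180 residues, hydration
boxes of ~60 waters × 50–200 frames, and 100-simulation batches for the
assay recovery statistics.  These sizes make every oracle comparison exact
or tightly bounded while keeping the whole suite in the tens of seconds.

## Known limitations

* BW bulge/deletion labels are unsupported (plain offsets only).
* Static-model hydrogen bonds have no angle term; expect some
  over-counting relative to hydrogen-aware criteria.
* The fitted bundle axis is biased for bundles with unequal helix lengths;
  pass an explicit axis when the membrane normal is known.
* The density estimator applies no periodic imaging and undercounts within
  r of the evaluation-region boundary.
* Assay fits assume homoscedastic Gaussian noise and a Hill slope of 1
  unless configured otherwise.
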