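# Methods

## Scope and philosophy

The package reimplements an analysis pipeline for facet-exposed
cellulose II nanocrystals as a desk-scale artifact: geometry and
statistics are computed exactly; the physics engines (force-field MD,
DFT, wavefunction topology) are out of scope and enter only through
tabulated inputs.  All randomized components run from a single integer
seed and are bit-reproducible.

## Nanocrystal construction

**Unit cell.**  The embedded cell is the conventional monoclinic
cellulose II cell: a = 8.10 A, b = 9.03 A, c = 10.31 A (fiber axis),
gamma = 117.1 deg, two anhydroglucose residues per c repeat.  It is
overridable via `UnitCell`.

**Residue template.**  An idealized 4C1 beta-D-glucopyranose is generated
programmatically (ideal chair ring, C-C 1.52 A, puckering +-0.25 A;
equatorial hydroxyls, axial ring hydrogens; hydroxymethyl arm placed by
torsion construction at omega = +60 deg).  It is *synthetic*: no
experimental coordinates are reproduced, and geometric invariants — not
coordinate identity — are the test surface.

**Chain assembly.**  Residues are stacked by the crystallographic 2-fold
screw along c (rotate 180 deg about the chain axis, translate c/2).  The
template is rigidly placed so that the screw closes the glycosidic
C1->O4' link at exactly 1.43 A; consequently every consecutive link
distance is identical and inside the 1.38-1.48 A window.  The free
in-plane ring orientation is fixed at +5 deg from the a axis — a packing
convention chosen once so that neighbouring chains' hydroxyl arms stay at
or beyond bonded O-H distance (0.96 A) at the half-cell chain spacing;
no non-bonded contact in any supported build falls below it.

**Antiparallel packing.**  Chains tile the a-b plane along the (1 -1 0)
and (1 1 0) half-cell diagonals: origin chains at integer (u, v), center
chains at half-integer (u, v), in a checkerboard.  A center chain is an
origin-built chain rotated 180 deg about a transverse axis *placed at the
anchor (C1) height*, then shifted by the intrinsic axial offset 0.216 c.
The flip-plane choice is the package's own convention: it makes
facet-anchor heights polarity-invariant, so a zero-offset flat facet is
exactly planar and the only residual anchor split at the default offset
is the 0.216 c itself (~2.23 A, shared between the two chain families by
the least-squares plane fit, worst-case deviation ~1.3-1.5 A).  A
perfectly level C1 plane on the flat facet is geometrically impossible
while the intrinsic center offset is nonzero; the coplanarity check
reports the honest value.

**Facet stagger.**  Chain ends reach the Miller plane
h x + k y + l z = m (fractional coordinates) by whole-residue staggers
n = round(2 (m - h u - k v) / l); fractional residues are unphysical, so
inclined facets are stepped at the c/2 residue rise.  m defaults to the
integer minimizing total |n| (model centered).  For the supported facets
the stagger is exact (no rounding): constant for (0 0 1), gradient 1
residue per a-step for (-1 1 2) and 4 per a-step for (-2 2 1).  Facets
with l = 0 (parallel to the chain axis) are rejected.

**Residue numbering.**  res_id 1 is the residue at the exposed-facet
(top) end of every chain, so the terminal / proximal / distal position
labels (first / second / remaining residues from the facet end) coincide
with res_id 1 / 2 / 3+.  Chain ids are lexicographic in (u, v); PDB
output cycles a 62-symbol chain-id alphabet and the reader re-partitions
chains wherever residue numbering restarts, so >62-chain models
round-trip.

## Hydroxymethyl conformers

omega is the signed O5-C5-C6-O6 dihedral in (-180, 180], standard
right-hand (IUPAC/MD) convention, cross-checked against an independent
library implementation.  Rotamer windows are fixed 120-degree bins
centered on the staggered states: gt = [0, 120), gg = [-120, 0),
tg = rest; chain-end populations that drift to ~20 deg therefore count
as gt.  Chain-end residues are classed omega1 (outward) or omega2
(inward) by the sign of the projection of C5->O5 onto the radial
direction from the bundle's cross-section centroid to C5 in the a-b
plane — a coordinate-only operationalization of "facing out of the
chain"; both chain ends are classified and flagged by end.  Internal
residues are omega3.  Profiles are computed over the equilibrated tail
(default: last 50 % of frames) and reported per (class, rotamer) stratum
together with a 1-degree histogram; empty strata are absent, not zero.

## Hydrogen bonds

Donors are the hydroxyl oxygens O2, O3, O6 (hydrogen located by canonical
name in the same residue); the ring O5 and glycosidic O4 accept only.
Detection requires O...O <= 3.5 A *and* D-H...A >= 140 deg — the
reference tables report only outcome geometries (~2.70-2.80 A,
~158-165 deg), so the cutoffs are standard MD practice and
configurable; a distance-only
fallback supports hydrogen-free inputs.  Same-oxygen pairs are never
counted; intra-residue pairs are excluded by default (configurable).
Types are directed (O2H..O6 and O6H..O2 are distinct).  The production
search is kd-tree accelerated and is tested for exact agreement with an
all-pairs reference.

One sample = one frame (configurable stride).  Per sample,
F_j^i = x_j^i / N_i; F_max(j) is the maximum over samples with ties
broken toward the smallest sample index; the mean fraction is the
N_i-weighted mean, which reduces exactly to the plain mean under equal
N_i (the weighted form equals total-count(j) / total-count, which is how
it is computed).  Samples with zero bonds are excluded from averages.
The persistence filter keeps types with mean fraction strictly > 0.60 by
default ("larger than 60 %" read literally).  Statistics default to the
terminal+proximal residue scope, with `scope="all"` for the whole
crystal.

## Energetics

E_HB = -223.08 rho + 0.7423 (kcal/mol; rho in a.u. at the O-H...O bond
critical point).  Against the 32 published (rho, E_HB) pairs the residual
is bounded by |slope| x half-ulp of the 3-decimal rho (223.08 x 0.0005
~ 0.112 kcal/mol); the package computes, it does not transcribe.
Strength bands default to weak >= -7.0 > medium >= -15.0 > strong, which
keeps every published bond in weak-to-medium.

dE_bind = E_total - E_i (same-medium enforcement; optional counterpoise
BSSE addition).  dE_sheet = E_i + dE_bind, re-referenced so a designated
reference family is zero; adding a constant to all input energies leaves
re-referenced values unchanged.  The published ledger table prints only
dE_sheet / dE_bind / BSSE (never E_i), so the bundled reference CSV
carries the Delta columns; the 0.000 row — the flat-facet model's
(110)+(220) family — is taken as the operative reference (its footnote
nominally names a different model; the body's zero row wins).  Family
sums are computed signed: the flat-facet model sums to -9.647 kcal/mol
per residue, the other models to -7.660 and -6.330 (two published sums
drop the minus sign; the computed signed values are reported).

**Solvent shifts** are reported as -|vacuum - water| per matched row:
both quantities move toward stability on solvation and the published
presentation reports all gaps as negative decreases while mixing operand
order; this convention reproduces all four headline extrema (-0.4 / -1.3
for dE_sheet excluding the reference row, -0.9 / -2.3 for dE_bind) at
1-decimal rounding.  Note the minimum-magnitude dE_bind gap arises from
the flat-facet model's (010)+(020) row (0.885 -> 0.9), not from the row
the published text cites (0.969, which would round to 1.0).

## Synthetic data

The generator's stated world: 500 frames by default; isotropic Gaussian
coordinate jitter sigma = 0.05 A (small thermal-like noise — the tests
target detectors and statistics, not physics); rotamer mixture
gt/gg/tg = 0.6/0.3/0.1 per class unless overridden, realized by rigidly
rotating the O6/H61/H62/HO6 arm about C5-C6 to a Gaussian draw around
+60/-60/180 deg with sigma_omega = 15 deg (4 sigma from every bin edge,
so bin leakage is negligible); planted contacts realized at the requested
O...O distance and D-H...A angle (defaults 2.75 A / 161 deg, the middle
of the published geometry range) with small geometry noise (0.03 A /
2 deg) and per-frame Bernoulli occupancy, the acceptor parked at 4.5 A
when absent.  One integer seed fans out to per-frame substreams
(SeedSequence([seed, frame])), so frame order is parallel-safe and output
is platform-independent.

Known limitations: planting a contact moves the acceptor oxygen without
its residue, so chemical geometry around the acceptor is sacrificed for
exact contact geometry — and planting onto an acceptor O5 or O6
overrides that residue's omega.  No water, no periodic box, no
thermodynamic meaning: a green recovery test establishes unbiased
measurement of planted parameters, nothing about force fields.

## Numerical choices

Angles in degrees, signed, wrapped to (-180, 180] with -180 mapped to
+180; lengths in A; energies in kcal/mol.  Torsions and HB geometry in
float64; trajectory frames stored float32 (PDB precision is 3 decimals
anyway).  Steric acceptance: no two atoms closer than 0.8 A at build
time.  Coplanarity uses an SVD plane fit through one C1 anchor per chain
at the facet end.  CSV output uses a fixed %.6g float format so
identical runs are hash-identical; NaN anywhere in a report table aborts
the stage.
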