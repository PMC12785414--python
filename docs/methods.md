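# Methods

## Scope and units

The package post-processes frame series of β-barrel fluorescent proteins and
fits pH titrations of their absorbance spectra.  All internal coordinates
are nm and all times ns; ångströms appear only at the PDB boundary
(multi-model PDB is the portable trajectory dialect, fixed columns, 0.001 Å
precision) and in crystal-comparison RMSD reporting.  Residue numbers follow
the author (mCherry-family) convention without renumbering: the chromophore
tripeptide is 66–68, the acylimine carbonyl belongs to residue 65, and the
marker residues used throughout are Q42, T43, A145, K198 and Y214.

## Superposition and fluctuation statistics

Rigid superposition is the closed-form least-squares (Kabsch) solution with
a proper rotation guaranteed; degenerate (collinear or coincident) point
sets are rejected rather than silently resolved.  RMSD series fit each
frame on a selection (canonically protein Cα) and measure over another
(canonically the chromophore heavy atoms including the acylimine carbonyl,
since the matured chromophore incorporates the residue-65 backbone).  RMSF
uses a two-pass reference: frames are aligned to frame 0, averaged, and
re-aligned to that average before fluctuations are taken — a standard,
stable and reproducible choice.  No mass weighting is applied anywhere: the
analyses are geometric, over Cα or heavy-atom selections, and masses would
add a parameter the data does not constrain.

Distance histograms use left-closed, right-open bins anchored at zero
(default width 0.1 nm); the mode is the center of the most populated bin
with ties broken toward the lower bin for determinism.

## Hydrogen bonds

A bond event is a (donor, hydrogen, acceptor) triple with donor–acceptor
distance ≤ 0.35 nm and hydrogen–donor–acceptor angle ≤ 30° — the documented
defaults of the widely used MD H-bond tools.  Donors and acceptors are
typed by a small element rule (N and O accept; N and O donate when carrying
a covalent hydrogen), overridable per call.  Hydrogens must be declared in
the topology (assigned to their heavy atom by proximity in frame 0);
heavy-atom-only input raises an explicit unsupported error instead of
inferring protons.  Partitioned counting is direction-agnostic — an event
counts toward a partner class when either end lies in the group and the
other in that class — and partner classes must be disjoint.

## Water residency and exit gates

The residency statistic is the earliest time t\* from which the distance
between a water's oxygen and the chromophore methylene-bridge carbon
(standard component atom name CB2, configurable) exceeds 2 nm at **every**
sampled frame of the window [t\*, t\* + 0.1 ns], inclusive of the start
frame — a literal reading of "consistently above".  The window must be
fully sampled, so an excursion beginning closer than the persistence time
to the end of the trajectory does not qualify; waters that never qualify
are censored at the trajectory duration and rendered as "> duration" in
text output.  Residency is monotone non-decreasing in both the cutoff and
the persistence.

Exits are classified at the first frame of the persistent excursion: each
named interstrand gate (Reg 1: bulge half-strand 139–145 × strand 10;
Reg 2: 146–153 × strand 10; Reg 3: 139–145 × strand 8; Reg 4: strand 3 ×
strand 11) is reduced to the centroid of its two segments' Cα atoms at that
frame, and the nearest centroid wins; ties break toward the earlier label
and the runner-up margin is logged for audit.  This geometric rule is the
package's operational definition of an exit point — simple, deterministic
and testable — standing in for tunnel-following methods.  The strand
residue ranges for S3/S8/S10/S11 are editable defaults in the region
config, since only the split strand-7 ranges are fixed by the numbering
convention.

Aggregation reports the per-water arithmetic mean and sample (n−1) sd over
non-censored records, with censored records counted separately; a water
with only censored records is flagged unavailable rather than given a
value.

## Chromophore states and the carbonyl flip

Conformer states are defined operationally by deterministic two-means
clustering of the chromophore RMSD series (centers initialised at the
series extremes, Lloyd iteration, labels by level).  This is this package's
operationalization of "two distinct conformations" — visual identification
from RMSD plots is not reproducible — and only two states are supported.
A constant series collapses to one occupied state with zero switches.

The flip observable is the signed N–CA–C–O dihedral of residue 65, in
(−180°, 180°].  A flip event starts where the angle departs from the
frame-0 reference by at least 120° (the ~180° flip with margin for the
intermediate in-plane rotations of up to ~50° seen in stable variants) and
persists for at least 0.05 ns — below the residency persistence scale,
above the frame interval, suppressing single-frame noise.  Note the
detector reports *departed episodes*: a toggle away and back contributes
one event.

## Titration model and ratiometric fitting

Deprotonation is strictly sequential — phenol first, thiol second — so the
mixed S⁻/OH species is excluded from the model; the neutral-pH form is the
thiol–phenolate.  Species populations follow the two-site scheme given in
the README; the parent protein uses the one-site analogue.

pKa estimation fits the Henderson–Hasselbalch sigmoid (Hill coefficient
fixed at 1; a free-Hill variant is available) to a two-wavelength
absorbance ratio.  For idealized mixture spectra the ratio is an exact
Möbius function of 10^pH, and its fitted midpoint equals
pKa − log₁₀(A_H(λ_den)/A_L(λ_den)): the fit reports the thermodynamic
constant exactly when the *denominator* wavelength is an isosbestic point
of the transition, and an apparent (shifted) value otherwise.  The package
therefore adopts the ratiometric convention of reading the numerator at the
neutral-pH main peak (566 nm; 587 nm for the parent) against isosbestic
reference wavelengths: 425 nm for the phenol (low-range) transition and
544 nm for the thiol (high-range) transition, with fitting windows
pH 4.5–8 and 6–11.  The choice of 425/544 rather than the 420/543 band
maxima matches how such ratio plots are measured.  Points whose denominator
falls below a floor are dropped with a warning rather than producing
unstable ratios.

## The synthetic generators

The trajectory generator emulates the *output cadence* of microsecond
explicit-solvent MD — 1000 ns sampled every 0.01 ns, 100,001 frames
inclusive of both endpoints — over a stylized, labelled geometry, not a
physical model.  The barrel is an 11-strand Cα cylinder (radius 1.5 nm,
height ~3 nm) with strand 7 split into lower/upper bulge halves sharing one
angular slot, giving four well-separated gate centroids (pairwise > 0.5 nm).
The chromophore is a minimal heavy-atom set around the bridge carbon at the
barrel centre, with the residue-65 carbonyl oxygen tilted out of the
conjugated plane so that its 180° flip about the CA–C axis (a Rodrigues
rotation, toggling at each planted flip time) lands in clear space.

Planted waters dwell 0.75–1.0 nm from the bridge atom on a smooth seeded
wander (biased away from the chromophore's polar atoms), then travel along
a short piecewise-linear path into the planted gate and cross the 2 nm
cutoff exactly at the grid-snapped planted time, receding to a 3.5 nm park
radius; optional sub-persistence "blips" above the cutoff exercise the
detector's edge cases, and censored waters simply never leave.  Because the
dwell stays ≤ 1.0 nm and the first outside frame is at 2.08 nm, the default
0.01 nm thermal jitter (applied to every non-scripted atom; scripted atoms
follow their plants exactly) leaves ≥ 5 sd of margin on both sides of the
cutoff, which is why recovery of planted (residency, gate) pairs is exact
at default noise.

Scripted hydrogen-bond counts are realized geometrically so the detector —
not a shortcut — is exercised: a pool of donor waters docks at 0.28 nm
with the hydrogen aimed at the acceptor (or parks at 0.6 nm), one water per
dock site.  Sites are distributed over distinct chromophore acceptors (the
acylimine carbonyl, two sites on the phenol hydroxyl, the imidazolinone
nitrogen), as in a real solvation shell, because a single acceptor cannot
host four waters without either mutual clashes or spurious contacts with
neighbouring polar atoms.  The carbonyl-oxygen site direction is selected
deterministically from a Fibonacci sphere to maximize clearance from every
competing polar atom, all placements are re-validated numerically at
template build (≥ 0.37 nm from everything but their own acceptor, in both
flip states), and a protein-partner bond is scripted through the Q42
carboxamide nitrogen.  Gap breathing translates strand S10 along the
A145–K198 axis so that the Cα distance follows a piecewise-linear schedule.

The titration generator evaluates the mixture spectrum on a 350–650 nm grid
at the experimental buffer pH points (4.5, 5.0, 5.5, 6.0, 7.0, 8.0, 9.0,
10.0, 11.0) and adds seeded Gaussian noise (clipped at zero).  The default
basis uses Gaussian bands of width 30 nm; the neutral species' amplitude
(0.45, and 0.35 for the parent) is well below the anionic main band, as for
neutral chromophore states generally, and the two isosbestic conditions
above fix the remaining amplitudes at run time (they are computed from the
constraint, not stored constants).  Same seed ⇒ byte-identical output;
different seeds change jitter and dwell wander but never the plants.

### What the generator does and does not emulate

It reproduces the *observables' structure*: frame cadence, planted event
times on the sampling grid, gate geometry, bond-count schedules, band
positions and ionization behaviour.  It does not attempt force-field
realism — no excluded volume, no solvent, water paths are scripted rather
than diffusive, and spectra are idealized Gaussians.  Passing recovery
tests therefore demonstrates the correctness of the analysis pipeline
(detectors, classifiers, estimators) under controlled conditions, not the
physical accuracy of any MD engine; quantities that depend on unpublished
real trajectories (absolute H-bond means, RMSF magnitudes,
distance-distribution modes) are treated as qualitative context, not
recovery targets.

## Numerical choices and degenerate inputs

- Superposition requires ≥ 3 non-collinear points per selection; selection
  resolution is deterministic and order-preserving, and empty selections
  are errors at use sites.
- Frame times must be strictly increasing and uniformly spaced within
  tolerance; the persistence window must span at least one frame interval.
- Two-means segmentation needs ≥ 10 frames; a constant series (peak-to-peak
  below 1e−12) short-circuits to a single state.
- The pKa fit needs ≥ 4 points and a non-flat curve; initialisation takes
  the asymptotes from the window ends and the midpoint from the first
  crossing of their mean, with pKa bounded to [0, 14].
- Ratio-fit self-consistency on exact sigmoids recovers pKa to < 0.01; the
  three-state low-range fit carries a small (< 0.1) structural offset from
  the thiolate tail inside the pH ≤ 8 window, which is inherent to the
  single-transition fit of a three-species system and is documented rather
  than corrected.
- Ties everywhere (histogram mode, gate assignment) break toward the lower
  bin / earlier label for determinism.

## Problem sizes

The test suite and the acceptance script run the full 100,001-frame cadence
where the claim depends on it (frame count; the residency detector on a
full-resolution trace) and smaller planted trajectories (1–20 ns, the same
0.01 ns interval) elsewhere, which the generator's exactness guarantees are
representative.  The demonstration drivers under `analysis/` use a 0.1 ns
cadence for the six 1000 ns residency runs and 0.02 ns for the shorter
dynamics runs; these are the package's chosen demonstration sizes, and all
detector guarantees (grid-snapped plants, ≥ 5 sd margins) hold identically
at any cadence.

## Known limitations

- The gate classifier assumes exits become geometrically committed at the
  first persistent frame; real escape paths can wrap around the barrel
  surface after leaving, which only a tunnel-following method would track.
- The two-means state definition cannot separate more than two conformers
  and will split pure noise into two near-degenerate levels; the level
  separation, not the existence of two labels, carries the signal.
- Ratiometric pKa values are apparent values whenever the reference
  wavelength is off-isosbestic; the package makes the isosbestic choice
  explicit rather than estimating crosstalk from data.
- Heavy-atom-only structures cannot be used for H-bond analysis by design.
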