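# Methods

This note documents the models, conventions, parameters and design choices
behind `ldbind`, and what the synthetic-data tests do and do not demonstrate
about real simulation data.

## Conventions

Coordinates in Å, times in ns. The membrane normal is z; generated patches
are centred at z = 0. "Heavy atom" means any non-hydrogen atom. Periodicity
is applied with the minimum-image convention in x and y only — the membrane
normal is treated as non-periodic in every analysis. The membrane centre is
the mean z of all lipid heavy atoms of the patch, with core neutral lipids
included for filled-monolayer systems and solvent excluded; for a symmetric
patch this coincides with the midplane.

## Contact analysis

The contact number of residue *i* at frame *t* sums the sigmoid kernel
`1 / (1 + e^{5(d − 4)})` over protein-heavy/membrane-heavy atom pairs within
5 Å. The kernel's midpoint is 0.5 at 4 Å and it falls below 0.007 at the
5 Å prefilter, so hard-zeroing pairs beyond the cutoff truncates each pair's
contribution by under 0.7 %; the prefiltered sum is verified against a
brute-force all-pairs oracle to 1e-12 on small systems. An exact z-interval
screen (z is non-periodic) skips frames where the protein cannot be within
the cutoff of any membrane atom.

A residue is in a *bound conformation* when C_i(t) exceeds 25, strictly.
Per-residue averages are taken **only over frames individually exceeding the
threshold** — not over all frames after first binding — so `avg_bound` is
either 0 (never bound) or > 25 by construction; the cumulative profile is
the running sum of `avg_bound` over residue index. The protein-level
first-binding frame (first frame any residue is bound) is reported as a
convenience statistic.

## Penetration depth

Residue depth is `|z_cog − z_center|` with the heavy-atom centre of
geometry (a Cα-only mode is available); the absolute value folds the two
leaflets together, since a symmetric patch can be approached from either
side. Histograms use half-open 1 Å bins from 0 to a default z_max of 60 Å
(covering the 50 Å placement height); deeper values are clipped into the
last bin with a logged warning. Rows are normalised by their own maximum —
P_i(z)/P_i(max) — rather than to unit area, which makes rows comparable as
relative-occupancy maps; every occupied row therefore peaks at exactly 1.

## Packing defects

The leaflet surface is rasterised into square cells (default 1 Å). For each
cell the leaflet-proximal extreme z over lipid and core-neutral heavy atoms
is tracked; a cell is a **defect** when no atom in it reaches above the
leaflet's glycerol plane. (An equivalent reading — highest atom is a
chain/core atom sitting below the glycerol plane, or the cell is bare —
collapses to the same rule, since whenever the highest atom is below the
plane no atom is above it.) This is a deliberately simplified, single-rule
stand-in for PackMem-style deep/shallow classification: the package only
uses defect areas comparatively, so one well-specified binary rule keyed to
the glycerol plane suffices. Components are 4-connected and do not merge
across the periodic x/y boundary; atoms are assigned to cells by minimum
image, and equal-height ties cannot change the binary classification.

Atom footprints are points by default. At bead resolution a point-footprint
scan can never tile the surface at 1 Å cells, so the generator-facing
pipeline default stamps each atom over a 4 Å in-plane radius (roughly a
bead's effective cross-section at the ~6 Å lattice spacing of a 100-lipid,
60×60 Å leaflet); with that radius a quiescent patch shows ~1 % defect
area and surfacing events dominate the signal.

Defect areas are summarised by the exponential size constant λ of
P(area) ∝ exp(−area/λ), fitted by maximum likelihood on component areas at
or above a_min = 5 Å² (below which grid discretisation dominates): for the
shifted exponential the MLE is simply mean(area − a_min). At least 20
qualifying areas are required; the estimator recovers a known λ = 12 Å²
within 10 % at n = 2000 draws.

## Helix analytics

The Wimley–White water→POPC-interface scale is embedded verbatim from its
source publication (charged forms for Asp/Glu/Lys/Arg, neutral His);
negative values are hydrophobic. Window sums are plain arithmetic sums, so
a substitution's effect on any window is the scale difference of the two
residues, independent of context — e.g. I→F plus M→L shifts any window by
(−1.13 − (−0.31)) + (−0.56 − (−0.23)) = −1.15 kcal/mol.

The helical wheel advances 100° per residue (the standard α-helix
periodicity; Heliquest-style). The hydrophobic moment is the vector sum of
negated scale values at wheel angles, so the resultant points at the
hydrophobic face; magnitude is invariant under wheel-phase rotation. The
per-residue face partition is by scale sign (negative = hydrophobic face
candidate), which is the sequence-only convention; a moment-relative
partition can be derived from the reported direction if needed.

Backbone φ/ψ use the IUPAC sign convention in (−180°, 180°]. A residue is
called helical when both angles are within 30° (circular, boundary
inclusive) of the canonical (−57°, −47°); the Ramachandran region label
uses declared rectangles (allowed α: φ ∈ [−100, −30], ψ ∈ [−80, −5];
marginal: the 20° dilation). The 30° tolerance and the rectangles are
package defaults, declared rather than fitted.

The ideal-helix builder places N/CA/C/O by sequential internal-coordinate
(NeRF) construction with φ = −57°, ψ = −47°, ω = 180° and standard bond
lengths/angles (N–CA 1.458, CA–C 1.525, C–N 1.329, C–O 1.231 Å). Measured
back, interior residues recover the target angles to < 1°, with a CA–CA
distance of 3.80 Å, a rise of ~1.56 Å/residue and ~100.4°/residue twist.

## Synthetic data generator

The generator produces scripted, seeded ground truth in place of molecular
dynamics; no energetics, thermostat or solvent is modelled. Its defaults
encode the study design the analyses target:

- **Patches.** Two leaflets of 100 pseudo-lipids each (head bead, glycerol
  bead, two 10-bead tails at 1.5 Å spacing) on a jittered lattice in a
  60×60 Å box; per-leaflet headgroup counts follow largest-remainder
  allocation of the jojoba-like or tobacco-like composition tables exactly.
  Filled monolayers separate the leaflets by a 30 Å core gap filled with
  wax-ester (two acyl arms joined by an ester bead) or TAG (glycerol bead
  plus three arms) bead molecules spanning the slab.
- **Placement.** A rigid pseudo-protein (60 residues of 6 heavy beads on a
  Fibonacci-sphere shell, ~5 Å residue spacing) is rotated into one of 6
  canonical orientations (x-axis 0/90/180/270°, y-axis ±90°) and its
  centroid placed 50 Å above the membrane centre (40 Å is the bilayer
  convention), centred in x,y. Frame 0 is the placement itself.
- **Kinematics.** The centroid height follows a mean-reverting (OU-like)
  approach with relaxation time bind_time/3 toward a clearance of 6 Å above
  the head plane (1 Å in bounce mode). At bind_time, the scripted binding
  residues ramp over 5 frames to insertion_depth (default 6 Å) below the
  proximal head plane and are held with small jitter; in bounce mode the
  protein instead holds contact briefly and retreats 25 Å. Residues more
  than 3 indices from the binding set are kept ≥ 6 Å above the head plane
  (outside the contact cutoff), and nearer neighbours ≥ 1 Å — this encodes
  the recovery contract: exactly the scripted loop, give or take its ±3
  flanks, can be called bound.
- **Surfacing.** Core molecules surface as a Poisson process
  (surfacing_rate events/ns, exponential dwell, default mean 10 ns): the
  molecule's top bead rises to the head-plane level and phospholipids
  within the surfacing disc (default 5 Å) are pushed radially out,
  exposing the core — the generator's packing-defect mechanism.
- **Randomness.** One seed per scenario; fixed-offset sub-streams for patch
  construction, kinematics, the surfacing schedule and per-frame bead
  jitter, so runs are bit-reproducible and extending a trajectory does not
  reshuffle earlier frames.

What passing tests show: the analysis stack recovers scripted ground truth
(binding loop identity, insertion depth ordering, defect-rate monotonicity,
estimator consistency) at bead resolution. What they do not show: anything
about force-field accuracy, real lipid chemistry, binding kinetics or the
thermodynamics of defect formation — the generator has no physics, by
design.

## Problem sizes and numerical choices

Default analyses run on 100–200-frame, ~5 000-atom systems — desk-scale
choices that exercise every code path with comfortable statistics. Patch
size is a free parameter (lipid counts per patch are not fixed by the
analyses). Degenerate inputs fail loudly: empty membrane selections,
empty leaflets, all-zero histogram rows, too-few defect areas and
wild-type mutation mismatches all raise with specific messages rather than
returning silent defaults.

## Known limitations

- Bead-resolution lipids; no chemical identity of tails (chain length /
  unsaturation enter only as bead-count parameters).
- Binary defect rule; no shallow/deep chemical categories, no curvature
  (planar patches only), components not merged across the periodic boundary.
- Orthorhombic boxes only; no force-field topology, bonds or charges.
- The helix-window identity for regional hydrophobicity sums must be given
  by the user; only mutation deltas are window-independent.
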