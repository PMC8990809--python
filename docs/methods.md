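# Methods

This note documents the models, conventions and numerical choices behind
`pipsites`, in the spirit of the methods documentation shipped with
analysis packages like MDAnalysis or statsmodels: what is computed, under
which assumptions, and where the genuinely open design choices were made.

## Coordinate conventions and the membrane frame

All coordinates are Cartesian angstroms. Structures are assumed to be
membrane-frame oriented (as produced by membrane-positioning servers):
the membrane normal is +z and the intracellular side lies below the
bilayer midplane. The membrane frame is *supplied*, not computed — it is
two numbers in the config, `midplane_z` (default 0 Å) and
`intracellular_boundary_z` (the inner-leaflet headgroup plane, default
−20 Å, roughly half a typical 40 Å bilayer). Trajectory formats that
store nanometers (GRO/XTC) are converted to angstroms on read by
MDAnalysis.

Residue identity is `(chain_id, author_residue_number)` throughout.
Insertion codes are rejected with an explicit error rather than silently
merged. GRO input carries no chain column; there the segment name stands
in for the chain, and residues must be numbered contiguously across
chains (the GROMACS convention).

## Rotational symmetry

A C_n protein is described by its order n and a `chain_cycle`
permutation mapping each chain to its image under one +360°/n rotation
about z. Pose analysis uses this to fold the n symmetry-equivalent
copies of every site onto one reference wedge: the unique k ∈ [0, n) is
found for which the rotated inositol centroid's azimuth lies in
[0°, 360°/n), and all three centroids are rotated by k steps. The
reduction is idempotent and undefined (error) only for a centroid
exactly on the symmetry axis. Because the orientation filter depends
only on t_z and |t|, filtering and wedge reduction commute; the pipeline
filters first, then reduces.

## Pose vectors and the orientation filter

A docked headgroup is condensed to three unweighted atom-group
centroids: glycerol C1, inositol ring, anchor phosphate. The atom-name
map per species is configuration (`AtomGroupMap`); the shipped defaults
use the idealized naming of the synthetic templates (ring C1–C6,
phosphates Pn/OnA–C, hydroxyls On, glycerol C1G). For species with
several 3/4/5 phosphates the anchor is the lowest-numbered
phosphorylated position; for PI, which has none, the C4 hydroxyl oxygen
is the documented fallback. Both choices are configurable.

"Tail parallel to or facing the membrane" is made precise as
φ = asin(t_z/|t|) ≥ −tolerance with **t** pointing from the inositol
centroid to the glycerol C1 (the direction in which the acyl tails
would continue). The tolerance defaults to 15°: a pose pointing slightly
into the cytoplasm is still plausible given headgroup flexibility, but
no published angle exists, so the value is a package choice exposed as a
knob.

## Clustering and representatives

Accepted, wedge-reduced pose vectors are clustered by single-linkage
agglomeration with an inclusive distance cutoff (default 15 Å). The
link criterion reads the plural "centroids" strictly: in the default
`all_centroids` mode the linkage distance between two poses is the
*maximum* of the three corresponding centroid distances, so a link
requires every pair within the cutoff; `inositol_only` uses just the
ring centroid. Single linkage over an explicit pair relation was chosen
because it is parameter-free beyond the cutoff and has an obvious
brute-force oracle (union-find over all pairs), which the test suite
exercises on randomized instances.

Determinism is pinned down everywhere a tie could occur: clusters are
ordered by descending size then smallest member pose id; the
representative is the medoid on the inositol centroid with ties broken
by smallest pose id. Outputs are therefore byte-reproducible.

Contacts use heavy atoms on both sides and an inclusive 4.0 Å boundary;
hydrogens are excluded because docking preparations merge nonpolar
hydrogens and CG models have none, so including them would make results
depend on protonation bookkeeping rather than geometry.

## Lipid-accessible surface residues

The inner-leaflet lipid-accessible surface is defined reproducibly as:
side-chain heavy-atom centroid z within
[`intracellular_boundary_z`, `midplane_z`], and relative side-chain
solvent accessibility ≥ 0.20 with a 1.4 Å Shrake–Rupley probe (300
sphere points, biotite implementation). Relative accessibility is the
side-chain SASA in the intact protein divided by the side-chain SASA of
the same residue extracted alone in the same conformation. This
self-referential normalization needs no per-residue-type reference table
and therefore also applies to the synthetic toy residues. Residues
without side-chain heavy atoms (glycine) never qualify. No claim is
made that this definition reproduces any particular published count of
accessible residues; it is one defensible operationalization of a
procedure that is usually left unstated.

## Dual-cutoff contact events

For each (lipid, residue) pair and frame, the distance is the minimum
over all headgroup beads of the lipid and all particles of the residue.
A contact event starts at the first frame with distance ≤ r_on (default
0.5 nm), persists while ≤ r_off (default 0.8 nm), and ends the frame
before the distance exceeds r_off. The two radii damp cutoff flicker:
brief excursions into the 0.5–0.8 nm shell neither start nor end an
event. Setting r_on = r_off recovers plain thresholding, which the tests
verify against a naive oracle. Which beads count as "headgroup" is a
per-species name list in the config.

Occupancy is the percentage of frames with ≥1 lipid in contact (union
over lipids — two simultaneous lipids count once). Residence times are
event durations in ps, `(end − start + 1) × frame_stride_ps`.

## Binding sites by lipid commonality

Residues are grouped into sites using co-contact: an edge connects two
residues when at least one single lipid molecule is in contact with both
in ≥ `min_edge_pct` of frames (default 5%), and connected components
with ≥2 residues become sites, ordered by descending site occupancy.
Contacted residues that remain alone are reported separately as
singletons. This deterministic construction replaces the community
detection some trajectory tools apply at the same step; it was chosen
because its behaviour on planted fixtures is exactly predictable, and
the threshold is exposed. Site occupancy uses union semantics over the
site's residues, so it is never below the best single residue.

## Density maps

The membrane-plane lipid density is a 2D histogram of bead xy positions
over all frames, divided by the frame count (mean beads per cell per
frame). The grid covers the data's bounding box at the configured
spacing (default 2 Å), with the final bin edge widened by 1e-9 Å so
boundary beads stay binned; total mass is conserved by construction.
Leaflets are selected by z relative to the midplane (inner: z ≤
midplane). The map is written as a plain-text matrix plus a small JSON
header (origin, spacing, shape, frame count).

## Synthetic fixtures

The generators define the study conditions under which the package is
validated, and every generator emits its planted truth.

* **Toy oligomer** — n exact C_n copies of an idealized subunit:
  residues stacked along z ∈ [−25, 25] Å on an 18 Å cylinder, backbone
  pegs plus radially outward side chains cycling through
  LYS/ARG/SER/LEU/THR/ASN. A small seeded radial jitter varies geometry
  between seeds without breaking the symmetry, which is exact to
  floating-point.
* **Pose sets** — an idealized headgroup (regular 1.4 Å inositol
  hexagon, phosphates at the phosphorylated positions, glycerol C1
  2.6 Å above the ring) is spun randomly about z, scattered with
  isotropic σ = 2 Å around each planted center, and flipped tail-down
  for exactly `round(f·n)` poses, so the planted acceptance fraction is
  1 − f up to rounding. Optionally, probe oxygens plant per-residue
  contact probabilities for frequency-recovery tests.
* **Dwell trajectories** — lipids teleport between a far field (≥50 Å
  outside the protein) and scripted dwells during which one bead sits
  3.5 Å outside each site residue's outermost heavy atom (inside the
  0.5 nm cutoff). Dwell/gap lengths are geometric with the requested
  means, or a single contiguous block when an exact occupancy
  percentage is requested. The generator refuses placements that come
  within 5.5 Å of any residue outside the site, so the schedule *is*
  the ground truth: detected events correspond one-to-one to scheduled
  dwells.

What the fixtures deliberately lack: force fields, diffusion,
competition between lipids, conformational flexibility, and crowding.
Passing the planted-truth tests therefore demonstrates that the
*analysis* is correct and deterministic — not that any particular real
system binds where the fixtures say.

## Problem sizes and numerical notes

The validation suite uses 100–500 poses per docking fixture and
500–6000 frame trajectories with up to four lipids — sizes at which
every brute-force oracle (all-pairs distances, union-find clustering,
frame-loop occupancy) runs in seconds while still exercising all code
paths; the implementations themselves are vectorized (scipy `cdist`,
`minimum.reduceat`, `histogram2d`) and handle larger inputs linearly in
frames. Planted pose clusters are separated by at least three cluster
cutoffs and kept ≥5 angular σ inside the reference wedge so that wedge
folding cannot split a cluster. All distance cutoffs are inclusive.
Randomness always comes from a `numpy.random.default_rng` seeded per
call; no global state is used.

## Known limitations

* The PDBQT reader handles the AutoDock dialect via MDAnalysis and a
  MODEL-block splitter; exotic PDBQT extensions (flexible-residue
  files) are untested.
* The accessible-surface definition is package-specific (see above);
  counts depend on the 0.20 threshold and probe radius.
* Binding-site detection is a deterministic re-specification of the
  co-contact idea, not a clone of any specific trajectory-analysis
  package's community detection; with sparse, noisy contacts the
  partition can differ from graph-community methods.
* Docking itself, system building, and MD integration are out of scope;
  the package starts from poses and trajectories.
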