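# Methods

## Model and assumptions

`rnapocket` treats an RNA molecule as a union of van der Waals spheres and
defines pockets by the difference of two probe-excluded volumes on a cubic
voxel grid. The underlying picture is the classic rolling-probe
(solvent-excluded) surface: a probe sphere of radius *r* is placed at every
position where it does not overlap the molecule, and everything no probe
covers is the probe-excluded region. A large *shell probe* cannot enter
surface invaginations, so its excluded region includes the molecule plus
its pockets; a small *solvent probe* tracks the surface closely, so its
excluded region is close to the molecular volume. The set difference is
the pocket region; its 26-connected components are individual pockets.

Probe placement is *positional*, not path-connected: a probe position is
admissible whenever it is clash-free, including positions inside a fully
enclosed internal cavity. This is what makes a sealed void appear in the
shell-probe map but not in the solvent-probe map, so enclosed cavities are
detected as pockets. Mathematically the operation is morphological closing
by a Euclidean ball, computed with two exact Euclidean distance transforms
(dilation: distance-to-occupied ≤ r; erosion: distance-to-complement > r).

Shape description treats a pocket mask as a rigid body of unit point
masses at occupied voxel centers. The inertia tensor about the center of
mass, I_ab = Σ(|r|²δ_ab − r_a r_b), yields principal moments
I11 ≤ I22 ≤ I33, which always satisfy the moment triangle inequality
I11 + I22 ≥ I33. The normalized ratios (rpd1, rpd2) = (I11/I33, I22/I33)
therefore always fall inside the triangle with vertices rod (0,1),
sphere (1,1), disc (1/2,1/2).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| shell probe radius | 10 | Å | standard large-probe radius for nucleic-acid pocket extraction |
| solvent probe radius | 3 | Å | standard solvent probe for RNA (coarser than the 1.4 Å water probe used for proteins; RNA grooves are wider) |
| detection grid δ | 0.5 | Å | volume error of the shell-cavity oracle is ≈ 0.3 % at 0.5 Å vs ≈ 2 % at 1.0 Å |
| descriptor grid | 1.0 | Å | inertia ratios are scale-free and insensitive to resampling; 1 Å keeps masks small and matches the MRC export convention |
| minimum pocket volume | 50 | Å³ | drops crevice fragments smaller than any plausible ligand site |
| binding-site cutoff | < 4.0 (strict) | Å | heavy-atom distance rule for calling a nucleotide a binding site |
| lining cutoff | 4.0 | Å | same distance used to decide which nucleotides line a pocket |
| H-bond-like / contact cutoffs | 3.5 / 4.0 | Å | N/O pairs under 3.5 Å counted as hydrogen-bond-like, all other heavy-atom pairs under 4.0 Å as non-bonded |
| motif window | 2–3 | nt | di- and tri-nucleotide motifs from runs of consecutive binding sites |
| tandem threshold | < 6 | bp | two loops are tandem when fewer than six base pairs separate them |
| vdW radii | C 1.70, N 1.55, O 1.52, P 1.80, S 1.80, H 1.20, other 1.70 | Å | Bondi-style table |

Water (HOH/WAT/DOD) and common monoatomic ions (MG, NA, K, CL, ZN, MN, CA,
SR, CS, BR, IOD) are excluded from both the polymer and the ligand by
default; the ion list is configurable. Hydrogens are used when present but
all distance rules are defined on heavy atoms (most crystal structures
lack hydrogens). All hetero atoms are stripped before voxelization:
pockets are a property of the RNA alone.

## Numerical conventions

* Voxel (i, j, k) has center origin + δ(i+½, j+½, k+½); occupancy is
  decided at voxel centers.
* The detection box extends max(vdW) + shell + 2δ beyond the atoms so
  probes can always be placed fully outside the molecule.
* Pocket components use 26-connectivity; surface area counts exposed
  6-neighbour faces (A_p = faces × δ²), volume counts voxels (V_p = n δ³).
* Closing by a ball is monotone in the radius in the continuum (closings
  by scaled convex structuring elements are increasing). The voxel-center
  sampled version can flip isolated boundary voxels between radii
  (observed 0–3 voxels per step at δ = 0.5–1.0 Å); the property tests
  assert exact agreement with a brute-force probe-placement oracle and
  near-monotonicity, not perfect set inclusion.
* Descriptor points that violate the triangle constraints by < 1e−9
  (floating-point noise) are snapped to the boundary; larger violations
  raise an error.
* Classification ties on a partition boundary are flagged and broken in
  the order sphere > disc > rod. The geometric ("region") classifier uses
  side-of-line tests against the three lines through O and each vertex;
  each such line is the locus where two scores tie, so the geometric and
  max-score classifiers agree everywhere.
* Alternate locations resolve to the highest occupancy, ties
  alphabetically; multi-model files default to model 1.
* The m + 3σ outlier filter uses the population standard deviation.
  Note an intrinsic small-sample property: with n pockets the largest
  attainable z-score is (n−1)/√n, so the filter can only ever remove
  anything when n ≥ 11; it is intended for dataset-scale pocket
  collections and is off by default for single structures.
* Degenerate inputs: masks with fewer than two voxels (or all centers
  coincident) raise a degenerate-shape error; an empty pocket list is a
  valid detection result, not an error.

## Synthetic data

The fixture generator produces three families with independently known
answers:

* analytic voxel solids (ball, cuboid, cylinder, ellipsoid) whose expected
  NPR points come from closed-form continuum moments (cuboid sides
  (a, b, c) → moments ∝ (b²+c², a²+c², a²+b²)); at ≥ 10-voxel dimensions
  the discrete moments match within 2 %;
* shells of carbon pseudo-atoms on a sphere (golden-angle lattice,
  spacing ≤ 1.5 Å) around a cavity of known analytic volume, with an
  optional circular mouth; a flood-fill self-check verifies the dilated
  shell actually seals when the mouth is narrower than the solvent-probe
  diameter;
* toy RNA–ligand complexes (one P and one N pseudo-atom per nucleotide
  along a helical path, a carbon-cluster ligand) whose ground-truth
  binding set is computed by an all-pairs scan at construction time.

These fixtures exercise the voxel, distance and classification logic
exactly, but they are deliberately non-physical: no sugar/phosphate
geometry, no base planes, no realistic packing. Passing tests demonstrate
the correctness of the algorithms, not calibration against experimental
RNA structures; on real structures, results depend on the usual caveats of
crystallographic models (missing atoms, alternate conformers, modified
nucleotides, which are currently ignored).

## Problem sizes

The test suite runs the detector on shell fixtures of ~1200 pseudo-atoms
at δ = 0.5 Å (≈ 100³-voxel boxes, a few seconds per detection, cached per
session) and brute-force probe oracles on ≤ 25³-voxel grids; the
classification equivalence check samples 10,000 random triangle points.
These sizes give sub-voxel-level agreement with every analytic oracle
while keeping the full suite under half a minute.

## Design choices

* Mask I/O uses the MRC2014 format through gemmi; masks store 0/1 voxel
  values, the voxel size, and the grid origin in the MRC origin header.
* The solvent-probe excluded volume is subtracted from the shell-probe
  one *on the same grid* so the two maps are commensurable by
  construction.
* Secondary structure is an input (dot-bracket); pseudoknot pairs written
  in secondary bracket alphabets are parsed and reported but excluded
  from loop classification, since the loop taxonomy is defined on the
  nested layer.
* Loop–loop base-pair distance is the sum of helix lengths along the path
  in the loop/helix tree; for directly adjacent loops this is the length
  of the single separating helix.
* Pattern labels join the sorted unique loop kinds of a pocket's unpaired
  lining nucleotides ("exterior-hairpin loop"); sorting makes the label
  canonical. A pocket lining only paired nucleotides is "stem-only".
* Motif counting is pooled over runs with overlapping windows; this
  convention (and the 2–3 length window) is configurable.
* The contact classifier is a deliberately simple distance rule with no
  donor/acceptor or angle geometry; it is meant for quick interface
  summaries, not for publication-grade hydrogen-bond assignment.

## Known limitations

* Modified nucleotides are not recognised as polymer residues.
* No channel/tunnel tracing, surface triangulation or electrostatics.
* The discrete face-count area overestimates smooth surface areas
  (staircase effect), which lowers Ψ for large smooth pockets; shape
  classification therefore relies on the inertia descriptors, which are
  insensitive to the staircase.
* Binding-pocket pairing uses a simple atom-in-mask rule (a ligand heavy
  atom within one voxel spacing of a pocket voxel center).
* Inertia is unit-mass per voxel (uniform density), not atom-weighted.
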