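# Methods

This note records the models, parameter choices and numerical conventions
behind each analysis stage, what the synthetic generators do and do not
emulate, and the design decisions that were genuinely open.

## Structure model

Structures are parsed with gemmi and flattened to an ordered atom table.
Author residue numbering, as deposited, is the canonical coordinate
system; domain ranges are inclusive on both ends. Model 1 of multi-model
files is used (with a recorded warning), waters are dropped, hydrogens are
dropped (the target crystal structures are H-free and every geometric
criterion here is heavy-atom based), calcium ions and glycans are kept and
flagged hetero. Alternate locations resolve to the highest-occupancy
conformer, first-encountered on ties.

Van der Waals radii (Å): C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, Ca 1.97,
H 1.20, default 1.70 for unknown elements. The set is bundled as JSON and
overridable; a fixed published-style table makes areas reproducible across
machines.

**EC-domain boundaries.** Only construct termini are published for the
Fat4/Dchs1 fragments (Fat4 EC1–3 ends at residue 353, EC1–4 at 475; Dchs1
EC1–3 at 362, EC1–4 at 472). The bundled default ranges anchor those
termini and interpolate ~105-residue cadherin repeats in between; they are
explicitly package-derived and should be replaced by calcium-linker-based
ranges (JSON/YAML `{chain, domain, start, end}`) when available. Residues
outside all ranges, including Ca²⁺ and glycans, are labeled `linker`.

## SASA and burial

Shrake–Rupley with a golden-angle Fibonacci lattice: deterministic,
quasi-uniform, no RNG. Defaults: probe 1.4 Å, 960 points per atom.
Neighbour search is a k-d tree restricted to `r_i + r_j + 2·probe`. At 960
points the per-atom error against the closed-form two-sphere overlap is
below 0.4%, and totals move by <0.5% when the lattice is refined to 3840
points; 960 keeps a ~13k-atom two-chain complex comfortably inside a
minute of CPU.

Two burial conventions are always reported: `total_buried = ΔSASA_A +
ΔSASA_B` and `interface_area = total_buried/2`. The half-sum is the
headline number because it is the convention of the PISA-style interface
reports this package replaces; published cadherin interface areas follow
it.

**Per-domain-pair partitioning.** Each buried atom's ΔSASA is attributed
to the pair (its own domain, the nearest domain of the partner chain by
heavy-atom distance). This makes the pair table sum exactly to the
whole-interface burial — no double counting — and on fixtures with
contacts planted between known domain pairs it assigns all burial to
exactly those pairs. The alternative (recomputing SASA against each
partner domain in isolation) overcounts where a region is occluded by two
domains at once; it can be emulated by restricting the input structure.

Hetero groups are included in the SASA of the chain whose author chain
identifier they carry (configurable); waters were never parsed.

## Contacts

All criteria are heavy-atom and distance-only by default, since the
structures carry no hydrogens and published counts for this family derive
from PISA-style heavy-atom geometry:

* hydrogen bond: donor-bearing N/O vs acceptor N/O (bundled per-residue
  table: backbone N except proline, backbone O/OXT, standard sidechain
  donors/acceptors; His treated as both) within 3.5 Å; one record per
  qualifying atom pair;
* salt bridge: Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 vs Asp OD1/OD2, Glu
  OE1/OE2 within 4.0 Å; one record per residue pair at the
  minimum-distance atom pair (atom-level expansion behind a flag) —
  residue-level counting is how salt-bridge totals are quoted for these
  interfaces;
* vdW minima: residue-pair minimum distances within 4.5 Å, excluding
  pairs already counted above; per-domain-pair minimum distances are also
  reported unconditionally, which is how the "weak vdW contact (4–6 Å)"
  character of a non-interacting domain pair is measured.

A pair qualifying as a salt bridge is excluded from the hydrogen-bond
list, so the two sets are disjoint by construction. Cutoffs are exposed in
every API and the CLI; contact counts as a function of cutoff (3.3–3.9 Å
and 3.8–4.3 Å grids) are part of the acceptance benchmark because the
exact criteria behind published counts are rarely stated.

## Superposition and tilt

Kabsch via SVD with a determinant correction so only proper rotations are
returned; degenerate inputs (<3 points, collinear sets, length mismatch)
are rejected. Cross-structure RMSD uses Cα atoms of residues shared by
author numbering (chain-equivalence map configurable); unpaired residues
are counted and reported.

A domain's long axis runs from the centroid of its N-terminal third of Cα
atoms to the centroid of its C-terminal third. This was chosen over the
principal inertia eigenvector because it has no sign ambiguity and matches
the visual long-axis reading of a cadherin repeat; an inertia mode exists
behind a flag for sensitivity analysis (the two agree to a few degrees on
elongated domains). The EC1 tilt between two structures is measured by
superposing them on the Cα atoms of EC2–EC3 and taking
`arccos(axis_query · axis_ref) ∈ [0°, 180°]`; the measurement is symmetric
in query/reference and recovers planted hinge bends of 10–60° within 1° on
synthetic twins. Published tilt values for this family (~35° for one
partner, ~22° for the other) depend on specific reference structures that
the user must supply; without them the package asserts only the recovery
property and the ordering (smaller bend ⇒ smaller measured tilt).

## Conservation and phosphomotif

Default score: `1 − H/ln 20` per column with gaps excluded from the
frequencies; columns that are entirely gaps are flagged and unscored, and
columns >50% gaps are marked low-confidence. The alternative is a min–max
normalized mean BLOSUM62 sum-of-pairs score. Scores map to 9 equal-width
categories, mirroring the 9-grade convention of conservation-painting
servers so painted structures are visually comparable; full Bayesian
rate inference (ConSurf-style) is deliberately out of scope.

Sequence→structure mapping uses a constant numbering offset (ungapped
reference position + offset = author residue number), sufficient because
the constructs start at a known residue; an explicit alignment can replace
it. "Interface residues" for painting are those appearing in any contact
record, optionally extended by a burial footprint.

The Fj motif `D-X-N-D-[X]7-S/T` is scanned with a regex lookahead so
overlapping matches are all reported; positions are 1-based and the
phosphosite is `start + 11`.

One spec-level invariant was corrected during development: adding a single
duplicate row to an alignment can *raise* column entropy (duplicating a
minority residue flattens the distribution), so the tested invariants are
that doubling the entire alignment leaves scores unchanged and that adding
the per-column consensus row never lowers them.

## ITC one-site model

Wiseman closed form (see README) with running concentrations from the
discrete perfusion dilution: each injection of volume dV multiplies cell
species by `(1 − dV/V₀)` and the titrant total is `X₀(1 − Π(1 − dVⱼ/V₀))`.
Measured heats carry the displaced-heat correction
`ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2` plus an `offset · X₀ · dVᵢ`
dilution term. The closed form is verified in tests against an
independent per-injection mass-action quadratic solver to 1e-8 relative.

Fitting: least squares (lmfit/Levenberg–Marquardt) over (n, log₁₀K, ΔH,
offset), K fitted in log space with bounds 10¹–10¹² M⁻¹. Defaults: first
injection (the small discard shot) excluded from residuals but included in
the concentration bookkeeping; initial values n=1, c=10 for K, ΔH from the
first usable molar heat minus the plateau, offset from the final plateau.
Fits outside c ∈ [1, 1000] are flagged low-information. Kd uncertainty is
propagated from the log₁₀K standard error; replicates are averaged
arithmetically with the half-range as spread, matching the two-replicate
reporting convention of ITC studies.

Simulation conditions default to the published protocol: 200 µL cell at
30 µM, 300 µM syringe, 0.4 µL discard + nineteen 2.0 µL injections, 20 °C.
Parameter-recovery checks use 2% of the maximum injection heat as Gaussian
noise at c ≈ 64 (median Kd error <10% over 100 seeds). The ninefold
fold-reduction check runs at 0.5% noise with two averaged replicates per
construct: the weak-binding construct sits at c ≈ 7, where single fits at
2% noise scatter beyond the 15% target for reasons of information content,
not implementation. Non-binders (unconverged or Kd above 1 mM) are
reported as the `"ND"` sentinel, never as infinity.

## Border colocalization

Boundary polylines (0-based row/col pixel coordinates, JSON) are
rasterized 8-connected and dilated with a disk of radius r under the
pixel-coverage convention (a pixel joins the disk when its centre is
within r + 0.5 of the origin, so r = 1 is the full 3×3 neighbourhood).
Defaults r = 3 px and blur σ = 2 px — the boundary width and optical blur
are image-specific, so both are exposed and echoed into outputs.
Normalization is by geometric polyline length (not mask area), which keeps
values comparable across boundary geometries. Blur is applied to the whole
images before masking, and the order of operations for the complex
statistic is blur → multiply → mask → sum → divide by length.

Group comparison is the classic pooled-variance unpaired t test, one-sided
(Welch available). Zero-variance identical groups are flagged degenerate.
Empirical type-I error at α = 0.05 over 1000 simulated null co-cultures
(12 vs 10 samples, the study's group sizes) falls within two binomial
standard errors of nominal.

## Synthetic generators

* **Toy complexes**: two antiparallel helical poly-alanine bead chains
  (N, CA, C, O, CB per residue), 4 domains × 12 residues by default, axes
  30 Å apart. Planted contacts place the designated atom pair (backbone
  N/O for H-bonds, Lys NZ/Glu OE1 for salt bridges, CB/CB for vdW) midway
  between the chains at the exact requested distance, laterally offset per
  contact so planted pairs never crowd each other; the generator verifies
  that each planted pair realizes its domain-pair minimum and that no
  unplanned pair falls within contact range, and raises on contradictory
  specs. Hinge bends rigidly rotate one domain about the interdomain
  junction. Geometry is deliberately toy-like: downstream operators depend
  on distances, labels and axes, not fold realism — so passing tests
  validate the measurement machinery, not cadherin energetics.
* **MSAs**: gap-free, i.i.d. uniform columns with designated conserved
  columns and an optional motif written into every row.
* **Cell images**: Voronoi mosaics (mirrored seed points bound the edge
  cells) whose true ridge polylines are the boundary annotation; channel
  intensity is `background · (1 + (f − 1) · k(d))` with a plateau-plus-
  Gaussian-shoulder kernel of the distance to the nearest boundary, plus
  clipped Gaussian noise. At the border the noiseless intensity is exactly
  f × background, so accumulation ratios recover f. Real micrographs add
  photon statistics, uneven illumination, and boundary-tracing error —
  none of which are modelled, which is why the acceptance checks are
  recovery and calibration properties rather than absolute intensities.

All generators are deterministic under their seed.

## Deposited-structure benchmarks

Five acceptance tests compare computed values against numbers published
for the deposited Fat4–Dchs1 crystal structures (whole-interface area,
one domain-pair burial, contact counts with a cutoff sensitivity grid,
cross-structure Cα RMSD, and the 4–6 Å vdW window of the non-interacting
domain pair). Coordinate files are not redistributable inside this
repository, so these tests read from a local cache (`PCPCAD_PDB_DIR`,
default `~/.cache/pcpcad/pdb`) and fail with an explanatory message when
it is absent. They are the only tests with an external data dependency.

## Known limitations

* SASA neighbour search is exact but per-atom Python-looped; ~10⁴-atom
  complexes take tens of seconds at 960 points. The lattice is fixed, not
  adaptive.
* H-bond detection has no angular term by default (an acceptor-angle
  filter exists); aromatic interactions, cation-π and metal coordination
  are out of scope.
* The one-site ITC model does not cover multi-site or sequential binding,
  nor peak integration from raw power traces.
* Conservation scoring is frequency-based, not phylogeny-aware.
* Boundary tracing is consumed, never inferred: no segmentation.
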