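# pcpcad

Quantitative analysis of planar-cell-polarity (PCP) cadherin complexes —
the Fat/Dachsous family of giant atypical cadherins whose heterophilic
*trans*-interactions across cell–cell boundaries polarize tissues.

Structural biologists and cell biologists studying these complexes combine
four kinds of measurement, and this package implements all four as one
tested toolkit:

1. **Interface structure.** Shrake–Rupley solvent-accessible surface area
   (SASA) with a deterministic Fibonacci point lattice, whole-complex and
   per-EC-domain-pair buried surface area (both the summed-burial and the
   half-sum "interface area" conventions), and heavy-atom contact
   inventories: hydrogen bonds (donor/acceptor N/O within 3.5 Å), salt
   bridges (basic N to acidic O within 4.0 Å, one per residue pair), and
   weak van der Waals minima.
2. **Superposition geometry.** Kabsch least-squares superposition (proper
   rotations via SVD), RMSD over residues shared between structures, and
   interdomain tilt angles: align two structures on EC2–EC3, then measure
   the angle between their EC1 long axes — the statistic that captures the
   asymmetric "puckered" EC1 bend of the Fat4–Dchs1 heterodimer.
3. **Sequence conservation.** Per-column MSA conservation (normalized
   Shannon entropy `1 − H/ln 20`, or BLOSUM62 sum-of-pairs), projection of
   scores onto interface residues ("painting"), and a scanner for the
   Four-jointed kinase phosphomotif `D-X-N-D-[X]₇-S/T` whose terminal
   Ser/Thr is the extracellular phosphosite.
4. **Binding and cell biology.** The one-set-of-sites (Wiseman) ITC
   isotherm — forward simulation with the perfusion-cell displaced-volume
   correction and nonlinear fitting of (n, K_d, ΔH) — plus mutant
   fold-reduction reporting; and the cell-boundary colocalization
   statistics used on two-channel co-culture images: *border accumulation*
   (Σ intensity over a dilated boundary mask / boundary length) and
   *border complexes* (Σ of the product of Gaussian-blurred channels over
   the mask / boundary length), compared across groups with one-sided
   unpaired t tests.

A first-class synthetic-data module generates fixtures with planted ground
truth for every stage — toy two-chain multidomain complexes with exact
planted contacts and hinge bends, MSAs with controlled conservation and
planted motifs, noisy one-site thermograms, and Voronoi cell-field images
with tunable border enrichment — so the whole pipeline is testable without
any deposited data.

## The core quantities

For a complex of chains A and B, burial is
`ΔSASA_X = SASA(X alone) − SASA(X in complex)` and the headline interface
area is `(ΔSASA_A + ΔSASA_B)/2`. The ITC model for cumulative heat after
total concentrations Mt (cell) and Xt (titrant) is

    Q = (n·Mt·ΔH·V₀/2) · [ 1 + Xt/(n·Mt) + 1/(n·K·Mt)
        − √( (1 + Xt/(n·Mt) + 1/(n·K·Mt))² − 4·Xt/(n·Mt) ) ]

with per-injection heats `ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2` plus a
dilution offset; the c-value `n·K·Mt₀` governs how much K_d information a
titration carries.

## Worked example

Generate the fixture suite and analyze it from the shell:

```
$ pcpcad make-fixtures --seed 7 --outdir fixtures
$ pcpcad interface-area --cif fixtures/toy_complex.pdb --chains A,B \
      --domains fixtures/toy_domains.json --n-points 960
{
  "chains": ["A", "B"],
  "delta_sasa_A": 52.06,
  "delta_sasa_B": 53.35,
  "total_buried_A2": 105.41,
  "interface_area_A2": 52.7,
  ...
}
```

The fixture plants one salt bridge (EC1–EC2) and one hydrogen bond
(EC2–EC3) across the two chains; the per-domain-pair table reports burial
only for those pairs and zero everywhere else. Fitting the bundled
simulated thermogram (true K_d 0.47 µM, ΔH −9000 cal/mol, 0.4 µL discard +
19 × 2 µL injections of 300 µM titrant into 30 µM cell material):

```
$ pcpcad itc-fit fixtures/toy_thermogram.csv --meta fixtures/toy_thermogram_meta.json
{
  "converged": true,
  "n": 0.9953,
  "Kd_uM": 0.4508,
  "delta_H_cal_per_mol": -8924.4,
  "offset_cal_per_mol": -80.227,
  "c_value": 66.24,
  "warnings": []
}
```

i.e. the fit recovers the planted affinity to within the noise of the
simulated injections (c ≈ 66 is comfortably inside the informative
regime). `pcpcad border-stats`, `pcpcad conservation`, `pcpcad superpose`
and `pcpcad contacts` work the same way, and `pcpcad run config.yaml`
executes any subset of stages with every parameter and input hash echoed
into a deterministic `summary.json`.

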