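# Methods

This note documents the models implemented in `pdzscaffold`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not establish.

## The scientific setting

The tandem first and second PDZ domains of the postsynaptic scaffold
protein PSD-95 ("PDZ1-2", ~21 kDa) bind the C-termini of partner channels.
At the millimolar concentrations found in postsynaptic densities,
ligand-saturated PDZ1-2 self-associates.  The analysis chain reproduced
here interprets that self-association as the population of a *scaffolding
lattice*: a body-centred cubic packing, space group I2₁3 (International
Tables no. 199), cell edge |a| ≈ 148 Å, in which every monomer is held by
five interactions of three types:

* **AB_DE** — the reciprocal αB(PDZ2) ↔ βD–βE(PDZ1) double contact of the
  twofold dimer (one partner, two interactions);
* **AA_BC** — the directed αA(PDZ2) → βB–βC(PDZ1) contact closing cyclic
  trimers around the threefold axes (two partners, one interaction each);
* **P1P1** — a single PDZ1–PDZ1 contact across a second twofold.

Because a monomer interior to the lattice must break five interactions to
leave, but a dimer or tetramer member only two, oligomers become
progressively harder to dissolve as they grow — the avidity argument that
explains why large oligomers persist after dilution.

## Space-group engine

The 13 Sohncke (chiral) cubic groups are generated by closure from literal
International Tables generator triplets; rotations are integer matrices and
translations exact `Fraction`s, so closure, inverses and involutions are
tested without numerical tolerance.  Table integrity is enforced at import:
each closure must reproduce the known group order (12/24/48/96) with
determinant +1 throughout.

Symmetry-element attribute flags (4-type axes; pure twofold rotations
vs 2₁ screws; 3₁ screws; whether pure threefold axes intersect) are stored
as a literal table *and* recomputed from the operator lists in the test
suite: screw components are separated by the intrinsic-translation formula
(1/n)Σ R^k t, and threefold-axis intersection is decided geometrically on
the fixed lines of all pure threefold operators over neighbouring cells.
The elimination procedure (no 4-type axes → non-intersecting threefolds →
pure twofolds present) is then an auditable filter that leaves exactly
group 199.

## The reference monomer placement

The monomer is coarse-grained as a dumbbell: two bead-filled spheres of
radius 12 Å (the two PDZ domains) joined by a short linker.  The default
generator separation of 40 Å gives R_g ≈ 22 Å; the *placed* reference
monomer uses 46 Å (R_g ≈ 24.6 Å), inside the 21–25 Å band of the extended
conformation.

The published construction ("dimer twofold perpendicular to the z–y plane
and intersecting the x axis; trimer generated by rotation about the
resultant of x, y, z") describes a frame in which twofold and threefold
axes pass through a common origin.  In the standard setting of I2₁3 this
cannot hold: the pure twofolds lie on (x, 0, ¼)-type lines, are mutually
skew, and never intersect the threefolds (that is precisely why the group
survives the elimination).  We therefore treat the published frame as the
*operational definition of the grid search* (below) and derive the lattice
placement separately: the two domain centres were optimized, once, so that

* the domain-centre distances of the five designated contacts fall in a
  22–27 Å window (they settle at 26.3–26.9 Å, i.e. surfaces 2–3 Å apart),
* every other lattice-image pair stays ≥ 30 Å (the optimum gives ≥ 32 Å),
* the separation stays within 36–46 Å so R_g stays in band.

The frozen positions are `REFERENCE_P1/P2` in `scaffold.py`.  The contact
relations that emerge are, as exact operators: AB_DE = (x, −y, −z+½) (an
exact involution — the dimer operation applied twice is the identity, not
merely a lattice translate); AA_BC = (z, x, y) and its inverse; P1P1 =
(−x+½, y, −z) shifted by (0, 0, 1).  Only that particular translate of the
P1P1 coset touches the home copy, which is what makes the interface graph
of a finite operator list well defined.

With this placement the *geometric* interface graph (domain-centroid
contacts at a 28 Å cutoff) of the full 24-copy unit cell is identical to
the *combinatorial* graph computed purely from operator relations — the
main internal consistency check of the reconstruction.

## Oligomer presets and the octamer configurations

The tetramer is the cyclic AA_BC trimer around the [111] threefold plus the
AB_DE partner of one ring member.  Docking a second tetramer through a free
dimer arm yields four lattice-consistent octamer configurations in this
geometry; exactly one of them also forms a P1P1 contact (three interactions
on association) and is the favored configuration, the others form only the
reciprocal AB_DE pair (two interactions).  The published account counts
three configurations with one favored; the difference (4 vs 3) is a
property of the synthetic dumbbell geometry and does not affect the
favored/non-favored interaction arithmetic.

Growth by favored dockings (three interactions per added tetramer)
continues through the 20-mer.  An exhaustive search over exact 6-tile
covers of the 24 general-position cosets shows that, in this geometry, no
all-favored sequence terminates on a unit-cell-covering 24-mer; the 24e
preset therefore uses a tiling assembled with one 2-interaction and four
3-interaction dockings.  The 24e operator list covers each of the 24
cosets exactly once and is clash-free (minimum inter-copy bead distance
26.3 Å).

Interior-copy dissociation cost grows monotonically along the series
1e → 2e → 4e → … and saturates at the lattice value 5 = 2+2+1.

## Trimer-of-dimers grid search

`trimer_of_dimers_search` implements the published frame literally: the
dimer's twofold (identified from the Kabsch rotation between its two
chains) is aligned with x, the dimer is displaced by Δx along x and rotated
about its twofold on a grid (defaults 5° and 1 Å); two further dimers are
generated by ±120° rotation about [1,1,1]; the grid point whose closest
inter-dimer contact best matches the reference distance wins, with ties
broken toward smaller Δx then smaller rotation.  The cell edge follows as
a = 4Δx, and the positional uncertainty is quoted as the half-period
(2π)/(2·q_max) ≈ 8 Å for q_max = 0.4 Å⁻¹, the resolution to which the
dimer model itself was refined.  The normative test is plant-and-recover:
a dimer placed at a known grid point defines the reference distance, and
the search must return that grid point exactly.

## Forward scattering and curve analyses

* **Debye sum.** I(q) = Σᵢⱼ fᵢfⱼ sinc(q·rᵢⱼ) over coarse beads; uniform
  weights for bead models, element electron counts for atomic input.  No
  hydration shell or excluded-volume term: absolute intensities are
  arbitrary, and all mixture fitting carries a free overall scale.
  Assemblies above 3000 beads are stride-decimated with weights rescaled to
  preserve I(0).
* **Guinier.** Weighted fit of ln I vs q² on a window q·R_g ≤ 1.3 iterated
  to self-consistency (≤ 20 iterations).  A quadratic-residual z-score > 3
  flags a nonlinear Guinier region (interference/aggregation); a positive
  slope returns a flagged result rather than raising.
* **P(r).** Indirect Fourier transform on an r-grid over [0, D_max] by
  non-negative least squares with a second-difference smoothness penalty
  (default weight 0.05·‖A‖₂).  A grid-NNLS representation was chosen over a
  sine-basis expansion so that p(r) ≥ 0 is structural rather than clipped.
  End values P(0) and P(D_max) are left free; P(0) > P(D_max) is reported
  as the classical interference diagnostic.  A χ² > 5 together with long
  same-sign residual runs flags a too-small D_max.

## Reduction

* **Frame merging.** Radiation damage is diagnosed as an increase of the
  low-q/high-q decile-mean intensity ratio relative to the first frame
  (default rejection at +10%); survivors are inverse-variance averaged.
* **Scaling.** Least-squares scalar over a high-q window (default
  0.22–0.48 Å⁻¹) where interparticle interference is negligible.
* **Infinite dilution.** After scaling, a σ-weighted straight line in
  concentration is fitted at every q and its intercept taken; relative
  dilution factors suffice because a line's intercept is invariant under
  rescaling of the abscissa.  On data generated by the exactly linear model
  I(q,c) = P(q)(1 − β(q)c) the projection is exact to machine precision.

## Mixture fitting and populations

Non-negative least squares on σ-weighted intensities fits unnormalized
component weights; fractions are the weights normalized to 1 and the scale
is their sum — linear, deterministic, no random initialization.  Reduced χ²
uses N−1 degrees of freedom unless a parameter count is supplied (the
convention is stated because published χ² values depend on it).
Populations follow p_k = f_k·n_k / Σ f_j·n_j: the volume fraction assigned
to an n-mer is multiplied by its oligomer number and renormalized, so the
histogram reports the proportion of *monomers* in each oligomer.  (If the
fitted fractions were already mass fractions this weights mass twice; the
formula is implemented as published, and this caveat is the reason the
populations are documented as a bookkeeping convention rather than
thermodynamic quantities.)  A free-ligand component — the Debye curve of an
extended hexapeptide, low-amplitude and smoothly varying — can be included
and is excluded from population accounting.

## ITC

Single class of independent sites.  Cell concentrations follow the
constant-volume perfusion recursion (each aliquot dV mixes into V₀ and
displaces an equal volume: resident species scale by V₀/(V₀+dV)); the bound
concentration comes from the stable quadratic root of the mass balance, and
the injection heat is ΔH·V₀·([MX]ᵢ − [MX]ᵢ₋₁·V₀/(V₀+dV)) plus a constant
dilution heat.  Defaults: 19 × 10 µL of 5 mM ligand into 0.13 mM
macromolecule, V₀ = 1.4195 mL, 25 °C.  K_d is fitted on a log scale by
weighted least squares; the Wiseman parameter c = N·M_cell/K_d < 1 or a
K_d–N correlation > 0.95 raises an identifiability flag — at c ≈ 2 (60 µM
affinity at 0.13 mM) the isotherm is hyperbolic and N and K_d trade off,
which is why stoichiometries refined from such data are not reliable.
Dilution heats measured in buffer controls are assumed subtracted before
fitting in the recovery studies (no free baseline); co-fitting a baseline
is available for real data.

## Synthetic data: what a green test establishes

Generators are pure functions of (spec, seed) and write their generating
parameters to a JSON ground-truth sidecar.  Noise is Gaussian, either
counting-like (σ ∝ √I, scaled so the quoted level is the fractional error
at the intensity peak — used for frame and dilution emulation, where the
low-q/high-q error gradient matters) or pointwise relative (σ = ε·I, the
conventional meaning of "ε noise" on a curve — used for mixture data).
Interference uses a smooth positive β(q) concentrated below ~0.05 Å⁻¹.
Mixture curves live on a 500-point grid over 0.006–0.48 Å⁻¹, emulating the
measured range and beamline sampling density.

What the generators do **not** emulate: buffer-subtraction residuals,
detector smearing, inter-frame drift other than the injected damage
signature, concentration-dependent oligomer equilibria (fractions are set,
not computed from affinities), and any difference between the dumbbell and
real domain shapes.  A green mixture-recovery test therefore establishes
that the fitting machinery recovers known populations from curves of the
stated information content — not that the published populations are
correct.

## Numerical conventions

Tolerance-free group theory via exact rationals; clash threshold 3 Å
between beads of different copies; domain-contact cutoff 28 Å between
domain centroids (contacts sit at ~26.5 Å, the nearest non-contact at
≥ 32 Å); grid-search ties broken toward smaller Δx then smaller rotation;
σ floors of 10⁻¹²·I_max (curves) and 10⁻⁶-relative (extrapolation weights)
to avoid infinite weights on degenerate input.

## Known limitations

* The reconstruction is synthetic: residue-level interface definitions
  (the residue-range Cα contact rule) are provided for atomic models but
  the normative tests run on the dumbbell, where interfaces are typed by
  domain centroids or operator relations.
* Absolute scattering intensities are not comparable with
  solvent-corrected predictions; only mixture *fractions* are meaningful.
* The population formula is a published bookkeeping convention (see above).
* Reproduction of the published cell edge from deposited coordinates, and
  of published fit χ² values on deposited curves, requires downloads and a
  solvent-corrected form factor; both are outside the test suite by
  design.
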