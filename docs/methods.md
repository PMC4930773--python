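# Methods

This note records the models, conventions and numerical choices behind
`loopgate`, what the synthetic fixtures do and do not emulate, and the
limitations a user should keep in mind.

## Coordinate model and input conventions

Structures are hierarchies of chains, residues and atoms in Å, keyed by
author numbering (chain id, sequence number, insertion code) so that
literature residue labels (S228, Y196, N82…) address residues directly;
an offset map is unnecessary when inputs keep crystallographic
numbering.  Multi-model PDB files are the ensemble interchange format:
each MODEL is one frame, and all frames must share an identical residue
and atom topology (a hard error otherwise, since silent topology drift
invalidates every per-residue statistic).  On reading, the
highest-occupancy alternate location is kept (ties broken by altloc
letter), waters are flagged by residue name (HOH/WAT/TIP3), and missing
element columns are inferred from atom names.  Hydrogens are accepted
but never required.  Binary trajectory formats and topology files are
out of scope.

## Superposition and displacement statistics

Rigid superposition is closed-form Kabsch (SVD with determinant
correction, proper rotation guaranteed); degenerate (collinear) inputs
are rejected rather than silently resolved.  Per-residue RMSD between
two conformations first fits the mobile structure globally on a
configurable selection — all shared Cα by default, the common convention
when the fitting set is otherwise unspecified — then evaluates each
residue over Cα, backbone or heavy atoms.  Perturbed-region selection
takes maximal runs of consecutive residues exceeding a threshold
(default 2.0 Å) of length ≥ `min_run` (default 3, suppressing
single-residue noise).  This is a descriptive fixed-threshold rule, not
a hypothesis test; the report labels it as such and applies no
multiple-comparison correction.  RMSF fits every frame to the first on
the fit selection and reports per-residue RMS fluctuation about the
mean fitted position.

The loop-gap statistic is the Euclidean Cα–Cα distance of a marked
residue pair inside each domain (N-terminal pair 82/108, C-terminal pair
173/200 by default).  It is an internal coordinate: no superposition is
involved, and a property test asserts invariance under rigid motion.
Both per-frame series and their arithmetic means are reported, along
with the last-frame values, since either convention may be wanted when
comparing against ensemble-averaged figures.

## Solvent accessibility

SASA is Shrake–Rupley point counting.  Each atom's probe-expanded sphere
(probe 1.4 Å) is sampled with a Fibonacci lattice — deterministic and
seedless, so results are bit-reproducible and independent of any RNG —
and a point is accessible if outside every neighbour's expanded sphere.
960 points per atom is the default; the convergence gap to 3840 points
is under 1% on the shipped fixtures.  Because the lattice is fixed in
space, SASA is exactly invariant under translation and invariant under
rotation only to within the lattice-convergence error (~1%); tests
assert both at their respective tolerances.  Van der Waals radii are
per-element tables (Bondi default, Chothia alternative) shipped as CSV;
unknown elements fall back to the set default with a warning.  Waters
are excluded as occluders unless requested.

Interface buried area is `SAA(A) + SAA(B) − SAA(AB)` with each term
computed by the same engine; it is non-negative up to lattice noise and
decays to zero as the chains separate (property-tested).

## Spatial aggregation propensity

Per atom, SAP sums over all side-chain atoms within radius R the product
of relative exposure — that atom's SASA over its value in a fully
exposed reference — and the residue hydrophobicity.  Choices:

* **Scale**: Black–Mould, normalised so glycine is zero (hydrophilic
  residues negative), shipped as a named CSV; the scale slot is
  pluggable.
* **R**: default 10 Å, configurable (5 Å is a common tighter choice);
  results at both radii are qualitatively consistent on the fixtures.
* **Fully exposed reference**: computed by this same SASA engine on
  idealized extended Gly-X-Gly tripeptides, per residue type and atom
  name.  Self-consistency (same radii, same probe, same lattice) beats
  importing literature constants computed under other conventions.  A
  versioned copy for the default parameters ships as
  `loopgate/data/fully_exposed_sasa.csv` and a test asserts it matches a
  fresh computation.
* **Glycine** has no side chain; its Cα stands in.

Per-residue SAP is the mean over the residue's side-chain atoms.  The
wild-type/mutant selection rule returns residues whose mutant SAP is
positive *and* increased relative to wild type, ranked by the increase.
The implementation is KD-tree accelerated and is tested for exact
equality against a naive all-pairs double loop.

## Contacts

H-bond detection is geometric with typed donors and acceptors per
residue.  The backbone amide N donates for every amino acid except
proline — encoding, at the typing level, why a Ser→Pro substitution
deletes a backbone donor.  Because crystal structures and stripped
frames usually lack hydrogens, the default criterion is hydrogen-free:
heavy-atom distance ≤ 3.5 Å and antecedent–donor···acceptor angle ≥ 90°.
With explicit hydrogens the conventional D–H···A ≥ 120° criterion is
applied.  The cutoffs are this package's choices (unstated in the
analyses it supports) and are configurable.

The interface report lists cross-chain Asp/Glu↔Arg/Lys/His salt bridges
(minimum N/O distance ≤ 4 Å) and a screened-Coulomb proxy: formal ±1
charges on Asp/Glu carboxylates (midpoint of the two oxygens), Arg (Cζ),
Lys (Nζ) and chain termini, ε(r) = 4r, 12 Å cutoff, i.e.
`332·q_iq_j/(4r²)` kcal/mol per pair.  This proxy is for *relative*
wild-type/mutant comparison only; it is not a force-field energy and no
absolute meaning is claimed.

Water penetration counts water oxygens within a cutoff (default 4 Å) of
any side-chain heavy atom of a core residue set, per frame.  The default
core set, when not given explicitly, is residues whose side-chain
relative SASA (against the Gly-X-Gly reference) is below 10% in the
reference structure.

## Mutagenesis

`mutate_residue` preserves the backbone exactly and grafts the new side
chain from the Chemical Component Dictionary ideal conformer (bundled
with biotite), superposed on the N/CA/C triad; the first side-chain
torsion defaults to the most common rotamer (χ₁ = −60°) and is
configurable.  There is no rotamer search, packing, minimization or
ΔΔG prediction: the product is a topological starting point, mirroring
workflows where relaxation is delegated to subsequent simulation.
Steric clashes (pairs closer than 0.6 of summed van der Waals radii) are
reported in the structure metadata but never repaired.

## Spectroscopy and kinetics

* **Parameter A** is I₃₂₀/I₃₆₅ with linear interpolation on the
  wavelength grid, computed from raw intensities (baseline correction,
  when wanted, is the caller's step).
* **E_max** smooths with a fixed 5-point moving average (deterministic;
  width configurable) and refines the grid maximum with a three-point
  quadratic.  Plateaus and edge maxima trigger an ambiguity warning and
  the leftmost candidate is reported.
* **Transition curves** assemble any scalar signal (or a reduction of a
  spectrum: E_max or Parameter A) against denaturant concentration;
  duplicates merge by mean.  Midpoints are extrema of the smoothed
  derivative of the min-max-normalised signal, refined quadratically,
  with a 0.3 mol/L minimum separation between reported transitions.
  No linear-extrapolation ΔG fitting is attempted: the curves' transition
  positions, not free energies, are the quantities of interest.
* **Aggregation kinetics** uses a single exponential rise to plateau
  after a lag — flat baseline for t < lag, then
  `baseline + plateau·(1 − e^{−k(t−lag)})` — fitted jointly by bounded
  least squares with data-driven initial guesses (lag from the 5%-range
  crossing, rate from the half-rise time).  The explicit lag parameter
  reflects turbidity progress curves in which seeding/nucleation delays
  the exponential phase.  Flat traces and non-positive fitted rates are
  rejected as errors rather than returned.

## Synthetic fixtures

The generator builds everything the pipeline consumes, with ground truth
recorded in a manifest; all generators are seed-deterministic
(byte-identical reruns).

* **Gate structure**: an idealized scaffold with real amino-acid atom
  naming and βB1-like author numbering — two loop pairs whose marked
  Cα–Cα separations are planted exactly (closed default 6.2 Å; the
  C-terminal gap is the control knob), eight buried hydrophobic core
  strands, and a serine-lock assembly in which S228 pairs antiparallel
  with Y196 so the two backbone hydrogen bonds and the side-chain bond
  form under the geometric criteria.  Residue content echoes the real
  local sequences where they matter (¹⁹⁹PGYRG²⁰³, P172–V176).  The toy
  is *not* a physically plausible protein: no packing quality, no
  realistic Greek-key topology, loops are straight segments.  Passing
  tests on it validate bookkeeping, geometry and the analysis rules —
  not force-field realism.
* **Ensembles**: frames are the base structure plus isotropic Gaussian
  jitter (σ_background, default 0.05 Å per coordinate).  Planted "hot"
  loops additionally drift coherently along a seeded random direction,
  ramping linearly to an amplitude (default 3.5 Å) at the final frame,
  with optional extra jitter.  A coherent ramp, rather than enlarged
  incoherent noise, is the deliberate model: the phenomenon being
  planted is a loop *opening* (a conformational change detectable by the
  last-frame 2 Å rule), while per-residue jitter models fluctuation
  (detectable by RMSF).  Both knobs exist per region.
* **Hydrated cores**: water oxygens rejection-sampled into the shell
  within the cutoff of core side chains (inside set) or beyond twice the
  cutoff (outside set), never closer than 2.4 Å to any heavy atom.
* **Spectra/traces**: Gaussian emission bands whose centre follows a
  three-state denaturation model (native → intermediate → unfolded,
  logistic transitions at 1.3 and 2.2 mol/L with widths 0.12/0.18),
  an 8 nm native/intermediate red-shift pair, and turbidity traces from
  the first-order-with-lag model (plateau 1.0, k 0.05 s⁻¹, lag 30 s,
  1500 points at 0.4 s), with optional multiplicative Gaussian noise.
  Real spectra have asymmetric bands, instrument baselines and
  correlated noise; none of that is emulated, so recovery tests
  demonstrate estimator correctness, not robustness to instrument
  artefacts.

Problem sizes throughout (90-residue scaffold, 11-frame ensembles,
20-seed recovery batches, 100-replicate noise studies) were chosen as
the smallest sizes at which the planted effects are comfortably resolved
by the analysis conventions; the region-recovery margin on the default
conditions is ≈2.4 Å (weakest hot residue) against ≈1.2 Å (strongest
background residue) across 100 seeds.

## Pipeline

One config (YAML or in-code) drives mutagenesis, geometry, surface,
contacts and reporting.  Defaults that restate published analysis
parameters (2 Å threshold, marker pairs 82/108 and 173/200, the
228-vs-196/198/201 lock) are marked as such in the config docstring;
everything else is labelled a package choice.  Reports carry a
provenance block (config hash, version, seed) and are byte-identical on
reruns with identical config and inputs.  For dimeric inputs the
analyses default to the first two protein chains; chain choice is
configurable rather than guessed.

## Known limitations

* No molecular dynamics, no force-field energetics, no
  Poisson–Boltzmann electrostatics: the interface proxy is qualitative.
* The mutant side-chain geometry is idealized; downstream analyses that
  depend on fine side-chain packing of the mutated residue should not be
  trusted beyond topology.
* SASA rotation invariance is bounded by the point-lattice convergence
  error, not machine precision.
* The hydrogen-free H-bond criterion over-detects relative to explicit
  hydrogen geometry; cutoffs are conventions, not fitted parameters.
* Synthetic fixtures validate the machinery; conclusions about real
  proteins require real coordinates and spectra.
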