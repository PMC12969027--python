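# Methods

This note records the models and numerical choices behind `colcg`, the
defaults that matter, and what the synthetic-fixture tests do and do not
demonstrate.

## Coarse-grained mapping

Each residue is represented by a single backbone (BB) bead at the
*unweighted* center of geometry of its backbone atoms. The default atom set
is `{N, CA, C, O}`; whether the carbonyl oxygen belongs in the BB center is
a genuine modelling choice, so the set is a parameter
(`backbone_atom_names`) and the default is stated here: including O follows
the common four-atom peptide-backbone definition and keeps the bead on the
peptide-plane centroid. Mapping an unweighted mean makes the operation
exactly equivariant under rigid motion, which the tests assert to 1e-9 nm.

Internally all coordinates are nm (PDB Å are converted on read), angles are
degrees, times ns. Multi-model PDB files are read as trajectory frames;
altloc `A` (or blank) is kept; insertion codes are rejected with an error
rather than silently renumbered. Torsions are signed, right-handed
(IUPAC), in (−180°, 180°]; the convention is pinned by a unit test against
an explicit cross-product formula and against MDAnalysis. When box vectors
are present, bonded measurements apply the orthorhombic minimum-image
convention; without a box, raw coordinates are used.

## Boltzmann inversion

Bonded-term distributions are histogrammed with Freedman–Diaconis binning
floored at 50 bins (robust across the 1e4–1e6 sample sizes the fitters see)
and fitted by least squares with a free amplitude, i.e. the fit is done on
the density histogram but does not force unit normalization; this keeps the
estimator insensitive to clipping at the variable's legal range. An
expectation-maximization alternative was considered and rejected: the
least-squares-on-density route matches how the reference distributions were
fitted, and the free amplitudes are needed later for the density-crossing
threshold.

Inversion of a fitted component against the canonical density gives
`eq = μ` and `k = k_B T / σ²`. Angles and dihedrals are converted to
radians for the force constant (GROMACS convention, kJ mol⁻¹ rad⁻²) while
equilibrium values stay in degrees. Default temperature: 300 K.

The backbone bond-length distribution is bimodal: PRO/HYP-first bonds are
short (0.318 nm fitted mean) and general bonds long (0.354 nm). The class
threshold between them is the density crossing of the two fitted
components. The toolkit ships 0.329 nm as the documented default constant
and *also* exposes the crossing computed from any actual fit
(`gaussian_intersection`, solved analytically from the log-density
quadratic with a bracketed numeric fallback); the two need not coincide
exactly because the crossing depends on the fitted amplitudes, which vary
with the data set. When the two components are closer than the sum of
their sigmas, or their densities do not cross between the means, the fit
is flagged non-separable and no threshold is reported.

Equilibrium inversion yields force constants appropriate for thermal
fluctuations, not for high-force response; the production bond constants
(18,000 and 34,000 kJ mol⁻¹ nm⁻²) are fine-tuned under load and applied via
`apply_fine_tuning`, which records both the equilibrium and the override
value so provenance is never lost.

## Topology generation

Backbone terms per chain of N residues: N−1 bonds, N−2 angles, N−3
dihedrals; chains shorter than a term's span contribute none of that term.
The bond class is decided by the *first* residue of the pair (PRO/HYP →
short). A data-driven classifier (`classify_from_trajectory`) reproduces
the rule from measured bond lengths and falls back to the sequence rule for
residue types with fewer than 50 samples.

Angles default to harmonic funct 1 with the printed numbers; cosine-harmonic
(funct 2) is selectable since Martini angle potentials are often
cosine-based — the numbers are kept as printed either way and the choice is
the user's. Dihedrals are proper, multiplicity 1. Bead masses follow
standard Martini sizing (72/54/36 amu for regular/small/tiny).

Gō-type contacts are generated from a reference frame: pairs within
[0.3, 1.1] nm, sequence separation ≥ 3 within a chain, no restriction
between chains of the *same* triple helix, and never across helices. The
LJ minimum sits at the native distance (σ = r/2^(1/6)) with well depth
ε = 9.414 kJ mol⁻¹. Contacts are emitted as explicit pair interactions
rather than virtual-site constructions; the mechanical contract (an LJ well
of depth ε at the native distance) is identical, and virtual-site
bookkeeping is a format-compatibility concern, not a physics one. The
cutoffs and separation follow the common Gō-Martini defaults and are all
parameters.

Cross-link fragments: HLKNL is a neutral, symmetric P1–SP1d–N6a scheme
(1-propanol arm, central secondary amine, 1-propanone arm). PYD carries a
protonated pyridine ring as four tiny beads (TQ2p +0.7 e, TP1q +0.2 e,
TC6q +0.1 e, TC4 0 e; one chloride counter-ion is implied at system level)
connected by four rhombic plain bonds R1–R2, R1–R3, R2–R4, R3–R4 — never
constraints, and deliberately without a ring dihedral, which destabilizes
high-force simulations; arm geometry is maintained by angles. The internal
bond/angle *values* shipped for the fragments are synthetic placeholders
chosen from Martini bead-size geometry (tiny-bead bonds 0.25 nm, small
0.28–0.33 nm); they are not fitted to any reference ensemble, are labelled
as such in the code, and are meant to be overridden from a JSON parameter
file for production use. Which helix/chain each PYD arm attaches to is
structure-dependent and must come from input connectivity; the fragment
only names its attachment beads.

The ITP writer is deterministic (byte-identical output for identical
topologies) and round-trips through the bundled parser losslessly.

## Free energies

The maximum-likelihood estimate of ΔG from forward/backward work sets
solves the Bennett self-consistent equation — a Fermi-function-weighted
balance of the two directions including the ln(n_F/n_R) term — by Brent
root finding on a bracket spanning all work values ±50 kJ mol⁻¹ (expanded
if needed), tolerance 1e-8. Sign convention: forward work couples the
solute (∅→S); backward work is the recorded work of the reverse process,
so Crooks reads P_F(W)/P_R(−W) = exp[β(W−ΔG)]. Swapping the two arrays
negates ΔG exactly, which is tested.

Uncertainties are bootstrap (1000 resamples by default, resampling both
directions, seeded). Non-overlapping work distributions yield a flagged,
not suppressed, estimate, since the ML solution then rests on exponential
extrapolation.

logP uses logP = −ΔΔG_{W→O}/(ln 10 · R T), negative for hydrophilic
compounds; the convention flag flips the sign and is recorded in output
metadata. For the divalent cross-link's transfer free energy of
−19.06 kJ mol⁻¹ this formula gives logP = +3.32 at 300 K (octanol-avoiding,
i.e. −3.32 under the opposite sign bookkeeping); reference values
published alongside such transfer free energies do not always match this
direct evaluation under any single sign convention — possibly due to
per-replicate averaging or a different effective temperature — so the
toolkit reports the raw formula result plus its convention metadata and
never adjusts one to match the other.

## Fibril observables

*Helix metrics.* Local rise and twist are estimated by the bisector
construction: v_i = (P_{i−1}−P_i) + (P_{i+1}−P_i) points from bead i
toward the helix axis; successive v_i rotate by exactly the per-residue
twist, and the axis direction follows from their cross products. This is
exact on an ideal helix (the acceptance contract is recovery of generator
parameters within 1%) and degrades gracefully under jitter; collinear
windows (zero radius) are counted and excluded, and an all-degenerate chain
raises an error rather than returning an arbitrary twist.

*Strain ratio.* Segment boundaries come from cross-link positions
(or explicitly); gap and overlap alternate, and only complete interior
segments enter the averages. Per frame, the ratio is the mean overlap
elongation over the mean gap elongation relative to a designated reference
frame. Uncertainty is first-order propagation of the standard errors of
the two means, σ = |ratio|·sqrt((s_num/num)² + (s_den/den)²); a Monte-Carlo
resampling oracle in the tests confirms this to within 5%. Frames with
zero mean gap elongation are masked, not dropped. Which alternating parity
is "overlap" can be taken from a bead-density heuristic (overlap is denser)
with manual override.

*Force profile.* Per bond and frame, F = k·|r−r₀|, converted at
1 kJ mol⁻¹ nm⁻¹ = 1.66054 pN, assigned to the bond midpoint's axial
coordinate (symmetric and binning-stable), pooled into 300 equal bins by
default.

*SASA.* Shrake–Rupley with a deterministic Fibonacci sphere lattice
(default 960 points per bead) on the probe-expanded spheres; default radii
0.264/0.230/0.191 nm for regular/small/tiny beads and a 0.191 nm probe,
all configurable. Accuracy improves monotonically with the point count;
rotation invariance holds to the lattice resolution (≲1% at defaults) and
translation invariance exactly.

## Synthetic fixtures: what they show and what they do not

The generators define the test conditions: ideal helices at the
experimental geometry (rise 0.290 nm, 3.28 residues per turn, radius
0.15 nm, GLY-PRO-HYP repeat); the backbone bond mixture with components
(0.318, 0.010) and (0.354, 0.013) nm at weights 0.34/0.66 — the GLY share
of the collagen triplet versus the rest; Crooks-consistent Gaussian work
sets with dissipation σ²/2k_BT at σ = 5 kJ mol⁻¹ and 100 transitions per
direction; and a 335 nm toy fibril with a 67 nm D-period split half/half,
giving 10 equally spaced boundaries and five complete overlap / four
complete gap segments, strained affinely at 0.5%/1.0% so the planted
strain ratio is exactly 0.5.

These fixtures validate the *estimators and formulas*, not the force
field: a single minor-helix stands in for collagen's supercoiled
triple helix, positional jitter is isotropic Gaussian rather than thermal,
the toy fibril is one-dimensional, and no molecular dynamics is run
anywhere. Passing tests therefore show that the mapping, fitters,
estimators and observables are correct on data whose ground truth is
known — they do not show that the emitted parameters reproduce atomistic
collagen, which requires the MD validation workflow outside this
toolkit's scope.

## Problem sizes

Default test and acceptance sizes: 1e5 samples per mixture fit (20 seeds
where robustness is quantified), 100 work values per direction with 1000
bootstrap resamples, 30-residue helices, a single-strand 335 nm toy
fibril (~500 beads) over 4–5 frames, and 960-point SASA lattices. These
sizes make every estimator's sampling error small relative to its
tolerance while keeping the full suite fast on a single CPU.

## Known limitations

- The shipped cross-link internal bond/angle values are geometric
  placeholders (see above), not fitted parameters.
- The bimodal fitter assumes exactly two Gaussian components; heavier
  mixtures fall back to flagged, non-separable fits rather than model
  selection.
- Helix metrics assume a locally constant-pitch helix within a window;
  strongly bent fibrils need small windows, at the cost of noise.
- PDB chain identity is taken from chain ID/segid; files without either
  collapse into one chain.
- The minimum-image convention supports orthorhombic boxes only.
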