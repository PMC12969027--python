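# colcg

A Martini 3 coarse-graining toolkit for cross-linked collagen fibrils, for
structural-bioinformatics and molecular-modelling researchers who build or
validate residue-resolution coarse-grained (CG) collagen models.

Collagen type I assembles stiff triple helices into fibrils with a 67 nm
axial D-band repeat of dense (overlap) and sparse (gap) zones, held together
by covalent cross-links such as the divalent HLKNL
(hydroxylysino-5-keto-norleucine) and the trivalent PYD (pyridinoline).
`colcg` implements the parametrization and validation workflow for such a
model:

- **CG mapping** — one backbone (BB) bead per residue at the center of
  geometry of its backbone atoms (`N, CA, C, O` by default), from single- or
  multi-model PDB; bond/angle/torsion sample extraction with minimum-image
  support.
- **Boltzmann inversion** — fit a Gaussian `P(q) = C_q exp(-(q-μ_q)²/2σ_q²)`
  to a bonded-term density and invert it against the canonical distribution
  `P(q) = Z⁻¹ exp(-βV(q))`, giving a harmonic term with equilibrium value
  `μ_q` and force constant `k = k_B T / σ_q²`. Collagen bond lengths are
  bimodal, so a two-component fit plus the density crossing `x₀` between the
  means is provided; bonds whose **first** residue is PRO or HYP form the
  short/stiff population.
- **Topology generation** — GROMACS ITP output with the dual-bond rule
  (0.356 nm / 18,000 kJ mol⁻¹ nm⁻² general; 0.320 nm / 34,000 kJ mol⁻¹ nm⁻²
  PRO/HYP-X), angle 138° / 152 kJ mol⁻¹, dihedral 76° / 17 kJ mol⁻¹;
  strictly intrahelical Gō-type Lennard-Jones contacts (ε = 9.414 kJ mol⁻¹,
  σ = r_native/2^(1/6)); HLKNL and PYD cross-link fragments including PYD's
  rhombic four-bond pyridine ring with charges +0.7/+0.2/+0.1 e.
- **Free energies** — the Crooks-fluctuation-theorem maximum-likelihood
  (Bennett acceptance ratio) estimator for ΔG from forward/backward
  nonequilibrium work sets, with seeded bootstrap errors; transfer free
  energies ΔΔG_{S1→S2} = ΔG_{∅→S2} − ΔG_{∅→S1} and
  logP = −ΔΔG_{W→O}/(ln 10 · R T).
- **Fibril analysis** — rise per residue and residues per turn, end-to-end
  distance, the overlap/gap strain ratio
  ⟨l_overlap,t − l_overlap,0⟩ / ⟨l_gap,t − l_gap,0⟩ with propagated
  uncertainty, axially binned bond-force profiles (default 300 bins), and
  Shrake–Rupley bead SASA.
- **Fixtures** — deterministic generators for ideal triple helices,
  Gaussian-mixture bonded samples, Crooks-consistent work sets, and toy
  gap/overlap fibrils, so every estimator can be tested against planted
  ground truth without downloads.

## Worked example

```python
import colcg as cc

# 1. topology for a (GLY-PRO-HYP)10 chain
topo = cc.build_backbone_topology([["GLY", "PRO", "HYP"] * 10])
short = [b for b in topo.bonds if b.eq_value == 0.320]
print(len(topo.bonds), len(short))            # 29 19

# 2. bimodal bond-length decomposition on synthetic AA-like samples
comps, weights = cc.backbone_bond_mixture()
samples = cc.sample_bonded("bond", comps, weights, 100_000, seed=1)
fit = cc.fit_bimodal(samples)
print(round(fit.lower.mu, 4), round(fit.upper.mu, 4))   # 0.318 0.3541

# 3. transfer free energy from nonequilibrium work distributions
ws = cc.gen_work_sets(-19.06, sigma_w=5.0, seed=2)
est = cc.ml_estimate(ws, seed=3)
print(f"{est.dg:.2f} +/- {est.se:.2f} kJ/mol")          # -18.98 +/- 0.38 kJ/mol
print(round(cc.logp(est.dg), 2))                        # 3.31

# 4. overlap/gap strain ratio of a toy fibril under load
traj, seg, fib_topo = cc.build_toy_fibril(cc.ToyFibrilSpec(), n_frames=4)
print(cc.strain_ratio(seg).ratio[1:])                   # [0.5 0.5 0.5]
```

The 29 bonds split 19/10 because every bond starting at PRO or HYP takes the
short class; the mixture fit recovers the planted component means; the
estimator lands within one bootstrap SE of the planted −19.06 kJ mol⁻¹ (a
hydrophilic compound, hence positive logP for the octanol→water direction as
printed here); and the toy fibril, whose overlap segments elongate half as
much as its gap segments, returns a strain ratio of exactly 0.5 in every
strained frame.

A command-line interface mirrors the library:

```sh
colcg topo chains.fasta --out topo/          # ITP with the dual-bond rule
colcg xlink PYD --out xl/                    # cross-link fragment
colcg fep --forward f.txt --backward b.txt --seed 1 --out fep/
colcg analyze helix cg.pdb --out metrics/
colcg fixtures fibril --seed 1 --out toy/
```

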