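# bmap — bipartite protein–protein interface mapping from NMR titrations

`bmap` is a Python toolkit for the analysis chain used to map a
two-site ("bipartite") protein–protein interface by solution NMR and to
cross-validate the resulting structural model. It was built around the
interaction between the fibrillin-1 N-terminal region and the
C-terminal region of latent TGF-β binding protein 1 — a pair of modular
glycoproteins whose individual binding sites are weak (K_d ≈ 100 μM and
≈ 300 μM) but whose tethered combination binds at ≈ 0.5–1 μM — and is
useful for any system where two surfaces are mapped by titration and
assembled by restraint-driven docking.

The pipeline stages, each usable on its own:

- **Titration mapping** (`bmap.titration`): per-residue combined
  chemical-shift perturbation Δ_comb = √(ΔδH² + (ΔδN/6)²) for
  fast-exchange sites, and fold intensity loss I₀/I_final (with
  noise-propagated errors and a 3σ vanished-peak rule) for
  intermediate/slow-exchange sites; threshold calls (0.06/0.05 ppm,
  strict; 7-/10-fold, inclusive) and per-domain mapping.
- **Dynamics and RDCs** (`bmap.rdc`): heteronuclear NOE ratios with
  Monte-Carlo errors (flexible below 0.5); Saupe-matrix least-squares
  fitting of N–H residual dipolar couplings, D_a/rhombicity/Q-factor,
  back-calculation, and a two-tensor comparison that flags inter-domain
  mobility.
- **SAXS** (`bmap.saxs`): curve scaling/merging, Guinier and Kratky
  analysis, coarse-grained Debye back-calculation (one bead per
  residue) and reduced-χ² model fitting.
- **Binding** (`bmap.binding`): one-site total-binding isotherm fits
  (apparent K_d, linear nonspecific term, background), Scatchard
  linearization that declines a K_d for curved (multi-site) data, and a
  closed-form bipartite-avidity model
  K_d,app = 1/(1/K_d1 + 1/K_d2 + c_eff/(K_d1·K_d2)) with a
  Gaussian-chain helper for the linker-derived effective concentration.
- **Structures** (`bmap.structures`): multi-model PDB/mmCIF ensembles
  (via gemmi), Kabsch superposition, NMR-style coordinate precision
  (RMSD to the iterated mean), disulfide and salt-bridge scans, linker
  span feasibility, and NOE restraint-category accounting
  (intra / sequential / short / long / ambiguous by |i−j|).
- **Docking** (`bmap.docking`): interface calls → ambiguous interaction
  restraints (active/passive, r⁻⁶ effective distance, 10% random
  exclusion per trial), a seeded rigid-body search with local
  refinement, salt-bridge screening across top poses, and splicing of
  two sub-complexes with linker-feasibility verdicts.
- **Synthetic data** (`bmap.synth`): a ground-truth bipartite complex
  and deterministic generators for every input (titrations, RDCs, SAXS,
  hetNOE, binding), emulating the study design: 300 μM labeled protein,
  0–250 μM ligand, one fast-exchange site (K_d 100 μM) and one
  broadening site (K_d 300 μM), 3 Hz RDC noise, 5% SAXS noise.

## Worked example

Run the whole pipeline on the synthetic complex (30 docking trials per
site):

```python
from bmap import pipeline
report = pipeline.run_synthetic_pipeline(seed=0, n_trials=30)
print(pipeline.format_report(report))
```

(equivalently `bmap run --seed 0 --outdir scratch/run0` with
`n_trials: 30` in a config file), which prints (abridged):

```
bmap pipeline report (seed 0)

interface calls:
  static_site_a: 24 residues called (recovered 100% of truth, false-call rate 0.0%)
  static_site_b: 22 residues called (recovered 100% of truth, false-call rate 0.0%)
  mobile_a: 20 residues called (recovered 100% of truth, false-call rate 0.0%)
  mobile_b: 16 residues called (recovered 100% of truth, false-call rate 0.0%)
docking site b: 38 AIRs (4 excluded/trial), best score 0.214, interface RMSD 0.34 A
assembly: valid=True (inter-body clashes 0)
  linker mobile_a:1036-mobile_b:2001: span 27.1 A, max reach 136.8 A, feasible=True
rdc: D_a pair A -13.68 Hz (Q 0.281), pair B 11.49 Hz (Q 0.333), mobility flag=True
saxs: chi2 0.98, Guinier Rg 8.08 A (coordinate Rg 8.03 A)
binding: fitted K_d 93.0 uM (truth 100 uM); two-site Scatchard linear=False (R^2 0.763);
         avidity apparent K_d 0.643 uM
```

Reading it: the titration thresholds recover both true binding surfaces
on both molecules with no false calls; docking under the derived
ambiguous restraints reproduces the ground-truth sub-complex to
sub-angstrom interface RMSD; the 36-residue linker easily spans the two
docked sites, so the bipartite assembly is geometrically consistent; the
two RDC tensors (D_a of −13.7 vs +11.5 Hz) flag inter-domain mobility;
the SAXS χ² ≈ 1 at matched noise and Guinier Rg matches the coordinate
Rg; and the fitted apparent K_d is within noise of the generating
100 μM, while tethering two weak sites yields a sub-micromolar apparent
K_d — the avidity effect that motivates the bipartite model.

Individual stages from the shell:

```bash
bmap titrate csp --series series.yaml --protein FBN1
bmap rdc fit --table rdc.tsv --pdb model.pdb
bmap saxs guinier --dat curve.dat
bmap bind avidity --kd1 100 --kd2 300 --linker 36
bmap structure precision --pdb ensemble.pdb --range 119-178 --atoms backbone
bmap simulate all --seed 7 --outdir fixtures/
```

The structure commands run unchanged on real deposited ensembles: with
a local copy of a multi-model PDB file,
`bmap structure precision --pdb 5MS9.pdb --range 119-178` and
`bmap structure contacts --pdb 5MS9.pdb --kind disulfide` reproduce the
published backbone-precision and disulfide-count checks.

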