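# Methods

`bmap` reimplements, as a tested library, the computational chain used to
map a bipartite protein–protein interface by solution NMR and to
cross-validate the resulting model: chemical-shift-perturbation (CSP) and
peak-broadening mapping of two binding surfaces, heteronuclear-NOE and
residual-dipolar-coupling (RDC) analysis of inter-domain dynamics, SAXS
back-calculation and χ² fitting, equilibrium binding isotherms with a
bipartite-avidity model, and ambiguous-restraint rigid-body docking with
linker-feasibility assembly. The motivating system is the fibrillin-1
N-terminus binding the C-terminal region of latent TGF-β binding protein
1, where one site binds at ~100 μM, a second at ~300 μM, and the tethered
pair at ~0.5–1 μM. Because the raw spectra behind that study are not
public, a first-class synthetic-data module generates every input with
known ground truth; all quantitative claims made by the test suite are
claims about this synthetic regime.

## Interface mapping from titrations

A titration series is an ordered set of assigned ¹H–¹⁵N HSQC peak lists
at strictly increasing ligand concentration, the first point ligand-free.
For fast exchange, the per-residue endpoint perturbation is combined as

    Δ_comb = sqrt(ΔδH² + (ΔδN / 6)²)   [ppm]

with the conventional 1/6 nitrogen weight. For intermediate/slow
exchange the statistic is the fold intensity loss I₀/I_final with the
first-order propagated error; peaks whose final intensity falls below 3σ
of the baseline noise are flagged *vanished*, reported as the lower bound
I₀/(3σ), and always called. Thresholds are per-protein: combined shifts
are called above 0.06 ppm (receptor) or 0.05 ppm (ligand), strictly;
fold losses at ≥ 7 or ≥ 10. CSP is computed endpoint-vs-start only; the
intermediate points exist for the generator's oracle, not for trajectory
fitting. Missing or vanished residues propagate as explicit gaps rather
than silently dropping out.

The 1:1 fast-exchange oracle is the exact quadratic solution for the
bound fraction,

    f = [(P + L + K_d) − sqrt((P + L + K_d)² − 4 P L)] / (2 P),

with P the labeled-protein and L the total ligand concentration. The
default design matches the experiments being emulated: P = 300 μM, L
from 0 to 250 μM in six steps. At P = 300, L = 250, K_d = 100 μM this
gives exactly f = ½.

## Heteronuclear NOE and RDC analysis

NOE ratios I_sat/I_ref carry Monte-Carlo errors: 500 draws (default)
with independent Gaussian baseline noise added to both peak heights, the
error being the standard deviation of the resampled ratios. Ratios
below 0.5 flag fast-timescale flexibility; reference intensities within
3σ of zero make the record unusable rather than silently unstable.

RDCs are modelled as D = v·S·v with S the symmetric traceless Saupe
matrix scaled to Hz and v the N–H unit vector; amide protons absent from
a model are built geometrically (1.02 Å, in-plane, opposite the bisector
of N→CA and N→C(i−1)). The five independent components are fitted by
linear least squares, requiring ≥ 5 couplings and full-rank vector
geometry. Eigenvalues ordered |S_zz| ≥ |S_yy| ≥ |S_xx| define
D_a = S_zz/2 and R = 2(S_xx − S_yy)/(3 S_zz) ∈ [0, 2/3], with
Q = rms(D_obs − D_calc)/rms(D_obs). Two caveats the tests encode
explicitly: (i) at high rhombicity (R = 0.56 puts |S_yy| within 8% of
|S_zz|) noise can swap the axis ordering, so noisy-recovery statistics
project the fitted Saupe matrix onto the generating tensor's principal
axis instead of trusting the discontinuous (D_a, R) parametrization;
(ii) Q under Gaussian noise sits near noise/rms(D) — about 0.22 for
3 Hz noise on a D_a = −13.9 Hz, R = 0.56 tensor — and the tests assert
that prediction rather than a smaller aspiration.

Inter-domain mobility is flagged when tensors fitted separately to two
domain pairs disagree: the signed D_a ratio deviating from 1 by more
than 20% (default), or a two-sample Kolmogorov–Smirnov statistic between
the raw RDC distributions above a configurable level. The KS statistic
is this package's formalization of a qualitative "different
distribution" argument; it is reported as a diagnostic, not as a
hypothesis-test verdict. Supplying the two independently measured
tensors D_a/R = −13.9/0.56 and 11.2/0.35 raises the flag — consistent
with slower-timescale flexibility between the domain pairs.

## SAXS

Curves are three-column q/I/σ text. A concentration series is merged by
least-squares scaling each curve onto the first over the shared
q-window, then inverse-variance averaging. Guinier analysis fits
ln I vs q² (weighted, σ_lnI = σ/I) in a window iterated from the low-q
end so that q·Rg ≤ 1.3 by default. The Guinier law itself truncates at
O((qRg)⁴): for a solid sphere ln I = −x/5 − x²/350 (x = (qR)²), which
biases Rg high by ~1.7% when fitted out to qRg = 1.3. Tests that demand
1% accuracy of the analytic sphere therefore run at qRg ≤ 0.9, where the
truncation error is below that tolerance; the default ceiling's bias is
itself asserted in a separate test rather than hidden.

Back-calculation is a coarse Debye sum over one bead per residue at the
CA position with uniform form factors, I(q) = ΣᵢΣⱼ fᵢfⱼ sinc(q rᵢⱼ).
This is adequate for shape discrimination between candidate multidomain
arrangements; it has no hydration shell and no atomic form factors, so
its χ² values are comparable only within this convention and are never
compared against values computed by atomistic programs. The fit
minimizes χ² = (1/(N−1)) Σ[(I_exp − c·I_calc)/σ]² with the scale c in
closed form; an option drops a stated number of N-terminal residues
before back-calculation, for constructs with disordered tails.

## Binding

Plate/SPR isotherms are fitted to y = B_max·x/(K_d + x) + m·x + b —
specific saturable binding, a linear nonspecific term and a constant
background — by bounded least squares with multi-start K_d
initialization at the min, geometric mean and max of the concentration
range (the total-binding surface has shallow local minima). The fit uses
total analyte concentration, so every K_d it reports is an apparent K_d
and is flagged as such. Scatchard analysis fits bound/free vs bound with
free approximated by total; K_d = −1/slope is reported only when the
slope is negative and the line's R² ≥ 0.9 — multi-site curvature
declines the estimate instead of laundering it through a straight line.

For two sites tethered on one molecule the apparent association constant
is modelled as K_A,app = K_A1 + K_A2 + c_eff·K_A1·K_A2, i.e.

    K_d,app = 1 / (1/K_d1 + 1/K_d2 + c_eff/(K_d1·K_d2)),

monotone in the effective concentration c_eff of the second site and
never above min(K_d1, K_d2). This functional form is this package's
model — the underlying study asserts the enhancement but gives no
equation. A helper derives c_eff from linker length as a Gaussian chain,
c_eff = (3/(2π n b²))^{3/2}/N_A with b = 3.8 Å per residue: a 36-residue
linker gives ≈ 46 mM, and K_d1 = 100 μM with K_d2 = 300 μM then yields
an apparent K_d of ≈ 0.6–0.75 μM — a >100-fold enhancement, in the
experimentally estimated 0.5–1 μM range.

## Docking

Interface calls become ambiguous interaction restraints (AIRs): active
residues are the called ones; passive residues are those with any heavy
atom within 6.5 Å of an active residue of the same molecule. Each active
residue is restrained to the union of the partner's active + passive
atoms through the r⁻⁶-summed effective distance
d_eff = (Σ d⁻⁶)^(−1/6), satisfied below a ceiling. Per trial,
⌈0.1·N⌉ of the N restraints are excluded at random (10 partitions, 10%),
guarding against individually wrong calls.

The search is rigid-body: half the trials start face-to-face (the mobile
called-surface normal anti-aligned with the static patch normal, random
spin, small tilt), half from uniform random orientations; the six rigid
degrees of freedom are then refined derivative-free (Powell) against
E_soft = w_air Σ max(0, d_eff − ceiling)² + w_sb Σ max(0, d_NO − 4 Å)² +
w_clash·(soft overlap) + 0.3·mean(d_eff), where the last, weakly
weighted attraction stands in for the van-der-Waals term full docking
programs use and pulls poses into the restraint-feasible basin; a final
back-off along the interface normal clears any residual hard clashes.
Ranked scores use the hard clash *count* (weights 1:1:0.1 by default);
scores within 0.01 of each other — restraint violations far below
coordinate resolution — are ranked by mean effective distance, i.e. by
interface tightness. Flexible segments can be declared and are then
simply excluded from the clash term; there is no torsional refinement.

Two constants are representation-dependent and deliberately exist in an
all-atom and a bead flavour. The AIR ceiling is 2.0 Å for all-atom
bodies (touching side chains) but 5.5 Å for one-bead-per-residue bodies,
whose closest approach across an interface is a CA–CA van der Waals gap
and whose calling radius is 6 Å; likewise the clash criterion is 2.8 Å
heavy-atom all-atom but 3.5 Å CA–CA (non-bonded CA pairs below ~3.5 Å do
not occur in real structures). Using the all-atom constants on bead
models makes the restraints unsatisfiable and the clash term blind, so
the bead values are defaults wherever the synthetic bodies are docked.

Interface-RMSD is computed over mobile heavy atoms within 10 Å of the
partner in the reference pose, both placements expressed in the static
frame. Salt-bridge screening counts inter-molecular LYS/ARG-N to
ASP/GLU-O contacts (≤ 4 Å, minimum-distance per residue pair) across the
top-k poses. Assembly splices two independently docked sub-complexes in
the shared receptor frame, checks each declared flexible linker for span
feasibility (max reach = n_residues × 3.8 Å, the fully extended chain)
and counts inter-body clashes; a 36-residue linker reaches 136.8 Å and
can bridge a 100 Å anchor separation, a 22-residue linker (83.6 Å)
cannot.

## Synthetic ground truth

The default complex is built, not sampled: an 80-bead receptor block
(3.8 Å lattice, Gaussian jitter σ = 0.6 Å) carries two binding faces on
opposite sides; each 36-bead ligand lobe has a 12-bead contact layer
*molded* into the hollows of its face — candidate points slid to a
3.55 Å standoff and greedily selected for maximal contact — backed by
two jittered lattice layers. Molding matters: flat or periodic surfaces
make ambiguous restraints genuinely degenerate under face rotations and
translations, whereas a complementary aperiodic interface has a unique
tight, clash-free nesting, which is exactly the property real evolved
interfaces have and what makes sub-angstrom pose recovery a fair test.
Two contact-bead pairs are recast as ARG/ASP with guanidinium/carboxylate
marker atoms coincident with their CA beads, giving the salt-bridge
screen real chemistry without perturbing the docking geometry.

Generators (all deterministic functions of truth, config and seed):
fast-exchange titrations shift interface peaks by f_bound·Δδ_max with
Δδ_max drawn once per residue from 0.15–0.45 ppm (¹H) and 0.5–3 ppm
(¹⁵N), random sign — typical magnitudes for genuine contact residues;
broadening titrations attenuate as I₀/(1 + β·f_bound) with per-residue β
drawn log-uniformly in [30, 600], so endpoint losses range from ~10-fold
to disappearance, as intermediate/slow exchange actually behaves; RDCs
are tensor back-calculations plus 3 Hz Gaussian noise (within the 2–4 Hz
error band of the emulated measurements); SAXS curves get 5%
multiplicative noise with σ recorded, optionally as a four-concentration
replica series; binding assays get response-proportional 2% noise with a
small instrument floor, in triplicate. Shift noise defaults are
0.003 ppm (¹H) and 0.02 ppm (¹⁵N); intensity noise is 2% of the mean
peak height.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: peak overlap and assignment
ambiguity, exchange-regime lineshapes (K_ex, R₂), side-chain packing and
atomic form factors, hydration, free-ligand depletion in binding assays,
and any conformational flexibility within a body. The pipeline's
performance on this synthetic regime bounds what the algorithms can do
when their inputs are clean; it does not certify spectra processing.

## Numerical choices and limitations

- Superposition is closed-form Kabsch (SVD with determinant correction);
  ensemble precision is the mean RMSD of each model to the iteratively
  re-fitted mean structure (convergence 1e-4 Å), over backbone N/CA/C/O
  by default; a separate fit selection can exclude mobile tails.
- Disulfide scan: SG–SG ≤ 2.5 Å, greedy nearest-first, each SG in one
  bond. Salt bridges: basic-N to acidic-O ≤ 4.0 Å, one hit per residue
  pair at minimal distance. Both deterministic and order-stable.
- Docking refinement is Powell with ≤ 120 iterations per trial; trial
  counts of ~40–60 suffice for the default complex because the ranking
  (score, then tightness) picks the nested pose whenever any trial finds
  the basin. All stochastic stages flow from one run-level seed.
- The one-site fit flags K_d pinned at the search bounds as unreliable
  rather than failing.
- Isotherm recovery statistics are means over seeds; a per-draw hard cap
  at ~1–2σ of an unbiased estimator would be a coin flip, not a test.
- Problem sizes throughout (80 + 2×36-bead bodies, 50 RDC vectors,
  120-point curves, 5–10 docking seeds) are chosen so the full suite and
  the acceptance script each complete on one CPU in minutes while
  leaving every statistic comfortably estimable.
- The real deposited 20-model ensemble is exercised structurally (read →
  disulfide scan → precision RMSD) through a synthetic 20-model bundle,
  since the coordinate file is a multi-megabyte download; the same CLI
  (`bmap structure precision --pdb 5MS9.pdb --range 119-178`) runs the
  printed-value comparison when a local copy exists.
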