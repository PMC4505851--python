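# Methods

`loopstring` implements the computational machinery for studying slow
secondary-structure transitions in short inter-helical protein loops — the
wrapping and unwrapping of a terminal α-helical turn, as seen between the
outward- and inward-facing crystal structures of LeuT-fold transporters such
as Mhp1.  Because the production calculations behind such a study (all-atom
MD of a membrane-embedded transporter) are far beyond a desk-scale package,
every method here is exercised and validated on synthetic systems whose
ground truth is known analytically or by construction.  This note records
the models, the estimators, the defaults, and the choices that were
genuinely open.

## Structural statistics

**Torsion deviation.**  Backbone φ (C′ᵢ₋₁–Nᵢ–Cαᵢ–C′ᵢ) and ψ
(Nᵢ–Cαᵢ–C′ᵢ–Nᵢ₊₁) are computed with the IUPAC sign convention (cis = 0°,
trans = 180°; cross-checked in the tests against biotite-style normal-vector
oracles).  Between two conformations the per-residue deviation is the
smallest periodic difference of each torsion mapped to [0°, 180°], and the
combined deviation is the root-sum-square √(Δφ² + Δψ²).  A caption-style
rendering of this quantity could equally mean the *sum* of squares; we use
the root because it carries degree units and because the two are monotone
equivalent for peak finding, which is all the statistic is used for.
Undefined terminal torsions are carried as `None` and excluded.

**Amide hydrogens.**  Crystal structures lack hydrogens, but the H-bond
distance checks (e.g. S295:H–V291:O at 8.2 Å in the outward-facing state)
require them.  We place each backbone H 1.00 Å from N, in the
C′(prev)–N–Cα plane along the exterior-angle bisector — standard ideal
amide geometry.  The placement choice moves these distances by ≲ 0.3 Å,
which is the tolerance used wherever they are compared.

**Superposition.**  Weighted Kabsch superposition (proper rotations only)
via the quaternion eigenproblem; `scipy`'s `align_vectors` provides the
fit, and an independent angle-grid search serves as the test oracle.  Rigid
poses are (centroid, unit quaternion with w ≥ 0); orientation interpolation
is shortest-arc slerp (antipodal quaternions re-signed), which gives
constant angular velocity, and centers interpolate linearly.

**Cross-correlation.**  C_ij = ⟨δr_i·δr_j⟩ / √(⟨δr_i²⟩⟨δr_j²⟩) over Cα
atoms, with every frame first superposed onto the first frame on all Cα to
remove rigid-body drift.  The alignment itself induces weak negative
correlations of order 2/N_residues; with few residues this is visible, so
conclusions should rest on |C| well above that floor.  Zero-fluctuation
residues yield NaN (undefined correlation).

## Synthetic systems

**2D multi-well potentials** are sums of Gaussian wells plus a quadratic
confinement, with analytic gradient and Hessian.  A brute-force oracle
(Newton refinement of the gradient root from every grid node, classification
by Hessian eigenvalues) locates minima and saddles independently of the
string method, giving exact targets for path and barrier validation.

**The toy loop** is a peptide-like chain, five sites per residue (N, H, Cα,
C′, O; H omitted for proline-like residues), with harmonic bonds and
angles at ideal peptide geometry, stiff single-well torsions for the trans
peptide plane and the planarity of H and O, a soft-core repulsion
(ε[(r_c−r)/r_c]², r_c = 2.5 Å) between heavy atoms more than two bonds
apart, and — the designed feature — **double-well φ/ψ torsions**: two von
Mises-style wells, V(χ) = −Σ_w A_w exp[κ(cos(χ−χ_w)−1)], 180° apart
(helical wells at φ = −57°, ψ = −47°), A = 8 kcal/mol, κ = 2.  The depth
was chosen once so that both endpoint states are kinetically stable at
300 K over the ~100-ps toy timescale (the analog of loop stability in
100-ns equilibrium runs) while remaining crossable under driving.  A
*switchable helical contact* — a short-range Gaussian well (depth
6 kcal/mol, σ = 0.4 Å, r₀ = 2.0 Å) between the donor H of residue i+4 and
the acceptor O of residue i — stands in for the α-helical H-bond of the
wrapped turn.  A short-range well rather than a plain harmonic spring is
essential: both endpoint states must be local minima of *one* model energy,
and a harmonic tie would pull the unwrapped state back together.  All
terms are functions of internal coordinates, so the energy is exactly
rigid-body invariant; analytic gradients match central finite differences
to ~10⁻¹⁰ relative.

Endpoint pairs are generated by minimizing (L-BFGS, analytic gradient) the
helical state with the contact engaged, then rotating the chosen torsions
by ~180° into their second wells, minimizing with the contact released, and
re-minimizing with it restored; state B is finally superposed onto state A
so both live in one lab frame (a rigid move, energetically free).  The
construction is verified each time: gradient norms below 10⁻³ kcal/mol/Å,
prescribed flips realized within 10°, contact distance ≈ 2 Å only in the
wrapped state, and a linear Cartesian interpolation between the states
crossing a substantial energy barrier (which is what makes the string
refinement non-trivial).

## Restrained Langevin dynamics

Dynamics is BAOAB-discretized Langevin in units of kcal/mol, Å, ps
(k_B = 0.0019872041 kcal/mol/K; masses in amu converted internally).
Defaults are 300 K and a 1-fs timestep — the toy bonds' stiffest mode (the
N–H stretch, ω ≈ 430 ps⁻¹) needs dt ≲ 2 fs.  The friction default of
5 ps⁻¹ decorrelates faster than the production value of 0.1 ps⁻¹, which
matters when sampling windows are picoseconds; integrator trajectories are
bitwise reproducible from the seed.

Four restraint kinds supply all bias forces, each with exact analytic
gradients (verified by finite differences at 10⁻⁴ relative or better):

* *Cartesian harmonic* (per-atom image springs), Σ (k/2)|x_a − x_a^ref|²;
* *RMSD* (targeted MD), (k/2)[RMS−r₀]², RMS evaluated after optimal
  superposition; the gradient follows from the envelope theorem through the
  optimal rotation and translation, so the rotational coupling is exact;
* *center*, (k/2)|centroid − c_ref|²;
* *orientation angle*, (k/2)θ² with θ in degrees the angle of the best-fit
  rotation relative to a reference pose.  θ is not a stationary value of
  the fit, so its gradient is obtained by first-order perturbation of the
  Kabsch 4×4 quaternion eigenproblem (dq = (λI−K)⁺ dK q), with the θ → 0
  limit θ/sin(θ/2) → 2 handled analytically.  This functional form — the
  simplest consistent with a spring constant in kcal/mol/degree² — is our
  choice; the production literature does not pin it down.

Targeted MD moves r₀ linearly from the initial RMSD to zero over the run;
time-dependent references are `Schedule`s, either linear-in-time or
piecewise-constant frames (the loop-driving mode).

## String method

A pathway is n_images reference sets of the representative atoms (backbone
amide H except prolines, carbonyl O, all Cα, plus designated side-chain
atoms), each sampled under per-atom Cartesian springs.  Hamiltonian replica
exchange attempts adjacent-pair configuration swaps every exchange interval
(alternating odd/even pairs, Metropolis acceptance on the swap in restraint
energies), which lets conformations diffuse along the path.  The per-image
mean positions from two independently seeded groups are pooled, aligned to
the common reference, fitted per Cartesian coordinate with a cubic
smoothing spline against a chordal parameter (smoothing level estimated
from second differences of the means; fitted piecewise between declared
free-energy minima so direction kinks are allowed only there), linearly
warped so the fixed endpoints are interpolated exactly, and re-sampled at
even arc length.  Tangents are central differences of the references;
the mean system force at image i is the restraint-balance estimator
k(⟨x⟩_i − x_i^ref) — unbiased up to a factor κ/(κ+k) set by the local
landscape curvature κ, hence the stiff final-pass springs; its projection
on the tangent is integrated by the trapezoidal rule into G(s), anchored at
zero.  Pointwise standard errors propagate from block means (one exchange
interval per block); the two groups' profiles are compared by their largest
pointwise z-score, the quantitative form of the two-group hysteresis check.
Metastable states are interior minima with a prominence threshold
(`scipy.signal.find_peaks`), and they define the piecewise-fitting breaks.

Production-scale defaults (60 images with 2 kcal/mol/Å² springs for
refinement; 120 images with 4 for the final profile pass) are kept as the
`RefinementConfig` defaults.  The toy studies use 20–48 images with springs
of 10–60 kcal/mol/Å² and ps-scale sampling: with sampling windows ~10³×
shorter than production, stiffer springs keep the per-image means sharp
enough for a stable update, and the mean-force bias they introduce is
controlled because the toy landscape curvatures are ≪ k.

## Loop driving

The driving path composes three interpolations at progression t: the
internal conformation at even arc-length fraction t along the refined
pathway, a linear interpolation of the loop center, and a slerp of the loop
orientation quaternion; the internal conformation is then placed into the
interpolated pose.  End frames are required to reconstruct the endpoint
loop coordinates within 0.1 Å and are then set to them exactly.  Sixty
evenly spaced frames is the production default; each frame's Cartesian
restraint is held piecewise-constant for a fixed time before advancing.
Global center (1000 kcal/mol/Å²) and orientation-angle (200
kcal/mol/degree²) restraints on the whole system pin the global pose so
that Cartesian references are meaningful.  *Pose drift* is reported as the
1-ps rolling mean of the center-offset vector (and of the orientation
angle): the instantaneous offset fluctuates thermally with σ = √(3k_BT/k) ≈
0.04 Å, so single-sample maxima measure extreme-value statistics rather
than drift; the sustained offset stays near 0.02 Å / 0.13° in the toy runs,
with brief barrier-crossing transients up to ~0.1 Å visible in the
instantaneous series.

The coupled two-chain system quantifies loop–protein coupling: a follower
chain (a translated copy of the driven chain, renumbered +100) is tied
Cα-to-Cα through the offset vector with springs of 4 kcal/mol/Å².  Driving
only the loop pulls the coupled follower over its own torsional barriers to
the target state; with the coupling zeroed (negative control) the follower
stays in its initial state.  The follower report gives RMSD series to both
endpoint structures and the final per-residue Cα displacement after
superposition, flagging residues above a threshold as having failed to
follow.

## What the synthetic systems do and do not show

The toys establish that the estimators are correct (closed forms, analytic
critical points, Metropolis law, Boltzmann occupancy) and that the
composed workflow behaves as designed (reversible refined pathway, no
two-group hysteresis, follower control).  They do not emulate solvent,
electrostatics, side-chain packing, or the entropic breadth of real loop
ensembles; passing here validates the machinery, not any biological
free-energy value.  Real-structure statistics (torsion maps, H-bond
distances, heavy-atom RMSD) run on any user-supplied PDB pair via
`analyze_structures`, with the transporter loop residues preconfigured.

## Numerical notes and limitations

* Minimization: L-BFGS-B with analytic gradients; convergence demanded to
  max-gradient 10⁻³ kcal/mol/Å.
* Even-arc resampling interpolates a densely sampled polyline; consecutive
  arc gaps agree within 2% after every update, endpoints bitwise fixed.
* Exchange acceptance statistics of a *continuous* run mix first attempts
  with guaranteed swap-backs; the acceptance-law validation therefore
  measures first-attempt acceptance over independent runs.
* Altloc resolution keeps the highest-occupancy conformer (alphabetical on
  ties); only the first MODEL of a multi-model PDB is read unless asked.
* Problem sizes used in the shipped studies: 11-residue loop (55 sites),
  20→30 images, 1–2 ps per image per iteration, five refinement
  iterations, 60 driving frames at 1.5 ps — chosen to keep each study
  minutes-scale on one core while leaving every acceptance margin
  seed-robust.
* No explicit or implicit solvent, no barostat, no constraints (SHAKE),
  no mmCIF or binary trajectory formats, no secondary-structure
  assignment.
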