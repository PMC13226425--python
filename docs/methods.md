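# Methods

This note documents the models, conventions and numerical choices behind
`igdyn`, module by module, in the order the pipeline runs.

## Relaxation physics (`spin_physics`)

R₁, R₂ and the steady-state ¹H→¹⁵N NOE of a backbone amide are computed from
the standard dipolar + chemical-shift-anisotropy expressions,

- R₁ = (d²/4)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + c²·J(ωN)
- R₂ = (d²/8)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
  + (c²/6)[4J(0) + 3J(ωN)] + R_ex
- NOE = 1 + (d²/4)(γH/γN)(1/R₁)[6J(ωH+ωN) − J(ωH−ωN)]

with d = (μ₀/4π)·ħγHγN/r³NH and c² = (Δσ·ωN)²/3.  The 2/5 normalisation sits
inside J(ω).  Angular frequencies are handled as positive magnitudes; the
sign of γN enters only through the γH/γN factor of the NOE.

Physical constants default to **rNH = 1.02 Å**, **Δσ = −160 ppm**,
**γH/γN = −9.8656** and a **800.13 MHz** proton frequency.  These are common
literature values rather than quantities fitted here; recovered order
parameters shift by a few percent under other defensible choices (e.g.
rNH = 1.04 Å, Δσ = −172 ppm), which is why all four are config-overridable
and reported alongside results.

Model 5 (slow internal motion) uses the extended spectral density with the
fast internal motion taken as infinitely fast, so only S², S²_f and τi are
reported; the constraint S² ≤ S²_f ≤ 1 is built into the fit
parameterisation (S² = s·S²_f with s ∈ [0, 1]).

## Decay fitting (`decay_fitting`)

V(t) = V₀·exp(−Rt) is fitted in nonlinear form (never log-linearised), with
V₀ initialised from the first point and R from a two-point log estimate; the
rate error is the square root of the covariance diagonal.  This matches the
behaviour of the curve fitting in standard NMR analysis software and weights
the noisy long-delay tail correctly.  Non-convergence or a non-positive rate
yields a flagged failure for that residue, never an exception for the batch;
series with fewer than three distinct delays are emitted as missing, not
imputed.  Heteronuclear NOE errors are the absolute difference between the
two experimental replicates — symmetric by construction and zero for
identical replicates.

## Rotational diffusion (`diffusion`)

Per-residue apparent correlation times invert the rigid-limit (S² = 1,
R_ex = 0) R₂/R₁ ratio, which is strictly increasing in τc; the root is
bracketed in [0.1, 50] ns and ratios outside the achievable range flag the
residue for exclusion.  The global spherical fit minimises
χ² = Σ[(ratio_obs − ratio_calc(τc))/σ_ratio]² over residues with
NOE > 0.6 (the cutoff that excludes fast-timescale-averaged residues), with
σ_ratio from first-order error propagation; fitting ratios rather than
individual rates follows the r2r1_diffusion approach.  τc's uncertainty
comes from the curvature of the χ² profile, σ = √(2/χ″).

The axially symmetric fit has four parameters (D_iso, D∥/D⊥, axis polar
angles θ/φ).  The search minimises the quadric local-diffusion target —
D_i = 1/(6τc,i) against D_eff(θi) = sin²θi·(D∥+D⊥)/2 + cos²θi·D⊥ — from a
coarse 3×3 grid of starting orientations, then refines against and reports
the χ² of observed vs back-calculated R₂/R₁ under the full three-exponential
axially symmetric spectral density (amplitudes (3cos²θ−1)²/4, 3sin²θcos²θ,
(3/4)sin⁴θ; times 1/(6D⊥), 1/(5D⊥+D∥), 1/(2D⊥+4D∥)).  Model comparison uses
F = [(χ²sph − χ²ax)/3]/[χ²ax/(n−4)] with p from F(3, n−4).  Note that a
published F of 1.21 for χ² values 19.2/18.6 is not reproducible from this
standard formula for any plausible residue count (n = 80 gives F ≈ 0.82,
p ≈ 0.49); the implementation documents its formula and does not force
agreement — the p ≫ 0.05 conclusion is unchanged either way.

Inertia tensors use element masses, exclude hydrogens, and report principal
moments sorted descending with ratios normalised to the largest — the
convention in which an elongated Ig domain reads ~1.00:0.98:0.55 (equivalent
uniform-ellipsoid semi-axes are also provided via a² ∝ I_b + I_c − I_a,
cyclic).  Wherever a single representative model is needed, model 1 of a
deposited ensemble is used (the PDB convention for NMR representatives).

## Model-free selection (`modelfree`)

Each residue contributes three observables, so the degrees-of-freedom
bookkeeping is tight: model 1 leaves 2, models 2/3 leave 1, models 4/5 leave
0.  The nested F-test for 1→2 and 1→3 therefore runs on (1, 1) degrees of
freedom — an intentionally stringent gate (the 5% critical value of F(1,1)
is ≈161).  When both upgrades pass, the lower χ² wins; ties go to model 2
(no assumption about an internal time constant).

The *critical χ²* of a model at a residue is the 95% empirical quantile
(nearest-rank order statistic) of χ² values obtained by refitting the model
to synthetic observables drawn around its own back-calculated rates with
Gaussian noise at the experimental σ.  For model 1 this distribution is
asymptotically χ² with 2 degrees of freedom, and the Monte-Carlo quantile
converges to 5.99 — a check the test suite performs.  Refits start from the
generating parameters (the noise keeps them in the same basin), which makes
the default n_sim = 500 affordable; parameter uncertainties are the standard
deviations of the same refit distribution.  Monte-Carlo streams derive from
one master seed with per-residue substreams keyed by residue id, so results
are independent of processing order.

The decision path: fit models 1–3; upgrade from model 1 only via the F-test;
accept the justified model if χ² < critical χ²; otherwise fall back to any
other *admissible* satisfactory model among 1–3 (model 1 always admissible,
models 2/3 only with a passed F-test; lowest χ² first); fit models 4/5 only
when all of 1–3 are unsatisfactory, accepting one only if it beats its own
critical χ²; failing everything, return the lowest-χ² fit flagged
unsatisfactory.  Every returned fit records the full decision path.

Bounded searches use S², S²_f ∈ [0, 1], τe, τi ∈ [0, 10 ns],
R_ex ∈ [0, 50 s⁻¹], with a small multi-start grid (short/long internal
times, low/high exchange) to avoid local minima.

## Ensemble geometry (`structure`)

Superposition is the Kabsch SVD solution with the determinant correction, so
the rotation is always proper even for near-degenerate or reflected inputs;
the test suite cross-checks it against a brute-force quaternion search.
Cross-conformer comparisons fit on backbone N/Cα/C′ of the ordered residues
(7–94 for the I82 construct numbering); family-spread RMSDs are means over
models 2..N against model 1 after per-model global fits.  Two RMSD
conventions exist in the literature (pairwise vs to-representative); this
package uses to-representative and the deposited-geometry tolerances absorb
the difference.

Dihedrals follow the IUPAC sign convention, φ = C(i−1)-N-Cα-C and
ψ = N-Cα-C-N(i+1), undefined at chain breaks; circular differences are
always reported in [0, 180]°.

Restraint evaluation expands '#'-wildcarded pseudo-atoms (methyls,
methylenes, degenerate aromatics; `HN` aliases the amide `H`) and averages
as d_eff = (Σ_pairs d⁻⁶)^(−1/6) — the r⁻⁶ *sum* convention used by ARIA
calibration, under which three equivalent protons at 4.0 Å give an effective
3.33 Å.  A restraint is compatible with a conformer when
max(0, d − upper) ≤ 0.3 Å (the attenuation allowance for conformer-specific
restraints), and the IN/OUT/both/neither classification partitions every
restraint; compatibility is monotone in the tolerance.

H-bonds use a purely geometric per-model criterion (H…O < 2.5 Å,
N-H…O angle > 120°, backbone N-H donors, oxygen acceptors) and are reported
when present in ≥ 15/20 of the family — the fraction used when promoting
observed H-bonds to restraints.

Buried interface areas are (SASA_A + SASA_B − SASA_AB)/2 with each term from
a Shrake–Rupley calculation of that group in isolation: 960 golden-spiral
points per atom, probe 1.4 Å, heavy atoms only, radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 Å.  Published interface areas are radii-set dependent, so
agreement beyond a few percent should not be over-interpreted.

## Chemical-shift rules (`shifts`)

Proline isomer calls compare Δ(Cβ−Cγ) to the published population
distributions (trans 4.51 ± 1.37 ppm, cis 9.64 ± 1.62 ppm) in units of each
distribution's σ and pick the nearer; values beyond 3σ of both are
ambiguous.  Cysteine Cβ < 32 ppm reads reduced, > 35 ppm oxidised.

Completeness percentages count assigned entities against a documented
observable-atom inventory: fast-exchanging OH/SH protons, lysine NH₃⁺ and
its NZ are excluded, and each arginine guanidinium NH₂ pair counts once.
Conventions here differ between groups, so the inventory is part of the
public API and the resulting percentages should be treated as approximate
when compared across software.

## Synthetic data (`synthetic`)

The default relaxation profile emulates a 102-residue I82-like construct
tumbling at τc = 6.6 ns observed at 800.13 MHz: a rigid core
(S² ~ N(0.85, 0.03), model 1), disordered termini (residues 1–6 and 95–102;
model 3 with S² = 0.2 and τe = 400 ps), and a five-residue exchange loop
(73–77; model 2 with S² ~ N(0.80, 0.03) and R_ex ~ U(3, 10) s⁻¹).  Noise is
2% multiplicative on rates and 0.02 absolute on the NOE.  The terminal
parameters were chosen so the termini show the full experimental signature —
negative NOE (−0.14), R₁ above the core value and strongly reduced R₂ —
which at this field requires sub-nanosecond τe (a 1 ns internal time would
flip the terminal NOE positive, to +0.64).

The toy two-conformer generator builds a 15-residue alanine-like scaffold
whose 5-residue loop bulges to opposite sides in the IN and OUT forms
(central Cα displaced 5 Å); atom-placement frames come from the
conformer-independent base path so non-loop atoms are bit-identical across
conformers.  Restraint upper bounds are the true distance in the compatible
conformer + 0.2 Å, with conformer-specific pairs required to differ by
≥ 1 Å between the forms — so each specific set is satisfied only in its own
ensemble at the 0.3 Å tolerance, by construction.  The geometry is not
force-field realistic; what passing tests demonstrate is the correctness of
the restraint arithmetic and classification logic, not the realism of NOE
calibration on real spectra.

All generators take one explicit seed, use a single local random generator,
and emit ground truth alongside observables; recovery tests read the truth
only at assertion time.

## What the tests do and do not show

Deposited relaxation data for I82 are not public, so the dynamics pipeline
is validated by parameter recovery on synthetic data at the study's noise
level: τc round trips to 10⁻³ ns on noiseless input; over 100 seeds of the
default profile the S² bias stays below 0.02 and the mean R_ex error below
1 s⁻¹; selection keeps ≥ 90% of rigid residues on model 1 while a residue
with R_ex = 8 s⁻¹ selects model 2 in the large majority of seeds.  These
simulation sizes (100 seeds; n_sim 100–200 in tests vs the production
default 500) were chosen to estimate the relevant proportions to a few
percent.  Synthetic recovery shows the estimators and the selection logic
are correct and calibrated under the stated noise model; it cannot detect
systematic effects present in real data (peak-overlap biases, anisotropic
tumbling beyond the axial model, CSA variability along the chain).

Checks against the deposited ensembles (cross-conformer RMSDs, the G76 Cα
displacement, inertia ratios, the NMR-vs-crystal RMSD) run only when the
PDB files 9IBI/9IBK/7AHS are placed in `data/`; they are exact re-derivations
from coordinates, with tolerances (±0.1 Å, ±0.03 on axis ratios) sized to
absorb superposition- and convention-level differences.
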