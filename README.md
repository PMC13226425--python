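# igdyn

**¹⁵N relaxation, Lipari–Szabo model-free analysis and two-conformer ensemble
geometry for small Ig-fold protein domains.**

`igdyn` re-implements, as a tested and reusable Python package, the complete
quantitative analysis used in a solution-NMR study of titin's I-band IgI
domain I82 (deposited as PDB 9IBI/9IBK and BMRB 34980/34981): a ~100-residue
β-sandwich whose EF-loop exchanges between two conformations ("IN" and "OUT")
on the fast–intermediate timescale.  The package covers every stage between
raw peak volumes and the published per-residue dynamics and geometry numbers,
and ships a synthetic-data generator so that each stage can be tested offline.

## What it computes

* **Decay fitting** — ¹⁵N T₁/T₂ peak-volume series → R₁/R₂ via nonlinear
  mono-exponential fits (errors from the fit covariance); heteronuclear NOE as
  the saturated/reference volume ratio with replicate-difference errors.
* **Rotational diffusion** — per-residue apparent τc from inverting the rigid
  R₂/R₁ ratio; a spherical fit of all ratios for residues with NOE > 0.6
  giving the global τc; an axially symmetric tensor fit
  (D_iso, D∥/D⊥, axis orientation) and the sphere-vs-axial F-test; principal
  moments of inertia of the structure (pdbinertia convention).
* **Model-free analysis** — per-residue fits of the Lipari–Szabo models

  | model | parameters | spectral density |
  |-------|-----------|------------------|
  | 1 | S² | J(ω) = (2/5)·S²τc/(1+(ωτc)²) |
  | 2 | S², R_ex | as model 1; R_ex added to R₂ |
  | 3 | S², τe | + (2/5)(1−S²)τ′/(1+(ωτ′)²), 1/τ′ = 1/τc + 1/τe |
  | 4 | S², τe, R_ex | model 3 + R_ex |
  | 5 | S², S²_f, τi | (2/5)[S²τc/(1+(ωτc)²) + (S²_f−S²)τ′/(1+(ωτ′)²)] |

  with R₁/R₂/NOE back-calculated from the standard dipolar + CSA expressions.
  Model selection follows the conservative scheme of the study: models 2/3
  replace model 1 only on a significant nested F-test (p < 0.05), a model is
  *satisfactory* only if its χ² beats a Monte-Carlo **critical χ²** derived
  from the experimental errors, and the zero-degree-of-freedom models 4/5 are
  admitted only when models 1–3 all fail that bar.
* **Ensemble geometry** — Kabsch superposition, global and per-residue RMSD,
  φ/ψ dihedrals and minimal circular differences, NOE distance-restraint
  evaluation with pseudo-atom r⁻⁶ sum averaging, conformer-specificity
  classification at a 0.3 Å tolerance, geometric backbone H-bond detection
  across a family of structures, and buried interface areas from
  Shrake–Rupley solvent-accessible surfaces.
* **Chemical-shift rules** — proline cis/trans calls from Δ(Cβ−Cγ)
  (trans 4.51 ± 1.37 ppm vs cis 9.64 ± 1.62 ppm, nearest-distribution rule),
  cysteine redox state from Cβ, and assignment-completeness statistics.
* **Synthetic data** — generators for decay series, I82-like relaxation
  profiles (rigid core, mobile termini with negative NOEs, exchange-broadened
  loop), toy two-conformer ensembles with conformer-specific restraint sets,
  and proline shift tables — each with ground truth and full seed control.

## Worked example

Simulate an I82-like relaxation dataset, fit the global tumbling time, then
run model-free analysis on three representative residues (a terminus, a core
residue, an EF-loop residue):

```bash
$ igdyn simulate relax --seed 42 --out sim
$ igdyn tauc --relax sim/relaxation.tsv
tau_c = 6.654 +/- 0.012 ns  chi2 = 1219.70  n = 88
```

The generator tumbled the domain at τc = 6.6 ns; the fit recovers it from the
noisy R₂/R₁ ratios.  The large χ² is dominated by the exchange-broadened
loop residues, which pass the NOE > 0.6 filter but carry R_ex — exactly the
situation the model-free stage resolves:

```python
>>> from igdyn import fit_dataset, make_field, read_relaxation_table
>>> records = [r for r in read_relaxation_table("sim/relaxation.tsv")
...            if r.residue_id in (3, 30, 75)]
>>> fit_dataset(records, tau_c=6.6, field=make_field(), n_sim=500, seed=42)
 residue_id  model       S2   S2_err      te_ps      Rex  Rex_err     chi2  chi2_crit
          3      3 0.197588 0.006629 401.294789      NaN      NaN 0.007187   4.075390
         30      1 0.859957 0.012051        NaN      NaN      NaN 2.437114   6.056995
         75      2 0.840148 0.016605        NaN 6.341356   0.3454 0.087611   3.867852
```

Residue 3 (disordered terminus) selects model 3 with S² ≈ 0.20 and
τe ≈ 400 ps, residue 30 (rigid core) stays with model 1 at S² ≈ 0.86, and
residue 75 (EF-loop) selects model 2 with R_ex ≈ 6.3 s⁻¹ — matching the
generating ground truth written alongside in `sim/relaxation_truth.tsv`.

The published proline shifts bundled with the package classify with the
Δ(Cβ−Cγ) rule:

```python
>>> from igdyn.reference_data import i82_proline_shifts
>>> from igdyn.shifts import proline_isomer
>>> [proline_isomer(r.CB, r.CG) for r in i82_proline_shifts().itertuples()]
[(5.3, 'trans'), (4.5, 'trans'), (5.3, 'trans'), (3.4, 'trans')]
```

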