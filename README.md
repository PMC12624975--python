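# arraystrain

Micromotion-induced tissue strain around Utah-style microelectrode
arrays, and its relation to electrode recording performance.

Chronically implanted bed-of-needles arrays (grids of stiff silicon
shanks in soft cortex) move slightly relative to the brain with
respiration, pulsation and head movement.  Because the silicon is ~8
orders of magnitude stiffer than tissue, this micromotion strains the
peri-electrode parenchyma, and the strain a given electrode's
neighborhood experiences depends on where the electrode sits in the
grid: tissue near corner and edge shanks deforms more than tissue in the
shielded interior.  This package is for researchers who want to model
that spatial strain pattern, summarize it per electrode, and test how it
relates to standard recording metrics.

It provides, as one pipeline:

- a parametric array + tissue geometry and a conforming quadratic
  tetrahedral mesher with per-tip refinement (`geometry`, `meshing`);
- a static nonlinear FEM with a one-term Ogden tissue model
  (`fem`): Psi = (mu1/alpha1)(l1^-a1 + l2^-a1 + l3^-a1 - 3)
  + (1/d1)(J-1)^2, cortical parameters mu1 = 150.5 Pa, alpha1 = 19,
  d1 = 6.65e-5 1/Pa, rigid-array micromotion boundary conditions, and a
  built-in p-multigrid preconditioned Newton solver sized for one CPU;
- per-electrode strain summaries over the 50 um recording volume:
  2.5 um radial bins, shell-volume-weighted average and maximum von
  Mises strain, concentric-ring and corner grouping (`roi`);
- a synthetic-recording generator whose per-electrode ground truth
  (impedance, spike amplitude, evoked gain) is monotonically linked to a
  strain map (`synth`);
- the recording-to-metric pipeline: impedance screening, 300-5000 Hz
  bandpass, 4.5 x RMS threshold crossings, top-2% peak-to-peak voltage
  (PTPV), noise floor and SNR, neighbor correlations, envelope
  multi-unit activity and evoked SNR, session averaging and within-array
  normalization (`pipeline`);
- Spearman / Kruskal-Wallis + Dunn / ANOVA + Tukey statistics and the
  strain-vs-metric correlation report (`stats`), with desk-scale study
  drivers in `studies`.

## Worked example

Solve a reduced 4x4 array under a 10 um lateral micromotion, refine the
per-tip strain with 3 um submodels, and test the location ordering:

```python
from arraystrain.fem import SolverParams
from arraystrain.studies import strain_ordering_study

study = strain_ordering_study(
    magnitudes=(1.0, 5.0, 10.0),
    params=SolverParams(n_load_steps=5, newton_rtol=3e-4,
                        krylov_rtol=1e-4),
    sub_params=SolverParams(n_load_steps=2, newton_rtol=1e-4))
print({k: round(v, 4) for k, v in study.group_means.items()})
print(f"ANOVA p = {study.anova.p_value:.3g}")
```

prints (exact digits vary in the last place with solver tolerances):

```
{'corner': 0.0436, 'edge': 0.0409, 'interior': 0.0391}
ANOVA p = 9.82e-08
```

i.e. the volume-weighted average von Mises strain in the 50 um sphere at
each tip is ~0.044 for corner electrodes, ~0.041 for other edge
electrodes and ~0.039 for interior electrodes at 10 um displacement —
the corner > edge > interior shielding pattern, overwhelmingly
significant across the 16 electrodes.  Feeding such a strain map to the
synthetic generator and the metric pipeline recovers the planted links,
e.g. a negative strain-impedance Spearman correlation of roughly
rho ~ -0.5 at 96 electrodes in the motor regime and a positive
strain-evoked-SNR correlation (rho ~ +0.5) in the evoked regime.

A thin CLI wraps the same drivers (`arraystrain mesh / simulate /
converge / synth / metrics / correlate`); see `arraystrain --help`.

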