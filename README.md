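# tfpdyn

Backbone dynamics and conformational-plasticity analysis for small
disulfide-rich proteins — built around the three-finger (Ly-6/uPAR)
fold: a rigid β-structural "head" and three protruding loops whose
mobility spans picoseconds to seconds.

The package is for structural-NMR practitioners who have per-residue
¹⁵N relaxation tables (R1, R2, heteronuclear NOE at one or two fields)
and multi-model NMR structure ensembles, and want the full downstream
analysis: model-free fits, motional classification, region-wise
aggregates, ensemble disorder, and entropy/affinity estimates — plus a
synthetic-data generator so every stage can be tested without any
experimental input.

## What it computes

**Model-free analysis.** The Lipari–Szabo spectral density

    J(ω) = (2/5) [ S² τ_R/(1+(ωτ_R)²) + (1−S²) τ′/(1+(ωτ′)²) ],
    1/τ′ = 1/τ_R + 1/τ_e

with the standard dipolar + CSA expressions links per-residue internal
motion (S², τ_e, R_EX, or the extended S_f²·S_s², τ_s of model 5) and
overall tumbling (isotropic τ_R or an axially symmetric tensor) to the
observed R1/R2/NOE. The inverse path fits intensity decays, seeds τ_R
from rigid-residue R2/R1 ratios, refines the diffusion tensor jointly
with per-residue fits, and selects among motional models 1–5 by a
stepwise χ²/F-test protocol with Monte-Carlo parameter errors.

**Classification.** High-amplitude ps–ns motion: S² < 0.8. Fast µs–ms
exchange: R_EX > 3.0 s⁻¹ at 800 MHz, scaled as the square of the field
(2.3 at 700, 1.7 at 600 MHz). Slower processes from doubled or
broadened resonances. An R1·R2 advisory flag marks likely exchange
before any fitting. Region aggregates (mean S², mean backbone RMSD)
use Cys-anchored loop/head/C-tail schemes.

**Ensemble geometry.** Kabsch superposition of 20-model ensembles on
the stable-region backbone with an iteratively refined mean; sausage
radii (mean displacement) and region RMSD about the mean.

**Thermodynamics.** Order-parameter conformational entropy
(diffusion-in-a-cone relation), −TΔS in kcal/mol and k_BT, and the
Boltzmann affinity ratio exp(ΔG/k_BT).

## Worked example

Simulate a 100-residue three-finger-like protein (τ_R = 4.3 ns, full
relaxation triple at 800 MHz plus R2 at 600 MHz, 3% noise) and run the
whole analysis:

```python
from tfpdyn import AnalysisConfig, run_pipeline

report = run_pipeline(AnalysisConfig(seed=1, mc_reps=0))
print(f"tau_R = {report.fit.tensor.tau_r_ns:.2f} ns")
print(report.region_s2[["region", "mean_s2", "n_available", "n_total"]])
```

prints

```
tau_R = 4.30 ns
     region   mean_s2  n_available  n_total
0    loop_I  0.852537           14       14
1   loop_II  0.779226           14       16
2  loop_III  0.640805           15       15
3    c_tail  0.556870           14       14
4      head  0.868419           39       40
```

— the generator's region profile (head ≈ 0.88 > loop I > loop II >
loop III ≈ 0.66) recovered from noisy two-field data, with the counts
of residues contributing to each bar. The per-residue table
(`report.classification`) carries the motional labels and the fitted
R_EX scaled to 800 MHz.

The entropy estimator from the command line:

```sh
$ tfpdyn entropy --s2-initial 0.7 --s2-final 0.85 --n-residues 15
{
  "formula_id": "cone_full",
  "minus_t_ds_kcal_mol": 6.86,
  "minus_t_ds_kbt": 11.39,
  ...
}
```

i.e. stiffening 15 residues from mean S² 0.70 to 0.85 costs ~11.4 k_BT
of backbone conformational entropy under the full cone relation (half
that, ~5.7 k_BT ≈ 3.4 kcal/mol, under the `cone_half` convention —
see `docs/methods.md` for why both are provided), enough to shift an
affinity by more than two orders of magnitude.

Other CLI entry points: `simulate`, `fit-decays`, `fit`, `classify`,
`ensemble`, `report` (`tfpdyn --help`).

## Layout

- `src/tfpdyn/relaxation.py` — forward model (spectral densities, rates)
- `src/tfpdyn/fitting.py` — decays, diffusion tensor, per-residue fits
- `src/tfpdyn/classify.py` — thresholds, labels, region aggregation
- `src/tfpdyn/ensemble.py` — superposition and disorder metrics
- `src/tfpdyn/thermo.py` — entropy and affinity estimates
- `src/tfpdyn/observables.py` — temperature coefficients, H/D exchange,
  methanol thermometer, sequence descriptors
- `src/tfpdyn/simulate.py` — synthetic datasets and ensembles
- `src/tfpdyn/io.py`, `pipeline.py`, `cli.py`, `validation.py` — IO,
  orchestration, CLI, deposited-data cross-checks

`docs/methods.md` documents the models, defaults, numerical choices
and limitations.
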