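# Methods

`tfpdyn` analyses the conformational plasticity of small disulfide-rich
proteins — the motivating case is the three-finger (Ly-6/uPAR) fold, a
rigid β-structural "head" with three protruding loops — from backbone
¹⁵N relaxation and from the coordinate scatter of multi-model NMR
ensembles. This note records the models, the defaults and their
rationale, the numerical choices, and what the synthetic benchmark does
and does not demonstrate.

## Forward model

Backbone amide ¹⁵N relaxation is described by the model-free formalism.
The spectral density for isotropic overall tumbling is the
two-Lorentzian form

    J(ω) = (2/5) [ S² τ_R / (1 + (ωτ_R)²) + (1 − S²) τ′ / (1 + (ωτ′)²) ],
    1/τ′ = 1/τ_R + 1/τ_e,

with generalized order parameter S² and effective internal correlation
time τ_e. The extended two-timescale form (model 5) replaces the second
amplitude with (S_f² − S²), S² = S_f²·S_s², and uses τ_s in place of
τ_e, taking the fast motion in the τ_f → 0 limit. For an axially
symmetric diffusion tensor each Lorentzian is replaced by the standard
three-component orientation-weighted sum with rates 6D⊥, 5D⊥ + D∥ and
2D⊥ + 4D∥ and weights depending on the NH-to-unique-axis angle. Fully
anisotropic tensors are not implemented; the analysis this package
reproduces used isotropic and axial tensors only, and found the choice
immaterial for this fold.

R1, R2 and the steady-state ¹⁵N-{¹H} NOE follow from the dipolar and
CSA expressions with d² = (μ₀ħγ_Hγ_N/4πr³)²/4 and c² = (Δσ·ω_N)²/3.
The ¹⁵N gyromagnetic ratio is negative; all frequency combinations are
formed with signs before taking magnitudes, which yields the correct
NOE behaviour from the slow-tumbling plateau (~0.78 at 800 MHz, τ_R
4.3 ns) down to the extreme-narrowing limit (~−3.9 without CSA).

Conformational exchange enters R2 only, stored at an explicit reference
field and scaled as R_EX ∝ (field)², never implicitly. The five
motional models are: 1 (S²), 2 (S², τ_e), 3 (S², R_EX), 4 (S², τ_e,
R_EX), 5 (S_f², S_s², τ_s).

### Interaction constants

The source analysis does not state its r_NH/CSA convention. Defaults
here are r_NH = 1.02 Å and Δσ = −160 ppm — the historical
Modelfree/FastModelFree conventions — and both are configurable
(`AnalysisConfig.r_nh_angstrom`, `csa_ppm`). Sensitivity: S² scales
approximately with r_NH⁶ (≈ +3.6% in S² when moving 1.02 Å data to the
1.04 Å convention) and the CSA term contributes ~25% of R1 at 800 MHz,
so a ±10 ppm CSA change shifts S² by ~1–2%. Fitted τ_R is nearly
convention-free (it is set by R2/R1 ratios in which the constants
largely cancel). Validation against deposited data should therefore be
read with a few-percent systematic band on S², and region means
compared across conventions, not across packages.

## Inverse problem

**Decay fitting.** R1/R2 are obtained from two-parameter monoexponential
least squares on the pseudo-3D intensity tables measured at the printed
schedules (R1 delays 100–1500 ms; CPMG lengths 17–170 ms). The repeated
planes (300/800 ms; 34/136 ms) estimate the intensity noise via the
pairwise-difference estimator σ = √(mean(Δ²)/2) — the published
protocol records duplicate planes for uncertainty but not the
estimator; this choice is configurable in the sense that any σ can be
supplied. Non-decaying series are flagged, never silently returned.

**Overall tumbling.** The initial τ_R comes from the S²-independent
rigid-limit R2/R1 ratio solved per residue (Brent's method on the
forward model) and aggregated by a 10%-trimmed mean. The rigid subset
keeps residues with NOE ≥ 0.65 at the highest field and R2 within a
trimmed mean ± 1.5·(trimmed SD) window — the spread must itself be a
trimmed estimate or the exchange outliers the window should reject
would inflate it. These exclusion rules are package decisions; the
source analysis does not state its own.

**Diffusion fit.** The tensor is refined by alternating (a) per-residue
internal-motion fits with the tensor fixed and (b) a tensor update
minimizing the aggregate χ² with residue parameters fixed, until τ_R
moves < 0.5% between rounds (whether the original analysis iterated or
fixed τ_R after one pass is unstated; iterating to convergence is the
safer choice and converges in 2–4 rounds on synthetic data). The inner
fits use model 2 only — τ_e free, nesting model 1 at the τ_e = 0
bound — so internal motion can never be absorbed into τ_R. Axial fits
require NH orientations from a structure (amide H rebuilt from the
C′(i−1)/N/Cα geometry) and are repeated over ensemble conformers with
the resulting tensors averaged; on isotropic synthetic data the axial
fit returns anisotropy 1.00 ± 0.05, i.e. no spurious anisotropy.

**Per-residue fits and model selection.** Each residue is fitted to
models 1–5 by bounded multistart local least squares from a coarse grid
(S² ∈ {0.4…0.9}, τ_e log-spread 20 ps–600 ps, R_EX ∈ {1, 5, 6} s⁻¹,
τ_s ∈ {0.5, 2} ns starts); best χ² wins, deterministic given the seed.
Selection is the stepwise χ²-goodness-of-fit / F-test protocol: model 1
is accepted when its GOF p ≥ 0.10; otherwise models 2/3 are accepted on
GOF or on an F-test against model 1 at α = 0.20; models 4/5 are
accepted **only** on a significant F-test against the best simpler
model — accepting them on GOF alone lets a three-parameter model
overfit four observables and return order parameters off by > 0.1.
When nothing is satisfactory, the best of models 1–3 is reported with
`satisfactory = False` (parsimony beats a formally better overfit).
Zero-degree-of-freedom fits are accepted only when χ² < 10⁻²
(effectively exact). AIC selection is available by switch
(`protocol="aic"`). Parameter uncertainties come from Monte-Carlo
resampling of the observables within their errors, 500 seeded draws by
default.

With the two-field design used here (full triple at 800 MHz plus R2 at
600 MHz: four observables) sites whose true R_EX lies within ~1σ of
the 3.0 s⁻¹ threshold are intrinsically ambiguous — the fitted R_EX
scatters by ±0.4–0.5 s⁻¹ at 3% rate noise, so threshold classification
of such sites is correct ~90% of the time on average, not always.

## Classification and aggregation

Per-residue labels follow the threshold rules: `fast_ps_ns` when
S² < 0.8 (for model 5, when S_f², S_s² or their product is < 0.8);
`us_ms_exchange` when R_EX exceeds 3.0·(field/800)² s⁻¹ (reported
rounded: 3.0/2.3/1.7 at 800/700/600 MHz; exact values kept internally;
comparison at 800 MHz by default, at the measurement field by option);
`ms_s_two_conformers` and `broadened` from resonance annotations;
`no_data` for prolines, the N-terminal Met0 expression artifact, and
overlapped/missing resonances. The R1·R2 product flag (10%-trimmed
mean + 1 SD) is advisory only — the numeric rule is a package decision.

Regions are Cys-anchored (loops between the invariant cysteines of the
disulfide scaffold, a C-terminal tail where present, head = everything
else except the first residue) and shipped as per-protein
configurations; every aggregate echoes the scheme that produced it.
Region means are arithmetic means over residues with data, reported
with n_available/n_total.

## Ensemble geometry

Models are superposed by proper-rotation (Kabsch, det = +1) least
squares onto an iteratively refined mean structure over the backbone
(N, Cα, C′) of a "stable-region" selection (default: head residues; 5
refinement rounds or Δmean < 10⁻⁶ Å). Disorder is reported as (a) the
per-residue mean displacement from the mean structure — the sausage
radius — and (b) per-region RMSD about the mean structure, averaged
over models/residues/atoms. RMSD-to-mean (not all-pairs) matches the
"average displacement" convention of ensemble visualization software;
all-pairs mode is available for cross-checks (≈ √2 larger for Gaussian
disorder). For isotropic per-axis Gaussian disorder of scale σ the
region RMSD estimate is σ√3·√((M−1)/M) at M models.

## Entropy and affinity

The per-residue backbone conformational entropy uses the
diffusion-in-a-cone order-parameter relation S_p/k_B = ln[π(3 −
√(1+8S))] with S = +√S², which diverges to −∞ in the rigid limit and is
only evaluated on 0 < S² < 1. For a stretch of n residues whose mean S²
moves from 0.70 to 0.85 on binding this gives −TΔS = +11.39 k_BT
(+6.86 kcal/mol at 303.15 K) for n = 15. Published estimates of the
same scenario are about half that (~5.7 k_BT ≈ 3.5 kcal/mol),
consistent with a ½ prefactor convention; because the convention behind
such printed values is often unstated, every output records a
`formula_id` (`cone_full`, the default, or `cone_half`) and no
agreement is forced. The Boltzmann affinity ratio exp(ΔG/k_BT) for
5.7 k_BT is ≈ 299 (log₁₀ ≈ 2.48 — "more than two orders of
magnitude"); k_B·T(303.15 K) = 0.6025 kcal/mol is centralized.

## Sequence and shift observables

Amide temperature coefficients are OLS slopes over ≥ 3 temperatures in
ppb/K with R² reported (linearity is itself evidence against a
structural transition in the range); slopes > −4.5 ppb/K mark
hydrogen-bond candidates, strict inequality as printed. H/D
half-exchange times come from monoexponential fits (t½ = ln2/k);
t½ > 20 min, strict, marks protection. The methanol-d4 chemical-shift
thermometer uses the Findeisen–Hackbusch–Berger (2007) quadratic
calibration, enforced on its 278–330 K validity range. The sequence
profile reports the mean Kyte–Doolittle index (bounds −4.5 poly-Arg,
+4.5 poly-Ile) and a charge census counting Arg/Lys plus the N-terminus
as positive, Asp/Glu plus the C-terminus as negative, His separately;
free cysteines are not counted. Whether to profile the recombinant
construct (with Met0) or the mature sequence is the caller's choice —
both are one function call.

## Synthetic benchmark: what it emulates, what it does not

The generator draws per-residue truth from region-wise truncated
normals (head 0.88 ± 0.02; loops I/II/III 0.86/0.78/0.66 ± 0.03–0.06;
C-tail 0.60 ± 0.07 — reproducing the observed ordering head > loop I >
loop II > loop III), places eight exchange sites of 3–8 s⁻¹ (at
800 MHz) in the β-structured head/loop II where exchange is observed
experimentally, two extended-model sites in the mobile regions, and
proline/doubled/broadened annotation sites; tumbling is isotropic at
τ_R = 4.3 ns, 310.15 K. Measurements are the two-field design (full
triple at 800 MHz, R2-only at 600 MHz) with 3% fractional noise on
rates and 0.02 absolute on NOE — typical cryoprobe uncertainties, since
the source tables do not print theirs. All draws are pure functions of
(spec, seed). The packaged preset has 100 residues; the unit-test
fixtures use 60 to keep the suite fast.

Synthetic ensembles perturb an idealized backbone template with
region-scaled isotropic Gaussian displacements — adequate for testing
superposition/RMSD machinery and its statistics, **not** a model of
real loop geometry: real disorder is anisotropic, correlated along the
chain, and constrained by covalent geometry. Passing recovery tests
therefore demonstrates the estimator chain (forward model, fits,
selection, aggregation) is unbiased at realistic noise, not that any
particular protein's dynamics are captured.

## Known limitations

- No reduced spectral-density mapping, cross-correlated relaxation, or
  CPMG dispersion modelling; exchange is a field-squared scalar.
- Fully anisotropic diffusion tensors are not supported.
- Doubled (two-conformer) residues are fitted per conformer only when
  both are tabulated; otherwise they are excluded from global fits.
- The NMR-STAR reader is minimal and read-only: heteronuclear
  T1/T2/NOE loops with standard tags, rates or times; it is meant for
  validation against deposited entries, not as a general STAR parser.
- Validation against deposited PDB/BMRB entries requires network
  access and is sensitive to the region boundaries and interaction
  constants chosen (see above); the deposited-data checks report their
  scheme and constants alongside.
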