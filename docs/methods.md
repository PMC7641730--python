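# Methods

This note records the models implemented in `nmrbind`, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Chemical-shift-perturbation mapping

For a residue tracked at both titration endpoints the shift differences are
final − initial for the amide proton (ΔδHN) and nitrogen (ΔδN), both in ppm.
Two weightings of the combined perturbation are in circulation and both are
implemented:

* `unscaled`: Δδ = √(ΔδHN² + (ΔδN/5)²)
* `scaled`:   Δδ = √((ΔδHN² + (ΔδN/5)²)/2) = unscaled/√2

The factor 5 is the conventional ratio of amide ¹H to ¹⁵N shift dispersions.
`unscaled` is the default because the classification thresholds users
typically quote (mean ≈ 0.015 ppm, mean + 1 SD ≈ 0.038 ppm for this class of
study) are attached to that form; the variant is a config/argument switch
everywhere and the two are interconvertible by √2, so no information is
lost either way.

Thresholds are recomputed from the data by default: the mean and sample SD
(ddof = 1) of Δδ over *tracked* residues, with tiers below_mean / above_mean
/ above_mean_plus_sd and strict inequalities at both cuts. Residues missing
at either endpoint are `untracked` — excluded from the statistics, never
imputed. Pinned thresholds (`threshold_mode="pinned"`) support comparison
against published cut-offs.

DNA-side flagging applies the analogous rule to the H1′ and H6/H8 proton
shifts of each base: flagged iff either class moves by more than 0.025 ppm
in absolute value (a disjunction; strict inequality). The assignment of the
fingerprint NOESY peaks is consumed as a table, not computed.

## The 1:1 binding isotherm and K_D fitting

Fast exchange is assumed throughout: the observed shift is the
population-weighted average of free and bound states, so

Δδ(D) = Δδmax · f_b,  f_b = [P + D + K_D − √((P+D+K_D)² − 4PD)]/(2P)

with total concentrations P (protein) and D (DNA) in μM. The discriminant is
strictly positive for K_D > 0 (asserted); f_b ∈ [0, min(1, D/P)];
Δδ is monotone nondecreasing in D and nonincreasing in K_D.

Fitting minimizes χ² = Σ (Δδ_obs − Δδ_pred)² over (K_D, Δδmax) with
`lmfit`/Levenberg–Marquardt under bounds K_D ∈ (10⁻³, 10⁵) μM,
Δδmax ∈ (10⁻⁴, 5) ppm. The χ² surface of this isotherm has a shallow
valley in K_D when the titration does not reach saturation, so the fit
multi-starts from K_D ∈ {1, 10, 100, 1000} μM and keeps the lowest χ².
Preconditions: ≥ 3 points with D > 0; an all-zero Δδ series leaves K_D
unidentifiable and returns a non-converged result with a diagnostic rather
than an arbitrary number.

Standard errors are, by convention, the curvature (covariance) errors of the
least-squares solution scaled by the reduced χ²; a seeded residual bootstrap
(`bootstrap=n`) is available as an alternative. With the short series
typical of these titrations (≈ 6 informative points, 4 residual degrees of
freedom) *both* conventions produce anti-conservative ±2·SE intervals —
coverage near 88 % rather than 95 % for curvature errors, lower still for
the n = 6 bootstrap — which users should keep in mind when quoting
uncertainties from few-point titrations.

`fit_kd_profile` fits every residue at or above a chosen CSP tier, computing
each point's Δδ against the free endpoint with the profile's variant;
points where a residue is unassigned are dropped from that residue's fit.
Fits are per-residue and independent by default; a shared-K_D global mode is
deliberately *not* the default since per-residue values are the usual
deliverable and heterogeneity between sites is itself informative.

## ¹⁵N relaxation and the correlation time

R1 and R2 are fitted per residue as I(t) = I0·exp(−R·t) (Levenberg–Marquardt
seeded by a log-linear fit). The delay schedules used by the generator and
fixtures are the standard ones with two redundant points: CPMG 10, 30,
50/50, 70, 90, 110/110, 130, 150 ms and inversion recovery 100, 300,
500/500, …, 1500 ms. Duplicate time points give the per-point intensity
error σ = √(Σdᵢ²/2n) over n pairs with differences dᵢ; when available it
weights the fit and scales the rate error. A fitted rate below 10⁻⁶ s⁻¹ is
flagged non-decaying instead of being reported as a rate. The hetNOE is the
plain intensity ratio with/without ¹H saturation.

τ_c uses the single-field estimate τ_c = √(6·R2/R1 − 7)/(4π·ν_N), valid for
isotropic tumbling when high-frequency spectral-density terms are
negligible; it requires mean R2/R1 ≥ 7/6 and the code refuses the negative
radicand explicitly. ν_N = 0.10136919 × ν_H (fixed gyromagnetic ratio).
Averaging is per-residue-ratio-then-mean by default (`average=` switches to
mean-rates-then-ratio; the two coincide for homogeneous cores). Residue
selection approximates "rigid core" without a structure: hetNOE ≥ 0.65 and
R2/R1 within median ± 1.5×IQR; an explicit residue list overrides both.

**Expected τ_c from mass.** The default is the empirical hydrated-globular-
protein rule τ_c[ns] = 0.6 × MW[kDa] at 298 K (other temperatures scale as
298/T). It reproduces the conventional expectations for this size range
(7.68 ns at 12.8 kDa, 13.92 ns at 23.2 kDa) to within a few percent. A
Stokes–Einstein–Debye mode (v̄ = 0.73 cm³/g, 3.2 Å hydration shell,
η = 0.89 mPa·s) is provided for comparison; it runs systematically lower
because the rigid-sphere model underestimates the effective hydrated volume
of real proteins. Stoichiometry inference picks the candidate (label, total
MW) whose expected τ_c is nearest the measured value; ties break to the
smaller mass so the call is order-invariant.

## Molecular weights

Average masses throughout. Protein: Σ residue masses + 18.02 Da, no terminal
modifications (His-tag remnants are the caller's responsibility — supply the
tagged sequence to see the delta). DNA strands: Σ internal
nucleotide-monophosphate masses − 61.96 Da for synthetic 5′-OH oligos
(5′-phosphate adds back 79.98 Da). Duplex construction validates exact
Watson–Crick reverse complementarity and rejects anything else.

## Restraint generation

Active protein residues: Δδ > 0.038 ppm AND relative accessibility > 50 %,
both strict, both configurable. Passive: residues within `neighbor_window`
(default 2) sequence positions of an active residue, known to the profile or
accessibility table, not themselves active. A sequence-window neighbour
definition was chosen because it needs no structure; surface-distance
neighbours are out of scope. DNA active bases are an explicit input
(typically the flagged bases); no passive DNA. The `.tbl` writer emits one
ambiguous restraint per active residue toward the partner's selection with
the conventional 2.0 Å effective distance and (−2.0/+0.0) bounds, in sorted
order, so identical inputs give byte-identical files.

## Synthetic data: what it emulates, and what it does not

`StudyConfig` defaults define one synthetic study emulating a ~13 kDa
DNA-binding domain titrated with AT-rich duplexes: P = 100 μM; D/P from 0.1
to 6 over 7 points; 113 residues numbered 95–207 with three unassigned
(135–137) and prolines absent; ten binding residues with K_D between 11 and
57 μM and per-nucleus Δδmax giving weighted saturation shifts of
~0.05–0.15 ppm; shift noise σ_H = 0.002 / σ_N = 0.010 ppm (HSQC peak-position
precision); τ_c truth 8.9 ns free / 13.7 ns bound; 2 % multiplicative
intensity noise; a flexible tail (190–207) with hetNOE −0.5 free / 0.0
bound; fields 500 and 800 MHz. The R1 scale for back-computing rates is
1.5 s⁻¹ at 500 MHz (documented constant, ∝ (500/f)^0.5 across fields); R2
follows from the τ_c-implied R2/R1 ratio, so `estimate_tauc` inverts the
generator by construction.

The protein sequence bundled with the generator is a **synthetic stand-in**
(so labelled in code and FASTA): a generated 113-residue sequence with a
plausible helical-domain composition, basic residues at the perturbed
positions, and a mass near 12.8 kDa. It is not the real Orc6 sequence, and
no result in this package depends on it being one.

Deliberately not emulated: lineshapes and exchange broadening (fast exchange
is hard-coded; peak positions are exact population averages), peak overlap
and picking errors, field-dependent CSPs, anisotropic tumbling, per-residue
spectral-density variation beyond the rigid/flexible dichotomy, and
NOESY-level detail on the DNA side. Passing tests therefore demonstrate the
*estimators* are correct and well-calibrated on data obeying the models'
assumptions — not that real spectra meet those assumptions.

All generation is driven by `numpy.random.default_rng` seeded from the
study seed (sub-streams per state/field via `SeedSequence`), so a study tree
is reproducible byte for byte.

## Problem sizes used in the checks

Recovery checks run at the study's own scale: ~110 residues per peak list, 7
titration points, 10-delay decays, 100-replicate Monte Carlo for the K_D
error calibration. These sizes match the emulated experiment; nothing is
scaled up beyond it.

## Known limitations

* Single-field τ_c only; no model-free analysis, R_ex detection, or
  diffusion-tensor anisotropy.
* The mass→τ_c rule is an empirical linear law for hydrated globular
  particles; elongated complexes or disordered tails bias it.
* ±2·SE intervals from few-point titrations under-cover (see above).
* The SPARKY reader handles assigned `<RES><NUM>N-H` backbone labels only;
  side-chain and unassigned-peak tracking are out of scope.
* Restraint neighbourhood is sequence-based, not surface-based.
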