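# nmrbind

Quantitative NMR analysis of protein–DNA binding by titration: weighted
chemical-shift-perturbation (CSP) mapping, per-residue dissociation-constant
fitting to the 1:1 fast-exchange binding isotherm, ¹⁵N relaxation
(R1/R2/hetNOE) analysis with rotational-correlation-time–based stoichiometry
inference, DNA-side shift flagging, and generation of ambiguous interaction
restraints for data-driven docking. The package was built around the study of
the human origin-recognition-complex subunit Orc6 and its DNA-binding domain
(Orc6-DBD, residues 95–207) titrated with short AT-rich duplexes, but every
component is generic over assigned amide peak lists.

It is aimed at solution-NMR practitioners who have assigned ¹H,¹⁵N-HSQC peak
lists from a titration and want the standard downstream numbers — binding
surface, K_D per residue, tumbling time, complex stoichiometry, docking
restraints — from one reproducible toolchain.

## The models

**CSP mapping.** For each backbone amide tracked between the first (free) and
last titration points, the weighted perturbation is

    Δδ = √( ΔδHN² + (ΔδN/5)² )            (default, "unscaled")
    Δδ = √( (ΔδHN² + (ΔδN/5)²) / 2 )      ("scaled" variant, = default/√2)

Residues are tiered against the mean and mean + 1 SD of the tracked Δδ
distribution (or pinned thresholds, e.g. the conventional 0.015/0.038 ppm).

**K_D fitting.** In fast exchange the observed shift change at total protein
P and total DNA D follows the exact quadratic 1:1 isotherm

    Δδ(D) = Δδmax · [ P + D + K_D − √((P+D+K_D)² − 4PD) ] / (2P)

where the bracket is the bound fraction of protein. `BindingIsothermModel`
minimizes the χ² between observed and predicted Δδ over (K_D, Δδmax) with
bounded, multi-start nonlinear least squares, returning standard errors from
the local curvature (seeded residual bootstrap optional).

**Relaxation and stoichiometry.** R1 and R2 come from mono-exponential fits
I(t) = I0·e^(−Rt) at CPMG / inversion-recovery delay schedules, with errors
propagated from duplicate time points. For rigid residues (hetNOE ≥ 0.65,
R2/R1 trimmed to median ± 1.5×IQR) the correlation time follows the
single-field estimate τ_c = √(6·R2/R1 − 7)/(4π·ν_N). The measured τ_c is
compared against the empirical expectation τ_c[ns] ≈ 0.6 × MW[kDa] for each
candidate stoichiometry (free protein, 1:1, 1:2 …) and the nearest wins.

**Restraints.** Active residues for docking are those with Δδ > 0.038 ppm
*and* relative solvent accessibility > 50 %; their sequence neighbours become
passive; flagged DNA bases (H1′ or H6/H8 Δδ > 0.025 ppm) become active on the
DNA side. Restraints are written as CNS-style `assign` statements.

## Worked example

Everything runs on a seeded synthetic study (no measured spectra needed):

```bash
nmrbind simulate --seed 1 --out study/
nmrbind run --study study/study.yaml --out out/
```

which prints (output of the code as run):

```
nmrbind 0.1.0 pipeline summary
titration points: 7 (P = 100 uM)
CSP variant: unscaled; mean = 0.0135 ppm, mean+SD = 0.0469 ppm
significant residues (> mean+SD): [158, 168, 169, 174, 177, 181, 198, 199, 200, 203]
K_D fits converged: 10/10
tau_c free = 8.88 ns, bound = 13.69 ns at 500 MHz
protein 12.8 kDa, duplex 10.4 kDa
stoichiometry call: 1:1
active protein residues: [158, 168, 169, 174, 177, 181, 198, 199, 200, 203]
passive protein residues: [156, 157, 159, 160, 166, 167, 170, 171, 172, 173, 175, 176, 178, 179, 180, 182, 183, 196, 197, 201, 202, 204, 205]
active DNA bases: 16
```

Reading: all ten residues the generator made bind DNA (and only those) clear
the mean+SD CSP threshold; every per-residue K_D fit converges
(`out/kd.csv` holds the estimates with standard errors and χ²); the
free-state tumbling time (~8.9 ns) matches a ~13 kDa monomer while the
DNA-bound value (~13.7 ns) matches the mass of a 1:1 protein–duplex complex,
so the stoichiometry call is 1:1; the significant, solvent-exposed residues
and the flagged DNA bases become the active sets in `out/air.tbl`.

The same analyses are available as library calls (`nmrbind.compute_profile`,
`nmrbind.BindingIsothermModel(...).fit()`, `nmrbind.estimate_tauc`, …) and as
per-stage subcommands (`csp`, `fit-kd`, `relax-fit`, `tauc`, `stoich`,
`restraints`, `molweight`).

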