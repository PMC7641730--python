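"""Seeded synthetic study generator.

Builds complete, fully deterministic synthetic datasets with the
statistical structure the analysis assumes, so every pipeline stage is
testable without measured spectra:

* fast-exchange titration shift trajectories: binding residues trace
  the 1:1 quadratic isotherm (observed shift = free shift +
  bound-fraction × Δδmax per nucleus), inert residues show noise only;
* mono-exponential R1/R2 relaxation decays at the standard CPMG and
  inversion-recovery delay schedules (duplicate time points included),
  with rates back-computed from a target rotational correlation time;
* hetNOE intensity pairs with a flexible C-terminal tail at a
  configurable NOE target;
* per-residue accessibility and DNA proton-shift tables, plus a
  ``truth.json`` recording every generating parameter.

The default :class:`StudyConfig` emulates a ~13 kDa DNA-binding domain
titrated with an AT-rich duplex: P = 100 μM, D/P from 0.1 to 6, ten
binding residues with K_D in the 11–57 μM range, τ_c 8.9 ns free /
13.7 ns bound, measured at 500 and 800 MHz.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .binding import IsothermParams, bound_fraction
from .csp import weighted_csp
from .exceptions import ConfigError
from .molweight import PAPER_DUPLEXES, DuplexSpec, duplex_mw, protein_mw
from .peaklist import (
    AmidePeak,
    IntensityTable,
    PeakList,
    TitrationSeries,
    _find_duplicate_pairs,
    write_titration_series,
)

__all__ = [
    "SYNTHETIC_DBD_SEQUENCE",
    "SYNTHETIC_DBD_START",
    "CPMG_DELAYS_S",
    "INVERSION_RECOVERY_DELAYS_S",
    "BindingResidue",
    "FlexibleTail",
    "StudyConfig",
    "RelaxationSim",
    "simulate_titration",
    "simulate_relaxation",
    "generate_fixture_study",
]

#: SYNTHETIC stand-in for the study's DNA-binding domain (residues 95-207).
#: This is NOT the real protein sequence: it is a generated 113-residue
#: sequence with a plausible helical-domain composition, lysines/arginines
#: placed at the binding-site positions the fixtures perturb, and an
#: average mass near 12.8 kDa. Use only for synthetic studies and tests.
SYNTHETIC_DBD_SEQUENCE = (
    "EISKHIAGEFLVRRSDNNDSTGRAENKNKLSLELGNELSAKTDNANDGSGSSEVIGIMQVEQV"
    "KYHQQVGMRGKKADKDRLLKEIRKADAFTQNAVLSNFMYKRKRKLIARWN"
)
SYNTHETIC_DBD_START = 95

#: CPMG relaxation delays with two redundant points (s)
CPMG_DELAYS_S = (0.010, 0.030, 0.050, 0.050, 0.070, 0.090, 0.110, 0.110, 0.130, 0.150)
#: inversion-recovery delays with two redundant points (s)
INVERSION_RECOVERY_DELAYS_S = (
    0.100, 0.300, 0.500, 0.500, 0.700, 0.900, 1.100, 1.100, 1.300, 1.500,
)


@dataclass(frozen=True)
class BindingResidue:
    """Ground truth for one binding residue."""

    residue_number: int
    K_D: float        # μM
    dmax_HN: float    # Δδmax of the amide proton, ppm (sign = direction)
    dmax_N: float     # Δδmax of the nitrogen, ppm

    @property
    def weighted_dmax(self) -> float:
        return weighted_csp(self.dmax_HN, self.dmax_N, "unscaled")


@dataclass(frozen=True)
class FlexibleTail:
    """Residue range simulated as disordered, with its hetNOE targets."""

    start: int
    end: int
    hetnoe_free: float = -0.5
    hetnoe_bound: float = 0.0
    tau_c_eff: float = 3.0  # ns, effective tumbling of the tail


def _default_binding_residues() -> tuple[BindingResidue, ...]:
    # ten binding residues; K_D spread over the tens-of-μM range with two
    # tighter sites, Δδmax per nucleus giving weighted Δδmax ~0.05-0.15 ppm
    return (
        BindingResidue(158, 54.3, 0.060, 0.30),
        BindingResidue(168, 45.0, -0.045, 0.40),
        BindingResidue(169, 47.1, 0.080, -0.35),
        BindingResidue(174, 36.4, 0.055, 0.50),
        BindingResidue(177, 50.0, 0.070, 0.25),
        BindingResidue(181, 42.0, -0.050, -0.45),
        BindingResidue(198, 40.0, 0.100, 0.60),
        BindingResidue(199, 38.0, 0.120, 0.40),
        BindingResidue(200, 11.0, 0.130, 0.55),
        BindingResidue(203, 11.3, 0.090, 0.70),
    )


@dataclass
class StudyConfig:
    """All generating parameters of one synthetic study.

    The seed fully determines every output. Concentrations are μM,
    shifts ppm, τ_c ns, fields MHz.
    """

    seed: int = 1
    sequence: str = SYNTHETIC_DBD_SEQUENCE
    residue_start: int = SYNTHETIC_DBD_START
    unassigned_residues: tuple[int, ...] = (135, 136, 137)
    binding_residues: tuple[BindingResidue, ...] = field(
        default_factory=_default_binding_residues
    )
    protein_conc: float = 100.0
    ligand_concs: tuple[float, ...] = (0.0, 10.0, 50.0, 100.0, 200.0, 400.0, 600.0)
    shift_noise_sd_H: float = 0.002
    shift_noise_sd_N: float = 0.010
    true_tau_c_free: float = 8.9
    true_tau_c_bound: float = 13.7
    field_mhz: tuple[float, ...] = (500.0, 800.0)
    r1_base: float = 1.5            # s^-1 at 500 MHz; documented scale constant
    intensity_noise_frac: float = 0.02
    hetnoe_rigid: float = 0.78
    flexible_tail: FlexibleTail | None = field(
        default_factory=lambda: FlexibleTail(190, 207)
    )
    duplex: tuple[str, str] = PAPER_DUPLEXES[17]
    dna_duplex_10bp: tuple[str, str] = PAPER_DUPLEXES[10]

    def __post_init__(self) -> None:
        if not self.ligand_concs:
            raise ConfigError("ligand_concs must not be empty")
        if self.shift_noise_sd_H < 0 or self.shift_noise_sd_N < 0:
            raise ConfigError("shift noise SDs must be nonnegative")
        if self.intensity_noise_frac < 0:
            raise ConfigError("intensity noise fraction must be nonnegative")
        nres = len(self.sequence)
        last = self.residue_start + nres - 1
        for br in self.binding_residues:
            if not (self.residue_start <= br.residue_number <= last):
                raise ConfigError(
                    f"binding residue {br.residue_number} outside "
                    f"{self.residue_start}..{last}"
                )

    @property
    def residue_numbers(self) -> list[int]:
        """Assigned residues (author numbering), prolines/unassigned absent."""
        last = self.residue_start + len(self.sequence) - 1
        skip = set(self.unassigned_residues)
        skip |= {
            self.residue_start + i
            for i, aa in enumerate(self.sequence)
            if aa == "P"  # prolines have no amide proton
        }
        return [r for r in range(self.residue_start, last + 1) if r not in skip]

    def residue_type(self, residue_number: int) -> str:
        return self.sequence[residue_number - self.residue_start]

    def truth_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["binding_residues"] = [dataclasses.asdict(b) for b in self.binding_residues]
        if self.flexible_tail is not None:
            d["flexible_tail"] = dataclasses.asdict(self.flexible_tail)
        return d


# ---------------------------------------------------------------------------
# titration simulation
# ---------------------------------------------------------------------------

def simulate_titration(cfg: StudyConfig) -> TitrationSeries:
    """Simulate a fast-exchange titration series.

    Free-form shifts are drawn uniformly from the amide windows
    (¹H 7.0–9.5, ¹⁵N 105–130 ppm); binding residues move along the
    isotherm's bound fraction toward their Δδmax, inert residues only
    jitter by the shift noise. Identical seeds give identical series.
    """
    rng = np.random.default_rng(cfg.seed)
    residues = cfg.residue_numbers
    free_H = rng.uniform(7.0, 9.5, size=len(residues))
    free_N = rng.uniform(105.0, 130.0, size=len(residues))
    truth = {b.residue_number: b for b in cfg.binding_residues}

    point_lists = []
    for D in cfg.ligand_concs:
        peaks = []
        for i, resid in enumerate(residues):
            br = truth.get(resid)
            if br is not None and D > 0:
                fb = bound_fraction(cfg.protein_conc, D, br.K_D)
                dH, dN = fb * br.dmax_HN, fb * br.dmax_N
            else:
                dH = dN = 0.0
            noise_H = rng.normal(0.0, cfg.shift_noise_sd_H) if cfg.shift_noise_sd_H else 0.0
            noise_N = rng.normal(0.0, cfg.shift_noise_sd_N) if cfg.shift_noise_sd_N else 0.0
            peaks.append(
                AmidePeak(
                    residue_number=resid,
                    residue_type=cfg.residue_type(resid),
                    delta_H=free_H[i] + dH + noise_H,
                    delta_N=free_N[i] + dN + noise_N,
                )
            )
        point_lists.append(PeakList(label=f"D={D:g}uM", peaks=peaks))
    return TitrationSeries(
        protein_conc=cfg.protein_conc,
        ligand_concs=list(cfg.ligand_concs),
        point_peaklists=point_lists,
    )


# ---------------------------------------------------------------------------
# relaxation simulation
# ---------------------------------------------------------------------------

def _ratio_from_tauc(tau_c_ns: float, nu_N_MHz: float) -> float:
    """Invert τ_c = √(6·R2/R1 − 7)/(4π·ν_N) for the R2/R1 ratio."""
    x = 4.0 * np.pi * nu_N_MHz * 1e6 * tau_c_ns * 1e-9
    return (x * x + 7.0) / 6.0


@dataclass
class RelaxationSim:
    """One simulated relaxation experiment (one field, one state)."""

    field_mhz: float
    state: str
    r1_tables: list[IntensityTable]
    r2_tables: list[IntensityTable]
    hetnoe: pd.DataFrame  # columns: residue, I_sat, I_unsat
    true_R1: dict[int, float]
    true_R2: dict[int, float]


def simulate_relaxation(
    cfg: StudyConfig,
    state: Literal["free", "bound"],
    field_mhz: float | None = None,
) -> RelaxationSim:
    """Simulate R1/R2 decay tables and hetNOE intensities for one state.

    Core residues get R1 = ``r1_base`` (small per-residue spread) and
    R2 = R1 × ratio(τ_c, field), with the ratio back-computed from the
    state's true τ_c, so :func:`nmrbind.relaxation.estimate_tauc`
    inverts the simulation. Flexible-tail residues tumble with the
    tail's shorter effective τ_c and get the tail hetNOE target. Decays
    are sampled at the standard CPMG / inversion-recovery schedules with
    multiplicative Gaussian noise.
    """
    if state not in ("free", "bound"):
        raise ConfigError(f"unknown state: {state!r}")
    field = float(field_mhz if field_mhz is not None else cfg.field_mhz[0])
    nu_N = 0.10136919 * field
    tau_c = cfg.true_tau_c_free if state == "free" else cfg.true_tau_c_bound
    core_ratio = _ratio_from_tauc(tau_c, nu_N)

    # derive a sub-seed so free/bound/field draws are independent streams
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, int(field), 0 if state == "free" else 1])
    )
    tail = cfg.flexible_tail
    r1_tables, r2_tables = [], []
    noe_rows = []
    true_R1, true_R2 = {}, {}
    for resid in cfg.residue_numbers:
        in_tail = tail is not None and tail.start <= resid <= tail.end and state == "free"
        in_tail_bound = (
            tail is not None and tail.start <= resid <= tail.end and state == "bound"
        )
        if in_tail:
            ratio = _ratio_from_tauc(tail.tau_c_eff, nu_N)
            noe_target = tail.hetnoe_free
        elif in_tail_bound:
            # tail becomes more ordered on binding but stays sub-core
            ratio = _ratio_from_tauc(0.6 * tau_c, nu_N)
            noe_target = tail.hetnoe_bound
        else:
            ratio = core_ratio
            noe_target = cfg.hetnoe_rigid
        r1 = cfg.r1_base * (500.0 / field) ** 0.5 * rng.uniform(0.95, 1.05)
        r2 = r1 * ratio
        true_R1[resid], true_R2[resid] = r1, r2
        i0 = rng.uniform(80.0, 120.0)

        for delays, rate, bucket in (
            (INVERSION_RECOVERY_DELAYS_S, r1, r1_tables),
            (CPMG_DELAYS_S, r2, r2_tables),
        ):
            t = np.array(delays)
            ideal = i0 * np.exp(-rate * t)
            noisy = ideal * (
                1.0 + rng.normal(0.0, cfg.intensity_noise_frac, size=t.size)
                if cfg.intensity_noise_frac
                else 1.0
            )
            bucket.append(
                IntensityTable(
                    residue_number=resid,
                    delays=t,
                    intensities=noisy,
                    duplicate_pairs=_find_duplicate_pairs(t),
                )
            )
        i_unsat = i0 * (
            1.0 + (rng.normal(0.0, cfg.intensity_noise_frac) if cfg.intensity_noise_frac else 0.0)
        )
        i_sat = i0 * noe_target * (
            1.0 + (rng.normal(0.0, cfg.intensity_noise_frac) if cfg.intensity_noise_frac else 0.0)
        )
        noe_rows.append({"residue": resid, "I_sat": i_sat, "I_unsat": i_unsat})

    return RelaxationSim(
        field_mhz=field,
        state=state,
        r1_tables=r1_tables,
        r2_tables=r2_tables,
        hetnoe=pd.DataFrame(noe_rows),
        true_R1=true_R1,
        true_R2=true_R2,
    )


# ---------------------------------------------------------------------------
# accessibility, DNA shifts, full fixture study
# ---------------------------------------------------------------------------

def _simulate_accessibility(cfg: StudyConfig) -> pd.DataFrame:
    """Synthetic relative solvent accessibility, percent.

    Binding residues (surface lysines/arginines in the emulated study)
    get high exposure; other residues are drawn over the full range.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    binding = {b.residue_number for b in cfg.binding_residues}
    last = cfg.residue_start + len(cfg.sequence) - 1
    rows = []
    for resid in range(cfg.residue_start, last + 1):
        if resid in binding:
            rsa = rng.uniform(55.0, 90.0)
        else:
            rsa = rng.uniform(2.0, 80.0)
        rows.append({"residue": resid, "rsa_percent": round(float(rsa), 1)})
    return pd.DataFrame(rows)


def _simulate_dna_shifts(cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Free and bound H1'/H6-H8 shift tables for the 10-bp duplex.

    Bases are numbered across both strands (1..10 top, 11..20 bottom);
    all bases except the two terminal steps of each strand end move by
    more than the flagging threshold, emulating a duplex engaged along
    its full AT tract.
    """
    s1, s2 = cfg.dna_duplex_10bp
    bases = [f"{b}{i + 1}" for i, b in enumerate(s1)]
    bases += [f"{b}{i + 11}" for i, b in enumerate(s2)]
    unaffected = {9, 10, 11, 12}  # G9/T10 and A11/C12: ends away from the tract
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    free_rows, bound_rows = [], []
    for base in bases:
        num = int(base[1:])
        h1p = rng.uniform(5.3, 6.3)
        h68 = rng.uniform(7.1, 8.3)
        free_rows.append({"base": base, "H1p_ppm": h1p, "H68_ppm": h68})
        if num in unaffected:
            d1, d2 = rng.uniform(-0.005, 0.005, size=2)
        else:
            d1 = rng.uniform(0.03, 0.12) * rng.choice([-1.0, 1.0])
            d2 = rng.uniform(0.0, 0.06) * rng.choice([-1.0, 1.0])
        bound_rows.append({"base": base, "H1p_ppm": h1p + d1, "H68_ppm": h68 + d2})
    return pd.DataFrame(free_rows), pd.DataFrame(bound_rows)


def _write_intensity_tables(tables: list[IntensityTable], path: Path) -> None:
    rows = []
    for t in tables:
        for d, i in zip(t.delays, t.intensities):
            rows.append({"residue": t.residue_number, "delay_s": d, "intensity": i})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def generate_fixture_study(out_dir: str | Path, cfg: StudyConfig | None = None) -> Path:
    """Write a complete synthetic study tree; returns the study.yaml path.

    Layout::

        out_dir/
          study.yaml                 pipeline configuration
          truth.json                 every generating parameter
          protein_synthetic.fasta    the synthetic stand-in sequence
          titration/series.yaml + point_XX.tsv
          relaxation/{free,bound}_{r1,r2,noe}_<field>.tsv
          accessibility.tsv
          dna_shifts_{free,bound}.tsv

    Identical config (including seed) reproduces the tree byte for byte.
    """
    import yaml

    cfg = cfg or StudyConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    series = simulate_titration(cfg)
    write_titration_series(series, out / "titration")

    field = cfg.field_mhz[0]
    (out / "relaxation").mkdir(exist_ok=True)
    relax_entries: dict[str, dict[str, str]] = {}
    for state in ("free", "bound"):
        sim = simulate_relaxation(cfg, state, field)
        paths = {}
        for kind, obj in (("r1", sim.r1_tables), ("r2", sim.r2_tables)):
            fname = f"relaxation/{state}_{kind}_{field:g}.tsv"
            _write_intensity_tables(obj, out / fname)
            paths[kind] = fname
        fname = f"relaxation/{state}_noe_{field:g}.tsv"
        sim.hetnoe.to_csv(out / fname, sep="\t", index=False, float_format="%.6f")
        paths["noe"] = fname
        relax_entries[state] = paths

    _simulate_accessibility(cfg).to_csv(out / "accessibility.tsv", sep="\t", index=False)
    dna_free, dna_bound = _simulate_dna_shifts(cfg)
    dna_free.to_csv(out / "dna_shifts_free.tsv", sep="\t", index=False, float_format="%.4f")
    dna_bound.to_csv(out / "dna_shifts_bound.tsv", sep="\t", index=False, float_format="%.4f")

    fasta = out / "protein_synthetic.fasta"
    fasta.write_text(
        f">synthetic_dbd residues {cfg.residue_start}-"
        f"{cfg.residue_start + len(cfg.sequence) - 1} SYNTHETIC stand-in, "
        "not a real protein\n" + cfg.sequence + "\n"
    )

    study = {
        "seed": cfg.seed,
        "titration": "titration/series.yaml",
        "relaxation": {
            "field_mhz": float(field),
            "free": relax_entries["free"],
            "bound": relax_entries["bound"],
        },
        "accessibility": "accessibility.tsv",
        "dna_shifts": {"free": "dna_shifts_free.tsv", "bound": "dna_shifts_bound.tsv"},
        "protein_fasta": "protein_synthetic.fasta",
        "duplex": {"strand1": cfg.duplex[0], "strand2": cfg.duplex[1]},
        "csp": {"variant": "unscaled", "threshold_mode": "data"},
        "fit": {"min_tier": "above_mean_plus_sd"},
        "restraints": {"csp_cut": 0.038, "acc_cut": 50.0, "neighbor_window": 2},
        "tauc": {"min_noe": 0.65},
    }
    study_path = out / "study.yaml"
    study_path.write_text(yaml.safe_dump(study, sort_keys=False))
    (out / "truth.json").write_text(json.dumps(cfg.truth_dict(), indent=2) + "\n")
    return study_path
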