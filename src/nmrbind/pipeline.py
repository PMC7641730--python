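"""End-to-end analysis pipeline.

Runs, in order: CSP mapping between titration endpoints, per-residue
K_D fitting, R1/R2/hetNOE fitting with τ_c estimation for the free and
DNA-bound states, molecular-weight bookkeeping and the stoichiometry
call, DNA-side shift flagging, and restraint generation. Every stage
writes its table under the output directory; a MANIFEST records what
was written (and, on failure, where the pipeline stopped), and both a
human-readable and a JSON summary are emitted. Given identical inputs
and seed the output tree is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .binding import fit_kd_profile
from .csp import compute_profile, flag_dna_bases
from .exceptions import ConfigError, DataError, NmrbindError
from .molweight import DuplexSpec, duplex_mw, protein_mw, read_fasta_range
from .peaklist import read_intensity_table, read_titration_series
from .relaxation import FieldSpec, estimate_tauc, rates_from_tables
from .restraints import read_accessibility, select_active_passive, write_air_tbl

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (paths resolved against base_dir)."""

    base_dir: Path
    titration: Path
    relaxation: dict[str, Any]
    accessibility: Path
    dna_shifts: dict[str, Path]
    protein_fasta: Path | None
    protein_range: tuple[int, int] | None
    duplex: tuple[str, str]
    csp: dict[str, Any] = field(default_factory=dict)
    fit: dict[str, Any] = field(default_factory=dict)
    restraints: dict[str, Any] = field(default_factory=dict)
    tauc: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [self.titration, self.accessibility, *self.dna_shifts.values()]
            if not Path(p).exists()
        ]
        for state in ("free", "bound"):
            for key, rel in self.relaxation.get(state, {}).items():
                p = self.base_dir / rel
                if not p.exists():
                    missing.append(str(p))
        if self.protein_fasta is not None and not self.protein_fasta.exists():
            missing.append(str(self.protein_fasta))
        if missing:
            raise ConfigError("missing input files: " + ", ".join(missing))


def load_config(study_yaml: str | Path, seed: int | None = None) -> PipelineConfig:
    """Load and validate a study.yaml pipeline configuration."""
    study_yaml = Path(study_yaml)
    if not study_yaml.exists():
        raise ConfigError(f"config not found: {study_yaml}")
    doc = yaml.safe_load(study_yaml.read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{study_yaml}: not a mapping")
    base = study_yaml.parent
    try:
        cfg = PipelineConfig(
            base_dir=base,
            titration=base / doc["titration"],
            relaxation=doc["relaxation"],
            accessibility=base / doc["accessibility"],
            dna_shifts={k: base / v for k, v in doc["dna_shifts"].items()},
            protein_fasta=(base / doc["protein_fasta"]) if doc.get("protein_fasta") else None,
            protein_range=tuple(doc["protein_range"]) if doc.get("protein_range") else None,
            duplex=(doc["duplex"]["strand1"], doc["duplex"]["strand2"]),
            csp=doc.get("csp", {}),
            fit=doc.get("fit", {}),
            restraints=doc.get("restraints", {}),
            tauc=doc.get("tauc", {}),
            seed=int(seed if seed is not None else doc.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"{study_yaml}: missing key {exc.args[0]!r}") from None
    cfg.validate()
    return cfg


@dataclass
class PipelineReport:
    """What the pipeline computed and wrote."""

    out_dir: Path
    outputs: list[str]
    stoichiometry: str | None
    tau_c_free: float | None
    tau_c_bound: float | None
    n_active: int
    n_kd_fits: int
    summary_text: str


def _write_manifest(out: Path, entries: list[str], failed_stage: str | None = None) -> None:
    lines = [f"nmrbind {__version__}"]
    lines += [f"output: {e}" for e in entries]
    if failed_stage:
        lines.append(f"FAILED at stage: {failed_stage}")
    (out / "MANIFEST").write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> PipelineReport:
    """Run the full analysis; raises NmrbindError subclasses on failure.

    Partial outputs are kept; the MANIFEST names the failing stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage = "setup"
    try:
        # ------------------------------------------------ CSP mapping
        stage = "csp"
        series = read_titration_series(cfg.titration)
        profile = compute_profile(
            series,
            variant=cfg.csp.get("variant", "unscaled"),
            threshold_mode=cfg.csp.get("threshold_mode", "data"),
            pinned_mean=cfg.csp.get("pinned_mean_ppm"),
            pinned_threshold=cfg.csp.get("pinned_threshold_ppm"),
        )
        df = profile.to_frame()
        df.columns = ["residue", "d_HN_ppm", "d_N_ppm", "delta_ppm", "tier"]
        (out / "csp.csv").write_text(df.to_csv(index=False, float_format="%.5f"))
        outputs.append("csp.csv")

        # ------------------------------------------------ K_D fitting
        stage = "fit_kd"
        fits = fit_kd_profile(
            series, profile, min_tier=cfg.fit.get("min_tier", "above_mean_plus_sd")
        )
        (out / "kd.csv").write_text(
            fits.to_frame().to_csv(index=False, float_format="%.5g")
        )
        outputs.append("kd.csv")

        # ------------------------------------------------ relaxation + tau_c
        stage = "relaxation"
        field_mhz = float(cfg.relaxation.get("field_mhz", 500.0))
        spec = FieldSpec(field_mhz)
        taucs: dict[str, float] = {}
        for state in ("free", "bound"):
            paths = cfg.relaxation[state]
            r1 = read_intensity_table(cfg.base_dir / paths["r1"])
            r2 = read_intensity_table(cfg.base_dir / paths["r2"])
            noe = pd.read_csv(cfg.base_dir / paths["noe"], sep=None, engine="python")
            rates = rates_from_tables(r1, r2, noe)
            rates_df = pd.DataFrame(
                {
                    "residue": [r.residue_number for r in rates],
                    "R1_s-1": [r.R1 for r in rates],
                    "se_R1_s-1": [r.se_R1 for r in rates],
                    "R2_s-1": [r.R2 for r in rates],
                    "se_R2_s-1": [r.se_R2 for r in rates],
                    "hetNOE": [r.hetnoe for r in rates],
                }
            )
            fname = f"rates_{state}.csv"
            (out / fname).write_text(rates_df.to_csv(index=False, float_format="%.4f"))
            outputs.append(fname)
            est = estimate_tauc(
                rates, spec, min_noe=cfg.tauc.get("min_noe", 0.65)
            )
            taucs[state] = est.tau_c
            (out / f"tauc_{state}.txt").write_text(est.summary() + "\n")
            outputs.append(f"tauc_{state}.txt")

        # ------------------------------------------------ MW + stoichiometry
        stage = "stoichiometry"
        from .relaxation import infer_stoichiometry

        duplex = DuplexSpec(*cfg.duplex)
        dna_kda = duplex_mw(duplex) / 1000.0
        if cfg.protein_fasta is not None:
            rng = cfg.protein_range or (None, None)
            seq = read_fasta_range(cfg.protein_fasta, *rng)
            prot_kda = protein_mw(seq) / 1000.0
        else:
            raise ConfigError("protein_fasta is required for the stoichiometry stage")
        call = infer_stoichiometry(
            taucs["bound"],
            [
                ("free", prot_kda),
                ("1:1", prot_kda + dna_kda),
                ("1:2", prot_kda + 2 * dna_kda),
            ],
        )
        (out / "stoichiometry.txt").write_text(call.summary() + "\n")
        outputs.append("stoichiometry.txt")

        # ------------------------------------------------ DNA flagging
        stage = "dna_flags"
        dna_free = pd.read_csv(cfg.dna_shifts["free"], sep=None, engine="python")
        dna_bound = pd.read_csv(cfg.dna_shifts["bound"], sep=None, engine="python")
        flags = flag_dna_bases(dna_free, dna_bound)
        flags_df = pd.DataFrame(
            {
                "base": [f.base_id for f in flags],
                "d_H1p_ppm": [f.d_H1p for f in flags],
                "d_H68_ppm": [f.d_H68 for f in flags],
                "flagged": [f.flagged for f in flags],
            }
        )
        (out / "dna_flags.csv").write_text(
            flags_df.to_csv(index=False, float_format="%.4f")
        )
        outputs.append("dna_flags.csv")

        # ------------------------------------------------ restraints
        stage = "restraints"
        access = read_accessibility(cfg.accessibility)
        rs = select_active_passive(
            profile,
            access,
            csp_cut=float(cfg.restraints.get("csp_cut", 0.038)),
            acc_cut=float(cfg.restraints.get("acc_cut", 50.0)),
            neighbor_window=int(cfg.restraints.get("neighbor_window", 2)),
            dna_active=[f.base_id for f in flags if f.flagged],
        )
        write_air_tbl(rs, out / "air.tbl")
        (out / "active_passive.tsv").write_text(
            rs.to_frame().to_csv(sep="\t", index=False)
        )
        outputs += ["air.tbl", "active_passive.tsv"]

        # ------------------------------------------------ summaries
        stage = "summary"
        n_conv = len(fits.converged)
        text = "\n".join(
            [
                f"nmrbind {__version__} pipeline summary",
                f"titration points: {series.n_points} (P = {series.protein_conc:g} uM)",
                f"CSP variant: {profile.variant}; mean = {profile.mean_delta:.4f} ppm, "
                f"mean+SD = {profile.threshold_active:.4f} ppm",
                f"significant residues (> mean+SD): "
                f"{profile.residues_at_least('above_mean_plus_sd')}",
                f"K_D fits converged: {n_conv}/{len(fits)}",
                f"tau_c free = {taucs['free']:.2f} ns, bound = {taucs['bound']:.2f} ns "
                f"at {field_mhz:g} MHz",
                f"protein {prot_kda:.1f} kDa, duplex {dna_kda:.1f} kDa",
                f"stoichiometry call: {call.best}",
                f"active protein residues: {rs.active_protein}",
                f"passive protein residues: {rs.passive_protein}",
                f"active DNA bases: {len(rs.active_dna)}",
            ]
        )
        (out / "summary.txt").write_text(text + "\n")
        summary_json = {
            "version": __version__,
            "seed": cfg.seed,
            "csp": {
                "variant": profile.variant,
                "mean_ppm": profile.mean_delta,
                "threshold_ppm": profile.threshold_active,
                "n_significant": len(profile.residues_at_least("above_mean_plus_sd")),
            },
            "kd": {"n_fits": len(fits), "n_converged": n_conv},
            "tau_c_ns": taucs,
            "mw_kda": {"protein": prot_kda, "duplex": dna_kda},
            "stoichiometry": call.best,
            "restraints": {
                "active_protein": rs.active_protein,
                "passive_protein": rs.passive_protein,
                "n_active_dna": len(rs.active_dna),
            },
        }
        (out / "summary.json").write_text(json.dumps(summary_json, indent=2) + "\n")
        outputs += ["summary.txt", "summary.json"]
        _write_manifest(out, outputs)
    except NmrbindError:
        _write_manifest(out, outputs, failed_stage=stage)
        raise
    except Exception as exc:  # surface unexpected errors with the stage name
        _write_manifest(out, outputs, failed_stage=stage)
        raise DataError(f"stage {stage!r} failed: {exc}") from exc

    return PipelineReport(
        out_dir=out,
        outputs=outputs,
        stoichiometry=call.best,
        tau_c_free=taucs["free"],
        tau_c_bound=taucs["bound"],
        n_active=len(rs.active_protein),
        n_kd_fits=n_conv,
        summary_text=text,
    )
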