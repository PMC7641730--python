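"""Ambiguous interaction restraints (AIRs) for data-driven docking.

Converts a CSP profile plus a per-residue relative-solvent-accessibility
table into the active/passive residue selections that drive HADDOCK-style
docking, and writes them as CNS ``assign`` statements:

* active protein residues: weighted Δδ strictly above the CSP cut
  (default 0.038 ppm) AND relative accessibility strictly above the
  accessibility cut (default 50 %);
* passive protein residues: sequence neighbors of active residues
  (within ``neighbor_window`` positions) that are not active themselves;
* active DNA bases are supplied explicitly (typically from the DNA
  shift flagging); no passive DNA is selected.

One ambiguous restraint is written per active residue of each molecule,
targeting the partner's active+passive selection, with the conventional
2.0 Å effective distance and (−2.0/+0.0) bounds. Output ordering is
deterministic, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .csp import CSPProfile
from .exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "RestraintSet",
    "read_accessibility",
    "select_active_passive",
    "write_air_tbl",
    "dna_base_label",
]

DEFAULT_CSP_CUT = 0.038   # ppm
DEFAULT_ACC_CUT = 50.0    # percent
DEFAULT_NEIGHBOR_WINDOW = 2

_BASE_NAME = {"A": "ADE", "C": "CYT", "G": "GUA", "T": "THY"}
_BASE_ID = re.compile(r"^([A-Za-z]+)(\d+)$")


def read_accessibility(path: str | Path) -> dict[int, float]:
    """Read a relative-accessibility table (columns residue, rsa_percent)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"accessibility table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"residue", "rsa_percent"}
    if not required.issubset(df.columns):
        raise DataError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    table = {int(r): float(v) for r, v in zip(df["residue"], df["rsa_percent"])}
    bad = {r: v for r, v in table.items() if not (0.0 <= v <= 100.0)}
    if bad:
        raise DataError(f"{path}: accessibility outside [0, 100]: {bad}")
    return table


@dataclass
class RestraintSet:
    """Active/passive protein residues and active DNA bases."""

    active_protein: list[int]
    passive_protein: list[int]
    active_dna: list[str]
    neighbor_window: int

    def __post_init__(self) -> None:
        self.active_protein = sorted(set(self.active_protein))
        self.passive_protein = sorted(set(self.passive_protein))
        overlap = set(self.active_protein) & set(self.passive_protein)
        if overlap:
            raise DataError(f"residues both active and passive: {sorted(overlap)}")

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("protein", r, "active") for r in self.active_protein]
            + [("protein", r, "passive") for r in self.passive_protein]
            + [("dna", b, "active") for b in self.active_dna]
        )
        return pd.DataFrame(rows, columns=["molecule", "residue", "role"])


def select_active_passive(
    profile: CSPProfile,
    access: Mapping[int, float],
    csp_cut: float = DEFAULT_CSP_CUT,
    acc_cut: float = DEFAULT_ACC_CUT,
    neighbor_window: int = DEFAULT_NEIGHBOR_WINDOW,
    dna_active: Sequence[str] = (),
) -> RestraintSet:
    """Select active and passive residues for docking restraints.

    Active: Δδ > ``csp_cut`` (ppm) AND accessibility > ``acc_cut`` (%),
    both strict, evaluated over tracked residues present in ``access``.
    Passive: residues within ``neighbor_window`` sequence positions of
    an active residue, known to the profile or the accessibility table,
    and not active themselves. DNA active bases are passed through
    (no passive DNA).
    """
    if neighbor_window < 0:
        raise ValueError("neighbor_window must be nonnegative")
    active = [
        r.residue_number
        for r in profile.tracked
        if r.delta > csp_cut and access.get(r.residue_number, -1.0) > acc_cut
    ]
    known = {r.residue_number for r in profile.records} | set(access)
    passive = {
        n
        for a in active
        for n in range(a - neighbor_window, a + neighbor_window + 1)
        if n in known and n not in active
    }
    if not active:
        logger.warning(
            "no active residues at csp_cut=%.3f ppm, acc_cut=%.0f%%",
            csp_cut,
            acc_cut,
        )
    return RestraintSet(
        active_protein=active,
        passive_protein=sorted(passive),
        active_dna=list(dna_active),
        neighbor_window=neighbor_window,
    )


def dna_base_label(base_id: str) -> tuple[str, int]:
    """Split a base id like ``T13`` or ``THY13`` into (CNS name, number)."""
    m = _BASE_ID.match(base_id.strip())
    if m is None:
        raise DataError(f"unparseable DNA base id: {base_id!r}")
    name, num = m.group(1).upper(), int(m.group(2))
    if len(name) == 1:
        if name not in _BASE_NAME:
            raise DataError(f"unknown base letter in {base_id!r}")
        name = _BASE_NAME[name]
    return name, num


def _selection(segid: str, resids: Sequence[int]) -> str:
    inner = " or ".join(f"resid {r}" for r in resids)
    return f"(segid {segid} and ({inner}))"


def write_air_tbl(
    rs: RestraintSet,
    path: str | Path,
    protein_segid: str = "A",
    dna_segid: str = "B",
    distance: float = 2.0,
    lower: float = 2.0,
    upper: float = 0.0,
) -> None:
    """Write CNS-style ambiguous interaction restraints.

    One ``assign`` per active protein residue against all active DNA
    bases, and one per active DNA base against the protein's
    active+passive selection. Deterministic ordering; an empty restraint
    set produces a header-only file with a warning.
    """
    path = Path(path)
    lines = [
        "! ambiguous interaction restraints",
        f"! active protein residues: {rs.active_protein or 'none'}",
        f"! passive protein residues: {rs.passive_protein or 'none'}",
        f"! active DNA bases: {rs.active_dna or 'none'} (no passive DNA)",
        "",
    ]
    dna_nums = [dna_base_label(b)[1] for b in rs.active_dna]
    protein_all = sorted(set(rs.active_protein) | set(rs.passive_protein))

    if not (rs.active_protein and dna_nums) and not (dna_nums and protein_all):
        logger.warning("empty restraint set; writing header-only %s", path)

    if dna_nums:
        for resid in rs.active_protein:
            lines.append(
                f"assign (segid {protein_segid} and resid {resid} and name HN) "
                f"{_selection(dna_segid, dna_nums)} "
                f"{distance:.1f} {lower:.1f} {upper:.1f}"
            )
    if protein_all:
        for base in rs.active_dna:
            _, num = dna_base_label(base)
            lines.append(
                f"assign (segid {dna_segid} and resid {num}) "
                f"{_selection(protein_segid, protein_all)} "
                f"{distance:.1f} {lower:.1f} {upper:.1f}"
            )
    path.write_text("\n".join(lines) + "\n")
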