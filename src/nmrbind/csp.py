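"""Weighted chemical-shift-perturbation (CSP) mapping.

A ligand titrated into a ¹⁵N-labelled protein moves backbone-amide
cross peaks; the per-residue weighted combination of the ¹H and ¹⁵N
shift changes between the first (free) and last titration points maps
the binding surface. Two conventional weightings are supported:

* ``unscaled`` (default):  Δδ = √(ΔδHN² + (ΔδN/5)²)
* ``scaled``:              Δδ = √((ΔδHN² + (ΔδN/5)²) / 2)

They differ by exactly √2. The ¹⁵N difference is down-weighted by 5,
the conventional ratio of the amide ¹H and ¹⁵N shift dispersions.

Residues are classified against thresholds computed from the tracked
residues themselves (mean, mean + 1 SD) or against pinned values
supplied by the caller. The same machinery flags DNA bases whose H1′
or H6/H8 proton shifts move on protein binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .exceptions import DataError
from .peaklist import TitrationSeries

__all__ = [
    "Variant",
    "Tier",
    "CSPRecord",
    "CSPProfile",
    "DNAShiftRecord",
    "weighted_csp",
    "compute_profile",
    "flag_dna_bases",
    "DEFAULT_DNA_THRESHOLD",
]

Variant = Literal["unscaled", "scaled"]
Tier = Literal["below_mean", "above_mean", "above_mean_plus_sd", "untracked"]

#: DNA flagging threshold, ppm (applied to H1' and H6/H8 differences)
DEFAULT_DNA_THRESHOLD = 0.025

_TIER_ORDER = {"untracked": -1, "below_mean": 0, "above_mean": 1, "above_mean_plus_sd": 2}


def tier_at_least(tier: str, min_tier: str) -> bool:
    """True if ``tier`` ranks at or above ``min_tier`` (untracked never does)."""
    if tier == "untracked":
        return False
    return _TIER_ORDER[tier] >= _TIER_ORDER[min_tier]


def weighted_csp(d_HN, d_N, variant: Variant = "unscaled"):
    """Weighted CSP from the amide ¹H and ¹⁵N shift differences (ppm).

    Accepts scalars or arrays; always nonnegative; the ``unscaled``
    value equals √2 × the ``scaled`` value for identical inputs.
    """
    d_HN = np.asarray(d_HN, dtype=float)
    d_N = np.asarray(d_N, dtype=float)
    if not (np.all(np.isfinite(d_HN)) and np.all(np.isfinite(d_N))):
        raise ValueError("CSP inputs must be finite")
    ss = d_HN**2 + (d_N / 5.0) ** 2
    if variant == "unscaled":
        out = np.sqrt(ss)
    elif variant == "scaled":
        out = np.sqrt(ss / 2.0)
    else:
        raise ValueError(f"unknown CSP variant: {variant!r}")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CSPRecord:
    """Per-residue shift differences (final − initial) and classification."""

    residue_number: int
    d_HN: float
    d_N: float
    delta: float
    tier: Tier


@dataclass
class CSPProfile:
    """A per-residue CSP profile with its classification thresholds.

    ``mean_delta`` and ``sd_delta`` are computed over tracked residues
    only (sample SD, ddof=1); ``threshold_active`` defaults to
    mean + 1 SD and is the cut used for the top tier.
    """

    records: list[CSPRecord]
    variant: Variant
    mean_delta: float
    sd_delta: float
    threshold_active: float

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def tracked(self) -> list[CSPRecord]:
        return [r for r in self.records if r.tier != "untracked"]

    def get(self, residue_number: int) -> CSPRecord | None:
        for r in self.records:
            if r.residue_number == residue_number:
                return r
        return None

    def residues_at_least(self, min_tier: Tier) -> list[int]:
        return [
            r.residue_number
            for r in self.records
            if tier_at_least(r.tier, min_tier)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": [r.residue_number for r in self.records],
                "d_HN_ppm": [r.d_HN for r in self.records],
                "d_N_ppm": [r.d_N for r in self.records],
                "delta_ppm": [r.delta for r in self.records],
                "tier": [r.tier for r in self.records],
            }
        )

    def plot(self, ax=None):
        """Bar plot of Δδ versus residue with the two threshold lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        tracked = self.tracked
        ax.bar(
            [r.residue_number for r in tracked],
            [r.delta for r in tracked],
            width=0.8,
            color="0.4",
        )
        ax.axhline(self.mean_delta, color="tab:blue", lw=1, label="mean")
        ax.axhline(
            self.threshold_active, color="tab:red", lw=1, label="mean + 1 SD"
        )
        ax.set_xlabel("residue")
        ax.set_ylabel("weighted Δδ (ppm)")
        ax.legend(frameon=False, fontsize="small")
        return ax


def _classify(delta: float, mean: float, threshold: float) -> Tier:
    if delta > threshold:
        return "above_mean_plus_sd"
    if delta > mean:
        return "above_mean"
    return "below_mean"


def compute_profile(
    series: TitrationSeries,
    variant: Variant = "unscaled",
    endpoints: str = "first_last",
    threshold_mode: str = "data",
    pinned_mean: float | None = None,
    pinned_threshold: float | None = None,
) -> CSPProfile:
    """Compute the weighted CSP profile between titration endpoints.

    Differences are final − initial per residue. Residues present at
    only one endpoint become ``untracked`` and are excluded from the
    mean/SD statistics. ``threshold_mode="pinned"`` substitutes caller
    thresholds (ppm) for the data-derived mean and mean + SD.
    """
    if series.n_points < 2:
        raise DataError("need at least 2 titration points for a CSP profile")
    if endpoints != "first_last":
        raise ValueError(f"unsupported endpoint rule: {endpoints!r}")
    if threshold_mode not in ("data", "pinned"):
        raise ValueError(f"unknown threshold_mode: {threshold_mode!r}")

    free, final = series.free, series.final
    common = free.residues & final.residues
    if not common:
        raise DataError("no residues in common between the titration endpoints")

    rows: list[tuple[int, float, float, float]] = []
    untracked: list[int] = []
    for resid in sorted(free.residues | final.residues):
        if resid not in common:
            untracked.append(resid)
            continue
        p0, p1 = free.get(resid), final.get(resid)
        d_HN = p1.delta_H - p0.delta_H
        d_N = p1.delta_N - p0.delta_N
        rows.append((resid, d_HN, d_N, weighted_csp(d_HN, d_N, variant)))

    deltas = np.array([r[3] for r in rows])
    mean = float(np.mean(deltas))
    sd = float(np.std(deltas, ddof=1)) if len(deltas) > 1 else 0.0
    if threshold_mode == "pinned":
        if pinned_mean is None or pinned_threshold is None:
            raise ValueError("pinned threshold_mode needs pinned_mean and pinned_threshold")
        mean_used, threshold = float(pinned_mean), float(pinned_threshold)
    else:
        mean_used, threshold = mean, mean + sd

    records = [
        CSPRecord(resid, d_HN, d_N, delta, _classify(delta, mean_used, threshold))
        for resid, d_HN, d_N, delta in rows
    ]
    records += [
        CSPRecord(resid, float("nan"), float("nan"), float("nan"), "untracked")
        for resid in untracked
    ]
    records.sort(key=lambda r: r.residue_number)
    return CSPProfile(
        records=records,
        variant=variant,
        mean_delta=mean_used,
        sd_delta=sd,
        threshold_active=threshold,
    )


# ---------------------------------------------------------------------------
# DNA-side shift flagging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DNAShiftRecord:
    """Shift differences of one DNA base's H1′ and H6/H8 protons (ppm)."""

    base_id: str
    d_H1p: float
    d_H68: float
    flagged: bool


def _as_dna_mapping(obj) -> dict[str, tuple[float, float]]:
    """Coerce DNA shift input to {base_id: (H1', H6/H8)}.

    Accepts a mapping base_id → (h1p, h68) or a DataFrame with columns
    base, H1p_ppm, H68_ppm.
    """
    if isinstance(obj, pd.DataFrame):
        required = {"base", "H1p_ppm", "H68_ppm"}
        if not required.issubset(obj.columns):
            raise DataError(
                f"DNA shift table needs columns {sorted(required)}, "
                f"found {list(obj.columns)}"
            )
        return {
            str(row["base"]): (float(row["H1p_ppm"]), float(row["H68_ppm"]))
            for _, row in obj.iterrows()
        }
    if isinstance(obj, Mapping):
        return {str(k): (float(v[0]), float(v[1])) for k, v in obj.items()}
    raise DataError("unsupported DNA shift input")


def flag_dna_bases(
    free,
    bound,
    dna_threshold: float = DEFAULT_DNA_THRESHOLD,
) -> list[DNAShiftRecord]:
    """Flag DNA bases whose H1′ or H6/H8 proton moves on binding.

    ``free`` and ``bound`` give the assigned H1′ and H6/H8 shifts per
    base (mapping or DataFrame, see :func:`_as_dna_mapping`); a base is
    flagged iff either proton class moves by more than ``dna_threshold``
    ppm in absolute value (disjunction of the two proton classes).
    """
    free_m, bound_m = _as_dna_mapping(free), _as_dna_mapping(bound)
    if set(free_m) != set(bound_m):
        missing = set(free_m) ^ set(bound_m)
        raise DataError(f"free/bound base sets differ: {sorted(missing)}")
    records = []
    for base in free_m:
        d_H1p = bound_m[base][0] - free_m[base][0]
        d_H68 = bound_m[base][1] - free_m[base][1]
        records.append(
            DNAShiftRecord(
                base_id=base,
                d_H1p=d_H1p,
                d_H68=d_H68,
                flagged=max(abs(d_H1p), abs(d_H68)) > dna_threshold,
            )
        )
    records.sort(key=lambda r: (int("".join(filter(str.isdigit, r.base_id)) or 0)))
    return records
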