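"""Peak-list and relaxation-table I/O.

Readers and writers for the small tabular formats the analysis touches:
SPARKY-style assigned amide peak lists, plain TSV/CSV peak tables, a
titration-series manifest (YAML), and relaxation peak-intensity tables
versus delay time.

Conventions (applied everywhere in the package):

* residue numbering is taken verbatim from the assignment labels
  (author numbering, 1-based); no renumbering is ever applied;
* unassigned or missing residues are represented by absence, never by
  sentinel values;
* concentrations are μM, chemical shifts ppm, delays seconds.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "AmidePeak",
    "PeakList",
    "TitrationSeries",
    "IntensityTable",
    "read_peaklist",
    "write_peaklist",
    "read_intensity_table",
    "read_titration_series",
    "write_titration_series",
]

#: plausible backbone-amide shift windows used when validation is enabled
H_RANGE = (5.0, 13.0)
N_RANGE = (100.0, 140.0)

# SPARKY assignment token for a backbone amide, e.g. "K169N-H" or "A170N-HN"
_SPARKY_ASSIGNMENT = re.compile(r"^([A-Za-z])(\d+)N-HN?$")


@dataclass(frozen=True)
class AmidePeak:
    """One assigned backbone-amide cross peak.

    Parameters
    ----------
    residue_number : int
        Author numbering from the assignment label (1-based).
    residue_type : str
        One-letter amino-acid code, or ``"X"`` when unknown.
    delta_H : float
        Amide-proton chemical shift, ppm.
    delta_N : float
        Amide-nitrogen chemical shift, ppm.
    """

    residue_number: int
    residue_type: str
    delta_H: float
    delta_N: float

    def validate(self) -> None:
        if not (H_RANGE[0] <= self.delta_H <= H_RANGE[1]):
            raise DataError(
                f"residue {self.residue_number}: 1H shift {self.delta_H} ppm "
                f"outside the amide window {H_RANGE}"
            )
        if not (N_RANGE[0] <= self.delta_N <= N_RANGE[1]):
            raise DataError(
                f"residue {self.residue_number}: 15N shift {self.delta_N} ppm "
                f"outside the amide window {N_RANGE}"
            )


@dataclass
class PeakList:
    """A labelled collection of assigned amide peaks.

    Residues may legitimately be absent (prolines, unassigned residues);
    absence is the representation of missing data.
    """

    label: str
    peaks: list[AmidePeak] = field(default_factory=list)
    source_path: str | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p in self.peaks:
            if p.residue_number in seen:
                raise DataError(
                    f"duplicate residue {p.residue_number} in peak list "
                    f"{self.label!r}"
                )
            seen.add(p.residue_number)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def residues(self) -> set[int]:
        return {p.residue_number for p in self.peaks}

    def get(self, residue_number: int) -> AmidePeak | None:
        for p in self.peaks:
            if p.residue_number == residue_number:
                return p
        return None

    def validate(self) -> None:
        for p in self.peaks:
            p.validate()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": [p.residue_number for p in self.peaks],
                "residue_type": [p.residue_type for p in self.peaks],
                "dH_ppm": [p.delta_H for p in self.peaks],
                "dN_ppm": [p.delta_N for p in self.peaks],
            }
        )


@dataclass
class TitrationSeries:
    """Concentrations and per-point peak lists for one titration.

    ``ligand_concs`` is the ordered list of total ligand (DNA)
    concentrations in μM; the first entry must be 0 (the free form) and
    the sequence must be nondecreasing. ``protein_conc`` is the total
    protein concentration P in μM, assumed constant over the titration.
    """

    protein_conc: float
    ligand_concs: list[float]
    point_peaklists: list[PeakList]

    def __post_init__(self) -> None:
        if self.protein_conc <= 0:
            raise DataError("protein_conc must be positive (μM)")
        if not self.ligand_concs:
            raise DataError("titration has no points")
        if len(self.ligand_concs) != len(self.point_peaklists):
            raise DataError(
                f"{len(self.ligand_concs)} concentrations but "
                f"{len(self.point_peaklists)} peak lists"
            )
        if self.ligand_concs[0] != 0:
            raise DataError("first titration point must be the free form (D = 0)")
        if any(b < a for a, b in zip(self.ligand_concs, self.ligand_concs[1:])):
            raise DataError("ligand concentrations must be nondecreasing")

    @property
    def n_points(self) -> int:
        return len(self.ligand_concs)

    @property
    def free(self) -> PeakList:
        return self.point_peaklists[0]

    @property
    def final(self) -> PeakList:
        return self.point_peaklists[-1]


@dataclass
class IntensityTable:
    """Peak intensities of one residue versus relaxation delay.

    ``duplicate_pairs`` holds index pairs of repeated delay values; the
    scatter between each pair is the error estimate used by the decay
    fit.
    """

    residue_number: int
    delays: np.ndarray
    intensities: np.ndarray
    duplicate_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.shape != self.intensities.shape:
            raise DataError("delays and intensities differ in length")
        if np.any(self.delays < 0):
            raise DataError(
                f"residue {self.residue_number}: negative relaxation delay"
            )
        for i, j in self.duplicate_pairs:
            if self.delays[i] != self.delays[j]:
                raise DataError(
                    f"residue {self.residue_number}: duplicate pair ({i}, {j}) "
                    "references unequal delays"
                )


def _find_duplicate_pairs(delays: np.ndarray) -> list[tuple[int, int]]:
    """Pair up indices that share a delay value (consecutive occurrences)."""
    pairs: list[tuple[int, int]] = []
    by_value: dict[float, list[int]] = {}
    for i, d in enumerate(delays):
        by_value.setdefault(float(d), []).append(i)
    for _, idx in sorted(by_value.items()):
        for k in range(0, len(idx) - 1, 2):
            pairs.append((idx[k], idx[k + 1]))
    return pairs


# ---------------------------------------------------------------------------
# peak-list readers / writers
# ---------------------------------------------------------------------------

def _parse_sparky_line(line: str, w1_is_N: bool) -> AmidePeak | None:
    fields = line.split()
    if len(fields) < 3:
        return None
    m = _SPARKY_ASSIGNMENT.match(fields[0])
    if m is None:
        return None
    try:
        w1, w2 = float(fields[1]), float(fields[2])
    except ValueError:
        return None
    d_N, d_H = (w1, w2) if w1_is_N else (w2, w1)
    return AmidePeak(
        residue_number=int(m.group(2)),
        residue_type=m.group(1).upper(),
        delta_H=d_H,
        delta_N=d_N,
    )


def read_peaklist(
    path: str | Path,
    dialect: str = "sparky",
    *,
    label: str | None = None,
    w1_is_N: bool = True,
    validate: bool = False,
) -> PeakList:
    """Read an assigned amide peak list.

    Parameters
    ----------
    path : str or Path
        Input file.
    dialect : {"sparky", "tsv"}
        ``sparky``: whitespace-separated lines ``<RES><NUM>N-H  w1  w2``
        where, by default, w1 is the ¹⁵N shift and w2 the ¹H shift
        (``w1_is_N=False`` swaps them, since exported lists differ).
        ``tsv``: a delimited table with header columns
        ``residue, dH_ppm, dN_ppm`` and optional ``residue_type``.
    validate : bool
        If true, check every shift against the plausible amide windows.

    Unparseable data rows are skipped with a logged warning and counted;
    a file yielding no peaks at all is an error. A residue appearing
    twice with identical shifts is deduplicated with a warning; with
    conflicting shifts it is an error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"peak list not found: {path}")
    if dialect not in ("sparky", "tsv"):
        raise ValueError(f"unsupported peak-list dialect: {dialect!r}")

    peaks: dict[int, AmidePeak] = {}
    n_rows = n_skipped = 0

    if dialect == "sparky":
        for raw in path.read_text().splitlines():
            line = raw.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            n_rows += 1
            peak = _parse_sparky_line(line, w1_is_N)
            if peak is None:
                n_skipped += 1
                logger.warning("%s: skipping unparseable row: %r", path, raw)
                continue
            _add_peak(peaks, peak, path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"residue", "dH_ppm", "dN_ppm"}
        if not required.issubset(df.columns):
            raise DataError(
                f"{path}: expected columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        for _, row in df.iterrows():
            n_rows += 1
            try:
                peak = AmidePeak(
                    residue_number=int(row["residue"]),
                    residue_type=str(row.get("residue_type", "X"))[:1].upper(),
                    delta_H=float(row["dH_ppm"]),
                    delta_N=float(row["dN_ppm"]),
                )
            except (TypeError, ValueError):
                n_skipped += 1
                logger.warning("%s: skipping unparseable row %s", path, dict(row))
                continue
            _add_peak(peaks, peak, path)

    if n_skipped:
        logger.warning("%s: skipped %d of %d data rows", path, n_skipped, n_rows)
    if not peaks:
        raise DataError(f"{path}: no parseable peaks")

    pl = PeakList(
        label=label if label is not None else path.stem,
        peaks=sorted(peaks.values(), key=lambda p: p.residue_number),
        source_path=str(path),
    )
    if validate:
        pl.validate()
    return pl


def _add_peak(peaks: dict[int, AmidePeak], peak: AmidePeak, path: Path) -> None:
    prev = peaks.get(peak.residue_number)
    if prev is None:
        peaks[peak.residue_number] = peak
        return
    if np.isclose(prev.delta_H, peak.delta_H, atol=1e-6) and np.isclose(
        prev.delta_N, peak.delta_N, atol=1e-6
    ):
        logger.warning(
            "%s: residue %d listed twice with identical shifts; deduplicated",
            path,
            peak.residue_number,
        )
        warnings.warn(
            f"residue {peak.residue_number} duplicated with identical shifts",
            stacklevel=3,
        )
        return
    raise DataError(
        f"{path}: residue {peak.residue_number} appears twice with "
        f"conflicting shifts"
    )


def write_peaklist(pl: PeakList, path: str | Path, dialect: str = "sparky") -> None:
    """Write a peak list re-readable by :func:`read_peaklist`.

    Shifts are written to 4 decimal places (the precision peak lists are
    conventionally exported at); the read∘write round trip is the
    identity at that precision.
    """
    if len(pl) == 0:
        raise DataError("refusing to write an empty peak list")
    path = Path(path)
    if dialect == "sparky":
        lines = ["      Assignment         w1         w2\n"]
        for p in sorted(pl.peaks, key=lambda q: q.residue_number):
            lines.append(
                f"{p.residue_type}{p.residue_number}N-H".rjust(16)
                + f"{p.delta_N:11.4f}{p.delta_H:11.4f}\n"
            )
        path.write_text("".join(lines))
    elif dialect == "tsv":
        df = pl.to_frame()
        df["dH_ppm"] = df["dH_ppm"].map(lambda v: f"{v:.4f}")
        df["dN_ppm"] = df["dN_ppm"].map(lambda v: f"{v:.4f}")
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unsupported peak-list dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# relaxation intensity tables
# ---------------------------------------------------------------------------

def read_intensity_table(path: str | Path) -> list[IntensityTable]:
    """Read per-residue relaxation intensity tables.

    Expects a delimited table with header columns ``residue``,
    ``delay_s`` (or ``delay_ms``, converted) and ``intensity``. Repeated
    delay values within a residue are detected automatically and
    recorded as ``duplicate_pairs``.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"intensity table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    if "delay_ms" in df.columns and "delay_s" not in df.columns:
        df = df.rename(columns={"delay_ms": "delay_s"})
        df["delay_s"] = df["delay_s"] / 1000.0
    required = {"residue", "delay_s", "intensity"}
    if not required.issubset(df.columns):
        raise DataError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    if not np.issubdtype(np.asarray(df["intensity"]).dtype, np.number):
        raise DataError(f"{path}: non-numeric intensities")
    if (df["delay_s"] < 0).any():
        raise DataError(f"{path}: negative delays")

    tables = []
    for resid, sub in df.groupby("residue", sort=True):
        delays = sub["delay_s"].to_numpy(dtype=float)
        tables.append(
            IntensityTable(
                residue_number=int(resid),
                delays=delays,
                intensities=sub["intensity"].to_numpy(dtype=float),
                duplicate_pairs=_find_duplicate_pairs(delays),
            )
        )
    return tables


# ---------------------------------------------------------------------------
# titration-series manifest
# ---------------------------------------------------------------------------

def read_titration_series(manifest: str | Path, dialect: str = "tsv") -> TitrationSeries:
    """Load a titration series from a YAML manifest.

    The manifest records the protein concentration and, per point, the
    total ligand concentration and the peak-list file (relative paths
    are resolved against the manifest's directory)::

        protein_conc_uM: 100.0
        dialect: tsv
        points:
          - {ligand_conc_uM: 0.0, peaklist: point_00.tsv}
          - {ligand_conc_uM: 50.0, peaklist: point_01.tsv}
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise DataError(f"titration manifest not found: {manifest}")
    doc = yaml.safe_load(manifest.read_text())
    if not isinstance(doc, dict) or "points" not in doc:
        raise DataError(f"{manifest}: not a titration manifest")
    dialect = doc.get("dialect", dialect)
    concs, lists = [], []
    for point in doc["points"]:
        concs.append(float(point["ligand_conc_uM"]))
        pl_path = manifest.parent / point["peaklist"]
        lists.append(
            read_peaklist(pl_path, dialect=dialect, label=f"D={concs[-1]:g}uM")
        )
    return TitrationSeries(
        protein_conc=float(doc["protein_conc_uM"]),
        ligand_concs=concs,
        point_peaklists=lists,
    )


def write_titration_series(
    series: TitrationSeries,
    out_dir: str | Path,
    dialect: str = "tsv",
    manifest_name: str = "series.yaml",
) -> Path:
    """Write a titration series as per-point peak lists plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "list" if dialect == "sparky" else "tsv"
    points = []
    for i, (conc, pl) in enumerate(zip(series.ligand_concs, series.point_peaklists)):
        fname = f"point_{i:02d}.{ext}"
        write_peaklist(pl, out_dir / fname, dialect=dialect)
        points.append({"ligand_conc_uM": float(conc), "peaklist": fname})
    manifest = {
        "protein_conc_uM": float(series.protein_conc),
        "dialect": dialect,
        "points": points,
    }
    out_path = out_dir / manifest_name
    out_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out_path
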