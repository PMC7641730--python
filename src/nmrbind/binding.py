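"""Per-residue K_D fitting to the 1:1 fast-exchange binding isotherm.

In the fast-exchange regime the observed shift change of a residue at
total protein concentration P and total ligand concentration D is the
bound fraction of protein times the saturation shift change:

    Δδ(D) = Δδmax · [ P + D + K_D − √((P + D + K_D)² − 4·P·D) ] / (2·P)

with K_D the dissociation constant of the 1:1 complex (μM here) and
Δδmax the shift change at 100 % saturation (ppm). The bracketed factor
is the bound fraction of protein and lies in [0, min(1, D/P)].

Fitting minimizes the χ² sum of squared differences between observed
and predicted Δδ over (K_D, Δδmax), via bounded nonlinear least squares
with multi-start over K_D decades — the χ² surface of this isotherm has
the shallow valley typical of titrations that do not reach saturation,
and a single start can stall far from the optimum.

Exposed statsmodels-style: :class:`BindingIsothermModel` wraps one
residue's titration curve and ``.fit()`` returns a
:class:`BindingFitResult`; :func:`fit_kd_profile` maps the model over
every significantly perturbed residue of a CSP profile and returns a
:class:`BindingFitResults` collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd

from .csp import CSPProfile, Tier, tier_at_least, weighted_csp
from .exceptions import DataError
from .peaklist import TitrationSeries

__all__ = [
    "IsothermParams",
    "BindingFitResult",
    "BindingFitResults",
    "BindingIsothermModel",
    "bound_fraction",
    "predicted_delta",
    "fit_kd",
    "fit_kd_profile",
    "KD_BOUNDS",
    "DMAX_BOUNDS",
    "KD_STARTS",
]

#: optimizer bounds, μM and ppm
KD_BOUNDS = (1e-3, 1e5)
DMAX_BOUNDS = (1e-4, 5.0)
#: multi-start grid over K_D decades, μM
KD_STARTS = (1.0, 10.0, 100.0, 1000.0)


@dataclass(frozen=True)
class IsothermParams:
    """Parameters of the 1:1 isotherm: K_D (μM) and Δδmax (ppm)."""

    K_D: float
    delta_max: float

    def __post_init__(self) -> None:
        if not (self.K_D > 0):
            raise ValueError(f"K_D must be positive, got {self.K_D}")
        if not (self.delta_max > 0):
            raise ValueError(f"delta_max must be positive, got {self.delta_max}")


def bound_fraction(P, D, K_D):
    """Bound fraction of protein for a 1:1 complex at total P, D, K_D (μM).

    Uses the exact quadratic solution; the discriminant
    (P+D+K_D)² − 4·P·D is strictly positive for K_D > 0.
    """
    P = np.asarray(P, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(P <= 0):
        raise ValueError("protein concentration P must be positive")
    if np.any(D < 0):
        raise ValueError("ligand concentration D must be nonnegative")
    if K_D <= 0:
        raise ValueError("K_D must be positive")
    s = P + D + K_D
    disc = s * s - 4.0 * P * D
    assert np.all(disc > 0), "isotherm discriminant must stay positive for K_D > 0"
    fb = (s - np.sqrt(disc)) / (2.0 * P)
    return float(fb) if fb.ndim == 0 else fb


def predicted_delta(P, D, params: IsothermParams):
    """Predicted Δδ (ppm) at total concentrations P, D (μM)."""
    return params.delta_max * bound_fraction(P, D, params.K_D)


@dataclass
class BindingFitResult:
    """Result of fitting one residue's titration curve.

    ``chi2`` is the minimized sum of squared residuals (ppm²);
    standard errors come from the local curvature of the least-squares
    solution (or, optionally, a seeded residual bootstrap). Estimates
    are meaningful only when ``converged`` is true.
    """

    residue_number: int | None
    params: IsothermParams | None
    se_KD: float
    se_delta_max: float
    chi2: float
    n_points: int
    converged: bool
    message: str = ""

    @property
    def K_D(self) -> float:
        return self.params.K_D if self.params else float("nan")

    @property
    def delta_max(self) -> float:
        return self.params.delta_max if self.params else float("nan")

    def summary(self) -> str:
        rid = self.residue_number if self.residue_number is not None else "-"
        if not self.converged:
            return f"residue {rid}: fit did not converge ({self.message})"
        return (
            f"residue {rid}: K_D = {self.K_D:.1f} ± {self.se_KD:.1f} uM, "
            f"ddmax = {self.delta_max:.4f} ± {self.se_delta_max:.4f} ppm, "
            f"chi2 = {self.chi2:.3g} (n = {self.n_points})"
        )


class BindingIsothermModel:
    """1:1 binding-isotherm model for one residue's titration curve.

    Parameters
    ----------
    P : float
        Total protein concentration, μM (constant over the titration).
    D : array-like
        Total ligand concentrations, μM.
    delta_obs : array-like
        Observed Δδ at each D, ppm (magnitudes; sign is ignored).
    residue_number : int, optional
        Carried through to the result for bookkeeping.
    """

    def __init__(self, P: float, D, delta_obs, residue_number: int | None = None):
        self.P = float(P)
        self.D = np.asarray(D, dtype=float)
        self.delta_obs = np.abs(np.asarray(delta_obs, dtype=float))
        self.residue_number = residue_number
        if self.P <= 0:
            raise DataError("protein concentration must be positive")
        if self.D.shape != self.delta_obs.shape:
            raise DataError("D and delta_obs differ in length")
        if np.count_nonzero(self.D > 0) < 3:
            raise DataError(
                "need at least 3 titration points with nonzero ligand "
                f"concentration, got {np.count_nonzero(self.D > 0)}"
            )

    # -- residuals ---------------------------------------------------------
    def _residual(self, pars: lmfit.Parameters) -> np.ndarray:
        prm = IsothermParams(pars["kd"].value, pars["dmax"].value)
        return predicted_delta(self.P, self.D, prm) - self.delta_obs

    def fit(
        self,
        kd_starts: Sequence[float] = KD_STARTS,
        bootstrap: int | None = None,
        seed: int | None = None,
    ) -> BindingFitResult:
        """Fit (K_D, Δδmax) by χ² minimization with multi-start.

        An all-zero (or numerically negligible) Δδ series leaves K_D
        unidentifiable and returns ``converged=False`` rather than an
        arbitrary estimate. ``bootstrap=n`` replaces curvature standard
        errors by a seeded residual bootstrap with n refits.
        """
        if float(np.max(self.delta_obs, initial=0.0)) < 1e-6:
            return BindingFitResult(
                residue_number=self.residue_number,
                params=None,
                se_KD=float("nan"),
                se_delta_max=float("nan"),
                chi2=0.0,
                n_points=int(self.D.size),
                converged=False,
                message="all observed shift changes are zero; K_D unidentifiable",
            )

        best = None
        dmax_start = float(
            np.clip(np.max(self.delta_obs) * 1.2, DMAX_BOUNDS[0] * 2, DMAX_BOUNDS[1] / 2)
        )
        for kd0 in kd_starts:
            pars = lmfit.Parameters()
            pars.add("kd", value=kd0, min=KD_BOUNDS[0], max=KD_BOUNDS[1])
            pars.add("dmax", value=dmax_start, min=DMAX_BOUNDS[0], max=DMAX_BOUNDS[1])
            try:
                res = lmfit.minimize(self._residual, pars, method="leastsq")
            except Exception:  # singular steps on pathological series
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None or not best.success:
            return BindingFitResult(
                residue_number=self.residue_number,
                params=None,
                se_KD=float("nan"),
                se_delta_max=float("nan"),
                chi2=float("nan"),
                n_points=int(self.D.size),
                converged=False,
                message="optimizer failed from every start",
            )

        params = IsothermParams(best.params["kd"].value, best.params["dmax"].value)
        se_kd = best.params["kd"].stderr
        se_dmax = best.params["dmax"].stderr
        if bootstrap:
            se_kd, se_dmax = self._bootstrap_se(params, bootstrap, seed)
        return BindingFitResult(
            residue_number=self.residue_number,
            params=params,
            se_KD=float(se_kd) if se_kd is not None else float("nan"),
            se_delta_max=float(se_dmax) if se_dmax is not None else float("nan"),
            chi2=float(best.chisqr),
            n_points=int(self.D.size),
            converged=True,
        )

    def _bootstrap_se(
        self, params: IsothermParams, n_boot: int, seed: int | None
    ) -> tuple[float, float]:
        """Residual-resampling bootstrap standard errors (seeded)."""
        rng = np.random.default_rng(seed)
        fitted = predicted_delta(self.P, self.D, params)
        resid = self.delta_obs - fitted
        kds, dmaxs = [], []
        for _ in range(n_boot):
            fake = fitted + rng.choice(resid, size=resid.size, replace=True)
            try:
                r = BindingIsothermModel(self.P, self.D, np.clip(fake, 0, None)).fit()
            except DataError:
                continue
            if r.converged:
                kds.append(r.K_D)
                dmaxs.append(r.delta_max)
        if len(kds) < 2:
            return float("nan"), float("nan")
        return float(np.std(kds, ddof=1)), float(np.std(dmaxs, ddof=1))

    def plot(self, result: BindingFitResult | None = None, ax=None):
        """Observed Δδ versus D with the fitted isotherm overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.D, self.delta_obs, "o", color="0.3", label="observed")
        if result is not None and result.converged:
            grid = np.linspace(0, float(self.D.max()) * 1.05, 200)
            ax.plot(
                grid,
                predicted_delta(self.P, grid, result.params),
                "-",
                color="tab:red",
                label=f"fit: K_D = {result.K_D:.1f} uM",
            )
        ax.set_xlabel("total DNA (uM)")
        ax.set_ylabel("Δδ (ppm)")
        ax.legend(frameon=False)
        return ax


def fit_kd(
    points: Iterable[tuple[float, float, float]],
    residue_number: int | None = None,
    **fit_kwargs,
) -> BindingFitResult:
    """Fit one residue from (P, D, observed Δδ) triples.

    Convenience wrapper over :class:`BindingIsothermModel`; all P values
    must agree (the titration holds protein constant).
    """
    pts = list(points)
    if not pts:
        raise DataError("empty titration series")
    P_vals = {p for p, _, _ in pts}
    if len(P_vals) != 1:
        raise DataError("protein concentration must be constant across points")
    model = BindingIsothermModel(
        P=pts[0][0],
        D=[d for _, d, _ in pts],
        delta_obs=[dd for _, _, dd in pts],
        residue_number=residue_number,
    )
    return model.fit(**fit_kwargs)


class BindingFitResults:
    """Collection of per-residue isotherm fits with tabular export."""

    def __init__(self, results: list[BindingFitResult]):
        self.results = results

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    @property
    def converged(self) -> list[BindingFitResult]:
        return [r for r in self.results if r.converged]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": [r.residue_number for r in self.results],
                "KD_uM": [r.K_D for r in self.results],
                "se_KD_uM": [r.se_KD for r in self.results],
                "ddmax_ppm": [r.delta_max for r in self.results],
                "se_ddmax_ppm": [r.se_delta_max for r in self.results],
                "chi2_ppm2": [r.chi2 for r in self.results],
                "n_points": [r.n_points for r in self.results],
                "converged": [r.converged for r in self.results],
            }
        )

    def summary(self) -> str:
        lines = [r.summary() for r in self.results]
        conv = self.converged
        if conv:
            kds = np.array([r.K_D for r in conv])
            lines.append(
                f"{len(conv)}/{len(self.results)} residues converged; "
                f"K_D range {kds.min():.1f}-{kds.max():.1f} uM, "
                f"median {np.median(kds):.1f} uM"
            )
        return "\n".join(lines)


def fit_kd_global(
    series: TitrationSeries,
    profile: CSPProfile,
    min_tier: Tier = "above_mean_plus_sd",
    kd_starts: Sequence[float] = KD_STARTS,
) -> BindingFitResults:
    """Global fit: one shared K_D, one Δδmax per selected residue.

    Useful when all perturbed residues report the same binding event and
    the per-residue curves are individually under-determined. Returns
    one result per residue, all carrying the shared K_D (and its shared
    standard error) with the residue's own Δδmax.
    """
    free = series.free
    data: list[tuple[int, np.ndarray, np.ndarray]] = []
    for resid in profile.residues_at_least(min_tier):
        p0 = free.get(resid)
        if p0 is None:
            continue
        D_vals, deltas = [], []
        for D, pl in zip(series.ligand_concs, series.point_peaklists):
            pk = pl.get(resid)
            if pk is None:
                continue
            D_vals.append(D)
            deltas.append(
                weighted_csp(
                    pk.delta_H - p0.delta_H, pk.delta_N - p0.delta_N, profile.variant
                )
            )
        if np.count_nonzero(np.asarray(D_vals) > 0) >= 3:
            data.append((resid, np.asarray(D_vals), np.asarray(deltas)))
    if not data:
        return BindingFitResults([])

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        kd = pars["kd"].value
        out = []
        for resid, D, obs in data:
            prm = IsothermParams(kd, pars[f"dmax_{resid}"].value)
            out.append(predicted_delta(series.protein_conc, D, prm) - obs)
        return np.concatenate(out)

    best = None
    for kd0 in kd_starts:
        pars = lmfit.Parameters()
        pars.add("kd", value=kd0, min=KD_BOUNDS[0], max=KD_BOUNDS[1])
        for resid, _, obs in data:
            pars.add(
                f"dmax_{resid}",
                value=float(np.clip(obs.max() * 1.2, DMAX_BOUNDS[0] * 2, DMAX_BOUNDS[1] / 2)),
                min=DMAX_BOUNDS[0],
                max=DMAX_BOUNDS[1],
            )
        try:
            res = lmfit.minimize(residual, pars, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        return BindingFitResults(
            [
                BindingFitResult(resid, None, float("nan"), float("nan"),
                                 float("nan"), int(D.size), False,
                                 "global fit failed from every start")
                for resid, D, _ in data
            ]
        )
    kd = best.params["kd"].value
    se_kd = best.params["kd"].stderr
    results = []
    for resid, D, obs in data:
        dmax = best.params[f"dmax_{resid}"]
        prm = IsothermParams(kd, dmax.value)
        resid_chi2 = float(
            np.sum((predicted_delta(series.protein_conc, D, prm) - obs) ** 2)
        )
        results.append(
            BindingFitResult(
                residue_number=resid,
                params=prm,
                se_KD=float(se_kd) if se_kd is not None else float("nan"),
                se_delta_max=float(dmax.stderr) if dmax.stderr is not None else float("nan"),
                chi2=resid_chi2,
                n_points=int(D.size),
                converged=True,
                message="shared-K_D global fit",
            )
        )
    return BindingFitResults(results)


def fit_kd_profile(
    series: TitrationSeries,
    profile: CSPProfile,
    min_tier: Tier = "above_mean_plus_sd",
    **fit_kwargs,
) -> BindingFitResults:
    """Fit K_D for every residue at or above ``min_tier`` in the profile.

    Per-residue Δδ at each titration point is computed against the
    free-form endpoint with the profile's CSP variant. Points where a
    residue is missing from the peak list are omitted from that
    residue's fit (its ``n_points`` shrinks accordingly). Per-residue
    fit failures are collected in the results, not raised.
    """
    out: list[BindingFitResult] = []
    free = series.free
    for resid in profile.residues_at_least(min_tier):
        p0 = free.get(resid)
        if p0 is None:
            continue
        D_vals, deltas = [], []
        for D, pl in zip(series.ligand_concs, series.point_peaklists):
            pk = pl.get(resid)
            if pk is None:
                continue  # untracked at this point; omit from the fit
            D_vals.append(D)
            deltas.append(
                weighted_csp(
                    pk.delta_H - p0.delta_H, pk.delta_N - p0.delta_N, profile.variant
                )
            )
        try:
            model = BindingIsothermModel(
                series.protein_conc, D_vals, deltas, residue_number=resid
            )
            out.append(model.fit(**fit_kwargs))
        except DataError as exc:
            out.append(
                BindingFitResult(
                    residue_number=resid,
                    params=None,
                    se_KD=float("nan"),
                    se_delta_max=float("nan"),
                    chi2=float("nan"),
                    n_points=len(D_vals),
                    converged=False,
                    message=str(exc),
                )
            )
    return BindingFitResults(out)
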