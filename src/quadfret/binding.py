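"""Equilibrium binding: one-site K_d regression and cross-construct tables.

The bound fraction of a titration is modeled by the one-site specific
binding equation ``Y = Bmax * X / (Kd + X)`` with Bmax fixed to 1 by default;
``Kd`` (nM) is estimated by nonlinear least squares with an asymptotic
standard error. Relative binding intensities normalize quantified band
intensities to a reference construct, and the comparative table pairs each
construct's NP-P direct-transition density with its relative binding,
reporting a rank-correlation coefficient without encoding any causal claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import kendalltau

from .errors import FitError, ParameterError

__all__ = [
    "BindingCurve",
    "BindingResults",
    "OneSiteBindingModel",
    "fit_kd",
    "aggregate_kd",
    "relative_binding",
    "dynamics_binding_table",
]


@dataclass
class BindingCurve:
    """A titration (concentrations in nM vs bound fraction) and its fit."""

    construct: str
    concentrations: np.ndarray
    bound_fraction: np.ndarray
    fitted_kd: float | None = None
    fitted_bmax: float | None = None
    fit_sd: float | None = None  # asymptotic standard error of Kd, nM
    residuals: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.bound_fraction = np.asarray(self.bound_fraction, dtype=float)
        if self.concentrations.shape != self.bound_fraction.shape:
            raise ParameterError("concentrations and bound fractions must align")
        if np.any(self.concentrations < 0):
            raise ParameterError("concentrations must be non-negative")
        if self.fitted_kd is not None and self.fitted_kd <= 0:
            raise ParameterError("fitted_kd must be positive")


class OneSiteBindingModel:
    """One-site specific binding model fitted to a titration.

    Parameters are concentrations (nM unless ``unit="uM"``) and the
    quantified bound fractions; ``fit(fix_bmax=True)`` constrains Bmax to 1.
    Initialization is deterministic: Kd starts at the concentration whose
    response is nearest half of the maximum observed bound fraction.
    """

    def __init__(self, concentrations, bound_fraction, construct: str = "", unit: str = "nM"):
        scale = {"nM": 1.0, "uM": 1000.0}.get(unit)
        if scale is None:
            raise ParameterError("unit must be 'nM' or 'uM'")
        self.x = np.asarray(concentrations, dtype=float) * scale
        self.y = np.asarray(bound_fraction, dtype=float)
        self.construct = construct
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ParameterError("concentrations and bound fractions must align")
        if np.unique(self.x).size < 3:
            raise ParameterError("need >= 3 distinct concentrations to fit")
        if np.any(self.x < 0):
            raise ParameterError("concentrations must be non-negative")
        if not np.all(np.isfinite(self.y)):
            raise ParameterError("bound fractions must be finite")

    def _kd_init(self) -> float:
        ymax = self.y.max()
        if ymax <= 0:
            raise FitError("all-zero bound fractions: Kd is not identifiable")
        pos = self.x > 0
        idx = np.argmin(np.abs(self.y[pos] - 0.5 * ymax))
        return float(self.x[pos][idx])

    def fit(self, fix_bmax: bool = True) -> "BindingResults":
        order = np.argsort(self.x)
        if self.y[order][-1] < self.y[order][0]:
            warnings.warn(
                f"{self.construct or 'titration'}: bound fraction decreases "
                "with concentration; fit attempted anyway",
                stacklevel=2,
            )
        kd0 = self._kd_init()
        try:
            if fix_bmax:
                popt, pcov = curve_fit(
                    lambda x, kd: x / (kd + x),
                    self.x,
                    self.y,
                    p0=[kd0],
                    bounds=([1e-9], [np.inf]),
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                    maxfev=10000,
                )
                kd, bmax = float(popt[0]), 1.0
                kd_se = float(np.sqrt(pcov[0, 0]))
                bmax_se = 0.0
            else:
                popt, pcov = curve_fit(
                    lambda x, kd, bmax: bmax * x / (kd + x),
                    self.x,
                    self.y,
                    p0=[kd0, max(self.y.max(), 1e-3)],
                    bounds=([1e-9, 0.0], [np.inf, np.inf]),
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                    maxfev=10000,
                )
                kd, bmax = float(popt[0]), float(popt[1])
                kd_se, bmax_se = (float(v) for v in np.sqrt(np.diag(pcov)))
        except RuntimeError as err:
            raise FitError(f"Kd fit failed to converge: {err}") from err
        resid = self.y - bmax * self.x / (kd + self.x)
        return BindingResults(
            model=self, kd=kd, bmax=bmax, kd_se=kd_se, bmax_se=bmax_se, residuals=resid
        )


@dataclass
class BindingResults:
    """Fitted one-site binding parameters with asymptotic uncertainties."""

    model: OneSiteBindingModel = field(repr=False)
    kd: float  # nM
    bmax: float
    kd_se: float  # nM
    bmax_se: float
    residuals: np.ndarray

    def predict(self, concentrations_nM) -> np.ndarray:
        x = np.asarray(concentrations_nM, dtype=float)
        return self.bmax * x / (self.kd + x)

    def as_curve(self) -> BindingCurve:
        return BindingCurve(
            construct=self.model.construct,
            concentrations=self.model.x,
            bound_fraction=self.model.y,
            fitted_kd=self.kd,
            fitted_bmax=self.bmax,
            fit_sd=self.kd_se,
            residuals=self.residuals,
        )

    def summary(self) -> str:
        lines = [
            f"One-site specific binding fit: {self.model.construct or 'titration'}",
            "=" * 52,
            f"Kd    = {self.kd:.6g} nM  (s.e. {self.kd_se:.3g} nM)",
            f"Bmax  = {self.bmax:.6g}"
            + ("  (fixed)" if self.bmax_se == 0 else f"  (s.e. {self.bmax_se:.3g})"),
            f"n     = {self.model.x.size} points, "
            f"{np.unique(self.model.x).size} distinct concentrations",
            f"RSS   = {float(np.sum(self.residuals ** 2)):.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.x, self.model.y, "o", **kwargs)
        grid = np.linspace(0, self.model.x.max() * 1.05, 300)
        ax.plot(grid, self.predict(grid), "-", lw=1.2)
        ax.set_xlabel("[protein] (nM)")
        ax.set_ylabel("bound fraction")
        return ax


def fit_kd(
    concentrations,
    bound_fraction,
    fix_bmax: bool = True,
    construct: str = "",
    unit: str = "nM",
) -> BindingCurve:
    """Fit ``Y = Bmax*X/(Kd+X)`` and return the populated BindingCurve."""
    model = OneSiteBindingModel(
        concentrations, bound_fraction, construct=construct, unit=unit
    )
    return model.fit(fix_bmax=fix_bmax).as_curve()


def aggregate_kd(curves) -> tuple:
    """Replicate-level mean and sample s.d. of fitted Kd across curves."""
    kds = np.array([c.fitted_kd for c in curves], dtype=float)
    if kds.size == 0 or np.any(~np.isfinite(kds)):
        raise ParameterError("all curves must carry a fitted Kd")
    sd = float(np.std(kds, ddof=1)) if kds.size > 1 else float("nan")
    return float(np.mean(kds)), sd


def relative_binding(intensities: dict, reference: str) -> pd.DataFrame:
    """Fold binding intensity of each construct relative to a reference.

    Invariant under global positive rescaling; the reference row is exactly 1.
    """
    if reference not in intensities:
        raise ParameterError(f"reference construct {reference!r} not present")
    ref = intensities[reference]
    if not ref > 0:
        raise ParameterError("reference intensity must be positive")
    rows = [
        {
            "construct": name,
            "raw_intensity": float(value),
            "relative_intensity": float(value) / ref,
        }
        for name, value in intensities.items()
    ]
    return pd.DataFrame(rows)


def dynamics_binding_table(summaries, binding_table: pd.DataFrame):
    """Pair per-construct direct-transition density with relative binding.

    ``summaries`` maps construct -> DynamicsSummary (or directly to the
    direct-transition density). Returns ``(table, tau)`` where ``tau`` is the
    Kendall rank correlation between the two columns, or ``None`` (flagged)
    when fewer than two constructs overlap.
    """
    dd = {
        name: getattr(s, "direct_density", s) for name, s in summaries.items()
    }
    rows = []
    for _, rec in binding_table.iterrows():
        name = rec["construct"]
        if name in dd:
            rows.append(
                {
                    "construct": name,
                    "direct_density": float(dd[name]),
                    "relative_intensity": float(rec["relative_intensity"]),
                }
            )
    if not rows:
        raise ParameterError("no overlapping constructs between inputs")
    table = pd.DataFrame(rows)
    if len(table) < 2:
        return table, None
    tau = kendalltau(table["direct_density"], table["relative_intensity"]).statistic
    return table, float(tau)
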