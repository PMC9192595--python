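"""FRET efficiency, ensemble histograms, and anchored Gaussian decomposition.

The FRET efficiency of each frame is the acceptor fraction of total intensity,
optionally corrected for donor leakage and detection efficiency gamma:
``E = (A - l*D) / (gamma*D + A - l*D)``. Short windows (first 2 s of each
molecule) are pooled across >~2000 molecules into a unit-area histogram, which
is decomposed into a sum of Gaussian components whose centers are anchored at
the known conformational FRET levels (within a tolerance, 0 = fixed), plus
optional free components for emerging peaks such as a protein-bound state.
The relative population of each state is the relative area under its
component. Differential histograms (condition minus reference) localize
density that appears or disappears upon a perturbation; the sum of positive
differential density is a proxy for the newly populated (bound) fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    EmptyDataError,
    FitError,
    IncompatibleBinsError,
    ParameterError,
)
from .traces import TraceRecord

__all__ = [
    "FretTrajectory",
    "FretHistogram",
    "DifferentialHistogram",
    "MixtureResults",
    "EmergingPeak",
    "locate_emerging_peak",
    "AnchoredGaussianMixture",
    "compute_fret",
    "build_histogram",
    "fit_mixture",
    "differential_density",
    "default_bin_edges",
]

logger = logging.getLogger(__name__)

_NORM = 1.0 / np.sqrt(2.0 * np.pi)


def default_bin_edges(width: float = 0.025, low: float = -0.2, high: float = 1.2):
    """Default FRET binning: 0.025-wide bins spanning [-0.2, 1.2]."""
    if width <= 0:
        raise ParameterError("bin width must be positive")
    n = int(round((high - low) / width))
    return low + width * np.arange(n + 1)


@dataclass
class FretTrajectory:
    """Per-frame FRET efficiency of one molecule after corrections.

    ``valid_until`` counts the usable prefix (frames at or past the bleach
    index are excluded); individual bad frames inside the prefix are NaN.
    """

    molecule_id: str
    efficiency: np.ndarray
    frame_interval: float
    valid_until: int

    def __post_init__(self):
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if not 0 <= self.valid_until <= self.efficiency.size:
            raise ParameterError("valid_until outside trace")

    @property
    def n_frames(self) -> int:
        return self.efficiency.size

    def valid_values(self, window: float | None = None) -> np.ndarray:
        """Finite efficiencies of the usable prefix, optionally the first
        ``window`` seconds only."""
        stop = self.valid_until
        if window is not None:
            stop = min(stop, int(np.floor(window / self.frame_interval + 1e-9)))
        vals = self.efficiency[:stop]
        return vals[np.isfinite(vals)]

    def filled_values(self, window: float | None = None) -> np.ndarray:
        """Usable prefix with interior NaNs forward-filled (frame-aligned)."""
        stop = self.valid_until
        if window is not None:
            stop = min(stop, int(np.floor(window / self.frame_interval + 1e-9)))
        vals = self.efficiency[:stop].copy()
        bad = ~np.isfinite(vals)
        if bad.all():
            return vals[:0]
        if bad.any():
            idx = np.where(~bad, np.arange(vals.size), 0)
            np.maximum.accumulate(idx, out=idx)
            vals = vals[idx]
            first_good = np.argmax(~bad)
            vals[:first_good] = vals[first_good]
        return vals


def compute_fret(
    trace: TraceRecord, leakage: float = 0.0, gamma: float = 1.0
) -> FretTrajectory:
    """Frame-wise FRET efficiency with optional leakage/gamma correction.

    With the defaults (no correction) this is the ratio ``E = A / (D + A)``.
    Frames past the trace's bleach index are excluded via ``valid_until``;
    pre-bleach frames with non-positive total intensity are NaN with a
    logged warning.
    """
    acc = trace.acceptor - leakage * trace.donor
    denom = gamma * trace.donor + acc
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(denom > 0, acc / denom, np.nan)
    valid_until = (
        trace.bleach_frame - 1 if trace.bleach_frame is not None else trace.n_frames
    )
    n_bad = int(np.sum(~np.isfinite(eff[:valid_until])))
    if n_bad:
        logger.warning(
            "%s: %d pre-bleach frame(s) with non-positive total intensity",
            trace.molecule_id,
            n_bad,
        )
    return FretTrajectory(
        molecule_id=trace.molecule_id,
        efficiency=eff,
        frame_interval=trace.frame_interval,
        valid_until=valid_until,
    )


@dataclass
class FretHistogram:
    """Unit-area binned density of pooled FRET efficiencies."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_molecules: int
    window: float | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.size != self.bin_edges.size - 1:
            raise ParameterError("density length must be n_bins")
        if np.any(self.density < 0):
            raise ParameterError("density must be non-negative")
        area = float(np.sum(self.density * self.bin_widths))
        if self.density.any() and abs(area - 1.0) > 1e-9:
            raise ParameterError(f"histogram area {area} != 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def mass_near(self, center: float, halfwidth: float = 0.1) -> float:
        """Probability mass within ``center +/- halfwidth``."""
        sel = (self.bin_centers >= center - halfwidth) & (
            self.bin_centers <= center + halfwidth
        )
        return float(np.sum(self.density[sel] * self.bin_widths[sel]))

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(
            self.bin_centers,
            self.density,
            width=self.bin_widths,
            align="center",
            **{"color": "0.7", "edgecolor": "0.4", **kwargs},
        )
        ax.set_xlabel("FRET efficiency")
        ax.set_ylabel("probability density")
        return ax


def build_histogram(
    trajectories,
    window: float = 2.0,
    bin_edges: np.ndarray | None = None,
) -> FretHistogram:
    """Pool the first ``window`` seconds of every trajectory into a histogram.

    Each molecule contributes its first ``floor(window / frame_interval)``
    valid frames (frame pooling: every frame weighs equally).
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    values, n_mol = [], 0
    for traj in trajectories:
        vals = traj.valid_values(window=window)
        if vals.size:
            values.append(vals)
            n_mol += 1
    if not values:
        raise EmptyDataError("no valid frames inside the histogram window")
    pooled = np.concatenate(values)
    density, _ = np.histogram(pooled, bins=bin_edges, density=True)
    return FretHistogram(
        bin_edges=bin_edges, density=density, n_molecules=n_mol, window=window
    )


@dataclass
class DifferentialHistogram:
    """Signed per-bin density difference, condition minus reference."""

    bin_edges: np.ndarray
    delta_density: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def positive_sum(self) -> float:
        """Total mass gained by the condition: sum of max(delta, 0) * width."""
        widths = np.diff(self.bin_edges)
        return float(np.sum(np.clip(self.delta_density, 0, None) * widths))

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        widths = np.diff(self.bin_edges)
        colors = np.where(self.delta_density >= 0, "tab:blue", "tab:red")
        ax.bar(self.bin_centers, self.delta_density, width=widths, color=colors, **kwargs)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("FRET efficiency")
        ax.set_ylabel("differential density")
        return ax


def differential_density(
    with_protein: FretHistogram, reference: FretHistogram
) -> DifferentialHistogram:
    """Per-bin density difference (condition minus reference), same bins only."""
    if not np.array_equal(with_protein.bin_edges, reference.bin_edges):
        raise IncompatibleBinsError(
            "histograms must share identical bin edges (no silent rebinning)"
        )
    return DifferentialHistogram(
        bin_edges=with_protein.bin_edges.copy(),
        delta_density=with_protein.density - reference.density,
    )


@dataclass
class MixtureComponent:
    label: str
    center: float
    sd: float
    weight: float  # area under the component
    anchored: bool


@dataclass
class MixtureResults:
    """Fitted anchored Gaussian decomposition of a FRET histogram.

    ``population`` maps each component label to its relative area (summing to
    one); ``residual`` is the sum of squared density residuals at the bin
    centers.
    """

    components: list
    anchors: dict
    tolerance: float
    residual: float
    model: "AnchoredGaussianMixture" = field(repr=False, default=None)

    @property
    def population(self) -> dict:
        total = sum(c.weight for c in self.components)
        if total <= 0:
            return {c.label: 0.0 for c in self.components}
        return {c.label: c.weight / total for c in self.components}

    @property
    def centers(self) -> dict:
        return {c.label: c.center for c in self.components}

    @property
    def free_components(self) -> list:
        return [c for c in self.components if not c.anchored]

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x)
        for c in self.components:
            amp = c.weight * _NORM / c.sd
            y += amp * np.exp(-0.5 * ((x - c.center) / c.sd) ** 2)
        return y

    def summary(self) -> str:
        pop = self.population
        lines = [
            "Anchored Gaussian mixture fit",
            "=" * 58,
            f"{'component':<12}{'center':>10}{'sd':>10}{'population':>14}{'anchor':>10}",
            "-" * 58,
        ]
        for c in self.components:
            anchor = f"{self.anchors[c.label]:.3f}" if c.anchored else "free"
            lines.append(
                f"{c.label:<12}{c.center:>10.4f}{c.sd:>10.4f}"
                f"{pop[c.label]:>14.4f}{anchor:>10}"
            )
        lines.append("-" * 58)
        lines.append(f"residual (SSR of density): {self.residual:.6g}")
        return "\n".join(lines)

    def plot(self, hist: FretHistogram | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if hist is not None:
            hist.plot(ax=ax)
            x = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 400)
        else:
            x = np.linspace(-0.2, 1.2, 400)
        for c in self.components:
            amp = c.weight * _NORM / c.sd
            ax.plot(x, amp * np.exp(-0.5 * ((x - c.center) / c.sd) ** 2), lw=1.2)
        ax.plot(x, self.predict(x), "k--", lw=1.0)
        return ax


class AnchoredGaussianMixture:
    """Least-squares sum-of-Gaussians model of a binned FRET density.

    Components listed in ``anchors`` have centers constrained within
    ``tolerance`` of the anchor (tolerance 0 fixes them exactly, mirroring
    fits where the conformational peak positions are restricted to their
    protein-free values); ``free_components`` additional components have
    unconstrained centers, initialized at the largest positive residual of
    the anchored-only fit. The initialization rule and optimizer settings are
    fixed, so the fit is deterministic given its inputs.

    When a perturbed condition is decomposed against a known reference (e.g.
    +protein against protein-free), pass ``reference=<protein-free
    MixtureResults>``: anchored components then inherit their widths from the
    reference fit and free components carry the reference's median width, so
    that only the populations and the free-peak position remain to be
    estimated — the well-posed version of the problem when peaks overlap.
    """

    _SD0 = 0.05
    _SD_BOUNDS = (0.01, 0.4)
    _MAX_NFEV = 2000

    def __init__(
        self,
        hist: FretHistogram,
        anchors: dict,
        free_components: int = 0,
        tolerance: float = 0.01,
        reference: "MixtureResults | None" = None,
    ):
        if not anchors and free_components < 1:
            raise ParameterError("need at least one anchored or free component")
        if tolerance < 0:
            raise ParameterError("anchor tolerance must be >= 0")
        if not np.any(hist.density > 0):
            raise EmptyDataError("cannot fit an empty histogram")
        self.hist = hist
        self.anchors = dict(anchors)
        self.free_components = int(free_components)
        self.tolerance = float(tolerance)
        self.sd_map = {}
        self.free_sd = None
        if reference is not None:
            self.sd_map = {
                c.label: c.sd for c in reference.components if c.label in self.anchors
            }
            self.free_sd = float(np.median([c.sd for c in reference.components]))

    def fit(self) -> MixtureResults:
        x = self.hist.bin_centers
        y = self.hist.density
        labels = list(self.anchors)
        specs = [(lab, self.anchors[lab], True) for lab in labels]
        result = self._fit_components(x, y, specs)
        for k in range(self.free_components):
            resid = y - self._model_curve(x, result)
            i0 = int(np.argmax(resid))
            specs = specs + [(f"free{k + 1}", float(x[i0]), False)]
            result = self._fit_components(
                x, y, specs, warm={lab: c for lab, c in result.items()}
            )
        components = [
            MixtureComponent(
                label=lab,
                center=params[0],
                sd=params[1],
                weight=params[2] * params[1] / _NORM,
                anchored=anchored,
            )
            for (lab, _, anchored), params in zip(specs, result.values())
        ]
        ssr = float(np.sum((y - self._model_curve(x, result)) ** 2))
        return MixtureResults(
            components=components,
            anchors=self.anchors,
            tolerance=self.tolerance,
            residual=ssr,
            model=self,
        )

    # each component is parameterized as (center, sd, peak height)
    def _fit_components(self, x, y, specs, warm=None):
        p0, lo, hi = [], [], []
        for lab, center, anchored in specs:
            if warm and lab in warm:
                c0, s0, h0 = warm[lab]
            else:
                c0, s0 = center, self._SD0
                h0 = max(float(y[np.argmin(np.abs(x - center))]), 1e-3)
            if anchored:
                c_lo = center - self.tolerance
                c_hi = center + self.tolerance
                fixed_sd = self.sd_map.get(lab)
            else:
                c_lo, c_hi = float(x[0]), float(x[-1])
                fixed_sd = self.free_sd
            if fixed_sd is not None:
                s_lo = s_hi = s0 = float(fixed_sd)
            else:
                s_lo, s_hi = self._SD_BOUNDS
            c0 = min(max(c0, c_lo), c_hi)
            s0 = min(max(s0, s_lo), s_hi)
            p0 += [c0, s0, h0]
            lo += [c_lo, s_lo, 0.0]
            hi += [c_hi, s_hi, np.inf]
        lo = np.asarray(lo)
        hi = np.asarray(hi)
        # degenerate zero-width center bounds upset the optimizer; widen by eps
        fixed = hi - lo <= 0
        hi = np.where(fixed, lo + 1e-12, hi)

        def residuals(theta):
            return self._curve_from_theta(x, theta) - y

        sol = least_squares(
            residuals,
            np.asarray(p0, dtype=float),
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=self._MAX_NFEV,
        )
        if not sol.success and sol.status <= 0:
            raise FitError(
                "mixture fit failed to converge", residual=float(np.sum(sol.fun**2))
            )
        theta = sol.x
        return {
            lab: (float(theta[3 * i]), float(theta[3 * i + 1]), float(theta[3 * i + 2]))
            for i, (lab, _, _) in enumerate(specs)
        }

    @staticmethod
    def _curve_from_theta(x, theta):
        y = np.zeros_like(x)
        for i in range(len(theta) // 3):
            c, s, h = theta[3 * i : 3 * i + 3]
            y = y + h * np.exp(-0.5 * ((x - c) / s) ** 2)
        return y

    @staticmethod
    def _model_curve(x, params):
        y = np.zeros_like(x)
        for c, s, h in params.values():
            y = y + h * np.exp(-0.5 * ((x - c) / s) ** 2)
        return y


@dataclass
class EmergingPeak:
    """A peak located in a differential histogram (condition minus reference).

    ``center``/``sd`` describe the gained Gaussian; ``gain_area`` is its
    mass, ``losses`` the mass removed from each reference component.
    """

    center: float
    sd: float
    gain_area: float
    losses: dict
    residual: float


def locate_emerging_peak(
    target: FretHistogram,
    reference: FretHistogram,
    reference_fit: MixtureResults,
    width: float | None = None,
) -> EmergingPeak:
    """Locate a newly appearing peak from the differential histogram.

    The density difference (condition minus reference) is decomposed as one
    free *gain* Gaussian minus non-negative *losses* pinned at the reference
    fit's component positions and widths. Because systematic features common
    to both conditions (camera blur between peaks, binning artifacts) cancel
    in the difference, this locates an emerging peak — e.g. a protein-bound
    state between two conformational levels — more accurately than a free
    component in the absolute decomposition when peaks overlap. The gain
    width defaults to the reference fit's median width. Deterministic.
    """
    diff = differential_density(target, reference)
    x = diff.bin_centers
    y = diff.delta_density
    comps = reference_fit.components
    if width is None:
        width = float(np.median([c.sd for c in comps]))

    def curve(theta):
        yy = theta[1] * np.exp(-0.5 * ((x - theta[0]) / width) ** 2)
        for i, c in enumerate(comps):
            yy = yy - theta[2 + i] * np.exp(-0.5 * ((x - c.center) / c.sd) ** 2)
        return yy

    c0 = float(x[np.argmax(y)])
    p0 = [c0, max(float(y.max()), 1e-3)]
    lo = [float(x[0]), 0.0]
    hi = [float(x[-1]), np.inf]
    for c in comps:
        loss0 = max(-float(y[np.argmin(np.abs(x - c.center))]), 1e-3)
        p0.append(loss0)
        lo.append(0.0)
        hi.append(np.inf)
    sol = least_squares(
        lambda th: curve(th) - y,
        np.asarray(p0),
        bounds=(lo, hi),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    theta = sol.x
    losses = {
        c.label: float(theta[2 + i] * c.sd / _NORM) for i, c in enumerate(comps)
    }
    return EmergingPeak(
        center=float(theta[0]),
        sd=float(width),
        gain_area=float(theta[1] * width / _NORM),
        losses=losses,
        residual=float(np.sum(sol.fun**2)),
    )


def fit_mixture(
    hist: FretHistogram,
    anchors: dict,
    free_components: int = 0,
    tolerance: float = 0.01,
    reference: MixtureResults | None = None,
) -> MixtureResults:
    """Fit an anchored Gaussian mixture to a FRET histogram (see
    :class:`AnchoredGaussianMixture`)."""
    return AnchoredGaussianMixture(
        hist,
        anchors,
        free_components=free_components,
        tolerance=tolerance,
        reference=reference,
    ).fit()
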