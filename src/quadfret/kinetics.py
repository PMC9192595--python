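"""Per-trajectory dynamics: segmentation, transitions, dwell times.

Trajectories are first split into docked (no state change within the first
100 s) and transitioning molecules. Transitioning trajectories are segmented
by a maximum-likelihood Gaussian hidden-Markov model fit on the FRET series,
with the number of states selected over K = 2..4 (plus a static K = 1
candidate) by BIC; the Viterbi path is collapsed into dwell segments.
Inferred states are identified with the known conformations by nearest
anchor FRET level. From the labeled paths come transition density plots,
transition-type counts, dwell-time tables with first/last-dwell censoring,
and the direct-transition statistic: the fraction of transitions that are
NP->P or P->NP, multiplied by the fraction of molecules that transition at
all — the quantity that tracks protein binding across constructs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy.stats import norm

from .errors import EmptyDataError, ParameterError
from .histogram import FretTrajectory
from .statepath import StatePath, path_from_frame_labels

__all__ = [
    "CORE_TRANSITIONS",
    "classify_trajectory",
    "infer_state_path",
    "assign_state_labels",
    "count_transitions",
    "transition_density_plot",
    "dwell_analysis",
    "corrected_dwell_means",
    "direct_transition_density",
    "analyze_paths",
    "ModelSelectionReport",
    "TransitionCounts",
    "TransitionDensity",
    "DwellTable",
    "DynamicsSummary",
]

logger = logging.getLogger(__name__)

CORE_STATES = ("UF", "NP", "P")
#: The six ordered transition types among the protein-free conformations.
CORE_TRANSITIONS = tuple(
    (a, b) for a in CORE_STATES for b in CORE_STATES if a != b
)

_VAR_FLOOR = 1e-4  # emission variance floor shared by all K candidates


def classify_trajectory(
    traj: FretTrajectory, window: float = 100.0, min_jump: float = 0.1
) -> str:
    """Label a trajectory ``"docked"`` or ``"transitioning"``.

    A molecule is transitioning if, within the first ``window`` seconds, the
    FRET series contains a level change larger than both ``min_jump`` and a
    noise-adaptive threshold. The detector compares means of adjacent 1-s
    blocks slid frame by frame; the per-frame noise scale is estimated
    robustly from successive differences (median absolute difference), which
    is insensitive to the rare genuine jumps. Deterministic given its inputs.
    """
    vals = traj.filled_values(window=window)
    n_window = int(np.floor(window / traj.frame_interval + 1e-9))
    if vals.size < 2:
        raise ParameterError(
            f"{traj.molecule_id}: need >= 2 valid frames to classify"
        )
    if vals.size < n_window:
        logger.warning(
            "%s: classification window exceeds usable trace (%d frames)",
            traj.molecule_id,
            vals.size,
        )
    diffs = np.diff(vals)
    # sd of successive differences is sqrt(2) * per-frame sd; 1.4826 scales
    # the median absolute value of a centered normal to its sd
    sigma = 1.4826 * float(np.median(np.abs(diffs))) / np.sqrt(2.0) if diffs.size else 0.0
    w = max(2, min(int(round(1.0 / traj.frame_interval)), vals.size // 2))
    cum = np.concatenate([[0.0], np.cumsum(vals)])
    means = (cum[w:] - cum[:-w]) / w  # mean of vals[i : i+w]
    jumps = np.abs(means[w:] - means[:-w])  # blocks [i-w, i) vs [i, i+w)
    threshold = max(min_jump, 4.5 * sigma * np.sqrt(2.0 / w))
    return "transitioning" if jumps.size and jumps.max() > threshold else "docked"


@dataclass
class ModelSelectionReport:
    """Per-K penalized-likelihood comparison behind one segmentation."""

    n_frames: int
    candidates: dict  # K -> {"loglik": float, "n_params": int, "bic": float}
    selected_k: int
    effective_k: int  # after merging near-degenerate states
    merged: bool


def _bic_candidates(x, k_range, random_state):
    """Fit K=1 and each K in k_range; return {K: (bic, loglik, model)}."""
    n = x.size
    out = {}
    mu, var = float(np.mean(x)), max(float(np.var(x)), _VAR_FLOOR)
    ll1 = float(np.sum(norm.logpdf(x, mu, np.sqrt(var))))
    out[1] = {"loglik": ll1, "n_params": 2, "bic": -2 * ll1 + 2 * np.log(n), "model": (mu, var)}
    X = x[:, None]
    for k in range(k_range[0], k_range[1] + 1):
        if k < 2 or k > n // 4:
            continue
        hmm = GaussianHMM(
            n_components=k,
            covariance_type="diag",
            min_covar=_VAR_FLOOR,
            n_iter=100,
            tol=1e-4,
            init_params="",
            params="stmc",
            random_state=random_state,
        )
        # deterministic initialization: emission means at E-quantiles,
        # shared variance, sticky uniform transitions
        q = (np.arange(k) + 0.5) / k
        hmm.startprob_ = np.full(k, 1.0 / k)
        hmm.transmat_ = np.where(
            np.eye(k, dtype=bool), 0.9, 0.1 / max(k - 1, 1)
        )
        means0 = np.quantile(x, q)
        if np.min(np.diff(means0)) < 1e-3:
            # skewed occupancy can collide quantiles (symmetric EM trap);
            # fall back to an even spread over the observed range
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi - lo < 1e-6:
                continue  # constant signal: K=1 covers it
            means0 = np.linspace(lo, hi, k + 2)[1:-1]
        hmm.means_ = means0[:, None]
        hmm.covars_ = np.full((k, 1), var)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hmm_logger = logging.getLogger("hmmlearn.base")
                old_level = hmm_logger.level
                hmm_logger.setLevel(logging.ERROR)
                try:
                    hmm.fit(X)
                    ll = float(hmm.score(X))
                finally:
                    hmm_logger.setLevel(old_level)
        except Exception:  # degenerate fit (e.g. unvisited component)
            continue
        if not np.isfinite(ll):
            continue
        p = k * (k - 1) + (k - 1) + 2 * k  # transmat + startprob + emissions
        out[k] = {"loglik": ll, "n_params": p, "bic": -2 * ll + p * np.log(n), "model": hmm}
    return out


def _merge_degenerate(labels, means, min_sep=0.02):
    """Merge inferred states whose emission means are closer than min_sep."""
    order = np.argsort(means)
    groups = []
    for idx in order:
        if groups and means[idx] - means[groups[-1][-1]] < min_sep:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    if len(groups) == len(means):
        return labels, means, False
    remap = {}
    new_means = []
    counts = np.bincount(labels, minlength=len(means)).astype(float)
    for g_id, members in enumerate(groups):
        w = counts[members]
        w = w if w.sum() > 0 else np.ones_like(w)
        new_means.append(float(np.average(means[members], weights=w)))
        for m in members:
            remap[m] = g_id
    new_labels = np.array([remap[l] for l in labels])
    return new_labels, np.asarray(new_means), True


def infer_state_path(
    traj: FretTrajectory,
    k_range: tuple = (2, 4),
    min_segment_frames: int = 2,
    random_state: int = 0,
):
    """Segment a FRET trajectory into dwell states by HMM + BIC selection.

    Fits Gaussian-emission hidden-Markov models for each K in ``k_range``
    (expectation-maximization with deterministic quantile initialization and
    fixed iteration caps) plus a static one-state candidate, selects K by
    BIC, and collapses the Viterbi state sequence into segments. States
    whose emission means fall within 0.02 of each other are merged; segments
    shorter than ``min_segment_frames`` (camera-blurred transition frames)
    are absorbed into the neighbouring state with the closer emission mean.

    Returns ``(path, report)`` where ``path`` carries numeric state labels
    ``s0, s1, ...`` ordered by emission mean and ``path.emission_centers``
    holds the fitted means; feed it to :func:`assign_state_labels` to name
    the states.
    """
    x = traj.filled_values()
    if x.size < 20:
        raise EmptyDataError(
            f"{traj.molecule_id}: need >= 20 valid frames, got {x.size}"
        )
    cands = _bic_candidates(x, k_range, random_state)
    best_k = min(cands, key=lambda k: (cands[k]["bic"], k))
    if best_k == 1:
        labels = np.zeros(x.size, dtype=int)
        means = np.array([cands[1]["model"][0]])
    else:
        hmm = cands[best_k]["model"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = hmm.predict(x[:, None])
        means = hmm.means_.ravel()
    labels, means, merged = _merge_degenerate(labels, means)
    # canonical state ids ordered by emission mean
    order = np.argsort(means)
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    labels = rank[labels]
    means = means[order]
    labels = _absorb_blur(labels, means, min_segment_frames)
    names = [f"s{i}" for i in range(means.size)]
    path = path_from_frame_labels(
        traj.molecule_id,
        [names[l] for l in labels],
        traj.frame_interval,
        source="inferred",
        emission_centers=dict(zip(names, means)),
    )
    report = ModelSelectionReport(
        n_frames=int(x.size),
        candidates={
            k: {kk: vv for kk, vv in v.items() if kk != "model"}
            for k, v in cands.items()
        },
        selected_k=int(best_k),
        effective_k=int(means.size),
        merged=merged,
    )
    return path, report


def _absorb_blur(labels, means, min_frames):
    """Merge runs shorter than min_frames into the closer-mean neighbour."""
    if min_frames <= 1:
        return labels
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        lo = 0
        for i in range(1, labels.size + 1):
            if i == labels.size or labels[i] != labels[lo]:
                runs.append((labels[lo], lo, i))
                lo = i
        if len(runs) <= 1:
            break
        for i, (state, lo, hi) in enumerate(runs):
            if hi - lo >= min_frames:
                continue
            left = runs[i - 1][0] if i > 0 else None
            right = runs[i + 1][0] if i < len(runs) - 1 else None
            if left is None:
                repl = right
            elif right is None:
                repl = left
            else:
                repl = (
                    left
                    if abs(means[left] - means[state])
                    <= abs(means[right] - means[state])
                    else right
                )
            labels[lo:hi] = repl
            changed = True
            break
    return labels


def assign_state_labels(
    path: StatePath, anchors: dict, max_distance: float = 0.08
) -> StatePath:
    """Name inferred states by the nearest anchor FRET level.

    Ties break toward the lower-E anchor; states farther than
    ``max_distance`` from every anchor become ``"other"``. Adjacent segments
    that end up with the same label are merged.
    """
    if not anchors:
        raise ParameterError("anchors must be non-empty")
    if not path.emission_centers:
        raise ParameterError("path has no emission centers to label from")
    ordered = sorted(anchors.items(), key=lambda kv: kv[1])  # low E first
    mapping = {}
    for state, center in path.emission_centers.items():
        best_label, best_dist = None, np.inf
        for label, level in ordered:
            d = abs(center - level)
            if d < best_dist - 1e-12:  # strict: ties keep the lower-E anchor
                best_label, best_dist = label, d
        mapping[state] = best_label if best_dist <= max_distance else "other"
    relabeled = path.relabel(mapping)
    centers = dict(relabeled.emission_centers)
    for state, center in path.emission_centers.items():
        centers.setdefault(mapping[state], center)
    relabeled.emission_centers = centers
    return relabeled


@dataclass
class TransitionCounts:
    """Tally of adjacent-segment label pairs across labeled paths.

    The six ordered types among UF/NP/P are in ``counts`` and define
    ``n_transitions_total``; pairs involving BD or "other" states are kept
    apart in ``extra_counts`` and excluded from the core denominator.
    """

    counts: dict
    extra_counts: dict = field(default_factory=dict)

    @property
    def n_transitions_total(self) -> int:
        return int(sum(self.counts.values()))

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"from": a, "to": b, "count": c, "core": True}
            for (a, b), c in self.counts.items()
        ] + [
            {"from": a, "to": b, "count": c, "core": False}
            for (a, b), c in sorted(self.extra_counts.items())
        ]
        return pd.DataFrame(rows)


def count_transitions(paths) -> TransitionCounts:
    """Count every segment-boundary transition across the labeled paths."""
    core = {pair: 0 for pair in CORE_TRANSITIONS}
    extra = {}
    for path in paths:
        for pair in path.transitions():
            if pair in core:
                core[pair] += 1
            else:
                extra[pair] = extra.get(pair, 0) + 1
    return TransitionCounts(counts=core, extra_counts=extra)


@dataclass
class TransitionDensity:
    """2-D density over (FRET before, FRET after) at each state change."""

    bin_edges: np.ndarray
    matrix: np.ndarray  # normalized to unit total mass
    n_transitions: int

    @property
    def is_empty(self) -> bool:
        return self.n_transitions == 0

    def mass(self, before: tuple, after: tuple) -> float:
        """Total mass with E_before in ``before`` and E_after in ``after``
        (half-open intervals)."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        sel_b = (centers >= before[0]) & (centers < before[1])
        sel_a = (centers >= after[0]) & (centers < after[1])
        return float(self.matrix[np.ix_(sel_b, sel_a)].sum())

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        extent = [
            self.bin_edges[0],
            self.bin_edges[-1],
            self.bin_edges[0],
            self.bin_edges[-1],
        ]
        ax.imshow(
            self.matrix.T,
            origin="lower",
            extent=extent,
            aspect="equal",
            **{"cmap": "viridis", **kwargs},
        )
        ax.plot(extent[:2], extent[:2], "w--", lw=0.6)
        ax.set_xlabel("FRET before transition")
        ax.set_ylabel("FRET after transition")
        return ax


def transition_density_plot(paths, bin_edges=None) -> TransitionDensity:
    """Bin (emission center before, after) over every detected state change.

    Coordinates use inferred emission centers, producing the discrete
    cluster structure of a transition density plot; the diagonal is empty by
    construction because adjacent segments differ. Zero transitions yield an
    empty result flagged by ``is_empty``, not an error.
    """
    from .histogram import default_bin_edges

    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    before, after = [], []
    for path in paths:
        centers = path.emission_centers
        for a, b in path.transitions():
            if a in centers and b in centers:
                before.append(centers[a])
                after.append(centers[b])
    n = len(before)
    matrix, _, _ = np.histogram2d(before, after, bins=[bin_edges, bin_edges])
    if n > 0:
        matrix = matrix / matrix.sum()
    return TransitionDensity(bin_edges=bin_edges, matrix=matrix, n_transitions=n)


@dataclass
class DwellTable:
    """Every dwell across the labeled paths, with censoring flags.

    The first and last segment of each trace are censored (their true
    durations are cut by the observation window) and excluded from means.
    """

    table: pd.DataFrame  # molecule_id, state, duration, censored

    def mean_dwell(self, state: str) -> float:
        """Mean over uncensored dwells; NaN when none exist (undefined)."""
        sel = (self.table["state"] == state) & (~self.table["censored"])
        if not sel.any():
            return float("nan")
        return float(self.table.loc[sel, "duration"].mean())

    @property
    def states(self) -> list:
        return sorted(self.table["state"].unique())

    def means(self) -> dict:
        return {s: self.mean_dwell(s) for s in self.states}

    def exit_rates(self) -> dict:
        """Exponential maximum-likelihood exit rate 1/mean per state."""
        return {s: 1.0 / m if m > 0 else float("nan") for s, m in self.means().items()}


def dwell_analysis(paths) -> DwellTable:
    rows = []
    for path in paths:
        n = len(path.segments)
        for i, seg in enumerate(path.segments):
            rows.append(
                {
                    "molecule_id": path.molecule_id,
                    "state": seg.state,
                    "duration": seg.duration,
                    "censored": i == 0 or i == n - 1,
                }
            )
    table = pd.DataFrame(rows, columns=["molecule_id", "state", "duration", "censored"])
    return DwellTable(table=table)


@dataclass
class DynamicsSummary:
    """Condition-level dynamics summary.

    ``direct_density`` is the NP-P direct-transition statistic: the fraction
    of (core) transitions that are NP->P or P->NP, multiplied by the
    fraction of molecules undergoing transitions at all. It is bounded by
    ``fraction_transitioning``, with equality iff every transition is direct.
    """

    label: str
    n_total: int
    n_transitioning: int
    direct_density: float

    @property
    def fraction_transitioning(self) -> float:
        return self.n_transitioning / self.n_total if self.n_total else 0.0

    def summary(self) -> str:
        return (
            f"{self.label or 'condition'}: {self.n_transitioning}/{self.n_total} "
            f"molecules transitioning (fraction {self.fraction_transitioning:.3f}), "
            f"NP-P direct transition density {self.direct_density:.4f}"
        )


def corrected_dwell_means(
    dwells: DwellTable,
    counts: TransitionCounts,
    dead_time: float,
    n_iter: int = 5,
) -> dict:
    """Dead-time- and missed-event-corrected mean dwell per state.

    Segment detection has a dead time: dwells shorter than the blur-merge
    threshold (``min_segment_frames`` frames) are never reported. For an
    exponential dwell distribution this biases the raw mean in two ways:

    * truncation — surviving dwells average ``dead_time + tau`` rather than
      ``tau``;
    * concatenation — when a short excursion to another state goes
      undetected and the path returns to the original state, the two
      flanking dwells are fused into one long apparent dwell.

    Both corrections are computed from quantities the pipeline itself
    estimates: the raw uncensored means and the branching probabilities of
    the embedded jump chain (from the transition counts). The fused-dwell
    probability for state ``i`` is ``p_i = sum_j b_ij P(d_j < c) b_ji`` and
    the plug-in update ``tau_i = (mean_i - c - extra_i) / (1 + p_i)`` is
    iterated to a fixed point (``extra_i`` is the expected undetected
    interloper time). With a 0.2-s dead time the corrections are a few
    percent for seconds-scale dwells and essential for sub-2-s ones.
    """
    if dead_time < 0:
        raise ParameterError("dead_time must be >= 0")
    all_counts = {**counts.counts, **counts.extra_counts}
    states = sorted(
        {a for a, _ in all_counts} | {b for _, b in all_counts} | set(dwells.states)
    )
    out_total = {
        s: sum(c for (a, _), c in all_counts.items() if a == s) for s in states
    }
    branch = {
        pair: c / out_total[pair[0]]
        for pair, c in all_counts.items()
        if out_total[pair[0]] > 0
    }
    obs = {s: dwells.mean_dwell(s) for s in states}
    tau = {
        s: max(obs[s] - dead_time, dead_time / 2) if np.isfinite(obs[s]) else obs[s]
        for s in states
    }
    for _ in range(n_iter):
        new = {}
        for s in states:
            if not np.isfinite(obs[s]):
                new[s] = obs[s]
                continue
            p_fuse = 0.0
            extra = 0.0
            for j in states:
                if j == s or not np.isfinite(tau.get(j, np.nan)):
                    continue
                p_short = 1.0 - np.exp(-dead_time / tau[j])
                if p_short <= 0:
                    continue
                # mean duration of an undetected (< dead_time) dwell in j
                e_short = tau[j] - dead_time * np.exp(-dead_time / tau[j]) / p_short
                loop = branch.get((s, j), 0.0) * p_short * branch.get((j, s), 0.0)
                p_fuse += loop
                extra += loop * e_short
            new[s] = max((obs[s] - dead_time - extra) / (1.0 + p_fuse), dead_time / 2)
        tau = new
    return tau


def direct_transition_density(
    counts: TransitionCounts,
    n_total: int,
    n_transitioning: int,
    label: str = "",
) -> DynamicsSummary:
    """NP-P direct-transition density from counts and the transitioning split.

    ``fraction_transitioning * (N[NP->P] + N[P->NP]) / N_core_total``; zero
    when nothing transitions (0/0 := 0).
    """
    if n_total < 0 or not 0 <= n_transitioning <= max(n_total, 0):
        raise ParameterError("invalid molecule counts")
    total = counts.n_transitions_total
    frac = n_transitioning / n_total if n_total else 0.0
    if total == 0:
        dd = 0.0
    else:
        direct = counts.counts[("NP", "P")] + counts.counts[("P", "NP")]
        dd = frac * direct / total
    return DynamicsSummary(
        label=label,
        n_total=int(n_total),
        n_transitioning=int(n_transitioning),
        direct_density=float(dd),
    )


def analyze_paths(
    trajectories,
    anchors: dict,
    k_range: tuple = (2, 4),
    classification_window: float = 100.0,
    min_jump: float = 0.1,
    label: str = "",
):
    """Full per-trajectory pipeline: classify, segment, label, summarize.

    Returns a dict with the labeled paths of transitioning molecules, the
    transition counts, dwell table, transition density, and the
    :class:`DynamicsSummary`. Docked molecules are counted but not segmented.
    """
    n_total = 0
    labeled = []
    dead_time = None
    for traj in trajectories:
        n_total += 1
        if dead_time is None:
            dead_time = 2 * traj.frame_interval  # matches min_segment_frames
        if classify_trajectory(traj, window=classification_window, min_jump=min_jump) != "transitioning":
            continue
        path, _ = infer_state_path(traj, k_range=k_range)
        labeled.append(assign_state_labels(path, anchors))
    counts = count_transitions(labeled)
    dwells = dwell_analysis(labeled)
    summary = direct_transition_density(
        counts, n_total=n_total, n_transitioning=len(labeled), label=label
    )
    return {
        "paths": labeled,
        "counts": counts,
        "dwells": dwells,
        "dwell_means": corrected_dwell_means(dwells, counts, dead_time or 0.2),
        "tdp": transition_density_plot(labeled),
        "summary": summary,
    }
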