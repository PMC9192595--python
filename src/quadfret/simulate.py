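"""Synthetic smFRET trajectory generator with known ground truth.

Molecules interconvert between conformational states (unfolded UF, non-parallel
G4 NP, parallel G4 P, and optionally a protein-bound state BD) as a
continuous-time Markov chain; the camera integrates state-dependent FRET
emission over 100-ms frames with additive Gaussian channel noise; fluorophores
photobleach in a single step with an exponential lifetime. A configurable
fraction of molecules is "docked": frozen in one conformation for the whole
recording, mirroring the static subpopulation seen in real recordings.

Construct presets encode the four telomeric repeat variants studied by
smFRET (TelG5 and its TAA/TTT/TT loop variants): per-state mean dwell times
on the seconds scale and a branching pattern that is unfolding-mediated
(UF <-> NP, UF <-> P) for TelG5/TelG5TAA and dominated by direct NP <-> P
exchange for TelG5TTT/TelG5TT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .statepath import Segment, StatePath, occupancy_matrix
from .traces import TraceRecord, TraceSet

__all__ = [
    "KineticModel",
    "SimulationConfig",
    "TruthRecord",
    "simulate_state_path",
    "render_intensities",
    "simulate_dataset",
    "simulate_binding_curve",
    "construct_model",
    "with_bound_state",
    "FRET_ANCHORS",
    "BD_LEVEL",
    "CONSTRUCTS",
]

#: FRET efficiency of each conformation (anchor levels used throughout).
FRET_ANCHORS = {"UF": 0.24, "NP": 0.47, "P": 0.66}
#: FRET efficiency of the protein-bound state, between the NP and P levels.
BD_LEVEL = 0.57

#: Per-construct kinetic presets: mean dwell time per state (seconds) and the
#: branching probabilities of the embedded jump chain out of each state.
#: Dwell means for NP and P are the measured values for each variant; the UF
#: dwell is 4.3 s for TelG5TAA and a quarter of that for the other variants,
#: whose unfolded state is four-fold shorter-lived. Branchings encode the
#: transition-density patterns: unfolding-mediated exchange for
#: TelG5/TelG5TAA, direct NP<->P exchange for TelG5TTT/TelG5TT.
CONSTRUCTS = {
    "TelG5": {
        "dwell": {"UF": 1.1, "NP": 7.6, "P": 10.3},
        "branching": {
            "UF": {"NP": 0.65, "P": 0.35},
            "NP": {"UF": 0.90, "P": 0.10},
            "P": {"UF": 0.90, "NP": 0.10},
        },
    },
    "TelG5TAA": {
        "dwell": {"UF": 4.3, "NP": 6.1, "P": 11.1},
        "branching": {
            "UF": {"NP": 0.70, "P": 0.30},
            "NP": {"UF": 0.95, "P": 0.05},
            "P": {"UF": 0.95, "NP": 0.05},
        },
    },
    "TelG5TTT": {
        "dwell": {"UF": 1.1, "NP": 2.3, "P": 5.2},
        "branching": {
            "UF": {"NP": 0.50, "P": 0.50},
            "NP": {"UF": 0.20, "P": 0.80},
            "P": {"UF": 0.20, "NP": 0.80},
        },
    },
    "TelG5TT": {
        "dwell": {"UF": 1.1, "NP": 2.1, "P": 4.3},
        "branching": {
            "UF": {"NP": 0.50, "P": 0.50},
            "NP": {"UF": 0.15, "P": 0.85},
            "P": {"UF": 0.15, "NP": 0.85},
        },
    },
}

#: Fraction of molecules frozen ("docked") for the whole recording; the
#: complement, 0.48, is the transitioning fraction measured for TelG5.
DEFAULT_DOCKED_FRACTION = 0.52


@dataclass
class KineticModel:
    """Conformational states, per-second transition rates, FRET emission.

    ``rates[i, j]`` is the rate k(i->j) in 1/s with zero diagonal; the mean
    dwell time of state i is ``1 / rates[i].sum()``. ``emission_mean`` and
    ``emission_sd`` give the FRET level and its molecular spread per state.
    ``docked_fraction`` of molecules are generated with all rates zeroed,
    frozen in a state drawn from the stationary distribution.
    """

    states: tuple
    rates: np.ndarray
    emission_mean: np.ndarray
    emission_sd: np.ndarray = None
    docked_fraction: float = 0.0

    def __post_init__(self):
        self.states = tuple(self.states)
        n = len(self.states)
        if n < 1:
            raise ParameterError("need at least one state")
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (n, n):
            raise ParameterError(f"rates must be {n}x{n}")
        if np.any(self.rates < 0):
            raise ParameterError("transition rates must be non-negative")
        if np.any(np.diag(self.rates) != 0):
            raise ParameterError("rate matrix diagonal must be zero")
        self.emission_mean = np.asarray(self.emission_mean, dtype=float)
        if self.emission_mean.shape != (n,):
            raise ParameterError("one emission mean per state required")
        if np.any(self.emission_mean < -0.2) or np.any(self.emission_mean > 1.2):
            raise ParameterError("emission means must lie in [-0.2, 1.2]")
        if self.emission_sd is None:
            self.emission_sd = np.full(n, 0.05)
        self.emission_sd = np.broadcast_to(
            np.asarray(self.emission_sd, dtype=float), (n,)
        ).copy()
        if np.any(self.emission_sd < 0):
            raise ParameterError("emission spread must be non-negative")
        if not 0 <= self.docked_fraction <= 1:
            raise ParameterError("docked_fraction must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def exit_rates(self) -> np.ndarray:
        return self.rates.sum(axis=1)

    @property
    def mean_dwell(self) -> dict:
        """Mean dwell time 1/sum_j k(i->j) per state (inf for frozen states)."""
        with np.errstate(divide="ignore"):
            dwell = 1.0 / self.exit_rates
        return dict(zip(self.states, dwell))

    @property
    def generator(self) -> np.ndarray:
        """CTMC generator Q (off-diagonal rates, rows summing to zero)."""
        return self.rates - np.diag(self.exit_rates)

    def stationary_distribution(self) -> np.ndarray:
        """Equilibrium occupancy pi solving pi Q = 0, or uniform if undefined."""
        n = self.n_states
        uniform = np.full(n, 1.0 / n)
        if n == 1 or np.all(self.rates == 0):
            return uniform
        A = np.vstack([self.generator.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.any(pi < -1e-9) or abs(pi.sum() - 1) > 1e-6:
            return uniform
        resid = np.abs(self.generator.T @ pi).max()
        if resid > 1e-8 * max(self.exit_rates.max(), 1.0):
            return uniform
        return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()

    def emission_centers(self) -> dict:
        return dict(zip(self.states, self.emission_mean))

    def transition_flux_fractions(self) -> dict:
        """Expected long-run fraction of transitions of each ordered type.

        Flux i->j is proportional to pi_i * k(i->j); used as the analytic
        oracle for transition-density and direct-transition statistics.
        """
        pi = self.stationary_distribution()
        flux = pi[:, None] * self.rates
        total = flux.sum()
        if total == 0:
            return {}
        return {
            (self.states[i], self.states[j]): flux[i, j] / total
            for i in range(self.n_states)
            for j in range(self.n_states)
            if self.rates[i, j] > 0
        }


def construct_model(
    name: str,
    emission_sd: float = 0.05,
    docked_fraction: float = DEFAULT_DOCKED_FRACTION,
) -> KineticModel:
    """Kinetic preset for one of the telomeric repeat variants.

    ``name`` is one of ``TelG5``, ``TelG5TAA``, ``TelG5TTT``, ``TelG5TT``.
    """
    if name not in CONSTRUCTS:
        raise ParameterError(
            f"unknown construct {name!r}; choose from {sorted(CONSTRUCTS)}"
        )
    spec = CONSTRUCTS[name]
    states = ("UF", "NP", "P")
    n = len(states)
    rates = np.zeros((n, n))
    for i, si in enumerate(states):
        exit_rate = 1.0 / spec["dwell"][si]
        for j, sj in enumerate(states):
            if si != sj:
                rates[i, j] = exit_rate * spec["branching"][si].get(sj, 0.0)
    means = np.array([FRET_ANCHORS[s] for s in states])
    return KineticModel(
        states=states,
        rates=rates,
        emission_mean=means,
        emission_sd=emission_sd,
        docked_fraction=docked_fraction,
    )


def with_bound_state(
    model: KineticModel,
    k_on_np: float = 0.08,
    k_on_p: float = 0.08,
    bd_dwell: float = 3.0,
    bd_level: float = BD_LEVEL,
    bd_sd: float | None = None,
) -> KineticModel:
    """Extend a 3-state model with a protein-bound (BD) fourth state.

    The BD state is entered from NP and P with rates ``k_on_np`` and
    ``k_on_p`` (1/s) — binding is seen right after NP<->P exchange — and left
    with rate ``1/bd_dwell``, releasing back to NP and P with equal weight.
    """
    if "BD" in model.states:
        raise ParameterError("model already has a BD state")
    if bd_dwell <= 0:
        raise ParameterError("bd_dwell must be positive")
    n = model.n_states
    rates = np.zeros((n + 1, n + 1))
    rates[:n, :n] = model.rates
    states = model.states + ("BD",)
    idx = {s: i for i, s in enumerate(states)}
    rates[idx["NP"], n] = k_on_np
    rates[idx["P"], n] = k_on_p
    k_off = 1.0 / bd_dwell
    rates[n, idx["NP"]] = k_off / 2
    rates[n, idx["P"]] = k_off / 2
    sd = bd_sd if bd_sd is not None else float(np.median(model.emission_sd))
    return KineticModel(
        states=states,
        rates=rates,
        emission_mean=np.append(model.emission_mean, bd_level),
        emission_sd=np.append(model.emission_sd, sd),
        docked_fraction=model.docked_fraction,
    )


@dataclass
class SimulationConfig:
    """Recording conditions for a synthetic dataset.

    Defaults emulate the study conditions: 200-s movies at 100 ms per frame,
    ~1000 camera units of total fluorescence, additive Gaussian channel noise
    of 60 units, no photobleaching unless ``bleach_lifetime`` is set.
    Identical configs (including ``seed``) produce bit-identical datasets.
    """

    model: KineticModel
    n_molecules: int = 100
    duration: float = 200.0
    frame_interval: float = 0.1
    total_intensity: float = 1000.0
    intensity_noise_sd: float = 60.0
    bleach_lifetime: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ParameterError("n_molecules must be >= 1")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")
        if self.duration < self.frame_interval:
            raise ParameterError("duration must cover at least one frame")
        if self.bleach_lifetime is not None and self.bleach_lifetime <= 0:
            raise ParameterError("bleach_lifetime must be positive or None")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))


@dataclass
class TruthRecord:
    """Simulator ground truth for one molecule."""

    path: StatePath
    docked: bool
    bleach_frame: int | None


def simulate_state_path(
    model: KineticModel,
    duration: float,
    rng: np.random.Generator,
    molecule_id: str = "sim",
    initial_state: str | None = None,
) -> StatePath:
    """Sample a continuous-time Markov path tiling [0, duration] exactly.

    Waiting times are exponential with the state's exit rate; the jump target
    is categorical with probability proportional to k(i->j). The initial
    state is drawn from the equilibrium (stationary) distribution when it
    exists, uniformly otherwise. A state with zero exit rate holds to the end
    of the recording.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if initial_state is None:
        pi = model.stationary_distribution()
        state = int(rng.choice(model.n_states, p=pi))
    else:
        state = model.states.index(initial_state)
    exit_rates = model.exit_rates
    segments = []
    t = 0.0
    while t < duration:
        r = exit_rates[state]
        dwell = duration - t if r == 0 else rng.exponential(1.0 / r)
        end = min(t + dwell, duration)
        segments.append(Segment(model.states[state], t, end))
        t = end
        if t >= duration:
            break
        state = int(rng.choice(model.n_states, p=model.rates[state] / r))
    return StatePath(
        molecule_id=molecule_id,
        segments=segments,
        source="simulated",
        emission_centers=model.emission_centers(),
    )


def render_intensities(
    path: StatePath,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TraceRecord:
    """Render a state path into camera-integrated donor/acceptor intensities.

    Per frame, the FRET level is the occupancy-weighted mean over the frame
    (so a frame spanning a jump is blurred, as a real camera blurs it), plus
    per-state molecular jitter with spread ``emission_sd``. Channels are
    ``donor = I(1-E) + noise`` and ``acceptor = I*E + noise`` with independent
    Gaussian noise of sd ``intensity_noise_sd``. If ``bleach_lifetime`` is
    set, an exponential bleach time is drawn and both channels carry noise
    only from the first bleached frame, recorded as ``bleach_frame``.
    """
    model = config.model
    dt = config.frame_interval
    if path.duration < dt - 1e-12:
        raise ParameterError("path shorter than one frame")
    n_frames = int(round(path.duration / dt))
    W = occupancy_matrix(path, n_frames, dt, list(model.states))
    e_bar = W @ model.emission_mean
    # independent per-state jitter integrates to one Gaussian per frame
    jitter_sd = np.sqrt((W**2) @ (model.emission_sd**2))
    eff = e_bar + rng.standard_normal(n_frames) * jitter_sd
    total = config.total_intensity
    donor = total * (1.0 - eff)
    acceptor = total * eff
    bleach_frame = None
    if config.bleach_lifetime is not None:
        t_bleach = rng.exponential(config.bleach_lifetime)
        first_dark = int(np.floor(t_bleach / dt)) + 1  # 1-based
        if first_dark <= n_frames:
            bleach_frame = first_dark
            donor[first_dark - 1 :] = 0.0
            acceptor[first_dark - 1 :] = 0.0
    sd = config.intensity_noise_sd
    if sd > 0:
        donor = donor + rng.normal(0.0, sd, n_frames)
        acceptor = acceptor + rng.normal(0.0, sd, n_frames)
    return TraceRecord(
        molecule_id=path.molecule_id,
        donor=donor,
        acceptor=acceptor,
        frame_interval=dt,
        bleach_frame=bleach_frame,
    )


def simulate_dataset(config: SimulationConfig, manifest: dict | None = None) -> TraceSet:
    """Simulate a full trace set with ground truth in ``TraceSet.truth``.

    Exactly ``floor(docked_fraction * n_molecules)`` molecules (the first
    ones, for determinism) are docked: frozen in a state drawn from the
    stationary distribution, with all transition rates zeroed.
    """
    model = config.model
    n = config.n_molecules
    n_docked = int(np.floor(model.docked_fraction * n))
    pi = model.stationary_distribution()
    children = np.random.SeedSequence(config.seed).spawn(n)
    width = max(4, len(str(n)))
    traces, truth = [], {}
    for i in range(n):
        rng = np.random.default_rng(children[i])
        mol = f"mol{i:0{width}d}"
        docked = i < n_docked
        if docked:
            state = model.states[int(rng.choice(model.n_states, p=pi))]
            path = StatePath(
                molecule_id=mol,
                segments=[Segment(state, 0.0, config.duration)],
                source="simulated",
                emission_centers=model.emission_centers(),
            )
        else:
            path = simulate_state_path(model, config.duration, rng, molecule_id=mol)
        trace = render_intensities(path, config, rng)
        traces.append(trace)
        truth[mol] = TruthRecord(
            path=path, docked=docked, bleach_frame=trace.bleach_frame
        )
    base = {
        "construct": getattr(model, "construct", "synthetic"),
        "n_molecules": str(n),
        "seed": str(config.seed),
        "frame_interval": repr(config.frame_interval),
    }
    if manifest:
        base.update(manifest)
    return TraceSet(traces=traces, manifest=base, truth=truth)


def simulate_binding_curve(
    kd: float,
    bmax: float,
    concentrations,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    construct: str = "synthetic",
):
    """Bound fraction Y = Bmax*X/(Kd+X) with additive noise, clipped to [0, 1].

    ``kd`` and ``concentrations`` are in nM. Returns a
    :class:`quadfret.binding.BindingCurve` carrying the noisy titration.
    """
    from .binding import BindingCurve  # local import avoids a cycle

    if kd <= 0:
        raise ParameterError("kd must be positive")
    x = np.asarray(concentrations, dtype=float)
    if np.any(x < 0):
        raise ParameterError("concentrations must be non-negative")
    y = bmax * x / (kd + x)
    if noise_sd > 0:
        if rng is None:
            raise ParameterError("rng required when noise_sd > 0")
        y = np.clip(y + rng.normal(0.0, noise_sd, x.size), 0.0, 1.0)
    return BindingCurve(construct=construct, concentrations=x, bound_fraction=y)
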