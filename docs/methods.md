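# Methods

`quadfret` analyzes single-molecule FRET recordings of telomeric
G-quadruplex (G4) DNA: per-molecule donor/acceptor intensity time series in
which the FRET efficiency reports which conformation the molecule occupies —
unfolded (UF, E ≈ 0.24), non-parallel G4 (NP, E ≈ 0.47), parallel G4
(P, E ≈ 0.66) — and, when the BRCA2 OB-fold domain is present, a bound state
(BD, E ≈ 0.57) between the two folded levels. This note describes the models
and estimators, the synthetic-data generator that provides ground truth, the
numerical choices, and the known limitations.

## The kinetic model

Conformational dynamics are modeled as a continuous-time Markov chain
(CTMC): state `i` is left at rate `r_i = Σ_j k(i→j)` (mean dwell
`τ_i = 1/r_i`, exponential dwell times), and the jump goes to `j` with
probability `k(i→j)/r_i`. Equilibrium occupancy `π` solves `πQ = 0` with
`Q` the generator. The four construct presets encode the telomeric repeat
variants studied by smFRET, using their measured per-state mean dwells (in
seconds) and a branching pattern consistent with their transition-density
signatures:

| construct  | τ(UF) | τ(NP) | τ(P) | exchange pattern |
|------------|------|------|------|------------------|
| TelG5      | 1.1  | 7.6  | 10.3 | unfolding-mediated (UF↔NP, UF↔P) |
| TelG5TAA   | 4.3  | 6.1  | 11.1 | unfolding-mediated, strongest    |
| TelG5TTT   | 1.1  | 2.3  | 5.2  | direct NP↔P dominant             |
| TelG5TT    | 1.1  | 2.1  | 4.3  | direct NP↔P dominant             |

The UF dwell is only characterized for TelG5TAA (4.3 s, four-fold longer
than the other variants); the other presets use 1.1 s. The branching
probabilities (e.g. NP exits 90% to UF for TelG5, 80% directly to P for
TelG5TTT) are design choices that reproduce the qualitative transition
density of each variant; the published ensemble conformational fractions
are *not* imposed, because ensemble fractions mix the static and dynamic
subpopulations and are not jointly realizable with the dwell means in a
single 3-state chain. The stationary fractions implied by the presets
(TelG5: UF 10%, NP 49%, P 40%) are close to, but not identical with, the
measured ensemble fractions.

Protein binding is modeled by `with_bound_state`: a fourth Markov state
entered from NP and P (default 0.08 s⁻¹ each, mean bound dwell 3 s,
released to NP and P with equal weight), reflecting the observation that
binding occurs in the middle of NP↔P exchange. At the defaults this puts
~18% of equilibrium occupancy in BD.

## The camera model

Recordings are rendered at 100 ms per frame for 200-s movies (long movies
for trajectories) or 2-s movies (histograms). Per frame the FRET level is
the occupancy-weighted average over the frame — a frame spanning a jump is
blurred, as a real integrating camera blurs it — plus per-state molecular
jitter with spread `emission_sd` (default 0.05 FRET units, chosen to match
the visual width of measured histogram peaks). Channels are
`donor = I(1−E) + ε`, `acceptor = I·E + ε` with total intensity
`I = 1000` camera units and independent Gaussian noise of 60 units per
channel, giving an effective per-frame FRET noise of ≈ 0.065 including
jitter. Photobleaching, when enabled, is single-step with an exponential
lifetime; both channels drop to noise-only afterwards. A configurable
docked fraction (default 0.52, matching the measured 48% transitioning
fraction for TelG5) freezes molecules in a state drawn from the stationary
distribution. No shot-noise, blinking, or spectral-crosstalk dynamics are
modeled; these are explicit swap-in points.

What passing tests show, and what they do not: recovery results on this
generator demonstrate correctness of the estimators under Markovian
dynamics, Gaussian noise, and single-step bleaching. Real recordings add
baseline drift, aperiodic blinking, heterogeneous intensities, and
non-Markovian kinetics, none of which are exercised here.

## FRET efficiency and histograms

Efficiency is the corrected acceptor fraction
`E = (A − l·D) / (γ·D + A − l·D)` with donor leakage `l` and detection
factor `γ` defaulting to 0 and 1 (no correction, `E = A/(D+A)`), since no
correction protocol is part of the analyzed computation. Frames at or past
the bleach index are excluded; the bleach index is found by a single-step
detector on the median-smoothed total intensity (first frame below 30% of
the initial median that stays below; traces are truncated, not discarded).

Ensemble histograms pool the first 2 s of every molecule (frame pooling:
each frame weighs equally; molecule-weighting is not implemented), binned
at 0.025 FRET units over [−0.2, 1.2] — fine enough to resolve peaks 0.1
apart with ≥5 bins per peak width — and normalized to unit area.

## Anchored Gaussian decomposition

Histograms are decomposed by nonlinear least squares into a sum of
Gaussians. Components representing known conformations are *anchored*:
their centers are constrained within `anchor_tolerance` (default 0.01; 0
fixes them) of the anchor level. Populations are relative component areas.
The fit is deterministic: fixed initialization (anchored centers at their
anchors, heights at the local density, widths at 0.05), fixed optimizer
settings, no random restarts.

Free components (for emerging peaks such as BD) are initialized at the
largest positive residual of the anchored-only fit. Because the BD level
(0.57) sits between NP (0.47) and P (0.66) while the effective peak width
is ≈ 0.066, a fully free four-component fit is ill-conditioned: the free
component can trade mass with a neighbouring anchored peak. The documented
protocol for a perturbed condition is therefore to fit the reference
(protein-free) histogram first and pass it as `reference`: anchored
components inherit the reference widths, the free component carries the
reference's median width, and anchored centers are fixed (tolerance 0).
This recovers the bound population well, but the free *center* of the
absolute fit still inherits a small systematic shift (~0.01) from residual
structure — camera blur between peaks and finite-sample shape errors —
that is common to both conditions.

The emerging-peak *position* is therefore estimated from the differential
histogram (`locate_emerging_peak`): the density difference is decomposed
into one free gain Gaussian minus non-negative losses pinned at the
reference components, so the shared misfit cancels. This mirrors the
experimental practice of reading a new bound-state peak off the
differential density and locates a planted 0.57 peak within ≈ 0.01 at
bound occupancies down to ~18%.

Differential histograms subtract per-bin densities on identical bins (no
silent rebinning). The positive differential sum estimates newly populated
density; peak overlap hides part of the bound mass, so it is a lower-bound
proxy, monotone in the true bound fraction.

## Trajectory classification and segmentation

A molecule is *transitioning* if its first 100 s contain a FRET level
change exceeding both `min_jump = 0.1` and a noise-adaptive threshold
(4.5× the standard error of a 1-s block-mean difference, with the
per-frame noise scale estimated robustly from the median absolute
successive difference). This automates a split that is often done by eye,
and is deterministic.

Transitioning trajectories are segmented by Gaussian-emission hidden
Markov models fitted by expectation-maximization for each state count
K in 2..4, plus a static K = 1 candidate. Initialization is deterministic
(means at E-quantiles, falling back to an even spread when quantiles
collide; shared variance; sticky transitions at 0.9) with a variance floor
of 1e-4 shared by all candidates. K is selected by BIC; fitted states
closer than 0.02 in mean are merged. The Viterbi path is collapsed into
segments, and segments shorter than `min_segment_frames = 2` frames are
treated as camera blur and absorbed into the neighbour with the closer
emission mean. Inferred states are named by the nearest anchor (ties to
the lower level; farther than 0.08 from every anchor → "other").

## Transition and dwell statistics

Transition density plots bin (emission center before, after) at each
segment boundary, normalized to unit mass; coordinates use inferred
centers, giving the discrete cluster structure standard for such plots.
Transition counts keep the six ordered types among UF/NP/P separate from
any BD- or "other"-involving pairs.

Dwell tables flag the first and last segment of each trace as censored
(their durations are cut by the observation window) and exclude them from
means. Raw segment means are biased high for short-lived states by two
detection effects: truncation (dwells shorter than the 2-frame dead time
are never seen; survivors of an exponential average `c + τ` rather than
`τ`) and fusion (an undetected short excursion to another state
concatenates the two flanking dwells). `corrected_dwell_means` removes
both with an iterated plug-in renewal correction computed from the
observed means and the branching probabilities of the embedded jump chain
— no external information. With the 0.2-s dead time the correction is a
few percent for seconds-scale dwells and essential below ~2 s.

The direct-transition statistic is
`fraction_transitioning × (N(NP→P) + N(P→NP)) / N(six core types)`,
0 when nothing transitions. BD-involving transitions are excluded from the
denominator because the statistic characterizes protein-free dynamics. It
is bounded by the transitioning fraction, with equality iff every
transition is direct.

## Binding regression

Bound fractions (pre-quantified band intensities; densitometry is
upstream) are fitted to the one-site specific binding equation
`Y = Bmax·X/(K_d + X)` with Bmax fixed to 1 by default. Concentrations are
nM internally (µM accepted with conversion). Initialization is
deterministic (K_d starts at the concentration nearest half the maximum
response); uncertainty is the asymptotic standard error, with a
replicate-level mean/SD utility for cross-experiment aggregation. Relative
binding tables normalize intensities to a reference construct and are
scale-invariant; the dynamics–binding comparison inner-joins per-construct
direct-transition density with relative binding and reports a Kendall rank
correlation, encoding no causal claim.

## Problem sizes and tolerances

The test and acceptance workloads use: 2000 molecules × 2-s movies for
histogram decomposition (population recovery within 3 percentage points;
free-peak center within 0.01); 100–200 molecules × 200-s movies per
construct for segmentation benchmarks (≥95% frame accuracy; corrected
dwell means within 10%, averaged over 3 seeded datasets); 2000 molecules
for the docked/transitioning split (±0.03); 200 noisy replicates for the
K_d bias check (<10% median bias, noise sd 0.05). The acceptance script
runs one seeded dataset per construct at 120 molecules, which recovers
dwell means to within roughly the same tolerance with proportionally wider
sampling error.

## Known limitations

* The HMM assumes Gaussian emissions with state-independent noise; strongly
  intensity-dependent noise would bias state widths.
* Dwell corrections assume exponential dwells (Markovian exits); stretched
  or multi-exponential kinetics would be over-corrected.
* The classifier's adaptive threshold assumes the noise scale is estimable
  from successive differences, i.e. transitions are rare at the frame
  scale; ultra-fast exchange (dwells ≲ 2 frames) reads as noise.
* Leakage/γ corrections are hooks, not calibrations: no alternating-laser
  excitation model is included, so dual-labeling is assumed upstream.
* The bound-state model is a single extra Markov state; cooperative or
  multi-step binding is out of scope, as are Hill/competition binding
  models.
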