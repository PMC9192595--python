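# quadfret

Single-molecule FRET analysis of telomeric G-quadruplex (G4) conformational
dynamics and protein binding.

Telomeric G-rich repeats fold into G-quadruplexes that interconvert between
an unfolded form (UF, FRET efficiency E ≈ 0.24), a non-parallel fold
(NP, E ≈ 0.47) and a parallel fold (P, E ≈ 0.66); a protein such as the
BRCA2 OB-fold domain binds intermediates of the NP↔P rearrangement and shows
up as a fourth FRET level (BD, E ≈ 0.57). `quadfret` takes per-molecule
donor/acceptor intensity time series (100-ms frames, plain TSV) and carries
out the complete analysis used to characterize such systems:

* **FRET histograms** — `E = A/(D+A)` (optional leakage/γ correction),
  2-s windows pooled over thousands of molecules, decomposed into Gaussian
  components with centers *anchored* at the known conformational levels
  (`Y(E) = Σ_k a_k exp(−(E−μ_k)²/2σ_k²)`, |μ_k − anchor_k| ≤ tol);
  populations are relative component areas. Differential histograms and an
  emerging-peak estimator localize a new bound-state peak.
* **Trajectory kinetics** — automated docked/transitioning classification,
  Gaussian-HMM segmentation with BIC selection over K = 2..4 states,
  transition density plots, dwell-time tables with censoring and
  dead-time-corrected mean dwells, and the NP–P direct-transition density
  `f_trans · (N(NP→P)+N(P→NP)) / N(transitions)` that tracks protein
  binding across sequence variants.
* **Binding** — one-site regression `Y = Bmax·X/(K_d+X)` (Bmax = 1 by
  default) with asymptotic uncertainties, relative-binding tables, and the
  dynamics-vs-binding rank comparison.
* **Synthetic data** — a continuous-time Markov trajectory generator with
  camera integration, Gaussian channel noise, single-step photobleaching,
  a docked subpopulation, and presets for the four characterized telomeric
  variants (TelG5, TelG5TAA, TelG5TTT, TelG5TT); every dataset carries its
  ground truth, so all estimators are testable end to end.

See `docs/methods.md` for the models, estimators and their assumptions.

## Worked example

```python
import numpy as np
import quadfret as qf

# simulate a TelG5-like experiment: 48% of molecules transition
model = qf.construct_model("TelG5")                  # UF/NP/P rate matrix
config = qf.SimulationConfig(model=model, n_molecules=300, duration=200.0, seed=1)
dataset = qf.simulate_dataset(config)

# histogram + anchored mixture
trajs = [qf.compute_fret(t) for t in dataset]
hist = qf.build_histogram(trajs, window=2.0)
fit = qf.fit_mixture(hist, qf.FRET_ANCHORS)          # {"UF":0.24,"NP":0.47,"P":0.66}
print(fit.summary())

# classification, segmentation, dwell/transition statistics
result = qf.analyze_paths(trajs, qf.FRET_ANCHORS, label="TelG5")
print(result["summary"].summary())
print({s: round(v, 1) for s, v in result["dwell_means"].items()})
```

prints

```
Anchored Gaussian mixture fit
==========================================================
component       center        sd    population    anchor
----------------------------------------------------------
UF              0.2380    0.0599        0.1090     0.240
NP              0.4674    0.0661        0.5084     0.470
P               0.6604    0.0708        0.3826     0.660
----------------------------------------------------------
residual (SSR of density): 0.0563783
TelG5: 145/300 molecules transitioning (fraction 0.483), NP-P direct transition density 0.0524
{'NP': 7.4, 'P': 9.6, 'UF': 1.1}
```

The mixture populations recover the planted equilibrium occupancies
(UF 10%, NP 49%, P 40%); 48% of the molecules transition, as planted; the
corrected mean dwells recover the preset values (UF 1.1 s, NP 7.6 s,
P 10.3 s) within sampling error; and the direct-transition density is low
for TelG5, whose NP↔P exchange runs through unfolding.

A K_d fit from a titration table:

```python
x = np.array([0, 5, 10, 20, 50, 100, 200, 500, 1000.0])   # nM
res = qf.OneSiteBindingModel(x, x / (456.0 + x), construct="TelG5TTT").fit()
print(res.summary())
# Kd    = 456 nM  (s.e. 7.27e-13 nM)   (Bmax fixed to 1)
```

## Command line

```sh
quadfret simulate  --construct TelG5 --n 300 --seed 1 --out traces.tsv
quadfret histogram --traces traces.tsv --anchors UF=0.24,NP=0.47,P=0.66 --out hist/
quadfret kinetics  --traces traces.tsv --k-range 2:4 --out kin/
quadfret binding   --curve titration.tsv --out kd.tsv
quadfret report    --kinetics kin/summary.tsv ... --binding folds.tsv --out paired.tsv
```

All commands are deterministic given their inputs and seed; outputs are
plain TSV tables.

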