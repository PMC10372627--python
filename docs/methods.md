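# Methods

## Kinetic model

Each DNA molecule is a continuous-time Markov chain over labeled pathway
states (`licfret.schemes.KineticScheme`). Trajectories are simulated
exactly with the Gillespie algorithm and only then integrated into camera
frames, so ground-truth event times carry no discretization bias. Terminal
states are absorbing; per-variant schemes share the same building blocks:

| parameter | default | units | meaning / rationale |
|---|---|---|---|
| k_off,bent | 0.01074 | s⁻¹ | ORC release from the bent (high-FRET) state |
| k_off,unbent | 0.4832 | s⁻¹ | 45× faster release from the unbent state |
| k_unbend (ORC) | 0.0050251 | s⁻¹ | bent→unbent fluctuation |
| k_rebend (ORC) | 0.5168 | s⁻¹ | unbent→bent; mean unbent visit 1 s |
| Cdc6 factor | 0.0073/0.0131 | — | scales both off-rates; bend equilibrium untouched |
| k_unbend (OCCM) | 1/3.9 | s⁻¹ | Mcm2-7-arrival-triggered unbending delay |
| k_deposit | 1.0 | s⁻¹ | unbending→deposition, so arrival→deposition means 4.9 s |
| k_Cdc6_release | 0.05 | s⁻¹ | deposition→Cdc6 release (free knob) |
| k_slide_onset | 0.05 (WT), 0.005 (ATPase-RA) | s⁻¹ | gated strictly behind Cdc6 release |
| k_Cdt1_release | 0.02 | s⁻¹ | sliding→Cdt1 release (free knob) |
| k_arrival (ORC / Mcm2-7) | 0.02 / 0.03 | s⁻¹ | colocalization onset rates |

**Why these bend-fluctuation rates.** The observable the assay measures is
events per unit bound time, which by renewal-reward equals
Σ (state time-fraction) × (state off-rate) **computed on the absorbing
chain**, not on the bend equilibrium alone. With the off-rates above and
the requirement that a bound dwell truly spends 0.5% of its time unbent,
k_unbend and k_rebend are solved so that the mean bound dwell is exactly
1/0.0131 s (0.995·0.01074 + 0.005·0.4832 = 0.01310 s⁻¹). A naive
equilibrium weighting (k_unbend/(k_unbend + k_rebend) = 0.005) misses both
targets by ~10% because release from the unbent state truncates unbent
visits. The 1-s mean unbent visit is a modeling choice: fast enough to be
a rare excursion, slow enough to appear in records at sub-second frame
intervals. Unbending/deposition delays are single-exponential — the
simplest kinetics matching the two printed means; multi-step (Erlang)
delays would narrow the interval distributions but leave the means, and
all recovery results here, unchanged.

## Sliding and dye-pair geometry

After onset, the complex performs an unbiased reflected random walk
(default D = 100 bp²/s, bounds −300…+1100 bp — the DNA extent; both are
free knobs, not measured values). FRET follows
E(r) = 1/(1 + (r/R₀)⁶), R₀ = 6 nm, with r combining the in-axis dye
separation (0.34 nm/bp on straight DNA) and the protein label's axial
offset in quadrature. The Mcm3-N label's axial offset is 5.63 nm (on the
N-tier of the ~13 nm hexamer): the deposited state at ~4 bp lateral
separation from the +51 dye then reads E = 0.55, the closest sliding
approach caps at E ≈ 0.6, and E ≈ 0 beyond ~30 bp (>10 nm). A small
(2 nm) offset would instead let a sliding hexamer crossing the dye emit
E ≈ 1 transients — a regime the deposited-state pair never shows — which
measurably corrupts two-component mixture fits. The ORC-N label uses
5.64 nm for the same reason (ACS-engaged E = 0.60 against the −4 dye).
Fixed-geometry states take their E directly from the scheme's
`efret_map` (bent 0.62 / unbent 0.05 for ORC•+51; pre-deposition 0.12 /
deposited 0.55 for MCM•+51 — the published fit centers).

## Photophysics and rendering

Per frame, state occupancy is integrated exactly over the exposure; donor
emission splits between donor and acceptor channels by the occupancy-
weighted E (quencher variants scale donor emission by 1 − q, q = 0.8, and
carry no FRET channel). Photobleaching is single-step with exponential
waiting times (defaults 10⁻⁴ s⁻¹ per dye; donor clock starts at protein
arrival, DNA-acceptor clock at time zero); frames after a bleach are
masked invalid. Noise is additive Gaussian per channel per frame
(SD 140 counts against a total brightness of 1000 counts/frame), giving a
measured E_FRET SD of ≈ 0.10 in the high-FRET states, comparable to the
published histogram widths. Shot noise, blinking and spectral crosstalk
are deliberately not modeled. A molecule is `colocalized` in a frame when
it is bound for more than half the exposure. Alternating excitation is
rendered at one value per excitation cycle; `frame_dt` is the cycle time.

Nonspecific binders (default 2% where enabled) reuse the variant's
kinetics with the high-FRET states' E replaced by the low value — they
colocalize but never show the bent/deposited signature.

## Analysis conventions

* **E_FRET**: A_em/(D_em+A_em) under donor excitation, clipped to [0, 1];
  frames failing colocalization, dye validity, or a total-emission floor
  are invalid. The floor defaults to 3× the per-channel background SD.
  This matters: a floor near the bound-state total (e.g. 6×SD here)
  silently conditions kept frames on upward noise fluctuations, biasing
  low-state E up by ~+0.025 and thinning rate denominators by ~20%.
* **State calling**: a frame is high iff E ≥ threshold; thresholds come
  from the trough (interior density minimum) of a two-component mixture
  fit, located by bounded 1-D minimization between the centers. For
  *transition timing* a state change needs ≥ 2 consecutive frames on the
  new side (timestamp = first frame of the persistent run; shorter
  excursions inherit the prior state; invalid frames neither break nor
  extend runs). For *release-frequency* counting, frames keep their raw
  per-frame labels — persistence smoothing would erase the ~1-s unbent
  excursions entirely — and invalid frames inside a dwell inherit the
  previous label so events/frames stays consistent.
* **Per-state release rates**: the state of frame *n* decides which state
  a release detected at frame *n+1* (colocalization loss with dyes still
  reporting) is charged to; rate = events/frames/frame_dt with binomial
  SE, a rule-of-three bound for zero events, and no −ln(1−p) correction
  (<1% at these rates; available as an option). Bleach-terminated and
  end-of-recording dwells are censored. The nonspecific screen uses a
  4-frame high-run requirement rather than the 2 frames used for timing:
  it classifies whole molecules, and at these noise levels a pair of
  flipped frames would otherwise rescue ~30% of long-dwell nonspecific
  binders, each polluting the rare low state with ~100 event-free frames.
* **Unquenching detector**: a candidate needs the next-two-frame mean to
  exceed the previous-two-frame mean by 2× and by ≥ 3 robust noise SDs,
  both new frames above the midpoint of the step, and the elevated level
  to persist (4-frame confirmation ≥ 75% of the step). The persistence
  rejects single-frame spikes; the confirmation rejects transient noise
  excursions in molecules that never unbend. The amplitude criterion is
  this package's substitute for an unpublished one.
* **Dwell statistics**: means ± SEM over observed intervals; survival and
  cumulative curves by the Kaplan–Meier product-limit estimator
  (censoring-aware), 95% CIs by seeded nonparametric bootstrap over
  molecules (default 1000 resamples) — also valid for cumulative curves,
  unlike Greenwood's formula.
* **Mixture fits**: maximum-likelihood Gaussian mixtures (EM; 10 seeded
  restarts, ties broken by log-likelihood then lowest first center;
  center SEs by 200-resample bootstrap). The global variant shares
  centers across groups with per-group weights/widths on the pooled
  likelihood; groups under 10×components are tied to pooled parameters.
  Component SDs are capped at 0.2: an E_FRET state does not have a 0.35
  spread on a [0,1] observable, and an uncapped component degenerates
  into a collector for the few bridge frames (transition straddles,
  sliding transients) that belong to no state, dragging the shared
  centers. Model order (1 vs 2) is the caller's choice, per experiment.
* **Heat maps**: Gaussian kernel (SD 5 s × 0.05 E) evaluated on a
  1 s × 0.005 grid, then each time slice renormalized to integrate to 1
  over E among molecules still visible (visibility = the molecule's
  valid-frame span, padded to whole frames); fraction-bound with a
  normal-approximation binomial CI. Time windows are half-open
  [start, end) to prevent double counting.
* **Ordering**: signed interval = t(target) − t(ref), positive when the
  reference precedes; same-frame ties are zero and reported separately
  from strict signs. Histogram bins are integer frame multiples with one
  edge at zero; a zero interval falls in the first nonnegative bin.

## Determinism

A master seed spawns per-molecule seed sequences (path, sliding, and
rendering seeds per molecule) and seeds every stochastic analysis step
(EM restarts, bootstraps), so a dataset + analysis rerun is byte-identical.
All derived seeds stay below 2³¹.

## What the simulator does and does not establish

The generator emulates the trace-level phenomenology — state-dependent
FRET, quenching, ordered events, diffusive sliding, bleaching, Gaussian
noise — under exactly known kinetics, so passing recovery tests shows the
*analysis chain* is unbiased at realistic noise and frame intervals. It
does not establish robustness to what real recordings add: photon
(Poisson) statistics, blinking, baseline drift, stage drift and
registration error, heterogeneous brightness between molecules, second-
hexamer recruitment, or MO-complex geometry. Conclusions about real data
should lean on the conventions being identical, not on the noise model
being complete.

## Known limitations

* **Per-state rates at coarse frame intervals.** With a ~1-s unbent
  lifetime, the frame-n/frame-n+1 estimator attenuates the fast state's
  rate by roughly e^−(k_rebend+k_off,unbent)·Δt plus noise dilution: at
  Δt = 1 s the recovered unbent:bent ratio is ~20–25 for a generating
  ratio of 45 (~30 at Δt = 0.25 s). This is intrinsic to threshold-based
  frame counting, not an implementation artifact — recovering fast-state
  ratios ≥ 40 requires frame intervals well below the fast state's
  lifetime. The aggregate rate is insensitive to this (recovered within a
  few percent at all tested intervals).
* The Cdc6-stabilized variant scales both off-rates uniformly; its
  measured aggregate is then ~5% above 0.0073 s⁻¹ because the unbent
  occupancy shifts slightly when absorption weakens.
* Mixture centers inherit a small (+0.003…+0.005) bias from ratio noise
  and clipping at low E; within the ±0.02 recovery tolerance used here.
* The sliding-onset call (first persistent E decrease after the deposited
  state) can fire early on rare double-flip noise (~0.5% of molecules at
  2.7-s frames) and is blind to onsets after acceptor bleach.

## Problem sizes

The recovery suite and `scripts/acceptance.py` use 150–300 molecules per
condition (1000 for the per-state ratio, where low-state events are rare)
at the experiment-appropriate frame intervals (0.25, 1, 2.7 s), sizes at
which every recovered mean is several SEs from its tolerance bound while
a full run stays under a minute on one core.
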