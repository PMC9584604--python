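# Methods

`fretkin` analyzes single-molecule FRET recordings of aminoacyl-tRNA
(aa-tRNA) selection on the ribosome, of the kind used to characterize how
the eEF1A inhibitors didemnin B and ternatin-4 stall translation
elongation. It provides a generative model for such recordings, so that
every stage of the analysis can be validated by parameter recovery on
synthetic data, and the analysis chain itself: hidden-Markov trace
idealization, dwell and transition-rate estimation, dose-response fitting
and slow-timescale (sneak-through / washout) rate fitting.

## The kinetic model

The observable is the per-frame FRET efficiency between a donor on P-site
tRNA and an acceptor on the incoming eEF1A(GTP)·aa-tRNA ternary complex.
aa-tRNA selection passes through three FRET states:

| state | meaning | FRET mean |
|---|---|---|
| CR | codon recognition | 0.2 |
| GA | GTPase-activated (eEF1A docked at the GAC) | 0.45 |
| AC | accommodated (A/A, peptidyl-transferase center) | 0.7 |

Dynamics are a continuous-time Markov chain with rate matrix `k[i][j]`
(s⁻¹). The package ships three presets (`fretkin.PRESETS`): the drug-free
control and saturating didemnin / ternatin-4 conditions, parameterized by
the apparent transition rates measured for these conditions prior to the
first long high-FRET dwell. An optional zero-FRET dark state models
exponential arrival of ternary complex after stopped-flow delivery
(default hazard 0.5 s⁻¹; the delivery concentration, 20 nM, is known but
no arrival rate constant is published, so this is a package default).
Making AC absorbing (`build_scheme(..., absorb_high=True)`) models *true*
accommodation — the preset rates describe pre-accommodation dynamics, in
which AC-like excursions are transient (exit rates 15–19 s⁻¹), whereas a
genuinely accommodated complex retains high FRET.

Paths are simulated exactly (Gillespie): state *i* dwells
Exponential(k_i), exits to *j* with probability `k[i][j]/k_i`.

## Photophysics and rendering

A camera frame integrates the path over `frame_period` (15 ms for
selection experiments, 1 s for sneak-through/washout movies). The
noiseless frame value is the occupancy-time-weighted mean of state FRET
means — the choice that reproduces the partial-amplitude frames real
cameras produce at state transitions. Gaussian noise (sd
`fret_noise_sigma`) is added per frame; donor/acceptor intensities are
back-computed from a constant total intensity so that
`fret = acceptor / (acceptor + donor)` holds exactly (proximity ratio, no
gamma or crosstalk correction). Single-step photobleaching is modeled by
independent exponential clocks per fluorophore (defaults 0.1 s⁻¹ each at
15 ms framing, i.e. ~5 s mean usable trace); bleaching of either channel
ends the usable trace — no donor-only tail is modeled.

Defaults and their provenance:

* `fret_noise_sigma = 0.06` at 15 ms — chosen so state distributions have
  widths comparable to published population histograms; not a measured
  value.
* `fret_noise_sigma = 0.01` at 1 s (`simulate_slow_process`) — per-frame
  FRET noise is shot-noise dominated and scales as 1/√(integration time);
  0.06·√(0.015/1) ≈ 0.007, kept conservatively at 0.01. Reusing the 15 ms
  value at 1 s resolution would be unphysical and generates spurious
  single-frame high-FRET events (~2×10⁻⁴ per frame) that dominate true
  conversions at rates of 10⁻⁵–10⁻⁴ s⁻¹.
* Photobleaching at 1 s framing defaults to zero (the low duty cycle is
  why those movies are recorded at 1 Hz); the movie end right-censors.

What a green synthetic test does **not** establish: the generator has no
shot noise, triplet blinking, spectral crosstalk, baseline drift or
multi-step bleaching, and drug occupancy is quasi-static per molecule
(no binding/unbinding during a trace). Recovery results quantify the
analysis chain's self-consistency, not its robustness to those artifacts.

## Idealization (segmental k-means)

Traces are idealized with the segmental k-means algorithm over a
Gaussian-emission HMM: Viterbi decoding alternates with maximum-likelihood
re-estimation of the transition matrix (and, optionally, emission
parameters) from the decoded path until the path is stable (`max_iter`
100, relative log-probability tolerance 1e-6). The joint log-probability
is non-decreasing across iterations. Ties in the decoder break toward the
lower state index.

The default model has four states — dark (0.0), CR (0.2), GA (0.45),
AC (0.7) — with means fixed (the states are nominal FRET classes) and a
weakly informative start: self-transition probability 0.95, remainder
uniform, uniform initial distribution. The dark state absorbs pre-arrival
frames so they cannot corrupt CR statistics; dark dwells are excluded
from all kinetics. An optional five-state model with a hybrid-state mean
(0.25–0.4) can be constructed via `default_model(means=...)` but is not
used in the headline kinetics. Frames with non-positive summed intensity
are trimmed (trailing) or rejected (interior).

## Rate estimation

Each idealized trace is truncated at the entry into its first high-FRET
dwell lasting ≥ 150 ms (inclusive; 10 frames at 15 ms), restricting the
analysis to pre-accommodation dynamics. The transition into that dwell is
an *observed* GA→AC event and is counted; shorter high-FRET excursions
are retained in full.

Apparent rates use the count/occupancy estimator

    k_i→j = N_i→j / T_i ,   k_i = Σ_j k_i→j ,

where `N` counts idealized transitions and `T_i` is total occupancy,
censored dwells (first/last of a trace) contributing occupancy but no
exit events. On continuous dwells this is the exact CTMC maximum-
likelihood estimator. States never visited are reported missing (null),
not zero. Standard errors resample whole traces with replacement (1000
bootstrap samples by default). Derived quantities: state lifetimes
`1/k_i`, the GA→AC / GA→CR transition ratio (proofreading vs initial-
selection reversal), and empirical dwell survival curves with bootstrap
bands.

### Numerical and convention details

* Times in seconds, rates in s⁻¹, FRET dimensionless; frames 0-based;
  a dwell occupies the half-open interval [start, end).
* Thresholds (150 ms truncation, 300 ms accommodation) are inclusive and
  compared with a 1 ns slack so that 10 × 0.015 s passes exact equality.
* Transition-probability floors of 1e-12 keep the decoder finite; rows
  of a re-estimated transition matrix are renormalized after flooring.
* One top-level seed spawns per-trace substreams (`SeedSequence.spawn`),
  so trace sets are bit-reproducible and order-independent.

### Known biases (quantified on synthetic data)

* **Truncation conditioning.** Restricting to before the first ≥150 ms
  high-FRET dwell conditions every retained AC dwell to be shorter than
  150 ms, inflating the apparent AC exit rate k₃ by ~35–60% relative to
  the generating value. This is a property of the protocol itself, so
  the truth-path oracle used in tests evaluates *untruncated* paths,
  where the estimator is unbiased (verified within Monte-Carlo error for
  all presets).
* **Frame-rate-limited event detection.** High-FRET excursions average
  3–4 frames at 15 ms resolution, and ~20% are shorter than one frame.
  A frame-level decoder cannot represent sub-frame dwells: even an
  oracle that assigns every frame its true majority state recovers only
  ~74% of GA→AC events on the control preset (k_GA→AC 0.551 vs the
  generating 0.74). SKM operates essentially at this information limit
  (across-seed mean ≈ −27% on control at n = 500–2000; didemnin ≈ −33%,
  ternatin-4 ≈ −30%). Published apparent rates measured through the same
  procedure carry the same deficit, so re-measuring data *generated at*
  apparent rates double-applies it; recovered mid→high rates should be
  read with this in mind. Slower transitions (GA→CR, CR→GA) are
  recovered within ~5–15%. No missed-event correction is applied — the
  count/occupancy estimate of the idealized path is reported as-is.

## Dose-response

A molecule is *accommodated* when its trace contains ≥ 300 ms of
contiguous high FRET (inclusive; censoring ignored — observed duration
counts). `simulate_dose_series` assigns each molecule the drug-bound
scheme with Hill occupancy probability cʰ/(cʰ+IC50ʰ), else the drug-free
scheme, both with AC absorbing. The accommodated fraction vs
concentration is fitted with the four-parameter Hill equation

    f(c) = floor + (ceiling − floor) / (1 + (c/IC50)ʰ)

by least squares with multi-start initialization (log-spaced IC50 grid
over the sampled range × h ∈ {0.5, 1, 2}); floor and ceiling are fitted,
not pinned, because escape is below 100% without drug and above 0% at
saturation. All starts and bounds derive from the data, making the fit
exactly scale-equivariant in concentration. Flat responses (range
< 0.05) and degenerate fits (ceiling − floor < 0.02) are rejected as
IC50-unidentifiable. c = 0 needs no surrogate: the model evaluates to the
ceiling there. Binomial weighting is available but off by default (plain
Hill fit). IC50 standard errors resample traces within each dose and
refit.

## Slow kinetics (sneak-through and washout)

At saturating inhibitor (with cycloheximide blocking hybrid-state
transitions after accommodation), stalled GA-like molecules convert
irreversibly to high FRET on the 10⁻⁵–10⁻³ s⁻¹ timescale — by drug-bound
sneak-through, or, after drug washout, at the drug dissociation rate.
Both scenarios are modeled as one irreversible GA→AC conversion observed
at 1 Hz with right censoring (washout assumes dissociation is promptly
followed by fast accommodation), and fitted by the censored exponential
MLE

    k̂ = (number of events) / (summed observed time),

each trace contributing its time to conversion or censoring. At 1 s
framing the 300 ms accommodation criterion is sub-frame, so one high-FRET
frame qualifies (configurable). With zero events only the upper bound
1/(total observed time) is reported. Fold changes between fits carry a
delta-method standard error.

## Design choices on genuinely open points

* The number of HMM states and whether emission means were re-estimated
  are not published; the package fixes means at the nominal class values
  by default and exposes re-estimation (`fixed_means=False`).
* Handling of censored dwells and missed fast events in the published
  rate tables is unstated; the censoring convention above is a
  documented choice and its bias is quantified here rather than
  corrected.
* Whether slow rates came from cumulative-accumulation or survival
  fitting is unstated; the censored MLE is asymptotically equivalent to
  both.
* The post-synchronization threshold ("first appearance of FRET") is
  operationalized as the first non-dark idealized frame, with a raw
  FRET > 0.12 fallback for models without a dark state; transition
  density plots use dwell-mean *raw* FRET so noise structure stays
  visible; default grids are 45 FRET bins over [−0.1, 1.0].

## Limitations

Beyond the generator simplifications above: degenerate hidden states
within one FRET class are not modeled; no hierarchical (per-molecule)
rate variability; the dose model has no binding kinetics (kon/koff);
washout re-binding is not modeled; SPARTAN binary trace containers are
not parsed (CSV/TSV only).
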