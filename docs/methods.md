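# Methods

This note documents the models, estimators and numerical choices behind
`sonophys`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic recordings

### Voltage clamp

A simulated voltage-clamp trace is

    I(t) = baseline + Σ_i A_i · k(t − t_i) · polarity + ΔI · 1[t ≥ t_step] + ε(t)

with event times t_i from a homogeneous Poisson process of configurable
rate, amplitudes A_i log-normal (median 30 pA, σ_log 0.35 — conventional
values for cultured hippocampal miniature PSCs; the distribution is fully
configurable because real cultures vary widely), white Gaussian noise ε
(default SD 3 pA), and an optional holding-current step ΔI modelling drug
application. The synaptic kernel k is a difference of exponentials
(τ_rise 1 ms, τ_decay 15 ms by default, GABA_A-like) normalized so its peak
equals 1: truth amplitudes are therefore directly comparable to detected
peak amplitudes. Inward events at −70 mV holding are negative deflections
(polarity −1); truth stores positive magnitudes.

`simulate_tonic_block_experiment` composes the pieces into a
GABA_A-blocker experiment: miniature IPSCs at a configurable rate plus an
inward tonic current during the baseline window; at the drug time the
events stop and the holding current steps up by the tonic amplitude.

### Current clamp

Network activity is modelled as recurrent bursting: burst onsets follow an
inhomogeneous Poisson process (defaults: 0.25 Hz, Poisson(8) spikes per
burst at 20-ms intra-burst intervals — typical of mature dissociated
hippocampal cultures), each spike a stylized triangular waveform (2 ms
wide, 100 mV from a −65 mV rest) whose peak is snapped to the sample grid
and recorded as the truth time. Only threshold-crossing fidelity matters
downstream, so no conductance-based biophysics is simulated. Stimulation
suppresses the burst intensity from r to r·s (s = suppression ratio) with a
linear ramp across the stimulation epoch by default (a step transition is
available), emulating the gradual onset of activity suppression. The
default current-clamp sampling rate is 2 kHz — four samples per spike
waveform, ample for threshold detection while keeping multi-cohort
simulations fast.

### Hydrophone scans

Raster scans are a radial Gaussian, peak·exp(−r²/2σ²) with
σ = FWHM/(2√(2 ln 2)), plus optional noise clipped at zero (peak-pressure
maps are magnitudes).

### Randomness

Each generator call builds one `numpy.random.SeedSequence` from its integer
seed and splits it into fixed sub-streams (event times, amplitudes, noise),
so outputs are bit-reproducible and changing one component's parameters
does not perturb the others' draws.

## Event detection

PSC detection subtracts a running-median baseline (200-ms window, computed
on a decimated grid for long traces — follows slow drift without absorbing
events), estimates the noise SD robustly as MAD(diff)/(0.6745·√2) (the
first difference suppresses events and slow structure), lightly smooths
with a 1-ms boxcar (<0.4% peak attenuation for a 1-ms rise, ~3× noise
reduction), and takes peaks exceeding `psc_threshold_sd` (default 5) times
the noise SD in the configured polarity, at least `min_event_separation`
(5 ms) apart. Requiring peak *prominence* equal to the threshold rejects
secondary noise wiggles riding on an event's decay. When a kernel template
is supplied, event times are localized on the steep rising edge — the
half-maximum crossing, linearly interpolated, minus the template's
onset-to-half-rise latency — which is far less noise-sensitive than the
flat peak; amplitudes are the smoothed peak height above the local
baseline. Overlapping-event deconvolution is out of scope: events closer
than the separation limit merge, which bounds attainable recall at high
rates.

Spike detection reports one event per upward crossing of the threshold
(default 0 mV) with refractory enforcement (default 2 ms); the reported
time is the maximum of the suprathreshold excursion, matching the
simulator's peak-time truth exactly on noise-free traces.

QC operationalizes three rejection rules on a 1-s-median-smoothed trace:
median resting potential above −60 mV; a stimulation-epoch depolarization
beyond −50 mV sustained for more than 1 s after rising faster than 2 mV/s
(the "steep change" rule — the steepness and sustain thresholds are
configurable since the original criterion is qualitative); series
resistance outside 8–25 MΩ when present in the channel metadata.

## Firing-rate estimation

The rate estimator is a uniform-kernel KDE: rate(t) = N([t−w/2, t+w/2])/w
with w = 0.5 s read as the *full* support of the kernel — this makes a
single event produce a 2-Hz plateau of width w, the conventional reading.
Windows truncated at the series boundaries use the truncated width as
denominator, keeping the edge estimates unbiased. The default evaluation
grid step is 10 ms. `kde_integral` integrates the kernel overlap
analytically, so the integral over any interval containing all kernel
supports equals the event count to floating precision (mass conservation).

Normalization divides by the mean rate over the pre-stimulation baseline —
5 s for single-shot stimuli, 5 min for repetitive protocols — and errors
explicitly (never a silent NaN) on a zero baseline. Interval summaries are
plain count/length means over labelled windows.

## Tonic current

I_hold per 1-s segment is the μ of a Gaussian fitted to the all-points
histogram of the raw samples (bin width: Freedman–Diaconis with a 0.2-pA
floor). Skew handling: the nonparametric skewness (mean − mode)/SD, with
the mode taken from a 5-bin moving-average smooth of the counts (raw
argmax is too bin-noise sensitive), triggers a positive-side fit — bins at
or above the mode — when it falls below −0.15. At −70 mV holding, inward
PSCs contaminate only the negative tail, so the at-or-above-mode side is
the event-free side. The fit is weighted least squares on counts with
Poisson weights √max(c,1), initialized from the mode and the right-side
half width at half maximum, with non-convergence raising an error carrying
diagnostics (never a silent fallback). Per condition, I_hold is the median
over non-overlapping 1-s segments — robust to within-condition drift; the
tonic amplitude is I_hold(drug) − I_hold(baseline), positive when the
blocker abolishes an inward tonic current. Whether one or several 1-s
segments per condition is used in practice varies between labs; the
median-of-segments policy is this package's choice.

## Dosimetry

All internal computation is SI; reported units are the field's (PII in
mJ/cm², I_SPPA in W/cm², I_SPTA in mW/cm²). For a rectangular-gated
sinusoid, PII = p₀²·TBD/(2ρc), I_SPPA = p₀²/(2ρc), I_SPTA = I_SPPA·DC —
the identity I_SPTA = I_SPPA·DC holds exactly on both the closed-form and
numeric (trapezoidal over the first located pulse) paths. The default
medium is degassed water at 25 °C (ρ = 998 kg/m³, c = 1482 m/s),
free-field, no derating — matching a hydrophone calibration context.
`metrics_from_pii` derives the intensities from a measured PII instead,
the appropriate route when the pulse shape is not ideal. Beam FWHM is the
separation of linearly interpolated half-maximum crossings along an axis
through the (unique) map peak.

## Statistics

Mann–Whitney U, Wilcoxon signed-rank (zero differences dropped — Wilcoxon's
original rule), Friedman and Shapiro–Wilk delegate to scipy.stats, which
enumerates exactly for small untied samples and uses tie-corrected
approximations otherwise. All-tied degenerate inputs return flagged results
(statistic 0, p 1) rather than raising.

The Steel many-one test is implemented from scratch. For treatment j with
n_j observations against a control of n₀, joint mid-ranks give the rank sum
R_j, standardized with the tie-corrected two-sample variance
n₀n_j Σ(r_i − r̄)²/(N_j(N_j−1)). The familywise two-sided p-value is
P(max_l |T_l| ≥ |T_j|) under the exchangeable null, computed by

- **exact enumeration** of all partitions of the pooled values into groups
  of the observed sizes (guarded at 50 000 partitions), or
- **seeded Monte-Carlo**: iid continuous null data are drawn and the
  statistics recomputed, reproducing the *discrete* joint null — including
  the shared-control correlation √(n_j n_l/((n₀+n_j)(n₀+n_l))), 1/2 at
  equal n — rather than its multivariate-normal limit (a plain MVN
  reference is visibly conservative at these group sizes). 10⁵ draws by
  default, sorted tails cached per group-size signature; p-values use the
  add-one convention and are clamped from below by the per-comparison tail
  of the same draws, so the adjusted p never undercuts the corresponding
  unadjusted test.

One calibration subtlety: for k = 3 and n = 10 the discrete null of
max|T_l| has an atom whose tail probability lies almost exactly at 0.05, so
the rejection rate conditional on a single Monte-Carlo null sample flips
between ≈0.040 and ≈0.050. Calibration harnesses therefore rotate
independent seeded null samples across replicates to measure the
procedure's average familywise error.

## Pipeline and reproducibility

Scenarios mirror the experiment designs: repetitive PW/CW (5-min pre, 192-s
train of twenty 2-s stimuli, 5-min post; 2-min pre/post and 3-min stim
comparison windows; treated cohort of 19 cells vs 25 controls; Steel test
on normalized post-interval rates), single-shot (five 2-s stimuli at 20-s
intervals, 2-s windows, Friedman over pre/stim/post), and tonic
measurement (Steel on cohort tonic amplitudes, default 20 pA treated vs
5 pA control ambient tonic current). Every cell owns a sub-seed spawned
from the scenario seed, so per-cell results are independent of execution
order and a re-run with the same config is byte-identical (fixed float
formatting, sorted JSON keys, no timestamps); the report carries a SHA-256
hash of the canonical config plus package version.

## What the synthetic benchmarks do and do not show

The simulators reproduce the *statistical structure* the analysis chain
relies on — Poisson event trains, biexponential kernels, white noise,
step-like drug effects, gradual rate suppression, Gaussian beam profiles —
with known truth, so the tests demonstrate correct recovery under those
assumptions. They do not emulate correlated (1/f) noise, electrode drift
faster than the baseline tracker, overlapping-event pileup beyond the
separation limit, seal or access-resistance instability, bursty mPSC
release, or non-Gaussian beam sidelobes; performance on real recordings
with those features is not certified by a passing suite. Problem sizes in
the shipped benchmarks (200 tonic replicates, 19+25-cell cohorts, 10⁴
calibration replicates) were chosen to make sampling error small relative
to the tolerances while keeping a full run in minutes on one CPU.

## Known limitations

- No overlapping-PSC deconvolution or template learning; detector
  equivalence to interactive commercial event-analysis software cannot be
  claimed, only ground-truth recovery on synthetic data.
- The Steel exact path is enumeration-bounded; large-group exact p-values
  fall back to the seeded Monte-Carlo reference.
- Dosimetry assumes rectangular gating; ramped envelopes and field
  simulation of the transducer are out of scope.
- Trace containers are delimited text and HDF5; no NWB export.
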