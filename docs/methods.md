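# Methods

## The measurement model

A single aerolysin pore in a lipid bilayer passes an open-pore current I₀
under an applied voltage; a captured peptide reduces the current to I_b for
a dwell time T_t. The analysis works entirely on the normalized blockade
level ΔI_b = (I₀ − I_b)/I₀ (deep blockades approach 1) and on T_t. For a
proline-rich peptide whose first proline isomerizes, three event populations
appear: A (trans isomer) and B (cis isomer), partially overlapping and both
produced by N-terminus-first entry, and C, a distinct right-skewed
population from C-terminus-first entry. The conformer equilibrium is read
from the heights of A and B in the max-normalized ΔI_b histogram via
trans% = 100·a/(a+b) with a ≡ 1.

## Synthetic-data generator

The generator emulates the statistical structure of such recordings, not
their biophysics:

* **Arrivals.** A Poisson process with rate `capture_rate_hz_per_uM ×
  concentration_uM × (V/100 mV)`. Default 0.7 Hz/µM; with the preset
  concentrations (15, 15, 10 µM) this gives ~7–10 Hz at +100 mV, a typical
  regime for peptide sensing at micromolar concentration. Arrivals landing
  while the pore is occupied are dropped and counted (a single pore senses
  one molecule at a time).
* **Population assignment.** A capture enters N-terminus first with
  probability `orientation_split` (default 0.7) and is then cis (B) with
  probability `cis_fraction_true`, else trans (A); otherwise it is C.
  The preset cis fractions are 0.34 (WT), 0.43 (S4F), 0.22 (R4F) — the NMR
  integral estimates for the corresponding peptides, used as ground truth so
  the pipeline's recovery can be compared with the published nanopore splits.
* **Levels.** A: Normal(0.78, 0.015); B: Normal(0.82, 0.015); C: log-normal
  with mode 0.88 and coefficient of variation 0.02/0.88 (right-skewed).
  These reproduce the reported 0.7–0.9 window with A/B partial overlap and a
  clearly separated C; the specific values are generator choices, not
  measurements. A and B share their width so that fitted component heights
  are proportional to event counts — the property that makes a/(a+b) an
  estimator of the trans fraction.
* **Dwell times.** Log-normal; log-median = `dwell_logmean_s + slope·(V −
  100 mV)` with logsd 1.0 and slope 0.01/mV ≥ 0. Medians at +100 mV: 1 ms
  (A and B, which share a dwell law — same entry orientation) and 3 ms (C).
  The linear-in-voltage log-median is the simplest law consistent with a
  monotone increase of residence time with voltage (the no-translocation
  signature); no functional form is asserted beyond monotonicity.
* **Trace rendering.** I₀ = G·V with G = 2.5 nS (an order-of-magnitude
  choice for 4 M KCl); baseline noise 4 pA and intra-event noise 5 pA
  (Gaussian, white); sampling 50 kHz; the 5 kHz filter cutoff is carried as
  metadata only — no digital filter is applied to synthetic traces.
  Rendering uses a random stream seeded at `seed + 1` so the same event
  stream can be re-rendered under different noise settings.

**What the generator does not emulate:** 1/f and filter-shaped noise,
baseline drift, capacitive transients, sub-state structure within events,
salt- and sequence-dependent electrokinetics (electroosmosis is represented
only by the phenomenological voltage scalings), and NMR lineshapes (peak
lists only). Passing tests therefore demonstrate the correctness and
statistical calibration of the analysis chain on data satisfying its
assumptions, not robustness to every artifact of real recordings.

## Event detection and selection

Baseline I₀ is an iterative robust estimate: the median of samples at or
above 75% of the running estimate (blockade samples excluded), with a
Gaussian-consistent MAD scale; it fails loudly if over 90% of samples are
excluded or the estimate is non-positive. Events are maximal runs below
`threshold_frac × I₀` (default 0.5 — well between the baseline and the
0.7–0.9 deep-blockade band); runs separated by fewer than 5 baseline samples
are merged to tolerate noise spikes. Per event, the mean in-event current
excludes 2 samples at each edge (rise-time bias), the local I₀ comes from
5 ms flanking windows clipped at neighbouring events (global fallback), and
the intra-event noise is the sample standard deviation of the interior.
Indices are half-open `[start, end)`; times in seconds, currents in pA.

Selection keeps events with 200 µs ≤ T_t < 1 s, ΔI_b within [0.5, 0.95]
(the per-voltage amplitude window, config-exposed), and noise within
[1, 100] pA; a rejected event records the first failing criterion in the
order duration, amplitude, noise. Filtering is idempotent.

## Histogram fit and the ratio statistic

The ΔI_b histogram uses 100 bins on [0, 1], counts divided by the maximum
bin. The model is a sum of peak-normalized shapes times heights: two
Gaussians plus a log-normal (evaluated in log space; its mode is the
location parameter reported). "Bi-Gaussian" is read as two Gaussian
components, because two separate heights a and b are extracted from the fit;
a single asymmetric (split-σ) Gaussian is the alternative reading and can be
realized by passing an explicit `init` and `share_sigma_ab=False`.
Fitting is bounded least squares (`scipy.optimize.least_squares`, TRF) on
the binned counts; heights are fitted amplitudes, not raw bin maxima, so the
A–B overlap does not contaminate the ratio. Initialisation is automatic
from `scipy.signal.find_peaks` (two largest maxima below the rightmost mode
for A/B, the rightmost mode for C) with quantile fallbacks when fewer peaks
are visible; labels are reordered after fitting so µ_A < µ_B. The two
Gaussians share one width by default (see above); non-convergence sets a
flag rather than raising; components collapsing below a 5% height floor are
reported near zero and excluded by `count_populations`.

`trans_cis_ratio` rescales heights so a = 1 and b = h_B/h_A; trans% =
100/(1+b). With equal A/B widths, b estimates the cis/trans odds among
N-terminus captures, so trans% estimates 100·(1 − cis fraction).

## Kinetics

Events are labeled by maximum component responsibility at their ΔI_b (ties
break to the lower-location component); A and B map to N-terminus-first
entry, C to C-terminus-first. Because A and B overlap, they are merged for
residence-time statistics. Replicate variability is emulated by splitting
the pooled events of a group into 3 random equal blocks (seeded), computing
the mean per block, and reporting the mean ± sd across blocks. A voltage
scan is monotone when each step decreases by no more than one pooled
standard error; voltages with no kept events are reported empty and
flagged. The arithmetic mean is the primary dwell statistic; a log-normal
fit (median, logsd) is reported alongside since which statistic real
analyses fit is an open choice.

## NMR cross-check

The cis estimator sums cross-peak volumes per isomer over both aromatic
sites (Cδ–Hδ and Cε–Hε) of the residue preceding the proline —
semi-quantitative direct summation, no lineshape deconvolution — and reports
100·V_cis/(V_cis + V_trans). Summation over both sites (rather than either
alone) is the default because it halves the volume-noise variance and
requires no site weighting. The synthetic peak-list generator perturbs each
volume by Normal(1, cv) truncated positive, so the estimator's mean
converges to the generating cis fraction up to O(cv²).

## Numerical choices and problem sizes

* Recording durations are planned analytically from the capture rate, the
  log-normal dwell-window retention probability and the pore-occupancy drop
  fraction, with a 10% margin, to hit a target kept-event count.
* Replicate seeds derive from one base seed via `numpy.random.SeedSequence`
  spawning (31-bit), so adjacent base seeds give independent replicates.
* Headline runs use ~5000 kept events per recording and 3 replicate seeds;
  property and unit tests use 400–3500 events. At 5000 events the binomial
  sampling of the isomer draw dominates the spread of the recovered trans
  percentage (≈1 point per recording, ≈0.6 for the 3-seed mean).
* Degenerate inputs raise informative errors: empty histograms, fewer than
  3 occupied bins, absent population A, missing HSQC sites, groups with
  fewer than 2 events, non-positive durations or rates.

## Known limitations

* The a/(a+b) estimator is calibrated only under the equal-width A/B
  assumption; if the two conformers produced genuinely different level
  spreads, heights would no longer be proportional to counts and the split
  would need a width correction.
* Detection is single-threshold with no sub-state idealization; events
  shorter than ~2 samples at 50 kHz are invisible, which is why the
  selection floor (200 µs = 10 samples) sits well above the resolution
  limit.
* The voltage dependence of capture and dwell is phenomenological (linear
  scalings); no electrokinetic quantities are modelled.
* Per-voltage amplitude windows default to [0.5, 0.95] at every voltage;
  real analyses would tighten these per condition.
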