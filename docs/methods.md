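# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what the synthetic tests do and do
not establish about real recordings.

## The analysis problem

Between 30 °C and 39 °C, two intrinsic changes push cortical pyramidal
neurons away from firing: spike threshold depolarizes and input
resistance falls.  A cell keeps spiking only if its stimulus-evoked
depolarization grows enough to keep reaching the moving threshold.
Classifying each cell's outcome across the temperature series
(NEVER / STAY / STOP / START), and asking what distinguishes STAY cells
(e.g. an evoked-peak-vs-threshold correlation consistent with a
warmth-activated depolarizing conductance such as TRPV3), is the core of
the pipeline.  The extracellular arm asks the complementary in vivo
question: among units that remain sortable throughout a
baseline/fever/recovery session, how do firing rates change at fever
temperature, separately for putative interneurons and principal cells?

## Synthetic cohort model

The generator is phenomenological, not conductance-based; it produces
traces with exactly the statistical structure the feature extractors
assume, plus recorded ground truth.

**Subthreshold response.**  Each sweep is holding potential (−50 mV)
plus a difference of dual-exponential kernels: an excitatory component
(rise 2 ms, decay 25 ms, onset 2 ms post-stimulus) and a delayed
inhibitory component (rise 8 ms, decay 60 ms, additional 5 ms delay).
Kernels are normalized to unit peak so amplitudes are in mV.

**Temperature scalings.**  Threshold: θ(T) = θ30 + 0.3 (T − 30) mV, with
θ30 ~ N(−42.5, 1.5²) mV — giving depolarization-to-threshold ≈ 7.5 mV at
30 °C rising to ≈ 10 mV at 39 °C, the observed order of magnitude.
Input resistance: R_in(T) = R30 · 0.8^((T−30)/10), R30 ~ N(150, 25²) MΩ.
The excitatory amplitude scales with R_in(T)/R30; cells fated to spike
at fever temperature (STAY, START) get an extra (1 + 0.08)^(T−30) gain —
the stand-in for a warmth-activated depolarizing conductance.  The
inhibitory amplitude shrinks as (1 − 0.04)^(T−30) for every cell.  The
gain and loss rates are package choices (no published per-cell values
exist); they are sized so that all four fates are realizable and the
STAY cells' evoked peak tracks their threshold, and they are fully
configurable.

**Fate realization.**  For each cell the generator computes, per
temperature, the minimal base amplitude ρ(T) whose drive peak reaches
θ(T) (bisection on the monotone peak-vs-amplitude map), then draws a
base amplitude inside the interval that realizes the assigned fate
pattern (above all ρ for STAY, below all for NEVER, between the spiking
and silent ρ values for STOP/START, with ≥ 15% interior margins).  A few
percent of intrinsic-parameter draws make a START pattern unreachable
(a threshold so close to holding that its proportional rise outpaces the
fever gain); such cells have their intrinsic parameters redrawn so the
configured fate mix is preserved exactly.  Spike insertion is decided on
the noiseless trace: where it crosses θ(T), a 4-ms stereotyped action
potential is spliced in (linear upstroke to +30 mV over 0.3 ms — a sharp
second-derivative onset at the crossing sample — repolarization to a
6 mV afterhyperpolarization, linear recovery into the subthreshold
trace).  Gaussian noise (default SD 0.2 mV) is added afterwards to all
samples.  Consequently the realized spiking pattern equals the fate
label at every noise level, and the recorded threshold ground truth is
the voltage at the crossing sample.

By default one spike is inserted per evoked sweep (a burst flag enables
more); evoked responses in this preparation carry spike counts near one,
and a single template keeps closed-form checks possible.

**What the generator does not emulate:** 1/f and synaptic background
noise (i.i.d. Gaussian only — a config hook exists for AR(1)),
trial-to-trial amplitude variability (the drive is frozen per
temperature; only noise varies across the 11 sweeps), holding-potential
drift, electrode artifacts, temperature-dependent kinetics of the PSP
waveform itself, and multi-compartment effects.  Passing recovery tests
therefore demonstrates correctness of the extraction logic under the
stated noise model, not robustness to every pathology of real
recordings.

## Feature extraction conventions

- **Second derivative** by central differences without smoothing
  (sampling is ≥ 20 kHz); a 3-point smoothing flag exists for noisier
  data.  The pre-stimulus window must contain ≥ 50 samples; a noiseless
  window (zero SD) is an explicit error rather than a silent division.
- **Threshold search range** is (stimulus onset, spike peak]; the
  pre-stimulus window is half-open [start, onset) so the onset sample
  itself never contaminates the baseline.
- **Evoked window**: 2.5–152.5 ms post-stimulus (the window start is the
  midpoint of the 2–3 ms convention and is configurable).
- **PSP measurement**: spikes are excised by ±2 ms linear interpolation
  around each peak; a 1-ms boxcar is applied before peaks are read off,
  because the raw maximum over ~10³ noisy samples carries an
  extreme-value bias comparable to the noise SD while the boxcar
  distorts the synaptic peak by < 0.1%.  The early value (2.5–50 ms) is
  the maximum signed deflection; the late value (50–150 ms) is the
  deflection of largest magnitude with its sign, so a dominated-by-
  inhibition late component reports negative.  The late window bounds
  are a package convention (only the concept "late component, 50 ms on"
  is fixed by the analysis design) and are configurable.  On spiking
  sweeps the drive peak is partly hidden under the excised spike, so
  peak-recovery accuracy is quantified on subthreshold sweeps, where the
  quantity is fully observable.
- **Eθ**: "more than 3 of 5 consecutive sweeps" is implemented as ≥ 4
  detections within the 5-sweep block (recorded as an explicit
  constant); which 4 need not be adjacent.
- **Depolarization-to-threshold** uses the measured pre-stimulus mean,
  not the nominal holding value, so holding drift cancels.

## Fate rules

Three temperatures: (F,F,F) → NEVER; a cell spiking at the first
temperature is STAY if it spikes at all three, otherwise STOP; a cell
silent at the first temperature that spikes later is START.  The
rarely-realized alternating patterns (T,F,T) and (F,T,F) therefore
resolve by the state at the first temperature (STOP and START
respectively) — the labels key on the 30 °C state.  "Spiking" at a
temperature means ≥ 1 sweep with ≥ 1 detected evoked spike.  The
two-temperature variant maps (T,T)/(T,F)/(F,T)/(F,F) to
STAY/STOP/START/NEVER.

## Extracellular conventions

- Bandpass 300–6000 Hz, zero-phase 3rd-order Butterworth (phase
  preservation protects trough/peak timing; only the band itself is
  fixed by the analysis design).  Trough-to-peak is global-trough to
  subsequent maximum; a boundary maximum (monotone tail) is an error
  naming the unit.
- Curation: ≥ 900 spikes (~0.1 Hz over the 145-min session), ≤ 1% of
  inter-spike intervals under 2 ms, and every tenth of the session
  nonempty.  The 1% and 10-bin operationalizations make the qualitative
  criteria ("clear refractory period", "present throughout")
  reproducible.
- Classification: dip test recorded, then exact 1-D 2-means (the optimal
  two-cluster split of 1-D data is contiguous in sorted order, so an
  O(n) prefix-sum scan over the n−1 splits is the global optimum).
  The class boundary is the midpoint of cluster means; a unit exactly on
  the boundary keeps its cluster label.
- Rates: last 25 min of each 45-min period; the 5-min temperature ramps
  between periods are excluded entirely.  Normalization is per-unit
  baseline division followed by a per-animal mean within class — the
  simplest reading of a per-animal normalized average; alternatives
  (e.g. grand-mean normalization) would rescale but not reorder the
  effect.

## Statistics

- **Dip**: the greatest-convex-minorant / least-concave-majorant
  algorithm on the sorted sample, returning sup-distance to the nearest
  unimodal CDF; validated against an independent linear-programming
  minimizer over piecewise-linear unimodal CDFs (mode atom allowed).
  p-values by uniform bootstrap (the least-favourable unimodal null),
  default 2000 replicates, seeded; null distributions are cached per
  (n, n_boot, seed) since they are data-independent.  p-value resolution
  is 1/n_boot, so "p < 0.001" at 2000 replicates means no null replicate
  reached the observed dip.
- **Binomial**: exact two-tailed by the small-p-values convention (sum of
  all outcome probabilities ≤ that of the observed count, with a 1e-7
  relative tolerance for floating-point ties); tail-doubling available
  behind a flag.
- **Deming**: closed form minimizing Σ(y−ŷ)² + λΣ(x−x̂)²; λ = 1 (default)
  is orthogonal regression and is symmetric under axis exchange; λ → ∞
  recovers ordinary least squares of y on x.
- **KS**: exact p by lattice-path counting when min(n) ≤ 10 and the
  pooled sample is tie-free; otherwise the asymptotic series with the
  small-sample effective-n correction.  Correlation p-values are always
  two-sided (t transform, n−2 df; Spearman uses average ranks).

## Problem sizes and seeds

The test suite and acceptance script use the study-scale conditions
throughout: 200 cells × 3 temperatures × 11 sweeps for recovery, 633
units with a 0.221 narrow fraction for typing, 100 seeds for dip-test
calibration and 10,000 draws for binomial calibration.  All randomness
flows from explicit integer seeds; identical configuration and seed give
byte-identical artifacts.

## Known limitations

- The dip p-value is bootstrap-based; tabulated critical values are not
  shipped.
- The exact KS enumeration assumes no pooled ties (falls back to the
  asymptotic series otherwise).
- The generator's fate calibration targets the drive peak; it does not
  model near-threshold fluctuation-driven spiking, so "borderline" cells
  whose fate flips sweep-to-sweep do not occur at the default noise.
- Waveform durations of wide units carry a ~1–2 sample filter-induced
  shift (the 300 Hz highpass slightly advances broad peaks); this is far
  from the 0.6 ms class boundary and does not affect classification.
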