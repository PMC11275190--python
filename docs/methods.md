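# Methods

This note records the models behind each stage, the defaults and why they
were chosen, and what the synthetic generator does and does not emulate.

## The measurement being modelled

Proteinoid microsphere ensembles, recorded differentially with needle
electrodes and a 24-bit logger, emit voltage spikes of order 0.1–2 mV riding
on slow electrode drift, with interspike intervals (ISIs) of minutes. Under
graded chloroform exposure (vapour from 0.5/1/3 cm² soaked filters, or
direct solvation at 25 mg/mL) the published per-condition tables give, for
each regime, the amplitude distribution's mean/SD/max/min/kurtosis/skewness
and the same for the ISI distribution. Those two tables are the generative
targets and the recovery targets of this package.

## Synthetic generator

**Amplitudes — shifted gamma.** Each condition's amplitude law is a
three-parameter gamma: `shape = (2/skew)²`, `scale = sd/√shape`,
`shift = mean − shape·scale`. A gamma was chosen over the skew-normal
because gamma skewness 2/√shape is unbounded while skew-normal skewness
caps near 0.995, below the control target of 1.37. Kurtosis is reported by
the summariser but is *not* a generative target: a 3-parameter family
cannot match four moments independently.

Draws are hard-clipped to the condition's observed [min, max]. Clipping a
2.4-σ window changes the moments (the SD drops ~8–11% for the built-in
conditions), so the underlying (mean, sd) are recalibrated by least squares
until the *clipped* law matches the targets; the clipped moments are
evaluated in closed form via regularized incomplete gamma functions (robust
for shape < 1, where the density is singular at the shift). Post-clip
mean/SD land within 0.7% of target for every built-in condition. Post-clip
skewness falls below the tabulated values (bounded support compresses the
right tail); this is a structural limitation of clipping to the observed
range, not a fitting error, and is left as is.

A non-positive skew target falls back to a normal truncated to the
amplitude bounds, since the gamma orientation used here only produces right
skew.

**ISIs — truncated normal, with a feasibility caveat.** ISIs are drawn from
a normal truncated to the condition's observed [min, max]. The solver
matches the truncated *mean* exactly (the truncated mean is monotone in the
location parameter, so a bracketing root-find always succeeds) and then
solves for the scale by bisection on the truncated SD, which is monotone in
scale up to a supremum.

That supremum matters: for **all five** built-in conditions the tabulated
ISI SD exceeds the largest SD any truncated normal can attain on the
tabulated range (shortfalls of 11–41%; the supremum is itself below the
Popoviciu bound (max−min)/2 that limits *any* distribution on the
interval). This is unsurprising — the published min/max are sample extremes
of ~10–20 intervals, not distribution bounds — but it makes the (mean, SD,
min, max) quadruples jointly unrealisable in this family. The solver
therefore saturates at the best-achievable SD by default and raises
`InfeasibleMomentsError` only in strict mode; targets whose SD exceeds the
Popoviciu bound are rejected outright. The ISI *mean*, which drives every
headline rhythm statistic, is always matched exactly.

**Rendering.** Spikes are biexponential pulses (rise 5 s, decay 20 s,
peak-normalised and time-shifted so the rendered peak lands on the event
time); the source recordings' waveform shape is not published, and these
constants give spikes much narrower than any tabulated ISI. Overlapping
pulses sum. The baseline is a sinusoid plus white noise:

* `drift_amplitude` 0.2 mV, `drift_period` 86 400 s — slow diurnal-scale
  electrode drift. The period must be long relative to the detrending knot
  spacing (10× median ISI ≈ 14 000 s for control): a cubic spline resolves
  an 86 400 s sinusoid to ~0.3% of its amplitude but would leave ~45% of a
  36 000 s one in the residual.
* `noise_sd` 3 μV, consistent with a 24-bit logger's noise floor at mV
  scale and small against even the weakest condition's 27 μV minimum
  amplitude.

All randomness in a generated trace flows through substreams spawned from
one seed, so (spec, seed) determines the output bit-for-bit.

**Current traces.** Chronoamperometric traces use the published
per-condition mean currents as constant baselines (vapour exposures above
control, solvation well below — the published ordering holds by
construction) with Poisson-arriving conductivity transients that relax
exponentially (τ = 0.5 s by default, i.e. subsecond). Noise defaults to
zero so a zero transient rate yields an exactly constant baseline.

**What the generator does not emulate.** No physical chemistry of
chloroform permeation; no spike-shape variability, bursting, or
non-stationarity in rate; no 50 Hz interference or electrode artifacts; ISI
draws are i.i.d. (no serial correlation). Passing recovery tests therefore
shows the *analysis chain* is unbiased under the stated statistical
structure, not that it is robust to every pathology of laboratory traces.

## Baseline removal

Least-squares B-spline (degree 3, clamped end knots, uniform interior
knots). The published analysis names the method but no parameters. Knot
spacing defaults to 10× a median-ISI estimate obtained from a coarse
first-pass fit (spacing = duration/20) and quick peak scan; knots sparse
relative to spike spacing cannot bend on the pulse timescale, so spikes
survive while drift is absorbed. Spacing below 2·dt is rejected.
Baseline + residual reconstructs the input to machine precision by
construction.

## Spike detection and summary statistics

Detection runs on the residual after a centred moving average of width
equal to the pulse rise time (5 s). Smoothing attenuates the peak by <1%
but shrinks the noise SD at the peak by √5, suppressing the
"maximum-of-noise" upward bias in peak-height readout. Amplitudes are
measured relative to the median of the smoothed residual, which cancels the
small uniform offset left when the spline absorbs the mean spike mass.

The noise scale is estimated as σ̂ = MAD/0.6745 (spikes are sparse, so the
MAD reflects noise only). Defaults: threshold 5σ̂, prominence 3σ̂,
refractory 30 s (the smallest tabulated ISI is ~70 s). The 5σ̂ threshold is
the extracellular spike-sorting convention; at ~7·10⁵ samples per control
run it yields ≪1 expected false peak, whereas a threshold of 3–3.5σ̂ admits
hundreds, each of which would split a genuine minutes-long interval.
Maxima closer than the refractory interval merge, keeping the larger.

Summary moments follow the published tables' conventions: sample SD (n−1),
skewness g₁ = m₃/m₂^1.5, and **non-excess** kurtosis m₄/m₂² — chosen
because the control kurtosis is printed as 3.91, near the Gaussian value 3
of the non-excess convention. ISIs are successive peak-time differences;
`sem_isi` = SD/√(n−1 intervals). At 500 spikes the full
generate→detrend→detect→summarise chain recovers every built-in condition's
amplitude and ISI means within ~2–4% (the residual bias is the clipped-tail
and smoothing effects above; the ISI sample mean has SE ≈ 1.3% at n=500).

## Dose–response

`percent_change(ref, treated) = 100·(1 − treated/ref)`; positive =
reduction. Each published claim names its own reference (control for the
solvation comparisons, the 0.5 cm² regime for the vapour-to-vapour decline),
and the report encodes changes against the first condition in the run.
Minutes are seconds/60 rounded half-up to one decimal. Two published values
are knowingly in tension — the abstract rounds the solvated amplitude to
0.1 mV where the table prints 0.065, and one section's text gives
0.091 ± 0.008 mV where the table prints 0.085 ± 0.047 — the tables are
treated as canonical throughout. No inferential statistics are computed;
the source analysis performs none.

## Harmonics

Base frequency: dominant rFFT magnitude peak (DC excluded) refined by
parabolic interpolation; a peak below 8× the median magnitude raises a
no-periodicity error (white noise peaks at ~3–4× median for 10³–10⁵
samples, genuine tones at orders of magnitude above). Components: least
squares onto {sin(kωt), cos(kωt)}, k ≤ K, with Aₖ = √(aₖ²+bₖ²) and
φₖ = atan2(bₖ, aₖ) in (−π, π], i.e. the sine-phase convention of the model
equation. K·ω above Nyquist is rejected. The mean is removed before
fitting. Signals exactly in the model span round-trip with RMS < 10⁻⁶, and
Σ Aₖ²/2 never exceeds the mean square of the zero-mean input. The published
harmonic amplitudes themselves are not reproducible — the underlying
recordings are not printed — so this stage is verified by construction and
property checks only.

## Neuromorphic abstraction and complexity

Binary coding: bit = 1 iff I > threshold, strictly, one bit per sample;
default threshold 10⁻⁴ μA as published. (Against the μA-scale synthetic
baselines this default marks every sample active — the published threshold
and the published mean currents are not mutually consistent; the threshold
is kept as stated and is a parameter.) Subsampling takes a uniform random
subset of active indices of size ⌊n_active/n_neurons⌋ (min 1 when any bit
is active) — "inversely related to the number of neurons" made concrete,
since no formula is published. Weights are i.i.d. uniform on [−1, 1)
(2u − 1 with u uniform on [0,1); the published formula's prose would give
[−3, 1], the only self-consistent reading is used), default 30 neurons.
Only initialisation is modelled: the iterative learning rule alluded to in
the source is never specified. Charge integrates I(t) = dQ/dt by the
trapezoid rule with Q(t₀)=0. Boxplot statistics use type-7 quartiles and
1.5·IQR whiskers.

LZ76 complexity is the exhaustive-history phrase count (the final,
possibly still-copyable phrase counts), computed by bisecting on the
longest reproducible prefix with C-level substring search; normalisation is
c·log₂(n)/n, which → 1 for fair-coin sequences. The published complexity
table's exact values are not reproducible (source sequences unpublished;
their values exceed any binary-LZ76 normalisation of plausible lengths),
so the implementation is verified against a brute-force parser
(exhaustively for all sequences of length ≤ 12) and by asymptotic and
invariance properties; matrix encoding is row-major sign binarisation.

## Energy audit

Pure bookkeeping: compensated (fsum) addition of the seven components and
comparison to the stated total at a default tolerance of 0.001 kcal/mol
(one unit in the last printed decimal of a 4-decimal table). No force-field
evaluation or geometry optimisation is performed; the published ledger for
the chloroform/L-Glu-L-Arg system is shipped as the worked example and sums
to within 10⁻⁴ of its stated total.

## Problem sizes and determinism

Recovery tests and the acceptance script use 500-spike runs (≈7·10⁵
samples for control at 1 Hz, a few seconds of compute); unit tests use
40–60-spike runs. Every stochastic stage takes an explicit seed;
pipeline-level runs spawn per-condition substreams from one global seed, so
a full run is byte-reproducible.

## Known limitations

* Clipped-gamma skewness undershoots heavy-tailed targets (see above).
* Tabulated ISI SDs are unattainable inside a range-truncated normal; the
  generator prioritises the mean and documents the achieved SD.
* The detector assumes positive-going spikes on a near-zero residual; it is
  not a general spike sorter (no templates, no overlapping-spike
  resolution).
* Harmonic analysis assumes a single shared base frequency; no
  time–frequency analysis is provided.
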