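# Methods

## The measurement model

A mouse vocal breath is one respiratory cycle — inspiration (airflow negative
by convention) then expiration (positive) — carrying one or more ultrasonic
syllables in the 40–120 kHz band. Three time series are analyzed on a common
clock: chamber airflow from whole-body plethysmography (1 kHz, arbitrary
units), ultrasonic audio (250–400 kHz), and diaphragm/laryngeal EMG (10 kHz).
Airflow calibration to absolute volume is undefined in this kind of
recording, so every analysis in the package is invariant to positive
rescaling of the airflow; tests assert this.

## Breath segmentation

Airflow is zero-phase high-pass filtered (2nd-order Butterworth, 2 Hz
default) and boxcar-smoothed (5 ms default), then segmented at signed zero
crossings with hysteresis: a crossing counts only once the new-sign excursion
reaches `hysteresis_frac` (default 0.05) of the robust amplitude (95th
percentile of |flow|), which makes segmentation scale-invariant and immune to
small wiggles around zero. A breath is inspiration-first:
inspiration onset (crossing into negative), expiration onset (crossing into
positive), end (next inspiration onset). Complete cycles shorter than
`min_breath_ms` (50) are merged into their predecessor. Features per breath:
Ti, Te, peak inspiratory/expiratory flow magnitudes Pif/Pef, and
instantaneous frequency 1/(Ti+Te). The algorithm is deliberately simple
enough to check against a brute-force per-sample state machine, and the test
suite does exactly that. Te runs to the next inspiration onset by
definition, so any post-syllable pause is part of Te.

USVs are assigned to the breath containing their *onset* (onset-centric,
matching the timing analyses downstream); onsets before expiration onset give
negative relative times and are flagged but kept.

## Pitch tracking

Spectrograms are DPSS multitaper: 512-sample windows (~2 ms at 250 kHz), 50%
step, 3 tapers at NW = 2 — averaging tapered periodograms lowers noise-floor
variance so a narrow-band whistle stands out. The pitch contour is the
per-time-bin argmax frequency within the band; a bin is valid when its peak
power exceeds the median in-band power by `floor_db` (15 dB). Detection
bridges gaps ≤ 5 ms and drops runs < 5 ms. Within one breath, intervals
separated by strictly more than 20 ms are distinct syllables of one
multi-syllable event; a gap of exactly 20 ms merges (the comparison carries a
1 ns tolerance so floating-point representation cannot flip the boundary
case).

The syllable-type classifier is a transparent stand-in for CNN classifiers:
precedence is short (< 10 ms) → flat (range < 5 kHz) → register jumps
(inter-bin steps > 10 kHz within a syllable: 1 up/down = step up/down, 2 =
two step, ≥ 3 = multi) → shape on a median-smoothed contour using interior
extrema with prominence ≥ 15% of the range (none = up/down fm by endpoint
slope, a single maximum = chevron, any trough or ≥ 2 reversals = complex).
On low-noise simulator output it recovers ≥ 99% of template labels; on noisy
real data it is a triage tool, and externally produced type tables can be
supplied instead.

## The intonation statistic and its nulls

For each USV event (all syllables concatenated), signed airflow is linearly
interpolated at the contour's valid bins and the Pearson correlation r is
computed; fewer than `min_bins` (5) pairs or zero variance in either vector
yields *indeterminate* (never NaN, never 0 — near-degenerate flat/short
contours are deliberately uncallable). Signed airflow is used rather than a
magnitude, so mini-breath dips below baseline enter the correlation as
negative flow.

Significance comes from two shuffle nulls: each USV's pitch paired with a
different USV's airflow (derangement permutations, no self-pairs), and the
mirror image, the partner signal linearly time-rescaled onto the recipient's
bins (a truncation alternative was considered and rejected as it discards the
recipient's late bins asymmetrically). Per-type nulls are used when a type
has ≥ 20 USVs, else the pooled null; both null modes are concatenated for
the quantile test. Calls: positive above the 97.5% null quantile, negative
below 2.5% (alpha = 0.05 two-sided). Both per-event and per-syllable
granularities are computable; per-event is the default reported one.

A structural caveat the test suite quantifies: a shuffle null only has power
when the population carries within-type signal diversity. If every syllable
of a type had the identical airflow trend, shuffled pairs would reproduce the
observed correlation and every call would be indeterminate — which is the
correct behaviour of the statistic, not a defect.

## EMG processing

Diaphragm traces are cleared of ECG first. With manual annotations, the
annotated spans are linearly interpolated (the authoritative path). The
automatic detector exploits two properties of heartbeats: rate regularity
(inter-spike CV < 0.2) and spectral concentration — a ~4 ms biphasic spike
lives *below* the 300 Hz–20 kHz EMG band, so candidates are peaks of the
250 Hz low-passed magnitude, gated by requiring the low-passed amplitude to
reach ≥ 15% of the local broadband amplitude (muscle-burst residuals retain
only a few percent; regular breathing bursts are therefore never mistaken
for a heartbeat). A spike template averaged from the candidates drives a
matched filter, and detected spikes are interpolated out.

Envelopes are full-wave rectified then integrated with a Paynter-style
third-order critically damped low-pass (triple real pole placed so the
single-pass −3 dB point is at 40 Hz), applied forward–backward for zero
phase and unit DC gain. Bursts are envelope excursions above 30% of the
robust maximum (95th percentile; the plain maximum when the envelope is
mostly silent), ≥ 10 ms long, merged across < 10 ms gaps.

Phase statistics over (vocal) breaths: ectopic diaphragm bursts are
diaphragm peaks within the expiration; `cycles_per_expiration` is their mean
count, and because "one cycle" could also count the breath's own inspiratory
burst, the +1 counting is reported alongside (the plain count is the default
reading). Laryngeal phase is (lar_peak − dia_peak_k)/(dia_peak_{k+1} −
dia_peak_k) for laryngeal peaks inside a diaphragm-to-diaphragm interval.
Peak-time PDFs use 20 bins over the normalized expiration. The EMG lead over
airflow is the argmax of the cross-correlation between the (block-averaged)
diaphragm envelope and the inspiratory airflow magnitude max(−flow, 0)
within ±50 ms — the inspiratory limb because the diaphragm drives
inspiration.

## The simulator

The generator is the package's test fixture: it emits airflow, contours,
audio, EMG and complete ground truth under one seed (all randomness flows
through named substreams; fixed seed ⇒ byte-identical outputs).

**Breath train.** Instantaneous frequency is drawn per breath
(normal, mean 7.5 Hz, 10% jitter; sniff bouts of 5–12 breaths at ~9 Hz
interleave with probability 0.25 per breath). Ti is 0.4 of the period.
Inspiration is a negative half-sine (peak −Pif); expiration rises to Pef at
0.12 Te, declines quasi-exponentially (τ = 0.55 Te, ~30% drop over a
syllable-length window), and returns late in expiration to a small positive
plateau (5% of Pef) so the next inspiration onset is a sharp zero crossing
rather than a noise-dominated graze. Each breath's expiration is rescaled so
expired volume equals inspired volume — real breathing conserves tidal
volume, and the balance keeps the 2 Hz high-pass from shifting the
zero-flow baseline around vocal breaths. Multiplicative smooth "wiggle"
noise on the driving pressure (std 0.2, 70 Hz bandwidth) models
breath-to-breath shape irregularity; additive white sensor noise is
0.01 a.u.

**The two mechanisms.** The quantitative convention is the minimal power-law
family in which constriction raises local velocity while lowering measured
flow: measured flow Q = P·a^β (β = 0.5 by default, β ∈ (0,1)), local
velocity v = Q/a, pitch affine in v, mapped into the syllable's target
frequency band. Model 1 holds the aperture constant (a_c = 0.3 of open), so
pitch is *exactly* affine in Q and the noise-free correlation is +1 — the
test suite asserts this to 1e−9. Model 2 holds P constant while the
aperture narrows (depth uniform in 0.4–0.8, with multiplicative laryngeal
motor noise, std 0.3 at 70 Hz); v = P·a^(β−1) then rises while Q = P·a^β
falls. Note f is a convex monotone — not affine — function of Q here, so the
clean correlation approaches but cannot equal −1; empirically it lies in
[−0.998, −0.980] over the depth range, and the tests assert ≤ −0.97.
Phonation is gated on a below 0.6 of open and Q > 0. Mini-breaths are
raised-cosine pressure attenuations (depth 0.9, width 25 ms; depth may
exceed 1 to produce transient inspiratory dips); complex syllables carry
1 + Bernoulli(cycles−1) of them, down fm a single burst ending at phonation
onset. Register jumps are multiplicative steps on pitch only; Q is
continuous at a register jump (asserted), while mixed-mechanism switch
points are tagged separately since holding P constant only inside model-2
segments leaves a small flow step there. Ten piecewise templates define
durations, bands, window placement and jump patterns; syllables that would
run past 90% of Te extend the breath (vocalizing late in expiration
prolongs it), which is why simulated vocal breaths average ~6.7–6.8 Hz
against the 7.5 Hz draw.

The laryngeal-motor-noise and expiration-decay defaults were chosen so that
within-type signal diversity resembles real recordings in the one respect
the statistic depends on: shuffled same-type pairs decorrelate while the
observed pairing does not. With wiggles off, same-type nulls collapse onto
the observed correlation and the method (correctly) loses power; the
defaults are therefore part of the study conditions, not free dials.

**EMG.** Band-limited noise carriers (300–3000 Hz) multiplied by
raised-cosine burst envelopes: diaphragm at every inspiration and every
mini-breath, larynx at fraction φ = 0.69 of each local
diaphragm-to-diaphragm interval. A stereotyped biphasic ~4 ms ECG spike
train (10 Hz — mouse heart-rate order of magnitude — regular, so the
automatic detector's regularity screen applies) contaminates the diaphragm
channel. Airflow and sound lag EMG by 10 ms; ground-truth burst and
mini-breath times are reported on the EMG clock, everything else on the
airflow/sound clock.

**Audio.** Phase-continuous FM sine gated to phonation bins; optional white
noise floor. Audio synthesis is optional in pipelines — contours can be
passed directly downstream, which keeps the test suite fast.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: harmonics and broadband calls, amplitude
modulation, sensor nonlinearity and temperature drift of the
plethysmograph, motion artifacts, inter-animal variability, and real
laryngeal fluid dynamics (the power-law family is a convention; β has no
measured value).

## Numerical conventions

Timestamps are seconds from recording start; intervals are half-open
[onset, offset); contour bins are sample-aligned with the airflow grid so
node interpolation is exact. Degenerate inputs follow one rule: empty or
constant traces segment to an empty list, degenerate correlations are
indeterminate, unclassifiable contours are "unknown" — no NaN propagation,
no exceptions for data-shaped problems. Problem sizes in the test suite and
the acceptance script (60–240 s sessions, 200–500 USVs, 200 permutations,
~500 vocal breaths for EMG statistics) were chosen as the smallest sizes at
which the binomial noise of the recovered fractions is well inside the
asserted margins.

## Known limitations

* The shuffle-null call is population-relative: the same USV can flip
  between positive and indeterminate depending on the diversity of the
  cohort it is analyzed with.
* The automatic ECG detector assumes a regular heartbeat clearly above the
  EMG floor; arrhythmic or buried ECG needs the annotation path.
* The rule-based classifier's precedence resolves ambiguous contours
  deterministically but crudely (e.g., a jump inside a chevron is called a
  step type); it is a stand-in, not a re-implementation of CNN classifiers.
* `burst_phase_metrics` pairs laryngeal peaks with enclosing
  diaphragm-to-diaphragm intervals and so reports no phase for laryngeal
  activity after the last diaphragm burst of a breath.
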