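# intonate

Breath-coupled intonation analysis of mouse ultrasonic vocalizations (USVs).

Mice vocalize in the 40–120 kHz band, one to three syllables nested in the
expiration of a single breath. The pitch pattern of a syllable can be shaped
by two biomechanical mechanisms:

* **positive intonation (breath modulation)** — the expiratory airflow itself
  fluctuates (notably through "mini-breaths": ectopic diaphragm bursts nested
  in expiration) and pitch follows the measured flow, so the Pearson
  correlation *r* between instantaneous expiratory airflow and the USV peak
  frequency is positive;
* **negative intonation (laryngeal constriction)** — a narrowing larynx speeds
  the local airflow (raising pitch) while impeding the overall measured flow,
  so *r* is negative.

`intonate` implements the full analysis chain for simultaneous whole-body
plethysmography (airflow at 1 kHz), ultrasonic audio (250–400 kHz), and
diaphragm/laryngeal EMG (10 kHz):

| module | what it does |
| --- | --- |
| `intonate.breath` | 2 Hz high-pass + smoothing, hysteresis zero-crossing breath segmentation, Ti/Te/Pif/Pef/instantaneous frequency, USV-to-breath assignment and expiration-normalized timing |
| `intonate.pitch` | DPSS multitaper spectrograms, peak-frequency ("pitch") contours, USV interval detection, the strict >20 ms syllable-grouping rule, a transparent rule-based contour classifier for the ten syllable types |
| `intonate.intonation` | per-USV airflow–pitch Pearson *r*, shuffle-null distributions (pitch vs other USVs' airflow and vice versa), positive/negative/indeterminate calls |
| `intonate.emg` | ECG artifact removal (annotated or automatic matched-filter), rectified + Paynter-integrated envelopes, burst detection, mini-breath cycles per expiration, laryngeal burst phase, EMG→airflow lag |
| `intonate.sim` | generative simulator of both mechanisms with complete ground truth — the package's test fixture and calibration surface |
| `intonate.io` / `intonate.cli` | CSV/WAV readers and writers, validated run configuration, manifests, the `intonate` command |

The core statistic, for one USV with valid pitch bins
f(t_1)…f(t_n) and signed expiratory airflow Q interpolated at those bins:

```
r = cov(Q, f) / (σ_Q σ_f)
```

judged against two shuffle nulls in which each USV's pitch (or airflow) is
paired with a *different* USV's airflow (or pitch), time-rescaled onto the
recipient's bins: positive if r exceeds the null's upper 97.5% quantile,
negative below the 2.5% quantile, else indeterminate.

## Worked example

```sh
python examples/04_intonation_calls.py
```

simulates 60 breath-modulation and 60 laryngeal-constriction syllables and
prints:

```
type_label  n  median_r  n_positive  n_negative  n_indeterminate
   complex 30  0.994360          30           0                0
   down fm 30  0.994915          30           0                0
     up fm 60 -0.954212           0          60                0

breath-modulation USVs:       median r = +0.995  (pitch follows measured flow)
laryngeal-constriction USVs:  median r = -0.954  (narrowing raises pitch while impeding flow)
pooled null: 48000 shuffled correlations, 2.5/97.5% quantiles -0.77 / +0.87
```

Every model-1 USV is called positive and every model-2 USV negative: the
observed correlations fall far outside what shuffled pairings produce.
The other examples cover simulation (`01`), breath segmentation (`02`),
audio pitch tracking (`03`), and EMG phase statistics (`05`); each prints the
numbers it computes and one line on what they mean.

The same stages are runnable from a shell:

```sh
intonate run --seed 1 --out out/        # simulate -> breaths -> pitch -> intonation -> emg
intonate simulate --seed 1 --out out/   # ground-truth tables only
```

## Scope

The package analyzes signals; it does not reimplement CNN-based USV
classification (the rule-based classifier is an explicit, documented
stand-in, and externally produced USV tables are accepted as input), does not
calibrate plethysmography to absolute volumes (airflow stays in arbitrary
units and every analysis is scale-invariant), and does not do group-level
statistics across animals. See `docs/methods.md` for the model conventions,
parameter defaults, and known limitations.
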