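"""Track USV pitch from audio with a multitaper spectrogram.

Renders one simulated syllable to a 250 kHz waveform, computes the DPSS
multitaper spectrogram, extracts the peak-frequency contour in the 40-120 kHz
band, detects the syllable interval, and classifies its shape.
"""
import numpy as np

import intonate as it

# low-noise conditions so the template shape is visible in the spectrogram
cfg = it.SimConfig(airflow_noise=0.0, pitch_jitter_khz=0.1, flow_wiggle=0.05,
                   aperture_wiggle=0.05, seed=3)
_, contour_true, rec = it.generate_vocal_breath("chevron", "model1", cfg)

audio = it.synthesize_audio(contour_true, cfg,
                            start_time=float(contour_true.times[0]))
print(f"rendered {audio.size / cfg.audio_rate_hz * 1000:.0f} ms of audio "
      f"at {cfg.audio_rate_hz/1000:.0f} kHz")

spec = it.multitaper_spectrogram(audio, cfg.audio_rate_hz)
contour = it.extract_pitch_contour(spec)
intervals = it.detect_usv_events(contour)
print(f"spectrogram: {spec.power.shape[0]} frames x "
      f"{spec.power.shape[1]} bins ({spec.freqs[1]-spec.freqs[0]:.0f} Hz/bin)")
print(f"detected {len(intervals)} syllable interval(s): "
      + ", ".join(f"{a*1000:.1f}-{b*1000:.1f} ms" for a, b in intervals))

f = contour.f_peak[contour.valid] / 1000
print(f"pitch range {f.min():.1f}-{f.max():.1f} kHz "
      f"over {contour.valid.sum()} valid bins")
ev = it.UsvEvent(id=0, onset=intervals[0][0], offset=intervals[-1][1],
                 syllables=intervals, contour=contour)
print(f"classified as: {it.classify_contour(ev)!r} "
      "(rise-fall contour -> chevron)")
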