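# batnav

A biomimetic model of how an echolocating big brown bat (*Eptesicus
fuscus*) finds a target of a specific *shape* among distractors, built from
two parts:

* **A SCAT receiver** (spectrogram correlation and transformation).  The
  bat's FM broadcast sweeps 100 → 20 kHz.  A target made of two point
  reflectors ("glints") returns two overlapping mini-echoes separated by a
  delay `δt`.  Overall echo delay — and hence range (5.8 ms per metre) —
  comes from *spectrogram correlation*: threshold-crossing events in an
  auditory bandpass filterbank are dechirped against the broadcast and
  pooled across frequencies.  Glint structure comes from *spectrogram
  transformation*: two reflections closer together than the ~350 µs
  cochlear integration time merge into one interference spectrum with
  nulls every `δf = 1/δt` (a 100 µs pair → nulls every 10 kHz), and
  inverting the mean null spacing recovers `δt`.  Reflections farther
  apart than the integration time resolve as separate echoes instead.
* **A search simulation.**  A model bat flies in a 2D range/crossrange
  arena containing two-glint targets whose glint delays span 30–2000 µs,
  exactly one of which has the desired 100 µs (17 mm) spacing.  Each
  broadcast defines an epoch: azimuth is estimated from the interaural
  time difference of the same detection events at the two ears, the sonar
  beam slews quickly onto the nearest target while the flight heading
  follows under a turn-rate limit, and — once the target is nearly dead
  ahead — it is accepted (glint delay within ±20 µs of 100 µs) or
  rejected.  Rejected targets are remembered; the search continues with
  the next nearest target until the desired one is captured.

## Worked example

```python
import numpy as np
from batnav import (generate_broadcast, ScatReceiver, Waveform,
                    preset_scene, run_search, epochs_metric)

# --- receiver: recover a 100 us glint pair from its interference nulls
bc = generate_broadcast()                       # 100->20 kHz, 2 ms, 1 MHz
rec = ScatReceiver(bc)
n = 16384
f = np.fft.rfftfreq(n, 1 / bc.sample_rate)
spec = np.fft.rfft(bc.samples, n)
h = np.exp(-2j*np.pi*f*6e-3) + np.exp(-2j*np.pi*f*(6e-3 + 100e-6))
est = rec.analyze(Waveform(np.fft.irfft(spec * h, n), bc.sample_rate))
print(f"delay {est.overall_delay*1e3:.3f} ms  glint {est.glint_dt*1e6:.1f} us")
print("nulls (kHz):", np.round(est.null_freqs / 1e3, 1))

# --- search: five-target scene, one desired 100 us target (T5)
result = run_search(preset_scene("five"), seed=1)
print(result.outcome, result.captured_target)
print(epochs_metric(result).to_string(index=False))
```

prints

```
delay 6.088 ms  glint 99.6 us
nulls (kHz): [24.9 35.  45.  55.  65.  75.  85.  95.1]
captured T5
 order target  epochs verdict
     1     T1       3  reject
     2     T3      10  reject
     3     T5      14  accept
```

The eight nulls sit near 25, 35, …, 95 kHz — 10 kHz apart, the reciprocal
of the 100 µs glint delay.  The overall delay of a *merged* two-glint echo
reads a few tens of µs late because amplitude-latency trading retards
events in the attenuated null channels (a single-reflection echo reads
true to within a few µs).  In the scene run the bat approaches the two
nearer distractors first (300 µs and 500 µs spacings, both rejected) and
then captures the desired target; the table is the per-target breakdown of
broadcast epochs spent.

## Command line

```
batnav run --scene five --seed 1 --out out/           # exit 0=captured
batnav run --scene scene.yaml --frames --out out/     # PNG frame per epoch
batnav make-scene --random 20 --seed 7 --out scene.yaml
batnav analyze-echo --in ears.wav --broadcast chirp.wav
```

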