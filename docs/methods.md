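# Methods

## Problem and model

The detector answers one question continuously: *has a chosen instant of a
stereotyped song just occurred in the audio stream?*  It treats the
problem as framewise classification of a rolling spectrogram patch.  The
model rests on the assumptions that make zebra finch song tractable: the
song is highly stereotyped across renditions, the chosen target instant is
characterized by the 50 ms of spectral history that precedes it, and the
negative world (silence, cage noise, calls) is spectrally distinguishable
from that history.

### Spectral front end

- FFT size 256 samples, symmetric Hamming window, one-sided power
  spectrum, no 1/N or window-gain normalization.  Absolute spectral scale
  is irrelevant because every recognition window is z-scored; what matters
  is that training and runtime share the identical computation, which the
  test suite checks bit-for-bit.
- The frame interval is quantized: hop = round(sample_rate ×
  requested_interval), ties rounded half away from zero, and the
  *effective* interval hop/sample_rate is what every downstream time
  computation uses.  At 44.1 kHz: 1.0 ms → 44 samples → 0.9977 ms; 1.5 ms
  → 66 samples → 1.4966 ms.  Half-sample ties are not distinguishable from
  either nearest-rounding convention on realistic rates; half-away is
  fixed and documented.
- Frequency band 1–8 kHz, bin inclusion inclusive on both edges (41 bins
  at the defaults).  Inclusivity at the edges is an arbitrary but
  reproducible choice.
- Frames are causal: frame k exists once sample 256 + k·66 has arrived,
  and is timestamped by the end of its analysis window.  No zero-padded
  warm-up frames are fabricated before the first full window; likewise no
  detection can fire before the 33-frame recognition ring first fills.

### Normalization

Window z-score uses the sample-SD convention (n−1), shared exactly between
the training matrix and the streaming path.  A constant window (digital
silence) maps to the zero vector — the unique scale-free choice, and it
keeps silence maximally far from any trained pattern.  Constancy is judged
on the raw values (max = min), not on the computed SD, because the SD of a
constant window can round to a nonzero denormal and amplify pure rounding
noise into unit-scale garbage.

Feature z-score (per element across the training set) stores (μ, σ) in the
model; σ is floored at 1e-8 so elements constant across the corpus cannot
divide by ~0.

### Targets

Targets are Gaussian bumps, σ = 2 ms, truncated at ±3σ, centered on the
*frame containing* t* — the first frame whose analysis window end reaches
t* — so the peak frame carries exactly 1 and the bump lives on the frame
grid.  Centering on the containing frame (rather than the nearest frame,
which may end before t*) keeps the target causal: the network is never
asked to report an instant its input has not yet seen.  It is also what
makes the measured ideal latency positive ≈ t_fft/2, matching how the
trigger instant is defined below.

### Network and training

y = W1·tanh(W0·ξ̌ + b0) + b1, hidden width 4 units per target syllable,
linear outputs, mean-squared-error loss.  The trainer is full-batch
L-BFGS with analytic backpropagation gradients, an 80/20 random
column split stratified so peak-target columns appear on both sides,
early stopping on validation MSE with patience 30, and the
best-validation parameters returned.  Weight initialization is uniform
±1/√fan_in, seeded; the seed is the only source of randomness in the whole
training phase, and training is bitwise reproducible for a fixed seed.
The optimizer identity is recorded in the model file.  Any full-batch
gradient method would serve; the contribution of the pipeline is the
architecture, normalization, and thresholding, not the optimizer.

### Thresholds

The cost FP(θ) + C_n·FN(θ) (C_n = 1, Δt = 10 ms, per-frame accounting on
raw un-de-bounced outputs) is piecewise constant in θ, so the optimizer
searches exactly the midpoints between consecutive sorted unique outputs
plus one point above the maximum; a dense-grid brute force is kept in the
tests as an independent oracle.  Ties are broken toward the **largest**
minimizing threshold: the cost surface is typically flat near the optimum,
and the high end of the flat region is conservative against false
positives on unseen data.  The flip side, verified experimentally, is that
when the training cost reaches exactly zero the chosen θ hugs the smallest
training-set event peak, leaving little false-negative margin; the
δ-corpus is therefore defined to make that margin deterministic (below).
One above-threshold frame may satisfy at most one event window (greedy
assignment in time order), which only matters when targets sit closer than
2Δt.

### Runtime detection

The streaming detector replays the training computation incrementally:
audio ring → per-hop Hamming/FFT/power → FFT ring → both normalizations →
forward pass.  A syllable triggers on an upward crossing (previous output
≤ θ, current > θ) and is then suppressed for 100 ms, counted per syllable
in whole frames rounded up; evaluation continues during the suppression
window.  The emitted events are invariant to how the audio stream is
chunked, and the event timestamp is the end sample of the triggering
frame — the earliest causally available instant.  Hardware side effects
(TTL pulses, serial triggers) are represented by the returned event
records.

## Quantification

- **Accuracy** is per frame: an event at t* is detected if any frame
  within ±Δt is above threshold; every above-threshold frame outside all
  event windows is one false-positive frame, and the false-positive rate
  divides by all out-of-window frames, so it remains meaningful on
  unsegmented streams.
- **Latency** is signed: trigger time − canonical time (a trigger at
  203 ms for a 200 ms target is +3 ms).  Negative latencies are real — the
  output can cross threshold while still rising.  **Jitter** is the sample
  SD of latency over detected events only.
- The **ideal detector** is the offline zero-buffer path: frames at exact
  hop positions, trigger at the first above-threshold frame inside the
  event window.  It measures the timing floor set by the FFT size, the
  frame interval, and the target smoothing, excluding all I/O.
- Canonical-to-trigger matching is greedy nearest-within-±Δt, one-to-one.

## The synthetic corpora

The generator emulates what the pipeline consumes — temporally aligned,
equal-length clips of a stereotyped song plus non-song material — not
zebra finch acoustics per se.

- A **song** is a fixed sequence of syllable archetypes (harmonic stacks,
  band-limited noise bursts, harmonic sweeps, gaps).  The sequence —
  including the fine structure of noise syllables — is rendered once per
  corpus: a stereotyped song is the same acoustic object on every
  rendition, which is the premise the detector exploits.  Renditions
  differ by onset jitter (default SD 2 ms, emulating alignment error and
  tempo variation), a multiplicative amplitude factor (default SD 10%,
  emulating the bird moving relative to the microphone), and additive
  white noise (default SNR 25 dB, plausible for a sound-isolation chamber).
  The `sequence_seed` identifies the "bird"; held-out corpora share it
  while drawing fresh renditions, mirroring the train/test split of a real
  recording session.
- **Non-song** clips mix a silence floor with randomly placed band-limited
  bursts, short tonal calls, and broadband hisses — the negative classes
  (cage noise, calls, wing flaps) that keep the false-positive rate
  honest.  They never contain the song sequence.
- The **δ-corpus** is a full-scale unit impulse per clip in digital
  silence, target 5 ms after the impulse, impulse position swept over one
  hop (66 samples) across the corpus so the impulse phase relative to the
  frame grid covers a full frame interval.  Silence (rather than a faint
  noise floor, available via `noise_floor_db`) keeps the measurement
  deterministic: each phase class is bit-identical across corpora, so the
  δ accuracy and timing results characterize the pipeline, not sampling
  noise.  Default sizes are 1000 songs/1000 non-song for song corpora
  (200/200 in the fast test paths) and 200/200 for δ corpora.

What passing on synthetic data shows: the pipeline's numerics, threshold
logic, streaming equivalence, and timing floor are correct, and the method
recovers a stereotyped song under onset/amplitude/noise variation.  What
it does not show: robustness to real vocal variability (directed vs
undirected song, drift over days), microphone and room acoustics, or other
birds' songs as confusers — those require real recordings.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 200-song/200-non-song
corpora (δ clips 120 ms, song clips ~400 ms), which train in seconds to a
few minutes on one CPU; 200 songs is the low end of what yields acceptable
detectors and keeps the full suite fast.  All floating point is float64
end to end.  Degenerate inputs are handled explicitly: constant windows →
zero vector; constant features → floored σ; events whose ±Δt window
contains no frame → permanent false negatives; corpora with no events →
threshold optimization refuses; clips shorter than one recognition window
→ error naming the clip.

## Known limitations

- The optimizer is L-BFGS rather than scaled conjugate gradient; results
  are equivalent for these problem sizes, but training trajectories are
  not comparable to the original MATLAB toolbox run for run.
- Resampling is out of scope: a model refuses audio at any rate other than
  its training rate.
- The largest-minimizer threshold tie-break is false-negative-brittle when
  training separates perfectly and the evaluation data are noisy near the
  decision boundary; `CostConfig.false_negative_cost` is the intended
  instrument for shifting that tradeoff.
- Per-song accuracy accounting, sliding DFT, data augmentation, and live
  audio hardware are deliberately not implemented.
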