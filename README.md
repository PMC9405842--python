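# oculodex

Binocular eye-tracking analysis for dyslexia screening: detection of
opposite-direction micro-movements of the two eyes (the **Disconjugacy
Global Index**, DGI), velocity-threshold saccade feature extraction, a
calibrated synthetic gaze simulator, and a cross-validated classification
pipeline.

## The problem

During reading and even free viewing, the two eyes of dyslexic adolescents
are less well yoked than those of typical readers: brief episodes occur in
which the left and right eye drift in *opposite* horizontal directions
(micro-convergence / micro-divergence), mostly during fixations between
saccades.  Counting these episodes over a whole recording gives a compact,
stimulus-agnostic marker that separates dyslexic from control groups.

`oculodex` implements this analysis for binocular horizontal gaze
recordings (CSV time series, nominally 200 Hz per eye, positions in
degrees), for researchers and clinicians working with video-oculography.

## The DGI algorithm

Given left/right horizontal positions `Xl, Xr` on timestamps `T`:

1. disparity signal `D[i] = Xl[i] − Xr[i]` (deg);
2. per-interval velocity product
   `DV[i] = (ΔXl[i]/ΔT[i]) · (ΔXr[i]/ΔT[i])` ((deg/s)²) — negative exactly
   when the eyes move in opposite directions;
3. candidate segments = maximal runs of consecutive `DV < 0` intervals;
4. each run is split wherever `sign(D)` changes (`D = 0` is a boundary) and
   each piece is labelled *converging* (|D| shrinking) or *diverging*;
5. segments spanning fewer than 3 position samples are discarded as noise;
6. `DGI = count / (T[n] − T[1])`, in segments per second, alongside the
   mean segment duration (ms) and mean amplitude `|D[end] − D[start]|` (deg).

For example, left eye at +10 °/s with right eye at −10 °/s gives
`DV = −100 (°/s)²` (disconjugate); +10 °/s with +20 °/s gives
`+200 (°/s)²` (conjugate, ignored).

The saccade module extracts the classic velocity-threshold descriptor set
on the conjugate signal `(Xl + Xr)/2` — amplitude, duration, peak/average
velocity, post-saccadic disconjugate drift over 80/160 ms, total amplitude
and fixation duration — summarized per recording as mean / SD / CV / N
(32 features).

## Worked example

```python
from oculodex import SimConfig, CONTROL_PROFILE, simulate_recording, compute_dgi

rec, truth = simulate_recording(CONTROL_PROFILE, SimConfig(seed=1), 12345)
res = compute_dgi(rec)
print(len(truth), res.count, round(res.dgi, 3))
```

prints `411 416 13.867`: the simulator injected 411 opposite-direction
micro-events into a 30 s free-viewing trace; the detector recovered 416
segments (the small surplus is tracker-noise-borne), a DGI of 13.87
segments/s — a typical control-group recording.  Each segment carries its
interval, direction and amplitude:

```python
seg = res.segments[0]
seg.start_time, seg.end_time, seg.direction, seg.amplitude_deg, seg.n_samples
# (0.065, 0.08, 'diverging', 0.00367, 4)
```

The same works from the shell:

```console
$ oculodex simulate --out cohort --n 10 --paintings 2 --seed 7
wrote 40 recordings to cohort
$ oculodex classify --manifest cohort/manifest.csv --features both --seed 42
combined+fused (svm_rbf, n=40): accuracy 87.50% sensitivity 90.00% specificity 85.00%
```

Other commands: `oculodex validate <csv>`, `oculodex dgi <csv>
[--segments-csv out.csv]`, `oculodex features <csv>`.

Sklearn users can drop the extractors into pipelines directly:

```python
from oculodex import DisconjugacyIndexTransformer, SaccadeFeatureTransformer
X = DisconjugacyIndexTransformer().fit(recs).transform(recs)   # (n, 3)
F = SaccadeFeatureTransformer().fit(recs).transform(recs)      # (n, 32)
```

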