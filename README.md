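# swallowfnirs

Event-related fNIRS analysis of swallowing under three head positions
(chin-down, chin-neutral, chin-up), built for researchers studying
postural compensation in deglutition with functional near-infrared
spectroscopy. The package provides the full workflow as tested,
composable modules:

- **`synthgen`** — forward simulation of complete sessions: two-wavelength
  (790/830 nm) optical intensity at 50 Hz over a 10-pair bilateral
  sensorimotor montage, laryngeal accelerometry at 4 kHz, respiratory
  plethysmography at 1 kHz, and ground-truth swallow events under a
  4-block × 3-position × 8-swallow protocol (32 swallows per position).
- **`physio_detect`** — swallow-onset detection: apneas are found where the
  smoothed respiratory derivative stays near zero; within each apnea the
  rectified accelerometer signal, smoothed with a 201-tap Bartlett
  window, is differentiated and the first sustained positive
  zero-crossing marks the onset.
- **`nirs_core`** — raw intensity → ΔOD = −ln(I/Ī) → zero-phase 0.01–0.5 Hz
  Butterworth band-pass → modified Beer-Lambert inversion,
  ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·DPF(λ), solved per sample as
  a 2×2 system → short-separation regression → correlation-based signal
  improvement (CBSI) motion correction.
- **`hdr_epochs`** — epochs from −10 s to +20 s around onset, baseline
  normalisation over [−10, 0) s, the median ΔHbO over the 5–20 s window
  as the response statistic, and aggregation per participant × position
  × hemisphere × timing group (first two / last two / all swallows of a
  segment).
- **`stats_model`** — random-intercept linear mixed model
  `oxyhb ~ position * timing * hemisphere (two-way interactions) + (1 | participant)`
  with backward elimination at α = .05 and Tukey-adjusted pairwise
  position contrasts on estimated marginal means.

## Worked example

```python
import numpy as np
from swallowfnirs import synthgen, physio_detect, pipeline, stats_model

# one synthetic session under the default protocol
session = synthgen.generate_session(seed=1)
events = physio_detect.detect_swallows(session)
frame = physio_detect.events_frame(events)
print(frame[frame["verified"]].groupby("position").size())

# process, epoch and summarise the hemodynamic response
out = pipeline.analyze_session(session)
print(out.summary[out.summary["timing"] == "all"]
      .pivot_table(index="position", columns="hemisphere", values="oxyhb")
      .round(2))

# inference on a cohort of 26 participants
cohort = synthgen.simulate_cohort_hdr(n_participants=26, seed=1)
result = stats_model.backward_eliminate(cohort)
print("retained:", result.retained_terms)
print(result.contrasts.round(3))
```

prints

```
position
down       32
neutral    32
up         32
dtype: int64
hemisphere     L     R
position              
down        0.35  0.36
neutral     0.44  0.46
up          0.75  0.74
retained: ['C(position)']
         contrast  estimate     se  p_adj
0  down - neutral    -0.352  0.128  0.018
1       down - up    -0.907  0.128  0.000
2    neutral - up    -0.555  0.128  0.000
```

All 96 swallows are detected and correctly assigned (32 per position);
the summary table is the mean per-channel median ΔHbO in µM, ordered
down < neutral < up as simulated; backward elimination keeps only head
position, and the Tukey contrasts show chin-up exceeding both other
positions (negative "down − up" and "neutral − up" differences).

The same stages are available from the shell:

```bash
swallowfnirs generate --seed 1 --out session_dir
swallowfnirs detect --session session_dir --out events.json
swallowfnirs run-all --seed 1 --out results_dir
```

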