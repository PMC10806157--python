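# ippgsim

Synthetic skin-patch videos with exact, controllable cardiac ground truth
— plus the classical imaging-photoplethysmography (iPPG) pulse-extraction
methods and the error metrics needed to validate them in a closed loop.

Camera-based vital-sign algorithms recover the blood volume pulse from
sub-percent skin color changes in ordinary video. Benchmarking them on
real recordings is hard because the true pulse at the skin is never
observed directly and confounds (motion, lighting, skin tone, compression)
cannot be varied one at a time. `ippgsim` takes the opposite route: it
*renders* small skin-region videos in which every component is known and
adjustable, then checks whether standard extraction methods give the
configured answer back.

## Model

Each pixel of a rendered frame follows a multiplicative illumination model
on a three-layer skin description (base color / pulsatile subsurface /
static texture):

    C(t) = I(t) · [ b·tex(x,y) + s·c(t) + m(t) ] + N(t)

with the pulsatile color `c(t) = (β_r, β_g, β_b) ⊙ P(t)`,
β = (0.33, 0.77, 0.53), where `P(t) ∈ [0,1]` is a unit-normalized PPG
waveform built from four key-points per beat (wave onset, systolic peak,
dicrotic notch, diastolic peak) joined by monotone cubic interpolation,
with sinusoidal inter-beat-interval modulation for HRV. `m(t)` is an
achromatic motion artifact (heart-rate-locked ballistocardiographic neck
rotation, 0.12° ± 0.03°, plus breathing in the 0.13–0.4 Hz band) projected
to intensity; `I(t)` carries illumination and scenario events; `N` is
Gaussian camera noise. Four benchmark scenarios (stable, expression/talk,
light change, physical activity) schedule periodic and non-periodic action
events on the frame grid.

The extraction suite implements **GREEN**, **ICA** (JADE), **CEEMDAN**,
**CHROM** and **POS**, and the evaluation module estimates a heart rate
every 10 s from the in-band periodogram peak, reporting RMSE (beats/min)
and percent error |P−T|/T·100 against the embedded ground truth. See
`docs/methods.md` for the full model, defaults and limitations.

## Worked example

```python
import numpy as np
from ippgsim import SimulationConfig
from ippgsim.pipeline import simulate_cube, extract_method, evaluate_cube_result

cfg = SimulationConfig(duration=60.0, hr=72.0, skin_tone="III",
                       scenario="stable", seed=1)
cube = simulate_cube(cfg, quantize_8bit=True)   # (1500, 64, 64, 3) uint8
result = extract_method(cube, "pos")            # recovered pulse waveform
report = evaluate_cube_result(cube, result)

print(np.round(report.estimates, 1))   # [72. 72. 72. 72. 72. 72.]
print(np.round(report.truths, 2))      # [72.09 72.09 72.09 72.09 72.09 72.09]
print(round(report.rmse, 3))           # 0.09
```

Six 10-s windows each estimate 72.0 beats/min against a ground truth of
72.09 beats/min (the small offset is the HRV modulation averaged within
windows), an RMSE of 0.09 beats/min — well inside the ≈1.5 beats/min
resolution of the zero-padded 10-s periodogram.

The same loop is available from the shell:

```sh
ippgsim simulate --scenario stable --hr 72 --duration 60 --seed 1 --out video/
ippgsim extract  --method pos --video video/ --out pulse.csv
ippgsim evaluate --pred pulse.csv --truth video/ground_truth.json --out report.csv
ippgsim pipeline --methods green,ica,ceemdan,chrom,pos --out full_report.csv
ippgsim fixtures --out fixtures/ --seed 0
```

Videos are written as lossless PNG frame sequences with JSON ground-truth
and YAML config sidecars (lossy codecs destroy the ~1% pulse signal).

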