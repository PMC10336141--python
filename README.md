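# circare

Circadian activity rhythm energy (CARE) from wrist actigraphy, via singular
spectrum analysis.

## The problem

Circadian amplitude — the strength of the ~24-hour rhythm driven by the
central clock — is usually measured from melatonin profiles, which require a
day of repeated saliva or blood sampling. Wrist accelerometers record activity
counts for free over many days, but the classical actigraphy measure of
amplitude, the relative amplitude

RA = (M10 − L5) / (M10 + L5),

built from the most active 10 h (M10) and least active 5 h (L5) of the day,
is easily distorted by voluntary behaviour (exercise, commuting) that has
nothing to do with the clock.

`circare` implements an energy-based alternative. A multi-day count series
x₁…x_N is embedded as an L×K Hankel trajectory matrix (K = N − L + 1),
factored by SVD into eigentriples (σᵢ, uᵢ, vᵢ), and each rank-one term is
mapped back to a time series by anti-diagonal averaging (singular spectrum
analysis). Eigentriples are grouped by the dominant period of their component
series into a *base* signal (the rank-1 trend), the *24-h signal* (periods in
a configurable circadian band, default 24 h ± 2 h), and *behavioural noise*
(periods < 24 h). Because Σᵢ σᵢ² = ‖T‖²_F, the groups partition the signal
energy exactly, and

CARE = Σ_{i∈I} ‖Xᵢ‖²_F / ‖X‖²_F = Σ_{i∈circadian} σᵢ² / ‖T‖²_F

is a unitless ratio in [0, 1]: the share of total activity energy carried by
the circadian oscillation. The analogous ratio over the sub-24-h group is the
relative energy of behavioural noise.

The package is a complete pipeline for this metric:

- **preprocess** — nonwear detection from zero-count runs (≥ 15 min inside
  08:00–23:00, ≥ 3 h elsewhere, plus diary intervals), valid-day scoring
  (≥ 20 h wear, no missing run > 3 h), two-stage imputation, and a ≥ 3
  valid-day requirement;
- **ssa** — Hankel embedding, exact or FFT-accelerated truncated SVD,
  diagonal-averaging reconstruction, periodogram-based period estimation,
  grouping;
- **features** — CARE, behavioural-noise energy fraction, M10/L5 relative
  amplitude, and an FFT band-energy baseline;
- **melatonin** — cleaning of sparse saliva samples, a skewed
  baseline-cosine (SBCF-style) fit, melatonin amplitude (max − min of the
  fitted 24-h curve), and Pearson validation of wearable features against it;
- **synthetic** — a generator of realistic multi-day count series with
  analytically known circadian energy fraction, for end-to-end testing;
- a `care` command line (`compute`, `simulate`, `validate`).

## Worked example

```python
from circare import SyntheticSpec, generate_subject, extract_features

series, truth = generate_subject(SyntheticSpec(seed=7))  # 7 days, 60-s epochs
fs, qc = extract_features(series)
```

prints, formatted:

```
CARE                 0.149   (planted circadian fraction 0.128)
noise fraction       0.121
base fraction        0.730
relative amplitude   0.576   (M10 328.3, L5 88.2 counts/min)
valid days           7
```

The generator plants a 24-h cosine carrying 12.8 % of the signal energy in a
record that also contains a constant activity level, daytime bursts, and
wideband noise; the SSA pipeline recovers that share as CARE = 0.149, while
the behavioural bursts and noise land in the noise fraction rather than in
the circadian estimate.

The same flow from the shell:

```bash
care simulate --spec spec.yaml --out cohort/          # activity + truth + melatonin CSVs
care compute  --activity cohort/activity --out features.csv
care validate --features features.csv --melatonin cohort/melatonin.csv --out report.json
```

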