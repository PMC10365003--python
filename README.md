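# ironmri

MRI T2* relaxometry for organ iron quantification.

Patients on lifelong transfusion programmes (e.g. transfusion-dependent
thalassaemia) accumulate iron in the liver, heart and pancreas. The
non-invasive standard for monitoring that burden is multi-echo
gradient-echo MRI: magnitude signal decays with echo time as

    y(TE) = K · exp(−TE / T2*)

and tissue iron shortens the effective transverse relaxation time T2*
(ms), so a lower T2* means more iron. This package implements that
measurement chain for imaging scientists and medical physicists:

* **ROI-based fitting** (`relaxometry`): mean in-ROI signal per echo,
  nonlinear least-squares mono-exponential fit, and **automated truncation**
  of late echoes contaminated by the rectified-noise floor — the plateau
  that otherwise inflates T2* exactly where iron overload is severe.
* **Pixel-based mapping** (`mapping`): per-pixel fits assembled into a
  parametric T2* map with a validity mask, map-derived ROI means, and
  deterministic RGB renderings.
* **Severity grading** (`grading`): configurable per-organ thresholds
  splitting T2* into severe / moderate / mild / normal.
* **Cohort statistics** (`cohort_stats`): descriptive summary tables,
  Spearman rank correlations with weak/moderate/strong labels, Loess
  scatter smoothing, and paired method-agreement (mean difference with
  paired-t CI).
* **Synthetic data** (`simulate`): Rician-noise decay curves, 2-D
  multi-echo phantoms, and Gaussian-copula patient cohorts with prescribed
  marginals and rank correlations — every stage is testable with known
  ground truth and no patient data.
* **I/O and pipeline** (`io`, `pipeline`, `ironmri` CLI): NIfTI + JSON
  echo-time sidecars, read-only DICOM series, provenance-stamped CSVs, and
  a deterministic end-to-end run over a patient bundle.

## Worked example

Simulate a severely iron-loaded liver ROI (true T2* = 1.5 ms) whose ROI
brushes background, adding a noise floor of 50 a.u. on top of Rician noise,
then fit with and without automated truncation:

```python
from ironmri import (DecayParams, default_echo_train, simulate_decay,
                     fit_monoexp, truncated_fit)

series = simulate_decay(
    default_echo_train(),                       # TE = 0.8, 1.8, ..., 9.8 ms
    DecayParams(K=1000, T2star=1.5, noise_floor=50, sigma=10, seed=42))

print(truncated_fit(series).summary())
print(fit_monoexp(series).summary())
```

```
Mono-exponential T2* fit
========================
T2*            1.8139 ms   (SE 0.0946)
K            981.1127 a.u. (SE 42.5201)
R2*          551.3134 1/s
r-squared    0.995294
echoes     5 of 10 used  [truncated]

Mono-exponential T2* fit
========================
T2*            1.9618 ms   (SE 0.1595)
K            933.0726 a.u. (SE 63.9935)
R2*          509.7320 1/s
r-squared    0.977932
echoes     10 of 10 used
```

The truncated fit drops the five plateau echoes and lands closer to the
true 1.5 ms; the untruncated fit absorbs the noise floor and overestimates
T2* (with a larger floor the error grows until the patient's severity
category flips). `res.plot()` draws the decay curve with the fitted
trendline and the truncation point.

Cohort statistics work the same way on tables:

```python
from ironmri import simulate_cohort, default_cohort_spec, spearman

cohort = simulate_cohort(default_cohort_spec(n=39, seed=42))
print(spearman(cohort["t2s_pancreas_ms"], cohort["t2s_heart_ms"]))
```

```
CorrelationResult(r=0.5977732793522267, p_value=5.860131401940119e-05,
                  n=39, magnitude='moderate')
```

— a moderate positive pancreas–heart rank correlation, as expected from
the generator's default target of 0.504: pancreatic and cardiac iron load
track each other because both organs take up non-transferrin-bound iron.

The same stages are scriptable from the shell:

```bash
ironmri simulate-bundle --n-patients 5 --seed 1 --out bundle
ironmri run --input-dir bundle --output-dir results --seed 1
ironmri simulate-cohort --n 39 --seed 1 --out cohort.csv
ironmri grade cohort.csv --out graded.csv
```

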