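# cobbkit

Computer-aided Cobb angle measurement for scoliosis radiographs, with a
complete validity and absolute-reliability analysis pipeline and a
synthetic observer-study simulator.

## The problem

The Cobb angle — the angle between the cranial endplate of the most
tilted vertebra above a scoliotic curve's apex and the caudal endplate
of the most tilted vertebra below it — is the clinical standard for
grading adolescent idiopathic scoliosis (AIS) and deciding between
observation, bracing and surgery. Manual measurement on film with
acetate and protractor carries inter-observer variability that can
exceed the 5° threshold conventionally taken to indicate progression.
Landmark-based measurement software removes most of those intrinsic
error sources: the observer clicks the two points defining each
candidate endplate, the software computes tilts, picks the most tilted
end vertebrae automatically, and reports the angle to 0.1°.

`cobbkit` is for researchers who run (or audit) observer-agreement
studies of such tools: it implements the measurement geometry, the
DICOM viewing transforms whose separation from measurement is the
tool's core safety property, the session/study-table data formats, the
reliability statistics, and a simulator that generates whole studies
from a known ground truth.

## The statistics

For each comparison distribution (per-curve errors between rounds,
between experience groups, or between methods), after single-pass
Tukey-fence outlier pruning (`Q1 − 1.5·IQR`, `Q3 + 1.5·IQR`) leaving
`gl` curves:

- **MBE** (mean bias error) — mean of the per-curve errors;
- **SD** — sample standard deviation (n−1);
- **SE** = SD/√gl;
- **MDC95** = 1.96·√2·SE — the minimum detectable change at 95%
  confidence;
- **ICC(2,1)** — intraclass correlation, two-way random effects,
  single measure, absolute agreement:
  `ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)`
  with the McGraw–Wong F-based 95% CI and the Landis–Koch label;
- **Bland–Altman** bias and 95% limits of agreement for
  software-vs-manual concordance, computed on per-curve consensus
  means (all observers × rounds per method);
- one-way **ANOVA + Tukey HSD** across the pooled intra-group error
  distributions and **Student's t** between the two inter-group
  distributions.

## Worked example

Simulate a full study — 35 curves in six severity strata, 4 expert and
4 novice observers, 3 rounds, software and manual methods, 1680
measurements — and analyse it:

```sh
cobbkit simulate --seed 7 --out study.csv
cobbkit analyze study.csv --out-prefix report
```

The report prints one row per comparison (here the first manual-method
rows; `E1E2` is the expert group's round-1-vs-round-2 error, `E` the
pooled expert intra-group error, `E1N1` the expert-vs-novice round-1
error):

```
comparison   method   MBE    SD  gl    SE  MDC95   ICC  CI95_low  CI95_high    landis_koch
      E1E2   manual 2.199 0.831  35 0.140  0.389 0.994     0.988      0.997 almost perfect
         E   manual 2.175 0.599  35 0.101  0.281 0.995     0.992      0.998 almost perfect
      E1N1   manual 0.916 0.627  35 0.106  0.294 0.997     0.994      0.998 almost perfect
```

and the method-agreement summary:

```
method agreement: MBE=0.231 SD=0.415 SEM=0.071 MDC95=0.197 ICC=0.999 CI95=(0.999, 1.000)
ANOVA across pooled intra-group errors: F=20.387 p=6.06e-11
```

Reading this: within the expert group, repeat manual measurements of
the same curve differ by ~2.2° on average; that error is stable enough
that a change larger than ~0.3–0.4° (MDC95) exceeds measurement noise;
agreement is "almost perfect" on the Landis–Koch scale; and the two
measurement methods agree with negligible bias. The ANOVA confirms the
group/method error levels differ (experts vs novices, software vs
manual), which is exactly what the simulator's noise calibration
encodes.

A phantom radiograph exercises the geometry end to end:

```sh
cobbkit phantom --tilts 27.4,-38.4 --out phantom.dcm --landmarks marks.json
cobbkit measure marks.json
# curve_id,cranial_vertebra,caudal_vertebra,cobb_deg
# C01,V1,V2,65.8
```

## Library use

```python
import numpy as np
from cobbkit import (StudyDesign, default_observers, sample_true_curves,
                     simulate_study, full_report)

design = StudyDesign()
rng = np.random.default_rng(1)
truth = sample_true_curves(design, rng)
table = simulate_study(truth, default_observers(), design, rng)
report = full_report(table)          # 24 comparison rows + agreement
print(report.rows.head())
print(report.agreement.icc.icc)
```

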