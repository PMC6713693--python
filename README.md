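# fatkinetics

Longitudinal MRI fat quantification after bariatric surgery, as a tested,
reusable analysis pipeline. The package is aimed at quantitative-imaging
and biostatistics researchers who track fat compartments — percentage
liver fat (%-LF), total liver volume (TLV), visceral and subcutaneous
adipose tissue (VAT, SAT) — over a surgical weight-loss time course and
need the full chain from segmentation masks to population statistics:

- **Quantification** — whole-organ volumes as voxel count × voxel volume
  from NIfTI label masks, mean fat fraction over the liver mask, axial
  confinement of adipose masks; plus a synthetic abdominal phantom with
  analytic ground truth.
- **Kinetics** — every compartment follows exponential decay with a late
  rebound, Y(t) = exp(A + B·t) + A1·t, where A = log initial value,
  B = decay rate (decay constant −B), and A1 = slope of the ascending
  process after the nadir. Per-subject damped Gauss–Newton fits feed a
  two-stage population summary.
- **Statistics** — one-way random-effects ICC of the triplicate
  presurgical measurements, exact paired Wilcoxon signed-rank comparisons
  of decay constants, Bonferroni-corrected comparisons vs baseline,
  per-timepoint linear associations with the blood panel (absolute and
  Δ-vs-Δ), HOMA-IR = glucose·insulin/22.5, percent decline.
- **Synthetic cohorts** — a seeded generator reproducing the study design
  (16 subjects; triplicate baseline plus 3, 6, 12, 24 months) with
  correlated per-subject decay rates, ICC-calibrated measurement noise
  and blood-panel links, so the whole pipeline runs without patient data.

See `docs/methods.md` for the model, calibration and numerical details.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/03_fit_kinetics.py
python analysis/04_compare_decay.py
```

`01` generates the default 112-record cohort and reports the
triplicate-baseline reproducibility:

```
triplicate-baseline reproducibility (one-way ICC):
  lf_percent: ICC = 0.88 (MSB 96.2, MSW 4.34)
         tlv: ICC = 0.90 (MSB 4.71e+05, MSW 1.69e+04)
         vat: ICC = 0.94 (MSB 15, MSW 0.316)
         sat: ICC = 0.93 (MSB 55.6, MSW 1.32)
```

`03` fits the kinetic model per subject and summarizes the population
(mean of per-subject estimates ± SE; decay constant = −B):

```
  lf_percent: A  2.1908+/-0.1383  B  -0.2144+/-0.0275  A1    0.0410+/-0.0199  decay constant 0.214  (n=16)
         tlv: A  7.4589+/-0.0480  B  -0.0799+/-0.0074  A1   47.7016+/-3.9239  decay constant 0.080  (n=16)
```

Liver fat clears at ≈0.21 per month — roughly twice the rate of the
adipose-tissue volumes — and `04` confirms the contrast with exact paired
Wilcoxon tests on the per-subject constants:

```
compartment_1 compartment_2  n_pairs     w        p method
   lf_percent           vat       16 126.0 0.001312  exact
          vat           sat       16  90.0 0.274445  exact
```

The same stages are available as a CLI (`fatkinetics simulate | phantom |
quantify | fit | test-decay | associate | report | run-all`), e.g.

```bash
fatkinetics run-all --seed 21 --out run/
fatkinetics quantify --ff ff.nii.gz --mask mask.nii.gz \
    --labels liver,sat,vat --confine 20:140 --out volumes.csv
```

`run-all` writes every stage table, a Markdown report, the resolved
configuration and a checksum log; reruns with the same seed are
byte-identical.

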