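# scpassay

Analysis of **spheroid control probability (SCP) assays** — the in-vitro
analogue of tumour control probability studies — for testing combined
hyperthermia (HT) + radiotherapy (RT) treatments on multicellular tumour
spheroids.

Spheroids (~400 µm 3-D tumour-cell aggregates) are heated, irradiated with a
single X-ray dose and imaged every 2–3 days for up to 60 days.  A spheroid
that never resumes growth is *controlled*; the per-arm controlled fraction is
the SCP.  This package takes longitudinal volume trajectories and produces:

* **relapse classification** — regrowth declared at the first run of three
  consecutive measurement-to-measurement volume increases; otherwise the
  spheroid is controlled and right-censored,
* **Kaplan–Meier curves** of the still-controlled proportion over time, with
  log-rank (Mantel–Cox) comparisons,
* **logistic dose–response fits** per thermal condition,

  SCP(D) = 1 / (1 + e^(−a − bD)),

  by binomial maximum likelihood (Firth-penalized fallback under
  separation), giving **SCD50 = −a/b**, the dose controlling 50% of the
  population, with percentile CIs from a 4000-sample spheroid-level
  bootstrap,
* **thermal enhancement ratios** TER = SCD50(RT) / SCD50(HT+RT) with
  bootstrap CIs and significance,
* **growth delay** — each spheroid's time to reach 5×V₀ (regression through
  the log-volumes around the crossing) normalised by the untreated control
  mean, compared with the Mann–Whitney U test,
* a **synthetic trajectory generator** with known ground truth (Gompertz
  growth, dose-dependent regrowth lag, lognormal measurement noise) so the
  whole pipeline is testable end to end without raw imaging data.

## Worked example

```python
from scpassay import (ExperimentDesign, ResponseParams, bootstrap_scd50,
                      compute_ter, compare_scd50, simulate_control_outcomes)

design = ExperimentDesign(n_per_arm=56)   # 11 dose arms, 0-25 Gy in 2.5 Gy steps
response = ResponseParams()               # true SCD50: 11.1 Gy (RT), 8.7 Gy (42.5C/30min)

fits = {}
for cond in ((37.0, 0.0), (42.5, 30.0)):
    flags = simulate_control_outcomes(design, response, cond, seed=11 + int(cond[0]))
    fits[cond] = bootstrap_scd50(flags, n_boot=4000, seed=17)
ter = compute_ter(fits[(37.0, 0.0)], fits[(42.5, 30.0)])
```

prints (see `examples/dose_response_fit.py`):

```
37C/0min: a=-5.09, b=0.456/Gy, SCD50 = 11.2 Gy (95% CI 10.5-11.8)
42.5C/30min: a=-4.32, b=0.519/Gy, SCD50 = 8.3 Gy (95% CI 7.8-8.9)
TER = 1.3 (95% CI 1.2-1.5), SCD50 difference p = 0
```

The fitted SCD50s recover the simulation ground truth within sampling error
at 56 spheroids/arm; TER = 1.3 means the heated population needs ~30% less
dose for the same control probability.  Each script in `examples/` is a
self-contained narrative of one capability (simulation, growth delay,
KM/log-rank, dose–response, full pipeline).

## Command line

A thin CLI wraps the library:

```sh
scp simulate --config sim.yaml --seed 1 --out traj.csv
scp classify --in traj.csv --out outcomes.csv
scp growth-delay --in traj.csv --k 5
scp km --in outcomes.csv --dose 7.5 --compare "37C/0min" "42.5C/30min"
scp fit --in outcomes.csv --reference "37C/0min" --n-boot 4000 --seed 17
scp report --config run.yaml
```

## Layout

```
src/scpassay/
  simulate.py       synthetic experiments with ground-truth labels
  volumetrics.py    volumes, time to 5xV0, growth delay, Mann-Whitney
  control.py        relapse rule, SCP, Kaplan-Meier, log-rank
  dose_response.py  logistic fits, SCD50, bootstrap, TER
  io.py             CSV schemas, validation, YAML config
  pipeline.py       end-to-end orchestration and reporting
  plotting.py       KM and dose-response figures
  cli.py            the `scp` command
```

See `docs/methods.md` for the model, parameter and design details.
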