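# t2dsim

An individual-level, discrete-time (1-year cycle) microsimulation of type 2
diabetes (T2DM) progression across the full care continuum, built for health
economists and modellers who need to evaluate **preventive** as well as
management interventions. Unlike models that start at diagnosis, `t2dsim`
simulates patients from normal glucose tolerance through pre-diabetes to
diagnosed diabetes, with comorbidities and mortality on both sides of onset
and correlated progression of the underlying risk factors.

## The model in brief

Each patient moves through two levels every simulated year:

* **Health state** from glycated haemoglobin: HbA1c < 6.5 % is
  NGT/pre-diabetes; HbA1c ≥ 6.5 % is T2DM (absorbing). A patient whose
  HbA1c lies in the pre-diabetes band (6.0–6.4 %) has probability
  *p* = 0.129 per year of a sudden rise of 0.54 percentage points that
  carries them into the diabetic range; otherwise HbA1c follows its
  progression equation.
* **Events and death.** Before onset: MI, CHF and stroke via
  Framingham-style annual hazards, with event-year mortality from age/sex
  case-fatality tables and cause-deleted background mortality otherwise.
  After onset: eight comorbidities (CHF, IHD, blindness, renal failure,
  MI, stroke, amputation, diabetic ulcer) via UKPDS-OM2-style Weibull /
  Gompertz / logistic equations, evaluated in randomised order with caps
  (chronic conditions once; acute events at most twice), and one of four
  mutually exclusive mortality equations selected by comorbidity history ×
  new events. Annual probabilities come from integrating the hazard over
  the cycle, `p = 1 − exp(−H(t, t+1))`.
* **Risk factors** (HbA1c, BMI, SBP, LDL, HDL, eGFR, haemoglobin, WBC,
  heart rate, plus binary albuminuria/PVD/AF/LVH) update each year through
  interdependent equations, producing correlated trajectories.

On top of the engine sit cost/QALY accrual (CAD 2022; 1.5 % discounting),
probabilistic sensitivity analysis with common random numbers across arms,
internal/external validation harnesses (Kaplan–Meier cumulative failure,
calibration regression, simulated-to-observed incidence ratios), and a
cost-effectiveness case study of a DPP-style intensive lifestyle
prevention programme (50 % compliance, INMB at CAD 30,000/QALY).

**Parameter values shipped with the package are synthetic reference
values** — structurally faithful, analytically calibrated to plausible
epidemiology, and fully editable in `src/t2dsim/data/default_model.yaml` —
see `docs/methods.md`. Replace them with literature-transcribed
coefficients to model a real population.

## Worked example

```python
import t2dsim as t

cfg = t.load_config()                                  # packaged defaults
cohort, _ = t.make_fixture_cohort("uk_t2dm_like", 5100, seed=1, cfg=cfg)
res = t.simulate_cohort(cohort, cfg.coefficients, horizon=20, seed=1)

print("deaths:", int((res.death_year >= 0).sum()))
mi = t.km_cumulative_failure(res, "MI")                # years 5/10/15/20
print("MI cumulative failure:", mi.cumulative_failure.round(3))

cost, qaly = t.accrue_cohort(res, cfg.costs, cfg.utilities)
from t2dsim.economics import discounted_totals
dc, dq = discounted_totals(cost, qaly, cfg.run.discount_rate)
print("mean discounted cost (CAD 2022):", round(dc.mean()))
print("mean discounted QALYs:", round(dq.mean(), 2))
```

Output (seed 1):

```
deaths: 2089
MI cumulative failure: [0.062 0.141 0.24  0.34 ]
mean discounted cost (CAD 2022): 78026
mean discounted QALYs: 12.11
```

Of 5,100 newly diagnosed patients, 2,089 die within 20 years; 6.2 % have
had a first MI by year 5 and 34 % by year 20; a patient accrues on average
about CAD 78k of discounted direct costs and 12.1 discounted QALYs.

The same pipelines are available from the shell:

```bash
t2dsim simulate --kind uk_t2dm_like --n 5100 --horizon 20 --seed 1 --out out/
t2dsim validate-internal --n 5100 --iterations 100 --seed 1
t2dsim validate-external --iterations 100 --seed 2
t2dsim case-study --iterations 100 --seed 3
```

## Layout

| Path | Contents |
| --- | --- |
| `src/t2dsim/cohort.py` | baseline sampling, health-state classification |
| `src/t2dsim/risk_models.py` | equation algebra, transition, mortality |
| `src/t2dsim/engine.py` | vectorised annual cycle, trajectories |
| `src/t2dsim/intervention.py` | prevention-programme overlay |
| `src/t2dsim/economics.py` | costs, QALYs, discounting, CEA |
| `src/t2dsim/psa.py` | parameter priors, PSA loop |
| `src/t2dsim/validation.py` | KM, calibration regression, ratios |
| `src/t2dsim/run.py` | study workflows |
| `src/t2dsim/config.py`, `cli.py` | config I/O, manifests, CLI |
| `src/t2dsim/data/` | editable synthetic parameter fixtures |
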