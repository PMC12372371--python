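# nursecast

System-dynamics projection of a nursing and midwifery workforce, built
for health-workforce planners studying the transition from foreign
recruitment to domestic self-sufficiency. The default parameterisation
describes Ireland's professionally active nurses and midwives from a
2021 base year over 30 years.

## The model

Supply is held in four age-structured stocks (gender × domestic/foreign
education), measured in whole-time equivalents (WTE), drained by three
annual outflows — retirement, emigration, net attrition — and fed by a
lagged education pipeline and by gap-filling foreign recruitment.
Demand is aggregate and compound:

```
D_t = D_0 (1 + g)^t,             D_0 = 64,383 WTE, g = 1.4 %/yr
RR_t = (D_{t+1} − D_t) + Σ outflows_t        (recruitment requirement)
foreign_t = max(0, RR_t − domestic_inflow_t)          (gap rule)
inflow_t = places_{t−4} × completion × conversion     (pipeline, 4-yr lag)
```

Three scenarios: **A** keeps student places constant (the gap stays
foreign-filled); **B** and **C** ramp places from 2024 so that domestic
graduate inflow equals the recruitment requirement by 2034 and 2044
respectively. A one-at-a-time sensitivity analysis perturbs the demand
growth rate and the net-attrition schedule by ±15 %.

The register data behind the original parameterisation is not public,
so `nursecast.synthetic_data` generates register-style stand-ins —
stable-growth age structures plus calibrated exit schedules — that hit
the published 2021 aggregates exactly (total 64,383; foreign 29,285;
domestic inflow 1,469/yr; requirement 3,019 = 901 expansion + 2,118
replacement). See `docs/methods.md` for model conventions, calibration
details, and what the synthetic fixtures do and do not validate.

## Worked example

```python
import nursecast as nc

params = nc.make_model(seed=0)            # calibrated synthetic register
ledger = nc.run_scenario(nc.scenario("A"), params)

print(round(ledger.loc[2051, "demand_wte"]))                   # 97703
print(round(ledger.loc[2021, "recruitment_requirement_wte"]))  # 3019
print(round(ledger.loc[2051, "recruitment_requirement_wte"]))  # 4524
print(round(100 * ledger.loc[2051, "stock_foreign_wte"]
            / ledger.loc[2051, "demand_wte"]))                 # 58

b = nc.run_scenario(nc.scenario("B"), params)
print(nc.self_sufficiency_year(b))                             # 2034

places = params.pipeline.required_places(3019.0)
print(round(places), round(100 * (places - 1570) / 1570))      # 3965 153
```

Reading the numbers: demand grows from 64,383 to ~97,703 WTE by 2051
(+52 %); the annual recruitment requirement rises from 3,019 to ~4,524
WTE; without reform the foreign-educated share of demand climbs from
45 % to ~58 %. Meeting the 2021 requirement domestically would have
needed 3,965 student places four years earlier — 153 % more than the
1,570 available. Under rapid reform (scenario B), domestic inflow first
covers the whole requirement in 2034 and foreign recruitment stops.

The same runs are available from the shell:

```sh
nursecast replicate-paper --out out/        # scenarios A/B/C + sensitivity
nursecast scenario --name B --config cfg.yaml --out out/
nursecast sensitivity --config cfg.yaml --out out/
nursecast make-fixture --seed 7 --out fixtures/
python scripts/make_figures.py --ledgers out --out figures/
```

A minimal `cfg.yaml` is just `fixture: {seed: 0}`; supply
`inputs: {stocks_csv: ..., rates_csv: ...}` instead to run on real
register extracts (CSV columns `age, gender, origin, wte` and
`age, gender, origin, retirement_rate, emigration_rate, attrition_rate`).

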