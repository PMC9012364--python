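# bphcea

A Markov cohort cost-utility model comparing five treatment strategies for
moderate-to-severe lower urinary tract symptoms attributed to benign
prostatic hyperplasia (BPH), from a US Medicare payer perspective over a
5-year horizon:

| Code | Strategy |
|------|----------|
| CT   | combination drug therapy (alpha-blocker + 5-ARI) |
| PUL  | prostatic urethral lift |
| WVTT | water vapor thermal therapy |
| PVP  | photoselective vaporization of the prostate |
| TURP | transurethral resection of the prostate |

A simulated cohort of 63-year-old men (baseline International Prostate
Symptom Score 22 ± 4.8) moves through quarterly cycles in year one and
annual cycles thereafter. Each strategy carries a published symptom-score
trajectory; symptom severity (mild/moderate/severe) maps to health-state
utilities and follow-up costs. The model layers on procedure costs,
catheterization, adverse events by category (periprocedural, short-term,
long-term), retreatment, age-dependent background mortality, and 3% annual
discounting, and reports total costs, QALYs, incremental
cost-effectiveness ratios (ICERs) against drug therapy, the efficiency
frontier, and one-way/probabilistic sensitivity analyses.

Several quality-of-life inputs (severity utilities, catheter and
adverse-event disutilities) and the background life table ship as clearly
labelled **synthetic stand-ins** in the packaged deck; see
[`docs/methods.md`](docs/methods.md) for exactly what is published data and
what is not, and what the test suite does and does not establish.

## Quick start

```sh
$ bphcea run --out out/
wrote out/cea.csv
    CT  cost $    6,910  QALYs 4.083  reference  -
   PUL  cost $    8,126  QALYs 4.101  icer       $70,401/QALY
  WVTT  cost $    2,537  QALYs 4.136  dominates  -
   PVP  cost $    6,190  QALYs 4.125  dominates  -
  TURP  cost $    6,991  QALYs 4.113  icer       $2,745/QALY
```

With the packaged reference deck and its synthetic stand-in inputs, WVTT
dominates drug therapy (cheaper and more effective) and anchors the
efficiency frontier. Other subcommands:

```sh
bphcea trace --out out/            # per-cycle cohort ledgers
bphcea owsa --strategy WVTT        # one-way sensitivity tornado
bphcea psa --seed 1 --draws 1000   # probabilistic sensitivity analysis
bphcea scenario --trajectories alt_trajectories.csv
bphcea calibrate --targets targets.json
bphcea synth --seed 7              # generate a random synthetic deck
```

Every invocation writes a `manifest.json` (command line, deck, seed, tool
version) beside its outputs so runs can be reproduced bit-for-bit. Exit
codes: 0 success, 2 input/validation failure, 64 usage error.

## Python API

```python
from bphcea import reference_deck, run_cohort, incremental_analysis, StrategyTotals

deck = reference_deck()
totals = []
for name in deck.strategy_names():
    tr = run_cohort(deck, name)
    totals.append(StrategyTotals(name, tr.total_cost, tr.total_qalys))

res = incremental_analysis(totals, reference="CT")
print(res.row("WVTT").label)        # 'dominates'
```

Input decks are a YAML manifest plus six CSV tables (strategies, symptom
trajectories, adverse-event rates, costs, utilities, life table); see the
packaged example under `src/bphcea/data/medicare2021/`. `load_input_deck`
validates every field and reports all violations at once.

## Tests

```sh
python -m pytest -q tests/
```

The suite covers unit oracles (hand-computed two-cycle ledgers, a
Monte-Carlo check of the severity mapping, a brute-force efficiency
frontier), property-based tests, CLI contracts, and an acceptance module
(`tests/test_acceptance.py`) that checks the model against the published
analysis it reimplements. One acceptance check — full-model reproduction
of the published totals within tolerance — fails by design with a
detailed deviation report: the packaged deck substitutes synthetic
stand-ins for unavailable quality-of-life and adverse-event inputs, and
those deviations are reported rather than hidden. `docs/methods.md`
discusses the gap.
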