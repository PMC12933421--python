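# evactwin

A digital-twin simulator for theory-driven crisis messaging in hurricane
evacuations, with the accompanying statistical analysis toolkit.

`evactwin` models how differently framed emergency messages — fear appeals,
efficacy cues, social-norm cues, and their combinations — change evacuation
compliance in a synthetic coastal-urban population. Agents carry beliefs from
the Extended Parallel Process Model (EPPM) and the Theory of Planned Behavior
(TPB); a message shifts those beliefs, an EPPM appraisal routes each agent into
*danger control* (deliberate protective action) or *fear control* (denial and
inaction), and a logistic decision rule

```
P(evacuate) = σ( α·T + β·E + γ·N − δ·C − c₀ )
```

turns perceived threat `T`, efficacy `E`, subjective norm `N`, and a
constraint burden `C` (mobility, vehicle access, finances, pets, caregiving)
into a deterministic, seeded decision. A 16-condition × 10-replication
experiment over 3,550 agent-observations reproduces the qualitative finding
the model is built around: single-cue messages barely move compliance, while
combined fear + efficacy (+ norm) messages raise it by an order of magnitude.

See [docs/methods.md](docs/methods.md) for the model and calibration details.

## Quick start (library)

```python
import evactwin as et

# simulate the default 16-condition experiment
design = et.default_design(master_seed=0)
result = et.run_experiment(design, et.load_population_config(),
                           et.load_default_weights())

# analyze: chi-square, pooled rates, odds ratios
table = et.build_table(result)
print(et.chi_square_test(table).statistic)
print(et.framing_rates(table, et.default_grouping()))

# the published-counts fixture reproduces the reference statistics exactly
published = et.load_published_counts()
fit = et.fit_grouped_logistic(published, et.default_grouping(), "control")
print(fit.estimates["fear_efficacy"].odds_ratio)   # 15.45
```

## Quick start (CLI)

```sh
evactwin simulate --out runs/demo --seed 0        # records.csv, counts.csv, manifest.json
evactwin analyze  --counts runs/demo/counts.csv --out runs/demo
evactwin report   --out runs/report --seed 0      # simulate + analyze in one step
evactwin calibrate --out weights.yaml             # seeded grid search
```

All commands are reproducible byte-for-byte for a fixed `--seed`, never mutate
their inputs, and write nothing on failure (missing files exit with status 2,
invalid content with status 1 and a message naming the offending field).
`--verbose` prints the per-replication seed derivations for audit.

## Package layout

- `evactwin.maf` — Message Assessment Framework: the 16-message catalog and
  the deterministic mapping from framing category to belief-construct deltas.
- `evactwin.population` — zoned synthetic population sampler (demographics,
  flood-zone residence, shelter distance, evacuation constraints).
- `evactwin.decision` — belief initialization, message ingestion, EPPM
  appraisal, the logistic decision rule, and `calibrate_weights`.
- `evactwin.engine` — seeded condition/replication orchestration and
  aggregation.
- `evactwin.stats` — chi-square with adjusted standardized residuals, pooled
  framing rates, grouped logistic odds ratios, noncentral-χ² power analysis.
- `evactwin.cli` — the `evactwin` command.

## Testing

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion: exact
reproduction of the reference statistics from the packaged counts fixture,
and property-based checks of the simulator (determinism, order invariance,
conservation, monotonicity against an exhaustive grid oracle, clipping, and
the qualitative framing-effect ordering under the shipped calibration).

`scripts/acceptance.py --seed 1 --out report.json` recomputes every headline
quantity from scratch and writes a machine-readable report.
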