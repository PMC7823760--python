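# fwaging

Healthy-aging (HA) analysis pipeline: operational scoring of the four HA
criteria on individual survey records, factor screening (Pearson chi-square
and block logistic regression), backward stepwise logistic selection, and
the F-W composite regional index (`HA = sum(F_i * w_i)`) with trend
classification and economic-zone aggregation. All stages run on synthetic
data generated with known ground truth, so the whole pipeline is testable
without any external microdata.

## Modules

| module | purpose |
| --- | --- |
| `fwaging.synthetic_data` | micro survey records from a logistic outcome model; macro regional panels with configurable trends |
| `fwaging.ha_criteria` | Y1-Y4 criterion scoring, composite HA, prevalence, Cronbach's alpha |
| `fwaging.factor_screening` | 2x2 crosstabs, chi-square screen, block and per-criterion logistic fits |
| `fwaging.stepwise_model` | backward stepwise elimination with full per-step trace |
| `fwaging.fw_index` | weight derivation (`w = |ln OR|`), regional factor ratios, composite scores, trend types, zone means, charts |
| `fwaging.cli_pipeline` | `fw-aging` CLI and end-to-end `run_all` with a reproducibility manifest |

## CLI

```bash
# synthetic inputs
fw-aging simulate --micro --out micro.csv --seed 1 -n 2000
fw-aging simulate --macro --out panel.csv --seed 2 -n 8

# individual-level stages
fw-aging score --in micro.csv --out profiles.csv --report reliability.json
fw-aging screen --in micro.csv --profiles profiles.csv --out-dir screen/
fw-aging stepwise --in micro.csv --profiles profiles.csv --alpha 0.05 --out step/

# regional index (weights come from the stepwise stage or a hand-written JSON)
fw-aging fw-index --panel panel.csv --weights step/weights.json --out index/
fw-aging classify --indices index/indices.csv --out trends.csv

# everything at once, with a manifest of checksums for bit-identical re-runs
fw-aging run-all --out-dir run/ --seed 1
```

Zone membership for the aggregation stage ships as an editable YAML file
(`src/fwaging/data/zones.yaml`); pass an alternative with `--zones`.

## Notes and caveats

- Chi-square is Pearson without continuity correction; two published
  reference statistics are truncated rather than rounded (8.478 printed as
  8.47, 7.959 as 7.95), so comparisons are made at one unit in the last
  printed place.
- Depression items are summed as recorded (no reverse-coding).
- Two published chi-square rows (X8, X10) are not reproducible from their
  own printed cells and are excluded from reference checks.
- Weights use the magnitude convention `|ln OR|`; a signed variant is
  available (`derive_weights(..., signed=True)`).
- The baseline-100 normalization is `100 * sum(F w) / sum(w)`, which makes
  a region at the national average in every factor score exactly 100.
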