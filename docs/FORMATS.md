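# File formats

## Plate table CSV (input and simulator output)

UTF-8, comma-separated, header row.  Columns, in order:

| column | type | notes |
|---|---|---|
| `target` | enum | `EGFR_DEL19`, `EGFR_L858R`, `EGFR_T790M`, `BRAF_V600`, `KRAS_EX2`, `EGFR_WT` |
| `standard` | label | `A`–`G`, `WT_ONLY`, `NTC` |
| `plate` | label | plate/run identifier |
| `instrument` | label | |
| `operator` | label | |
| `replicate` | int ≥ 1 | |
| `ct` | float or blank | blank = no amplification (empty well); `0` is a parse error |
| `tm` | float or blank | melt-peak °C; must be blank when `ct` is blank |
| `wt_copies` | int ≥ 0 | WT background copies in the well |
| `truth_copies` | float or blank | nominal mean mutant input for control wells |
| `seq_confirmed` | `true`/`false`/blank | blank = not sequenced |

A custom column mapping can be passed to `read_plate_table(path, schema=...)`.

## QC config JSON

```json
{
  "min_ct": 10,
  "max_ct": 45,
  "tm_windows": {"BRAF_V600": [80.5, 83.5]}
}
```

## Simulation config JSON (CLI `simulate` / `validate`)

```json
{
  "curve": {"slope": -3.45, "intercept": 38.6, "sigma_ct": 0.3},
  "wt_shift": [-0.32, 0.52],
  "fp_rate": 0.04,
  "tm_specific": [82.0, 0.4],
  "tm_nonspecific": [76.0, 1.5],
  "max_cycles": 45
}
```

The seed always comes from the CLI `--seed` flag, not the file.

## Run config JSON (CLI `validate`)

Exactly one of:

```json
{"plates": ["plate1.csv", "plate2.csv"]}
{"simulation": {}}
```

## Report bundle (output)

`tsv` format writes one `<name>.tsv` per table into the output
directory; `json` writes a single file keyed by table name.  Rows are
sorted by `target` then `standard` where present, so identical inputs
give byte-identical files.  Rounding conventions: Ct and ΔCt to 2
decimals, precision tables to 3, curve coefficients to 4, percentages
to 2.  Dropout copy estimates print with up to 2 decimals, dropping a
trailing zero (0.8, 1.2), and render `>10` when no empty wells were
observed.  Tables:

* `curves.tsv` — `target, group_id, y_intercept, slope, efficiency, r_squared, n_points` (per-plate fits plus the `:master` row)
* `occupancy.tsv` — `target, standard, nominal_copies, n_empty, n_wells, percent_empty, lambda_dropout, lambda_mle`
* `delta_ct.tsv` — `target, standard, mean_ct, mean_ct_wt, delta_ct`
* `performance.tsv` — `target, tp, fn, fp, tn, sensitivity, specificity, lod_maf`
* `reproducibility_intra.tsv` / `reproducibility_inter.tsv` — `target, group, standard, n, mean_ct, sd_ct, cv_percent, pass`

## Acceptance JSON (`scripts/acceptance.py`)

One object per statistic: `{"<name>": {"value": <number>, "n": <size>}}`.
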