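# File formats

## Dataset CSV

Comma-separated, dot decimal, header row:

```
L,a,b,A1,A4,B4,C4,D4
```

`L,a,b` are CIELAB coordinates of the fired specimen; `A1..D4` are the
powder mass fractions (study-design recipes are multiples of 0.08
summing to 0.40).  Headerless files can be read by declaring the column
order (`read_dataset(path, columns=...)`).  Unicode minus signs are
accepted.

## Model JSON (`shadematch train --out`)

```json
{
  "format_version": 1,
  "config":     {"n_in": 3, "n_hidden": 12, "n_out": 5,
                 "activation": "tangent", "lambda_factor": 1.0},
  "weights":    {"W": [[...]], "V": [[...]],
                 "theta_hidden": [...], "theta_out": [...]},
  "normalizer": {"mins": [...], "maxs": [...], "lo": -1.0, "hi": 1.0},
  "profile":    "bp-improved",
  "seed":       1,
  "metric_as_printed": true
}
```

`W` is input→hidden (h × 3) and `V` hidden→output (5 × h), row-major.

## Training history CSV (`--history-out`)

Columns `epoch,total_error`: the total squared error over the training
batch after each epoch (rolled-back epochs repeat the previous value).

## Prediction CSV (`shadematch predict --out`)

Input colour columns `L,a,b` followed by predicted `A1,A4,B4,C4,D4`.
Raw network outputs by default; with `--clip` they are non-negative and
sum to 0.40.

## Evaluation JSON (`shadematch evaluate --out`)

`per_sample_error` (list of E_p), `mse_as_printed` (mean of E_p²),
`mse_mean_ep` (mean of E_p), `n_samples`, and the input paths.

## Hidden-width survey CSV (`shadematch size-hidden --out`)

Columns `h,rep,test_mse`: one row per (candidate width, repetition);
`test_mse` is the held-out mean of squared per-sample errors.

## Comparison CSV + summary (`shadematch compare --out`)

Per-trial columns `trial,bp_mse,gabp_mse`; beside it a
`*.summary.json` with trial counts, means and sample variances of both
arms.

## Sidecars

Every artifact-writing command also writes `<out>.run.json` with the
fully resolved configuration and seed; `generate` writes
`<out>.params.json` with the synthetic forward-model parameters.

## GA generation log

`evolve` returns per-generation records (generation, best fitness,
mean fitness, best error); the library exposes them as dataclasses and
the CLI stores them only through the model sidecar's configuration.
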