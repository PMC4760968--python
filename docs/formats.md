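# File formats

## Traces

**CSV** — two columns, header `time_ms,dff`; frame interval inferred from the
median time difference.

**HDF5** — dataset `dff` with attributes `dt_frame` (ms) and optionally
`baseline_window` (two frame indices delimiting the pre-stimulus baseline).

## Event sets (JSON)

```json
{"onset_times_ms": [512.3, 2711.0], "source": "inferred", "seed": 1}
```

`source` is `"true"` for simulated ground truth. Match reports add
`n_true`, `missed`, `falsely_detected`, `timing_errors` (inferred − true,
in frames when `unit` is `"frames"`), `timing_error_mean`, `timing_error_std`.

## Posteriors (HDF5)

Datasets `state_means` (frames × states), `state_covs`
(frames × states × states), `free_energy` (per accepted sweep); groups
`theta` and `phi` with `mean`/`cov` datasets and a `names` attribute
(log-scale modal coordinates for positivity-constrained parameters); group
`natural` whose attributes hold the natural-scale point estimates; root
attributes `state_names`, `dt_frame`, `model`, `converged`, and the Gamma
shape/rate pairs `alpha_shape`, `alpha_rate`, `sigma_shape`, `sigma_rate`.

## Parameter sets and run configuration (YAML)

`parameter_set_to_yaml` writes a `NamedParameterSet` (model name, role tag
`SIM`/`INV`, neuron/calcium/observation parameter maps with the field names
used throughout the package, integration steps, lag, inverse-covariance
weights, free-parameter list); `parameter_set_from_yaml` restores it
losslessly.
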