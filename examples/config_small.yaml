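# A reduced study for quick CLI runs:
#   twaskit all --config examples/config_small.yaml --seed 1 --out-dir out/
n_genes: 300
n_panels: 2
panel_strata: [blood, brain]
n_signal_genes: 15
n_cases: 300
n_controls: 300
target_liability_r2: 0.05
n_drugs: 80
n_enriched_drugs: 6
seed: 1
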