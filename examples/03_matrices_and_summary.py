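"""A small end-to-end run: fits, association matrices, counting summary.

Runs the pipeline for two pollutants, three disease chapters and lags 0-2 on
synthetic data with a planted lag-0 NO2 effect, then prints the summed
association matrices and the counting summary.
"""

import tempfile

import aircrossover as ac

sim = ac.SimulationConfig(
    n_days=365, start_date="2004-04-01", seed=7,
    effect=ac.EffectParams("NO2", lag=0, beta=0.03))

with tempfile.TemporaryDirectory() as tmp:
    cfg = ac.AnalysisConfig(
        pollutants=("NO2", "SO2"), chapters=("J00-J99", "I00-I99", "F00-F99"),
        lags=(0, 1, 2), simulation=sim, output_dir=tmp, seed=7)
    bundle = ac.run_full_analysis(cfg)

print("cells planned:", bundle["diagnostics"]["n_cells_planned"],
      "fitted:", bundle["diagnostics"]["n_fitted"])

# Summed matrix: how many of the 3 chapters show a positive significant
# association per (stratum, lag). NO2 carries the planted effect at lag 0;
# SO2 is simulated independently of the counts.
for pol in cfg.pollutants:
    m = bundle["summed"][pol]
    print(f"\n{pol} summed matrix (rows = strata, cols = lags 0-2):")
    print(m.to_frame().to_string())

print("\ncounting summary (per-stratum totals over lags, then overall rows):")
print(bundle["summary"].to_string())

print("\npersistence of associations at p<0.001 vs p<0.05:")
print(bundle["persistence"].to_string(index=False))
# NO2's lag-0 column should be saturated near 3 while SO2 cells stay mostly
# 0: positive-significant calls for an unrelated pollutant occur at roughly
# alpha/2 of cells.
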