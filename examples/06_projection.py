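"""Project compound-event frequency shifts under planted warming scenarios.

The full chain on synthetic data: fit station models on base-period
"reanalysis" predictors, then drive them with bias-corrected,
merged-standardized pseudo-ESM predictors under two warming scenarios.
Percent changes compare 20-year future time slices (2041-2060 and
2081-2100) against the historical slice (1995-2014), averaged over an
ensemble of pseudo-ESMs.
"""

from otevents import workflow

# late-century warming targets of ~1.5 C (moderate) and ~3 C (strong),
# expressed as trends in C per decade from 2015
exp = workflow.run_projection_experiment(
    seed=6, n_models=3,
    scenario_trends={"MODERATE": 1.5 / 7.55, "STRONG": 3.0 / 7.55},
    stations=2, som_iterations=2000,
)

print("Ensemble-mean percent change in o-t-event days vs 1995-2014:")
tbl = exp.ensembles.pivot_table(
    index=["station_id", "scenario"], columns="slice", values="mean"
)[["midcentury", "late_century"]].round(1)
print(tbl.to_string())

anom = exp.anomalies.groupby(["scenario", "slice"])["anomaly"].mean().round(2)
print("\nEnsemble-mean MT anomalies (C) vs the historical slice:")
print(anom.to_string())
print("\nThe stronger scenario produces larger event-frequency increases at"
      " every station, and late-century shifts exceed midcentury ones;"
      " anomalies near or above 2.7 C flag projections whose stationarity"
      " assumption deserves caution.")
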