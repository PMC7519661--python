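"""End-to-end analysis of a synthetic field campaign.

Generates 137 daytime observations across 4 marshes with the study's
statistical structure, then runs the full pipeline: SI conversion, pi
evaluation, PCA driver selection, regime classification, pairwise ANOVA,
site summaries, and response binning.  Outputs land in ./scratch/report.
"""

import marshsim as ms

bundle = ms.run_report(None, "scratch/report", ms.PipelineConfig(seed=42),
                       simulate=ms.GeneratorConfig())

print("records per regime:", bundle.pis["regime"].value_counts().to_dict())
print(f"PC1+PC2 variance explained: {bundle.pca_variance:.1%}")
print(f"selected dominant driver:   {bundle.selected_driver}")
print(f"fitted AT at ST = 17 degC:  {bundle.at_threshold:.1f} degC")
print("\npairwise regime ANOVA on LUE:")
print(bundle.anova.to_string(index=False))
print("\nSite summaries:")
print(bundle.sites.round({"lue": 3, "bgc": 3, "st": 1}).to_string())
print("\nAll regimes separate at p < 0.05 and the selected driver should be"
      "\nbgc: by construction LUE is governed by temperature and salinity,"
      "\nwhich BGC combines. Figures and CSVs are under scratch/report.")
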