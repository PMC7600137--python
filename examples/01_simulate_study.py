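"""Generate a synthetic two-group EBC study with ground truth.

Simulates 26 cases (sampled at T0 and T1), 16 controls and 8 pooled-QC
replicate injections over 108 LC-MS features, with 10 features carrying
a standardized case/control shift of 1.5 on the log scale.
"""

import breathomics as bo

config = bo.SimConfig(seed=42)
table, meta, truth = bo.generate_study(config)

print(f"feature table: {table.shape[0]} samples x {table.shape[1]} features")
print(f"missing cells in study samples: "
      f"{table.loc[~meta['is_qc'].to_numpy()].isna().to_numpy().mean():.3f}")
print("samples per group:")
print(meta.groupby(["group", "timepoint"]).size())
print(f"planted discriminating features ({len(truth.discriminating_feature_ids)}):")
for fid in sorted(truth.discriminating_feature_ids)[:5]:
    print("  ", fid)
print("   ...")
# The planted ids are the ground truth against which recovery of the
# downstream feature selection is judged.
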