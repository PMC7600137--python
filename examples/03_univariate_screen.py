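"""Univariate screening: Mann-Whitney tests with BH-FDR at delta = 0.10.

Screens each feature for a case/control difference at T0 and reports how
many of the planted features are recovered.
"""

import pandas as pd

import breathomics as bo

table, meta, truth = bo.generate_study(bo.SimConfig(seed=42))
proc, _ = bo.preprocess_untargeted(
    table, set(meta.loc[meta["is_qc"], "sample_id"]), seed=42
)
sel = meta[(meta["group"] == "control")
           | ((meta["group"] == "case") & (meta["timepoint"] == "T0"))]
labels = pd.Series(sel["group"].to_numpy(), index=sel["sample_id"])

result = bo.mann_whitney_screen(proc.loc[sel["sample_id"]], labels, delta=0.10)
sig = result.significant_features
planted = truth.discriminating_feature_ids & set(proc.columns)
print(f"significant features at q <= 0.10: {len(sig)} of {proc.shape[1]}")
print(f"planted features recovered: {len(sig & planted)} of {len(planted)}")
print("\ntop of the result table (statistic, p, q):")
print(result.table.nsmallest(5, "p").round(4))
# q is the BH-adjusted p-value; 'significant' marks q <= delta.
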