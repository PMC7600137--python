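"""Preprocess an untargeted feature table step by step.

QC CV filter (25%) -> below-minimum imputation -> probabilistic quotient
normalization -> log transform + mean centering.
"""

import breathomics as bo

table, meta, _ = bo.generate_study(bo.SimConfig(seed=42))
qc_ids = set(meta.loc[meta["is_qc"], "sample_id"])

filtered, rep = bo.qc_cv_filter(table, qc_ids, threshold=0.25)
print(f"QC CV filter removed {len(rep.removed_feature_ids)} of {table.shape[1]} features")
for fid, (cv, reason) in list(rep.removed_feature_ids.items())[:3]:
    print(f"  {fid}: {reason}")

study = filtered.drop(index=sorted(qc_ids))
study.attrs["preprocess_history"] = ["qc_cv_filter"]
imputed, rep2 = bo.impute_missing(study, seed=42)
print(f"imputed {rep2.imputation_count} missing cells below each feature's minimum")

normalized, rep3 = bo.pqn_normalize(imputed, reference="median")
q = list(rep3.pqn_quotients.values())
print(f"PQN median quotients range {min(q):.2f} .. {max(q):.2f} "
      "(per-sample dilution factors)")

final = bo.log_center(normalized)
print(f"log-centered table: per-feature means all |m| < 1e-10: "
      f"{bool((final.mean(axis=0).abs() < 1e-10).all())}")
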