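"""Adduct-based putative annotation of relevant features.

Converts each feature's m/z to candidate neutral masses under the
polarity-consistent adduct rules (M-H; M+H, M+H-H2O, M+H-NH3) and looks
them up in a local metabolite mass table at 20 ppm.  Matches are
accurate-mass only: annotation Level 3.
"""

import breathomics as bo

features = [
    ("4.42@172.1332", 172.1332, "negative"),
    ("5.53@295.1543", 295.1543, "negative"),
    ("4.92@198.1864", 198.1864, "positive"),
    ("3.12@415.2546", 415.2546, "positive"),
]
db = bo.load_marker_db()
hits, unannotated = bo.match_features(features, db, tol_ppm=20)

for h in hits:
    print(f"{h.feature_id}: {h.candidate} [{h.candidate_class}] "
          f"via {h.adduct}, {h.error_ppm:+.2f} ppm (Level {h.level})")
print(f"unannotated: {unannotated}")

m = bo.neutral_mass(415.2546, "M+H")
print(f"\nadduct arithmetic: m/z 415.2546 as M+H -> neutral mass {m:.4f} Da")
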