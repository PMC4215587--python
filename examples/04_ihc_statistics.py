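"""IHC scoring and the categorical/continuous marker statistics.

Scores a few stained cases, dichotomizes each marker with its published
cutoff, and reproduces the published contingency-table Fisher tests: DUSP6
p=0.176, phospho-ERK p=0.179, DUSP4 p=1.0 (none significant at the small
ERBB2+ sample size, but DUSP6/phospho-ERK trend higher in ERBB2+ tumors).
"""

from phosphosig.ihc import (
    dichotomize_marker, fisher_exact_2x2, score_ihc, spearman_correlation,
)
from phosphosig.reference import IHC_CONTINGENCY, IHC_SPEARMAN

# scoring: intensity (0-3) x percent stained -> categorical tier + continuous score
for intensity, pct in [(2, 50), (3, 80), (1, 4)]:
    s = score_ihc(intensity, pct, marker="DUSP6")
    print(f"intensity {intensity}, {pct}% cells -> categorical {s.categorical}, "
          f"continuous {s.continuous:.0f}")
print("DUSP6 dichotomized (0 vs 1-3):", dichotomize_marker([0, 1, 2, 3], "DUSP6"))
print("DUSP4 dichotomized (0-1 vs 2-3):", dichotomize_marker([0, 1, 2, 3], "DUSP4"))

for marker, table in IHC_CONTINGENCY.items():
    p = fisher_exact_2x2(table)
    print(f"{marker}: TN vs ERBB2+ contingency {table} -> Fisher two-sided p = {p:.3f}")

# published continuous-score correlations, for orientation
for (a, b), (rho, p) in IHC_SPEARMAN.items():
    print(f"published Spearman {a} ~ {b}: rho={rho}, p={p}")

# the same statistic on toy continuous scores
rho, p = spearman_correlation([20, 90, 150, 40, 200, 10], [0, 120, 160, 80, 210, 30])
print(f"toy continuous scores: rho={rho:.3f}, p={p:.3f}")
# rho near 1 with small p = the two stainings rank the cases the same way.
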