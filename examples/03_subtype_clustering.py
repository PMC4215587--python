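"""Unsupervised two-cluster subtype assignment of an ER-negative cohort.

The simulator makes group A ERBB2-positive and plants fold changes that
separate the groups, so complete-linkage clustering on the phosphatase
probes should recover an ERBB2-enriched ("molecular ERBB2") and a
basal-like enriched cluster, mirrored by the first principal component.
"""

from phosphosig import SimConfig, simulate_cohort
from phosphosig.io import select_phosphatase_probes
from phosphosig.subtype import (
    hierarchical_cluster_two_groups, label_clusters_by_erbb2, pca_scores,
)

cohort = simulate_cohort(
    SimConfig(n_probes=1000, frac_phosphatase=0.3, n_samples_per_group=20,
              n_de_probes=200, fc_range=(1.5, 4.0), probe_sd=0.5, seed=6)
)
phos = select_phosphatase_probes(cohort.annotation)
assignment = hierarchical_cluster_two_groups(cohort.expression, phos)
labeled = label_clusters_by_erbb2(assignment, cohort.clinical)

counts = labeled.labels.value_counts()
print("cluster sizes:", dict(counts))
print("fraction of clinical ERBB2+ per cluster:",
      {k: round(v, 3) for k, v in labeled.erbb2_fractions.items()})

scores = pca_scores(cohort.expression)
groups = cohort.clinical.set_index("sample_id")["group"]
print("mean PC1 score, ERBB2+ samples:", round(scores.loc[groups == "A", "PC1"].mean(), 2))
print("mean PC1 score, TN samples:    ", round(scores.loc[groups == "B", "PC1"].mean(), 2))
# the molecular_ERBB2 cluster should be strongly enriched in clinical ERBB2+
# tumors, and the two clusters should sit on opposite sides of PC1.
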