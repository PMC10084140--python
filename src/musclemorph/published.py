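"""Published group summaries of the bilateral semitendinosus ACLR study.

Printed mean +- SD inputs (n = 18 per group) used to reproduce the study's
worked-example statistics — the raw imaging data were never deposited, so
these summary rows are the only recomputable entry point for the group
comparisons. Units as printed: similarity metrics on their native scales,
normalized morphology per limb length (m) or mass x limb length (kg.m).
"""

from .stats import GroupSummary

N_PER_GROUP = 18

#: bilateral shape-similarity outcomes, healthy controls vs reconstructed
SIMILARITY_SUMMARIES = {
    "jaccard": {
        "healthy": GroupSummary(0.70, 0.09, N_PER_GROUP),
        "aclr": GroupSummary(0.47, 0.12, N_PER_GROUP),
    },
    "rmse_mm": {
        "healthy": GroupSummary(3.34, 1.03, N_PER_GROUP),
        "aclr": GroupSummary(7.57, 2.44, N_PER_GROUP),
    },
    "hausdorff_mm": {
        "healthy": GroupSummary(9.60, 2.47, N_PER_GROUP),
        "aclr": GroupSummary(23.1, 8.68, N_PER_GROUP),
    },
}

#: normalized whole-muscle morphology, averaged healthy vs injured limb
MORPHOLOGY_SUMMARIES = {
    "length_cm_per_m": {
        "healthy": GroupSummary(36.64, 3.01, N_PER_GROUP),
        "uninjured_aclr": GroupSummary(38.89, 3.85, N_PER_GROUP),
        "injured_aclr": GroupSummary(26.44, 6.32, N_PER_GROUP),
    },
    "peak_csa_cm2_per_kg_m": {
        "healthy": GroupSummary(0.18, 0.04, N_PER_GROUP),
        "uninjured_aclr": GroupSummary(0.18, 0.04, N_PER_GROUP),
        "injured_aclr": GroupSummary(0.13, 0.05, N_PER_GROUP),
    },
    "volume_cm3_per_kg_m": {
        "healthy": GroupSummary(3.21, 0.58, N_PER_GROUP),
        "uninjured_aclr": GroupSummary(3.40, 0.75, N_PER_GROUP),
        "injured_aclr": GroupSummary(1.72, 0.90, N_PER_GROUP),
    },
}
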