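"""Published reference values shipped as inputs.

These are the printed results of the original phosphatome study: the IHC
contingency tables, the 58-probe multiphosphatase signature membership with
its univariate Cox "raw scores", the reported hazard ratios, and the
reproduction targets that *cannot* be recomputed without downloading the
original cohorts (flagged ``desk_scale=False``).  Nothing here is produced
by this package; it is reference data for cross-checking and for orienting
outputs.
"""

from __future__ import annotations

# --- IHC 2x2 contingency tables (rows: TN, ER-/ERBB2+; cols: marker low, high)
IHC_CONTINGENCY = {
    "DUSP6": [[20, 13], [4, 8]],
    "pERK": [[19, 13], [4, 8]],
    "DUSP4": [[9, 23], [3, 9]],
}
IHC_FISHER_P = {"DUSP6": 0.176, "pERK": 0.179, "DUSP4": 1.0}

IHC_SPEARMAN = {
    ("pERK", "DUSP6"): (0.307, 0.043),
    ("pERK", "DUSP4"): (0.136, 0.379),
    ("DUSP6", "DUSP4"): (0.415, 0.005),
}

# --- reported survival-signature statistics
REPORTED_SIGNATURE_STATS = {
    "training_continuous_hr": 2.718,  # index refit on the training cohort (= e)
    "training_continuous_ci": (1.616, 4.571),
    "validation_continuous_hr": 3.005,
    "validation_continuous_ci": (1.315, 6.870),
    "training_logrank_p_quintile_3v2": 0.0002,
    "validation_logrank_p_quintile_3v2": 0.01,
    "training_logrank_p_median": 0.0019,
    "validation_logrank_p_median": 0.0658,
    "validation_multivariate_hr": 2.784,
    "validation_multivariate_ci": (1.086, 7.136),
    "validation_multivariate_p": 0.033,
}

# --- the published 58-probe / 48-gene signature (probe, symbol, raw score)
# Raw scores are the univariate Cox selection scores; negative = protective
# when overexpressed.  Reference fixture only - not a trained model.
SIGNATURE_58_PROBES = [
    ("204014_at", "DUSP4", -2.24), ("204015_s_at", "DUSP4", -2.652),
    ("212587_s_at", "PTPRC", -1.684), ("209392_at", "ENPP2", -1.432),
    ("207238_s_at", "PTPRC", -1.14), ("204960_at", "PTPRCAP", -1.27),
    ("210839_s_at", "ENPP2", -1.76), ("208893_s_at", "DUSP6", -1.079),
    ("203332_s_at", "INPP5D", -1.337), ("41577_at", "PPP1R16B", -1.036),
    ("213651_at", "INPP5J", -1.506), ("201904_s_at", "CTDSPL", -1.466),
    ("216988_s_at", "PTP4A2", -1.562), ("204852_s_at", "PTPN7", -1.477),
    ("200637_s_at", "PTPRF", -1.601), ("212750_at", "PPP1R16B", -1.06),
    ("209457_at", "DUSP5", -1.634), ("211178_s_at", "PSTPIP1", -1.208),
    ("200635_s_at", "PTPRF", -1.42), ("203011_at", "IMPA1", 1.876),
    ("200695_at", "PPP2R1A", -1.304), ("202313_at", "PPP2R2A", -1.047),
    ("218852_at", "PPP2R3C", 1.233), ("209896_s_at", "PTPN11", -1.014),
    ("212494_at", "TENC1", -1.275), ("203253_s_at", "HISPPD1", 1.184),
    ("204048_s_at", "PHACTR2", 1.031), ("212230_at", "PPAP2B", -1.113),
    ("204566_at", "PPM1D", 1.91), ("201603_at", "PPP1R12A", 1.205),
    ("207000_s_at", "PPP3CC", -1.239), ("206547_s_at", "PPEF1", 1.454),
    ("212640_at", "PTPLB", 1.538), ("209895_at", "PTPN11", -1.238),
    ("204554_at", "PPP1R3D", 1.724), ("203555_at", "PTPN18", -1.052),
    ("219235_s_at", "PHACTR4", -1.218), ("201598_s_at", "INPPL1", 1.124),
    ("218516_s_at", "IMPAD1", 1.343), ("202429_s_at", "PPP3CA", 1.517),
    ("202794_at", "INPP1", -1.064), ("200726_at", "PPP1CC", 1.579),
    ("202425_x_at", "PPP3CA", 1.442), ("218576_s_at", "DUSP12", 1.314),
    ("206833_s_at", "ACYP2", -1.057), ("202066_at", "PPFIA1", 2.244),
    ("214978_s_at", "PPFIA4", 1.368), ("203338_at", "PPP2R5E", 1.097),
    ("217956_s_at", "ENOPH1", 2.002), ("200733_s_at", "PTP4A1", 1.564),
    ("206844_at", "FBP2", -1.144), ("212610_at", "PTPN11", 1.396),
    ("202464_s_at", "PFKFB3", 2.534), ("215066_at", "PTPRF", 1.301),
    ("203607_at", "INPP5F", 1.355), ("201702_s_at", "PPP1R10", 1.0),
    ("214043_at", "PTPRD", 1.478), ("202457_s_at", "PPP3CA", 1.956),
]

# --- reproduction targets and whether they can be recomputed at the desk
# desk_scale=False entries need the original cohort downloads; exact
# membership may additionally depend on unknown SAM/preprocessing versions.
REPRODUCTION_TARGETS = [
    {
        "id": "fisher_table_vii",
        "description": "Two-sided Fisher exact p-values for the published IHC contingency tables",
        "desk_scale": True,
        "requires": [],
    },
    {
        "id": "training_continuous_hr_e",
        "description": "Training-cohort continuous-index Cox refit HR = e (analytic self-consistency)",
        "desk_scale": True,
        "requires": [],
    },
    {
        "id": "erbb2_vs_tn_de_tables",
        "description": "Differential-phosphatase table memberships and fold changes (ERBB2 vs TN / basal-like)",
        "desk_scale": False,
        "requires": ["GSE51999", "GSE20194", "NKI-295"],
    },
    {
        "id": "er_pos_vs_neg_79_probe_intersection",
        "description": "79-probe / 62-gene ER+ vs ER- intersection across three series",
        "desk_scale": False,
        "requires": ["GSE7390", "GSE20194", "GSE2034"],
    },
    {
        "id": "signature_58_probe_selection",
        "description": "The 58-probe / 48-gene signature membership at screening threshold 1",
        "desk_scale": False,
        "requires": ["GSE2034"],
    },
    {
        "id": "validation_continuous_hr",
        "description": "Validation-cohort continuous-index HR = 3.005",
        "desk_scale": False,
        "requires": ["GSE2034", "GSE7390"],
    },
]


def signature_gene_count() -> tuple[int, int]:
    """(probe count, distinct gene count) of the published signature: (58, 48)."""
    probes = {p for p, _, _ in SIGNATURE_58_PROBES}
    genes = {g for _, g, _ in SIGNATURE_58_PROBES}
    return len(probes), len(genes)
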