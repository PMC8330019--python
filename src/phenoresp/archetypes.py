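"""Default archetype parameters for the synthetic cohort generator.

Four response archetypes emulate the four treatment-outcome phenotypes of
the study cohort (n = 347 complete cases of 365 enrolled): per-archetype
category distributions over (GOOD, MODERATE, POOR) for each response metric
and consecutive inter-visit interval, baseline covariate profiles
(mean/SD or category frequencies), and genotype frequencies for rs37973
(GLCCI1).  Counts are kept as published and row-normalized at use.

The published per-interval table omits the MEF50 1st-to-2nd-control row;
that distribution is imputed here from the printed cumulative MEF50
baseline-to-2nd-control row, which reflects the compounded (0,1)+(1,2)
trajectory and matches the narrative description of archetype 2 as a poor
MEF50 responder.
"""

from __future__ import annotations

import numpy as np

#: archetype sizes in the study cohort (sum = 347 complete cases)
ARCHETYPE_SIZES = (58, 87, 138, 64)

#: number of patients enrolled before missing-data exclusion
N_ENROLLED = 365

#: (GOOD, MODERATE, POOR) counts per archetype for each of the 12
#: consecutive (metric, interval) response features; keys match the
#: coded-matrix feature names
CATEGORY_COUNTS: dict[str, list[list[int]]] = {
    "FEV1_v0_v1":  [[17, 27, 14], [8, 45, 34], [75, 49, 14], [19, 24, 21]],
    "FENO_v0_v1":  [[1, 57, 0],   [79, 7, 1],  [108, 14, 16], [58, 4, 3]],
    "CTRL_v0_v1":  [[34, 12, 12], [55, 22, 10], [94, 16, 28], [34, 11, 19]],
    "MEF50_v0_v1": [[18, 22, 18], [5, 43, 39], [75, 43, 20], [20, 22, 22]],
    "FEV1_v1_v2":  [[9, 46, 3],   [10, 64, 13], [44, 70, 24], [18, 40, 6]],
    "FENO_v1_v2":  [[48, 10, 0],  [55, 21, 11], [84, 30, 24], [39, 14, 11]],
    "CTRL_v1_v2":  [[52, 2, 4],   [59, 11, 17], [118, 4, 16], [46, 6, 12]],
    # imputed from the cumulative baseline-to-2nd-control MEF50 row
    "MEF50_v1_v2": [[17, 27, 14], [3, 36, 48], [74, 60, 4],  [14, 35, 15]],
    "FEV1_v2_v3":  [[3, 45, 10],  [11, 73, 3], [21, 89, 28], [4, 42, 18]],
    "FENO_v2_v3":  [[16, 26, 16], [29, 48, 10], [54, 75, 9], [23, 29, 12]],
    "CTRL_v2_v3":  [[53, 3, 2],   [82, 5, 0],  [128, 6, 4],  [2, 9, 53]],
    "MEF50_v2_v3": [[3, 41, 14],  [20, 57, 10], [38, 76, 24], [4, 36, 24]],
}


def category_distributions() -> dict[str, np.ndarray]:
    """Row-normalized (4 archetypes x 3 categories) probability arrays."""
    out = {}
    for feature, counts in CATEGORY_COUNTS.items():
        arr = np.asarray(counts, dtype=float)
        out[feature] = arr / arr.sum(axis=1, keepdims=True)
    return out


#: continuous baseline covariates: per archetype (mean, SD), plus sampling
#: bounds (truncated-normal support at physiologic limits)
CONTINUOUS_PROFILES: dict[str, dict] = {
    "age_years": {
        "per_archetype": [(11.79, 3.39), (10.16, 3.82), (9.98, 3.84), (9.61, 3.64)],
        "bounds": (2.0, 22.0),
    },
    "height_cm": {
        "per_archetype": [(153.05, 17.78), (143.9, 19.11), (143.86, 21.12),
                          (142.23, 21.24)],
        "bounds": (80.0, 210.0),
    },
    "disease_duration_years": {
        "per_archetype": [(5.72, 3.43), (5.08, 3.84), (4.12, 3.8), (3.45, 3.11)],
        "bounds": (0.0, 20.0),
    },
    "total_ige_kIUL": {
        "per_archetype": [(686.34, 744.36), (421.95, 578.5), (653.9, 1164.19),
                          (484.79, 516.04)],
        "bounds": (1.0, 6000.0),
    },
    "eosinophil_abs": {
        "per_archetype": [(419.99, 284.96), (418.71, 347.17), (380.16, 305.29),
                          (377.22, 349.65)],
        "bounds": (0.0, 3000.0),
    },
    "neutrophil_pct": {
        "per_archetype": [(49.72, 11.26), (50.79, 13.18), (49.57, 12.82),
                          (51.99, 12.96)],
        "bounds": (5.0, 95.0),
    },
    "hscrp_mgL": {
        "per_archetype": [(2.58, 6.31), (4.02, 14.45), (3.11, 7.52), (2.57, 3.72)],
        "bounds": (0.0, 100.0),
    },
    "platelets_1e9L": {
        "per_archetype": [(291.09, 86.54), (278.68, 108.14), (283.72, 105.47),
                          (257.7, 105.31)],
        "bounds": (50.0, 800.0),
    },
    "fev1_pp_baseline": {
        "per_archetype": [(0.89, 0.20), (0.96, 0.13), (0.82, 0.17), (0.88, 0.15)],
        "bounds": (0.2, 1.6),
    },
    "mef50_pp_baseline": {
        "per_archetype": [(0.92, 0.22), (1.03, 0.19), (0.79, 0.22), (0.84, 0.24)],
        "bounds": (0.2, 1.6),
    },
    "feno_baseline_ppb": {
        "per_archetype": [(21.5, 23.61), (17.23, 16.15), (23.07, 23.14),
                          (18.59, 13.38)],
        "bounds": (1.0, 150.0),
    },
}

#: per-archetype categorical covariates: category labels and counts
CATEGORICAL_PROFILES: dict[str, dict] = {
    "bmi_percentile_class": {
        "labels": ["underweight", "normal", "overweight_obese"],
        "per_archetype": [[0, 47, 11], [3, 53, 31], [4, 94, 40], [3, 46, 15]],
    },
    "hdm_strong_sige": {
        "labels": [0, 1],
        "per_archetype": [[18, 40], [40, 47], [73, 65], [31, 33]],
    },
    "ics_medhigh_v2_v3": {
        "labels": [0, 1],
        "per_archetype": [[28, 30], [55, 32], [87, 51], [26, 38]],
    },
    "saba_v2_v3": {
        "labels": [0, 1],
        "per_archetype": [[51, 7], [81, 6], [134, 4], [37, 27]],
    },
}

#: cohort-wide categorical covariates (no per-archetype values published):
#: frequencies over the 365 enrolled patients
COHORT_CATEGORICALS: dict[str, dict] = {
    "sex": {"labels": ["M", "F"], "probs": [0.611, 0.389]},
    "atopy": {"labels": [0, 1], "probs": [0.126, 0.874]},
    "allergic_rhinitis": {"labels": [0, 1], "probs": [1 - 0.8548, 0.8548]},
    "atopic_dermatitis": {"labels": [0, 1], "probs": [1 - 0.2767, 0.2767]},
    "gerd": {"labels": [0, 1], "probs": [1 - 0.2782, 0.2782]},
    "osa": {"labels": [0, 1], "probs": [1 - 0.0384, 0.0384]},
    # medication plumbing for the visits table; rates fixed at plausible
    # pediatric step-2/3 usage (not published per cluster)
    "laba": {"labels": [0, 1], "probs": [0.6, 0.4]},
    "ltra": {"labels": [0, 1], "probs": [0.7, 0.3]},
}

#: baseline GINA control level distribution (patients start treatment, so
#: mostly partly controlled / uncontrolled); same for all archetypes
BASELINE_CONTROL_PROBS = (0.25, 0.50, 0.25)

SNPS = ("rs37973", "rs9910408", "rs242941", "rs1876828", "rs1042713", "rs17576")

#: rs37973 (GLCCI1) genotype counts (GG, GA, AA) per archetype
RS37973_COUNTS = [[13, 18, 27], [13, 48, 26], [15, 70, 53], [12, 34, 18]]

#: genotype labels per SNP; SNPs without published frequencies default to
#: Hardy-Weinberg proportions with allele frequency 0.5
GENOTYPE_LABELS = {
    "rs37973": ["GG", "GA", "AA"],
    "rs9910408": ["AA", "AG", "GG"],
    "rs242941": ["GG", "GT", "TT"],
    "rs1876828": ["CC", "CT", "TT"],
    "rs1042713": ["GG", "GA", "AA"],
    "rs17576": ["AA", "AG", "GG"],
}

HWE_HALF = (0.25, 0.5, 0.25)


def genotype_frequencies() -> dict[str, np.ndarray]:
    """Per-SNP (4 archetypes x 3 genotypes) probability arrays."""
    out = {}
    for snp in SNPS:
        if snp == "rs37973":
            arr = np.asarray(RS37973_COUNTS, dtype=float)
            out[snp] = arr / arr.sum(axis=1, keepdims=True)
        else:
            out[snp] = np.tile(HWE_HALF, (4, 1))
    return out
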