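"""Published genetic-parameter estimates used to calibrate the simulator.

These constants are the reported estimates for a commercial black tiger
shrimp (*Penaeus monodon*) breeding population: 838 progeny of 55 sires
and 52 dams in 67 full-/half-sib families across 7 ponds, with body
weight, body length, CIE Lab colour of uncooked and cooked shrimp, and
two subjective colour scores (4-point uncooked, 3-point cooked).

They serve three purposes:

* defaults for the synthetic-data generator (the study conditions);
* inputs for the deterministic table identities (heritability ratio,
  correlated response, indirect-selection efficiency, scoring
  repeatability) that are functions of printed estimates alone;
* the worked examples in the analysis drivers.
"""

from __future__ import annotations

import math

import numpy as np

#: Liability-scale residual variance of the logit threshold model.
LOGISTIC_RESIDUAL_VARIANCE = math.pi**2 / 3.0

#: Study design sizes.
DESIGN = {
    "n_sires": 55,
    "n_dams": 52,
    "n_families": 67,
    "n_progeny": 838,
    "n_ponds": 7,
}

#: Trait order used throughout (ordinal scores first, then colorimetric,
#: then growth traits).
TRAITS = [
    "manual_uncooked",
    "manual_cooked",
    "L_uncooked",
    "a_uncooked",
    "b_uncooked",
    "L_cooked",
    "a_cooked",
    "b_cooked",
    "body_weight",
    "body_length",
]

ORDINAL_TRAITS = {"manual_uncooked": 4, "manual_cooked": 3}

#: Descriptive statistics of the recorded traits: n, mean, SD, min, max.
DESCRIPTIVES = {
    "body_weight": (838, 13.64, 3.50, 1.04, 26.21),
    "body_length": (838, 10.56, 0.95, 4.78, 12.85),
    "L_uncooked": (838, 23.84, 3.82, 14.96, 37.71),
    "a_uncooked": (838, 0.80, 1.72, -3.95, 6.64),
    "b_uncooked": (838, 9.80, 2.04, 3.73, 16.01),
    "L_cooked": (838, 44.06, 4.12, 30.72, 58.13),
    "a_cooked": (838, 56.85, 6.00, 17.01, 70.72),
    "b_cooked": (838, 55.84, 6.46, 15.45, 70.67),
}

#: Manual score distributions: category -> count (838 animals).
SCORE_COUNTS = {
    "manual_uncooked": {1: 29, 2: 272, 3: 424, 4: 113},
    "manual_cooked": {1: 92, 2: 472, 3: 274},
}

#: Variance components: trait -> (sigma2_A, sigma2_e); ordinal traits have
#: the fixed logistic residual.
VARIANCE_COMPONENTS = {
    "manual_uncooked": (0.48, LOGISTIC_RESIDUAL_VARIANCE),
    "manual_cooked": (0.46, LOGISTIC_RESIDUAL_VARIANCE),
    "L_uncooked": (1.94, 11.44),
    "a_uncooked": (0.72, 1.71),
    "b_uncooked": (1.51, 2.75),
    "L_cooked": (1.06, 10.94),
    "a_cooked": (1.78, 30.92),
    "b_cooked": (2.03, 29.19),
    "body_weight": (3.95, 10.20),
    "body_length": (0.34, 0.69),
}

#: Reported heritabilities (with standard errors) per trait.
HERITABILITY = {
    "manual_uncooked": (0.12, 0.04),
    "manual_cooked": (0.12, 0.04),
    "L_uncooked": (0.14, 0.05),
    "a_uncooked": (0.29, 0.08),
    "b_uncooked": (0.35, 0.08),
    "L_cooked": (0.08, 0.04),
    "a_cooked": (0.05, 0.03),
    "b_cooked": (0.06, 0.03),
    "body_weight": (0.27, 0.07),
    "body_length": (0.32, 0.08),
}

# Genetic correlations (lower triangle of the published correlation table).
_RG_LOWER = {
    ("manual_cooked", "manual_uncooked"): 0.77,
    ("L_uncooked", "manual_uncooked"): -0.88,
    ("L_uncooked", "manual_cooked"): -0.81,
    ("a_uncooked", "manual_uncooked"): 0.33,
    ("a_uncooked", "manual_cooked"): 0.36,
    ("a_uncooked", "L_uncooked"): -0.25,
    ("b_uncooked", "manual_uncooked"): -0.41,
    ("b_uncooked", "manual_cooked"): -0.54,
    ("b_uncooked", "L_uncooked"): 0.60,
    ("b_uncooked", "a_uncooked"): 0.07,
    ("L_cooked", "manual_uncooked"): -0.82,
    ("L_cooked", "manual_cooked"): -0.84,
    ("L_cooked", "L_uncooked"): 0.82,
    ("L_cooked", "a_uncooked"): -0.37,
    ("L_cooked", "b_uncooked"): 0.43,
    ("a_cooked", "manual_uncooked"): 0.74,
    ("a_cooked", "manual_cooked"): 0.81,
    ("a_cooked", "L_uncooked"): -0.81,
    ("a_cooked", "a_uncooked"): 0.10,
    ("a_cooked", "b_uncooked"): -0.53,
    ("a_cooked", "L_cooked"): -0.81,
    ("b_cooked", "manual_uncooked"): -0.35,
    ("b_cooked", "manual_cooked"): -0.50,
    ("b_cooked", "L_uncooked"): 0.28,
    ("b_cooked", "a_uncooked"): -0.63,
    ("b_cooked", "b_uncooked"): 0.30,
    ("b_cooked", "L_cooked"): 0.48,
    ("b_cooked", "a_cooked"): -0.14,
    ("body_weight", "manual_uncooked"): -0.28,
    ("body_weight", "manual_cooked"): -0.30,
    ("body_weight", "L_uncooked"): 0.31,
    ("body_weight", "a_uncooked"): -0.21,
    ("body_weight", "b_uncooked"): 0.15,
    ("body_weight", "L_cooked"): 0.43,
    ("body_weight", "a_cooked"): -0.39,
    ("body_weight", "b_cooked"): 0.33,
    ("body_length", "manual_uncooked"): -0.21,
    ("body_length", "manual_cooked"): -0.20,
    ("body_length", "L_uncooked"): 0.24,
    ("body_length", "a_uncooked"): -0.22,
    ("body_length", "b_uncooked"): 0.09,
    ("body_length", "L_cooked"): 0.34,
    ("body_length", "a_cooked"): -0.27,
    ("body_length", "b_cooked"): 0.32,
    ("body_length", "body_weight"): 0.96,
}

# Phenotypic correlations (upper triangle of the same table).
_RP_UPPER = {
    ("manual_uncooked", "manual_cooked"): 0.44,
    ("manual_uncooked", "L_uncooked"): -0.74,
    ("manual_uncooked", "a_uncooked"): 0.32,
    ("manual_uncooked", "b_uncooked"): -0.28,
    ("manual_uncooked", "L_cooked"): -0.47,
    ("manual_uncooked", "a_cooked"): 0.36,
    ("manual_uncooked", "b_cooked"): -0.04,
    ("manual_uncooked", "body_weight"): -0.12,
    ("manual_uncooked", "body_length"): -0.12,
    ("manual_cooked", "L_uncooked"): -0.57,
    ("manual_cooked", "a_uncooked"): 0.28,
    ("manual_cooked", "b_uncooked"): -0.30,
    ("manual_cooked", "L_cooked"): -0.62,
    ("manual_cooked", "a_cooked"): 0.59,
    ("manual_cooked", "b_cooked"): -0.18,
    ("manual_cooked", "body_weight"): -0.03,
    ("manual_cooked", "body_length"): -0.03,
    ("L_uncooked", "a_uncooked"): -0.42,
    ("L_uncooked", "b_uncooked"): 0.38,
    ("L_uncooked", "L_cooked"): 0.55,
    ("L_uncooked", "a_cooked"): -0.53,
    ("L_uncooked", "b_cooked"): 0.00,
    ("L_uncooked", "body_weight"): 0.05,
    ("L_uncooked", "body_length"): 0.06,
    ("a_uncooked", "b_uncooked"): 0.09,
    ("a_uncooked", "L_cooked"): -0.28,
    ("a_uncooked", "a_cooked"): 0.31,
    ("a_uncooked", "b_cooked"): -0.04,
    ("a_uncooked", "body_weight"): -0.02,
    ("a_uncooked", "body_length"): -0.04,
    ("b_uncooked", "L_cooked"): 0.24,
    ("b_uncooked", "a_cooked"): -0.20,
    ("b_uncooked", "b_cooked"): 0.25,
    ("b_uncooked", "body_weight"): 0.11,
    ("b_uncooked", "body_length"): 0.11,
    ("L_cooked", "a_cooked"): -0.51,
    ("L_cooked", "b_cooked"): 0.33,
    ("L_cooked", "body_weight"): 0.15,
    ("L_cooked", "body_length"): 0.16,
    ("a_cooked", "b_cooked"): 0.44,
    ("a_cooked", "body_weight"): -0.04,
    ("a_cooked", "body_length"): -0.01,
    ("b_cooked", "body_weight"): 0.15,
    ("b_cooked", "body_length"): 0.20,
    ("body_weight", "body_length"): 0.93,
}


def _corr_matrix(pairs: dict) -> np.ndarray:
    n = len(TRAITS)
    idx = {t: i for i, t in enumerate(TRAITS)}
    R = np.eye(n)
    for (x, y), v in pairs.items():
        i, j = idx[x], idx[y]
        R[i, j] = R[j, i] = v
    return R


#: Genetic correlation matrix in TRAITS order.
GENETIC_CORRELATIONS = _corr_matrix(_RG_LOWER)
#: Phenotypic correlation matrix in TRAITS order.
PHENOTYPIC_CORRELATIONS = _corr_matrix(_RP_UPPER)


def genetic_correlation(trait_x: str, trait_y: str) -> float:
    idx = {t: i for i, t in enumerate(TRAITS)}
    return float(GENETIC_CORRELATIONS[idx[trait_x], idx[trait_y]])


#: Expected-selection-response table rows:
#: (trait_x, trait_y, h2_x, h2_y, rg, CR_printed, IS%_printed).
SELECTION_RESPONSE_ROWS = [
    ("manual_uncooked", "manual_cooked", 0.12, 0.12, 0.77, 0.09, 77.00),
    ("manual_uncooked", "a_uncooked", 0.12, 0.29, 0.33, 0.06, 21.23),
    ("manual_uncooked", "b_uncooked", 0.12, 0.35, -0.41, -0.08, -24.01),
    ("manual_uncooked", "L_cooked", 0.12, 0.08, -0.82, -0.08, -100.43),
    ("manual_uncooked", "a_cooked", 0.12, 0.05, 0.74, 0.06, 114.64),
    ("manual_uncooked", "b_cooked", 0.12, 0.06, -0.35, -0.03, -49.50),
    ("manual_cooked", "L_uncooked", 0.12, 0.14, -0.81, -0.10, -74.99),
    ("manual_cooked", "a_uncooked", 0.12, 0.29, 0.36, 0.07, 23.16),
    ("manual_cooked", "b_uncooked", 0.12, 0.35, -0.54, -0.11, -31.62),
    ("manual_cooked", "L_cooked", 0.12, 0.08, -0.84, -0.08, -102.88),
    ("manual_cooked", "a_cooked", 0.12, 0.05, 0.81, 0.06, 125.48),
    ("manual_cooked", "b_cooked", 0.12, 0.06, -0.50, -0.04, -70.71),
    ("L_uncooked", "manual_uncooked", 0.14, 0.12, -0.88, -0.11, -95.05),
    ("L_uncooked", "manual_cooked", 0.14, 0.12, -0.81, -0.10, -87.49),
    ("L_uncooked", "L_cooked", 0.14, 0.08, 0.82, 0.09, 108.48),
    ("L_uncooked", "a_cooked", 0.14, 0.05, -0.81, -0.07, -135.54),
    ("L_uncooked", "b_cooked", 0.14, 0.06, 0.28, 0.03, 42.77),
    ("b_uncooked", "manual_uncooked", 0.35, 0.12, -0.41, -0.08, -70.02),
    ("b_uncooked", "manual_cooked", 0.35, 0.12, -0.54, -0.11, -92.22),
    ("b_uncooked", "L_cooked", 0.35, 0.08, 0.43, 0.07, 89.94),
    ("b_uncooked", "a_cooked", 0.35, 0.05, -0.53, -0.07, -140.22),
    ("b_uncooked", "b_cooked", 0.35, 0.06, 0.30, 0.04, 72.46),
    ("a_uncooked", "manual_uncooked", 0.29, 0.12, 0.33, 0.06, 51.30),
    ("a_uncooked", "manual_cooked", 0.29, 0.12, 0.36, 0.07, 55.96),
    ("a_uncooked", "L_cooked", 0.29, 0.08, -0.37, -0.06, -70.45),
    ("a_uncooked", "a_cooked", 0.29, 0.05, 0.10, 0.01, 24.08),
    ("a_uncooked", "b_cooked", 0.29, 0.06, -0.63, -0.08, -138.50),
    ("body_weight", "manual_uncooked", 0.27, 0.12, -0.28, -0.05, -42.00),
    ("body_weight", "manual_cooked", 0.27, 0.12, -0.30, -0.05, -45.00),
    ("body_weight", "L_uncooked", 0.27, 0.14, 0.31, 0.06, 43.05),
    ("body_weight", "a_uncooked", 0.27, 0.29, -0.21, -0.06, -20.26),
    ("body_weight", "b_uncooked", 0.27, 0.35, 0.15, 0.05, 13.17),
    ("body_weight", "L_cooked", 0.27, 0.08, 0.43, 0.06, 79.00),
    ("body_weight", "a_cooked", 0.27, 0.05, -0.39, -0.05, -90.63),
    ("body_weight", "b_cooked", 0.27, 0.06, 0.33, 0.04, 70.00),
    ("manual_uncooked", "body_weight", 0.12, 0.27, -0.28, -0.05, -18.67),
]

#: Scoring-chart confusion matrices (rows = first replicate listed).
#: Study-specific 3-point cooked chart, 188 doubly scored images per pair.
STUDY_CHART_CONFUSIONS = {
    ("rep1", "rep2"): np.array([[18, 6, 0], [7, 82, 1], [0, 18, 56]]),
    ("rep1", "rep3"): np.array([[20, 5, 0], [3, 101, 2], [0, 2, 55]]),
    ("rep2", "rep3"): np.array([[18, 6, 0], [5, 83, 2], [0, 19, 55]]),
}
#: Reported repeatabilities for the study chart (rep2-rep3 prints 0.80
#: although the printed counts give 0.81; see docs/methods.md).
STUDY_CHART_REPORTED_R = {
    ("rep1", "rep2"): 0.81,
    ("rep1", "rep3"): 0.92,
    ("rep2", "rep3"): 0.80,
}

#: Commercial 12-point chart confusions (only categories 9-11 tabulated;
#: the printed r values do not reproduce from these counts).
COMMERCIAL_CHART_CONFUSIONS = {
    ("rep1", "rep2"): np.array([[60, 10, 0], [5, 12, 1], [0, 2, 4]]),
    ("rep1", "rep3"): np.array([[53, 12, 0], [6, 16, 2], [0, 3, 2]]),
    ("rep2", "rep3"): np.array([[54, 16, 0], [5, 12, 1], [0, 3, 3]]),
}
COMMERCIAL_CHART_CATEGORIES = [9, 10, 11]
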