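"""Published group-level summary statistics of a hereditary-
hemochromatosis MCP joint-space cohort.

These are the unadjusted group means +/- SD of the six joint-space
parameters (per MCP joint) and of the demographics, for 24 HH patients
(16 men, 8 women) and for the sex/age-matched healthy-control
subanalyses (8 women vs 8 controls; 5 men vs 5 controls). They serve
two roles in this package: as default generating parameters for
synthetic cohorts, and as the inputs from which the published percent
contrasts between groups are recomputed.

Note the matched subanalyses were measured with a different (consensus)
variant of the joint-space algorithm, so their absolute levels are not
comparable with the main-cohort table; contrasts are always computed
within one table.

Each morphometry entry maps parameter -> (mean, sd); units are mm^3 for
``jsv_mm3``, mm for widths, unitless for ``jsw_as``.
"""

from __future__ import annotations

MORPHOMETRY_PARAMS = ("jsv_mm3", "jsw_mm", "jsw_min_mm", "jsw_max_mm", "jsw_as", "jsw_sd_mm")

# Main HH cohort, stratified by sex (n=24: 16 men, 8 women).
HH_COHORT = {
    "hh_all": {
        "n": 24,
        "sex": None,
        "demographics": {"age": (54.7, 10.8), "bmi": (26.6, 4.5), "height_cm": (175.5, 11.2)},
        "MCP2": {"jsv_mm3": (131.83, 32.13), "jsw_mm": (1.65, 0.34), "jsw_min_mm": (0.67, 0.47),
                 "jsw_max_mm": (2.18, 0.30), "jsw_as": (9.17, 10.35), "jsw_sd_mm": (0.33, 0.10)},
        "MCP3": {"jsv_mm3": (124.51, 37.46), "jsw_mm": (1.46, 0.25), "jsw_min_mm": (0.63, 0.42),
                 "jsw_max_mm": (2.08, 0.28), "jsw_as": (7.77, 8.39), "jsw_sd_mm": (0.33, 0.08)},
        "MCP4": {"jsv_mm3": (112.08, 23.24), "jsw_mm": (1.42, 0.20), "jsw_min_mm": (0.75, 0.34),
                 "jsw_max_mm": (1.94, 0.22), "jsw_as": (4.67, 6.47), "jsw_sd_mm": (0.29, 0.09)},
    },
    "hh_men": {
        "n": 16,
        "sex": "M",
        "demographics": {"age": (53.1, 11.9), "bmi": (27.3, 4.7), "height_cm": (180.1, 9.7)},
        "MCP2": {"jsv_mm3": (141.39, 33.64), "jsw_mm": (1.71, 0.39), "jsw_min_mm": (0.60, 0.49),
                 "jsw_max_mm": (2.24, 0.33), "jsw_as": (10.95, 11.03), "jsw_sd_mm": (0.35, 0.10)},
        "MCP3": {"jsv_mm3": (137.44, 40.13), "jsw_mm": (1.49, 0.30), "jsw_min_mm": (0.62, 0.46),
                 "jsw_max_mm": (2.18, 0.28), "jsw_as": (7.95, 8.00), "jsw_sd_mm": (0.36, 0.08)},
        "MCP4": {"jsv_mm3": (124.88, 16.54), "jsw_mm": (1.48, 0.21), "jsw_min_mm": (0.78, 0.40),
                 "jsw_max_mm": (2.03, 0.18), "jsw_as": (5.66, 7.89), "jsw_sd_mm": (0.31, 0.11)},
    },
    "hh_women": {
        "n": 8,
        "sex": "F",
        "demographics": {"age": (58.0, 7.8), "bmi": (25.1, 3.9), "height_cm": (165.4, 6.8)},
        "MCP2": {"jsv_mm3": (112.73, 18.48), "jsw_mm": (1.53, 0.15), "jsw_min_mm": (0.80, 0.43),
                 "jsw_max_mm": (2.05, 0.15), "jsw_as": (5.61, 8.34), "jsw_sd_mm": (0.29, 0.08)},
        "MCP3": {"jsv_mm3": (101.89, 17.35), "jsw_mm": (1.40, 0.15), "jsw_min_mm": (0.66, 0.38),
                 "jsw_max_mm": (1.90, 0.15), "jsw_as": (7.47, 9.59), "jsw_sd_mm": (0.29, 0.06)},
        "MCP4": {"jsv_mm3": (88.08, 11.84), "jsw_mm": (1.31, 0.13), "jsw_min_mm": (0.69, 0.20),
                 "jsw_max_mm": (1.77, 0.21), "jsw_as": (2.82, 1.05), "jsw_sd_mm": (0.26, 0.06)},
    },
}

# Matched subanalysis: HH women (n=8) vs age-matched control women (n=8),
# MCP 2 and 3, consensus-algorithm measurements.
MATCHED_WOMEN = {
    "hh_women": {
        "n": 8,
        "sex": "F",
        "demographics": {"age": (58.0, 7.8), "bmi": (25.1, 3.9), "height_cm": (165.4, 6.8)},
        "MCP2": {"jsv_mm3": (81.52, 14.90), "jsw_mm": (1.56, 0.16), "jsw_min_mm": (0.83, 0.41),
                 "jsw_max_mm": (2.64, 0.20), "jsw_as": (5.06, 5.23), "jsw_sd_mm": (0.33, 0.06)},
        "MCP3": {"jsv_mm3": (79.0, 7.77), "jsw_mm": (1.43, 0.16), "jsw_min_mm": (0.71, 0.36),
                 "jsw_max_mm": (2.58, 0.31), "jsw_as": (6.21, 6.07), "jsw_sd_mm": (0.33, 0.06)},
    },
    "control_women": {
        "n": 8,
        "sex": "F",
        "demographics": {"age": (58.0, 8.2), "bmi": (25.4, 3.0), "height_cm": (165.9, 6.5)},
        "MCP2": {"jsv_mm3": (87.5, 11.6), "jsw_mm": (1.80, 0.26), "jsw_min_mm": (1.27, 0.36),
                 "jsw_max_mm": (2.78, 0.12), "jsw_as": (2.39, 0.83), "jsw_sd_mm": (0.28, 0.07)},
        "MCP3": {"jsv_mm3": (87.8, 17.10), "jsw_mm": (1.66, 0.26), "jsw_min_mm": (1.22, 0.21),
                 "jsw_max_mm": (2.65, 0.25), "jsw_as": (2.21, 0.31), "jsw_sd_mm": (0.24, 0.07)},
    },
}

def reference_contrasts() -> dict[str, float]:
    """The published percent contrasts, recomputed from the group means.

    Keys name the comparison; values are percent differences of the
    comparison group relative to the reference group, rounded to one
    decimal (the reporting convention). Men-vs-women contrasts come from
    the sex-stratified main table; HH-vs-control contrasts from the
    matched subanalysis tables.
    """
    from .stats import percent_difference

    men = HH_COHORT["hh_men"]
    women = HH_COHORT["hh_women"]
    out = {}
    for joint in ("MCP2", "MCP3", "MCP4"):
        out[f"jsv_men_vs_women_{joint}"] = percent_difference(
            women[joint]["jsv_mm3"][0], men[joint]["jsv_mm3"][0]
        )
    out["jsw_men_vs_women_MCP4"] = percent_difference(
        women["MCP4"]["jsw_mm"][0], men["MCP4"]["jsw_mm"][0]
    )
    out["jsw_max_men_vs_women_MCP3"] = percent_difference(
        women["MCP3"]["jsw_max_mm"][0], men["MCP3"]["jsw_max_mm"][0]
    )
    out["jsw_max_men_vs_women_MCP2"] = percent_difference(
        women["MCP2"]["jsw_max_mm"][0], men["MCP2"]["jsw_max_mm"][0]
    )
    hw, cw = MATCHED_WOMEN["hh_women"], MATCHED_WOMEN["control_women"]
    out["jsw_sd_women_vs_controls_MCP3"] = percent_difference(
        cw["MCP3"]["jsw_sd_mm"][0], hw["MCP3"]["jsw_sd_mm"][0]
    )
    out["jsw_min_women_vs_controls_MCP3"] = percent_difference(
        cw["MCP3"]["jsw_min_mm"][0], hw["MCP3"]["jsw_min_mm"][0]
    )
    out["jsw_women_vs_controls_MCP3"] = percent_difference(
        cw["MCP3"]["jsw_mm"][0], hw["MCP3"]["jsw_mm"][0]
    )
    out["jsw_women_vs_controls_MCP2"] = percent_difference(
        cw["MCP2"]["jsw_mm"][0], hw["MCP2"]["jsw_mm"][0]
    )
    hm, cm = MATCHED_MEN["hh_men"], MATCHED_MEN["control_men"]
    out["jsw_as_men_vs_controls_MCP3"] = percent_difference(
        cm["MCP3"]["jsw_as"][0], hm["MCP3"]["jsw_as"][0]
    )
    return out


# Matched subanalysis: HH men (n=5) vs age-matched control men (n=5).
MATCHED_MEN = {
    "hh_men": {
        "n": 5,
        "sex": "M",
        "demographics": {"age": (59.8, 12.5), "bmi": (29.9, 6.1), "height_cm": (175.8, 8.2)},
        "MCP2": {"jsv_mm3": (106.33, 33.60), "jsw_mm": (1.56, 0.37), "jsw_min_mm": (0.31, 0.33),
                 "jsw_max_mm": (2.77, 0.20), "jsw_as": (14.2, 6.37), "jsw_sd_mm": (0.46, 0.14)},
        "MCP3": {"jsv_mm3": (92.03, 29.36), "jsw_mm": (1.45, 0.28), "jsw_min_mm": (0.34, 0.36),
                 "jsw_max_mm": (2.76, 0.24), "jsw_as": (12.75, 6.28), "jsw_sd_mm": (0.49, 0.14)},
    },
    "control_men": {
        "n": 5,
        "sex": "M",
        "demographics": {"age": (60.8, 15.7), "bmi": (28.0, 3.9), "height_cm": (173.6, 10.5)},
        "MCP2": {"jsv_mm3": (102.52, 21.81), "jsw_mm": (1.79, 0.04), "jsw_min_mm": (1.00, 0.34),
                 "jsw_max_mm": (2.83, 0.10), "jsw_as": (3.28, 1.66), "jsw_sd_mm": (0.37, 0.12)},
        "MCP3": {"jsv_mm3": (117.85, 13.74), "jsw_mm": (1.72, 0.26), "jsw_min_mm": (1.08, 0.36),
                 "jsw_max_mm": (2.76, 0.11), "jsw_as": (2.78, 0.92), "jsw_sd_mm": (0.34, 0.10)},
    },
}
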