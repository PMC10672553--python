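"""Canonical descriptor names, family membership and column order.

The extractor emits exactly 81 named descriptors across six families.
Columns in feature tables are ordered family-by-family (first-order,
GLCM, GLRLM, GLSZM, Tamura, LBP) and alphabetically within each family.
"""

from __future__ import annotations

FIRST_ORDER = [
    "fo_energy",
    "fo_entropy",
    "fo_iqr",
    "fo_kurtosis",
    "fo_mad",
    "fo_max",
    "fo_mean",
    "fo_median",
    "fo_min",
    "fo_p10",
    "fo_p25",
    "fo_p75",
    "fo_p90",
    "fo_range",
    "fo_skewness",
    "fo_std",
    "fo_variance",
]

GLCM = [
    "glcm_asm",
    "glcm_autocorrelation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_diff_average",
    "glcm_diff_entropy",
    "glcm_diff_variance",
    "glcm_entropy",
    "glcm_idm",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_inverse_diff",
    "glcm_inverse_diff_norm",
    "glcm_joint_average",
    "glcm_joint_max",
    "glcm_mcc",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_sum_squares",
    "glcm_sum_variance",
]

GLRLM = [
    "glrlm_glnu",
    "glrlm_glnu_norm",
    "glrlm_glv",
    "glrlm_hgre",
    "glrlm_lgre",
    "glrlm_lre",
    "glrlm_lrhge",
    "glrlm_lrlge",
    "glrlm_rlnu",
    "glrlm_rlnu_norm",
    "glrlm_rlv",
    "glrlm_rp",
    "glrlm_run_entropy",
    "glrlm_sre",
    "glrlm_srhge",
    "glrlm_srlge",
]

GLSZM = [
    "glszm_glnu",
    "glszm_glnu_norm",
    "glszm_glzv",
    "glszm_hgze",
    "glszm_lgze",
    "glszm_lze",
    "glszm_lzhge",
    "glszm_lzlge",
    "glszm_sze",
    "glszm_szhge",
    "glszm_szlge",
    "glszm_zp",
    "glszm_zse",
    "glszm_zsnu",
    "glszm_zsnu_norm",
    "glszm_zsv",
]

TAMURA = [
    "tam_coarseness_entropy",
    "tam_coarseness_mean",
    "tam_coarseness_median",
    "tam_coarseness_std",
    "tam_contrast",
    "tam_roughness",
]

LBP = [
    "lbp_mean",
    "lbp_median",
    "lbp_n_peaks",
    "lbp_uniformity",
]

FAMILIES = {
    "FO": FIRST_ORDER,
    "GLCM": GLCM,
    "GLRLM": GLRLM,
    "GLSZM": GLSZM,
    "TAM": TAMURA,
    "LBP": LBP,
}

#: All 81 descriptor names in canonical column order.
ALL_FEATURES = FIRST_ORDER + GLCM + GLRLM + GLSZM + TAMURA + LBP

#: Metadata columns preceding the descriptors in a cohort feature table.
METADATA_COLUMNS = ["subject_id", "group", "sequence"]

assert len(ALL_FEATURES) == 81
assert all(names == sorted(names) for names in FAMILIES.values())
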