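"""Published summary statistics from a Swedish Medical Birth Registry cohort.

The cohort comprises 626,600 deliveries recorded 2002-2010, stratified by
parity (344,001 multiparous / 282,599 primiparous).  The underlying
pregnancy-level records are not public; what is public are stratum sizes,
outcome counts, per-exposure counts, absolute risks (PPV, %) among
marker-positive groups, and mutually adjusted odds ratios.  Those summary
numbers serve two roles here:

* calibration defaults for the synthetic registry generator
  (:mod:`pescreen.synthetic`), and
* inputs for reconstructing the 2x2 tables behind the published
  discriminatory-accuracy statistics (:func:`reconstruct_contingency`).

Reconstruction logic: for a marker with ``n_marker`` positive pregnancies in
a stratum of ``n_total`` with ``n_outcome`` preeclampsia cases, and a printed
absolute risk ``ar`` (%) among marker-positives,

    tp = round(ar/100 * n_marker),  fp = n_marker - tp,
    fn = n_outcome - tp,            tn = n_total - n_marker - fn.

Because ``ar`` is printed to 3 significant digits the reconstructed counts
carry rounding error of order ``n_marker/2000``; downstream statistics are
exact functions of these counts.
"""

from __future__ import annotations

from .accuracy import ContingencyTable

MULTIPAROUS = "multiparous"
PRIMIPAROUS = "primiparous"
STRATA = (MULTIPAROUS, PRIMIPAROUS)

#: Stratum sizes and preeclampsia (PE) case counts.
STRATUM_N = {MULTIPAROUS: 344_001, PRIMIPAROUS: 282_599}
PE_CASES = {MULTIPAROUS: 8_291, PRIMIPAROUS: 15_732}

#: Parity-specific PE incidence (proportions).
PE_INCIDENCE = {
    MULTIPAROUS: PE_CASES[MULTIPAROUS] / STRATUM_N[MULTIPAROUS],    # 2.41 %
    PRIMIPAROUS: PE_CASES[PRIMIPAROUS] / STRATUM_N[PRIMIPAROUS],    # 5.57 %
}

#: Exposure-positive counts per stratum (registry margins).
EXPOSURE_COUNTS = {
    MULTIPAROUS: {
        "age_ge40": 15_617,
        "low_education": 207_059,
        "non_cohabiting": 9_853,
        "dm": 2_511,
        "hbp": 2_851,
        "autoimmune": 771,
        "ckd": 1_848,
        "obesity": 44_177,
        "previous_pe": 13_407,
        "smoker": 51_963,
        "multiple_pregnancy": 5_625,
        "art": 5_163,
        "gestational_diabetes": 2_962,
    },
    PRIMIPAROUS: {
        "age_ge40": 4_583,
        "low_education": 156_937,
        "non_cohabiting": 17_009,
        "dm": 1_700,
        "hbp": 2_076,
        "autoimmune": 615,
        "ckd": 1_333,
        "obesity": 28_086,
        "smoker": 59_207,
        "multiple_pregnancy": 3_454,
        "art": 11_113,
        "gestational_diabetes": 2_063,
    },
}

#: Marginal exposure prevalences (proportions).
EXPOSURE_PREVALENCE = {
    stratum: {k: v / STRATUM_N[stratum] for k, v in counts.items()}
    for stratum, counts in EXPOSURE_COUNTS.items()
}

#: Published absolute risks (PPV, %) among exposure-positive pregnancies.
SINGLE_FACTOR_AR = {
    MULTIPAROUS: {
        "age_ge40": 4.04,
        "low_education": 2.68,
        "non_cohabiting": 3.04,
        "dm": 10.5,
        "hbp": 20.1,
        "autoimmune": 5.58,
        "ckd": 7.52,
        "obesity": 5.80,
        "previous_pe": 18.4,
        "smoker": 2.30,
        "multiple_pregnancy": 10.1,
        "art": 5.0,
        "gestational_diabetes": 7.49,
    },
    PRIMIPAROUS: {
        "age_ge40": 9.14,
        "low_education": 5.97,
        "non_cohabiting": 5.36,
        "dm": 22.7,
        "hbp": 24.1,
        "autoimmune": 9.27,
        "ckd": 10.1,
        "obesity": 12.1,
        "smoker": 5.13,
        "multiple_pregnancy": 19.7,
        "art": 7.59,
        "gestational_diabetes": 13.9,
    },
}

#: Mutually adjusted odds ratios from the stratified multiple logistic models.
#: These seed the synthetic generator's log-odds coefficients.
ADJUSTED_OR = {
    MULTIPAROUS: {
        "age_ge40": 1.73,
        "low_education": 1.20,
        "non_cohabiting": 1.24,
        "dm": 2.64,
        "hbp": 4.63,
        "autoimmune": 1.54,
        "ckd": 2.15,
        "obesity": 2.44,
        "previous_pe": 10.6,
        "smoker": 0.90,
        "multiple_pregnancy": 5.42,
        "art": 1.71,
        "gestational_diabetes": 1.85,
    },
    PRIMIPAROUS: {
        "age_ge40": 1.49,
        "low_education": 1.13,
        "non_cohabiting": 0.94,
        "dm": 4.29,
        "hbp": 4.07,
        "autoimmune": 1.12,
        "ckd": 1.34,
        "obesity": 2.56,
        "smoker": 0.83,
        "multiple_pregnancy": 4.27,
        "art": 1.17,
        "gestational_diabetes": 2.04,
    },
}

#: Guideline-style high-risk groups: (n flagged, AR %) per stratum.
GUIDELINE_GROUPS = {
    MULTIPAROUS: {
        "any_risk": (81_162, 6.59),
        "one_major_or_two_moderate": (25_135, 13.8),
        "one_major_incl_multiple": (25_218, 13.9),
    },
    PRIMIPAROUS: {
        "any_risk": (48_924, 11.3),
        "one_major_or_two_moderate": (9_235, 17.9),
        "one_major_incl_multiple": (8_769, 19.1),
    },
}

#: Forest-guided subgroup variables per stratum (published selection).
SUBGROUP_VARIABLES = {
    MULTIPAROUS: ("previous_pe", "hbp", "obesity", "multiple_pregnancy"),
    PRIMIPAROUS: ("dm", "hbp", "obesity", "multiple_pregnancy"),
}

#: Exact-combination subgroups: bitmask over SUBGROUP_VARIABLES -> (n, AR %).
SUBGROUP_CELLS = {
    MULTIPAROUS: {
        (0, 0, 0, 1): (4_698, 8.56),
        (0, 0, 1, 0): (39_533, 3.79),
        (0, 0, 1, 1): (708, 13.0),
        (0, 1, 0, 0): (1_453, 14.7),
        (0, 1, 0, 1): (24, 16.7),
        (0, 1, 1, 0): (706, 19.6),
        (0, 1, 1, 1): (10, 50.0),
        (1, 0, 0, 0): (9_635, 15.1),
        (1, 0, 0, 1): (136, 34.6),
        (1, 0, 1, 0): (2_935, 24.8),
        (1, 0, 1, 1): (43, 39.5),
        (1, 1, 0, 0): (410, 31.5),
        (1, 1, 0, 1): (6, 16.7),
        (1, 1, 1, 0): (242, 33.8),
    },
    PRIMIPAROUS: {
        (0, 0, 0, 1): (3_056, 19.1),
        (0, 0, 1, 0): (26_939, 11.5),
        (0, 0, 1, 1): (358, 23.5),
        (0, 1, 0, 0): (1_418, 22.5),
        (0, 1, 0, 1): (17, 47.1),
        (0, 1, 1, 0): (505, 29.7),
        (0, 1, 1, 1): (6, 16.7),
        (1, 0, 0, 0): (1_316, 21.7),
        (1, 0, 0, 1): (13, 23.1),
        (1, 0, 1, 0): (237, 30.4),
        (1, 0, 1, 1): (4, 50.0),
        (1, 1, 0, 0): (93, 12.9),
        (1, 1, 1, 0): (37, 29.7),
    },
}

#: Predicted-probability centile groups: centile -> (n flagged, AR %).
CENTILE_GROUPS = {
    MULTIPAROUS: {95: (16_847, 17.5), 97: (6_237, 23.6), 99: (3_160, 27.5)},
    PRIMIPAROUS: {95: (8_884, 20.8), 97: (7_997, 21.5), 99: (2_392, 25.6)},
}


def reconstruct_contingency(n_marker: int, ar_pct: float, *, stratum: str | None = None,
                            n_total: int | None = None, n_outcome: int | None = None
                            ) -> ContingencyTable:
    """Rebuild the 2x2 table behind a published (n, AR%) pair.

    Either pass ``stratum`` (to use the published stratum size and case
    count) or ``n_total`` and ``n_outcome`` explicitly.
    """
    if stratum is not None:
        n_total, n_outcome = STRATUM_N[stratum], PE_CASES[stratum]
    if n_total is None or n_outcome is None:
        raise ValueError("need a stratum name or explicit n_total and n_outcome")
    tp = round(ar_pct / 100.0 * n_marker)
    fp = n_marker - tp
    fn = n_outcome - tp
    tn = n_total - n_marker - fn
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def primiparity_contingency() -> ContingencyTable:
    """Exact 2x2 of primiparity vs PE in the whole cohort (no rounding)."""
    tp = PE_CASES[PRIMIPAROUS]
    fp = STRATUM_N[PRIMIPAROUS] - tp
    fn = PE_CASES[MULTIPAROUS]
    tn = STRATUM_N[MULTIPAROUS] - fn
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
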