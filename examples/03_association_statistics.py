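"""Association between HRD status and chemotherapy response.

Computes odds ratios with Woolf 95% confidence intervals and exact p-values
for 2x2 tables relating HRD positivity (high HRD score or BRCA mutation) to
pathologic complete response (pCR) and to residual cancer burden class
(RCB 0/1) after anthracycline-based neoadjuvant chemotherapy.
"""

from acornhrd.stats import ContingencyTable, association

tables = {
    "HRD positivity vs pCR": ContingencyTable(
        10, 20, 1, 19,
        row_labels=("HRD positive", "HRD negative"),
        col_labels=("pCR", "non-pCR"),
    ),
    "HRD positivity vs RCB0/1": ContingencyTable(
        16, 14, 2, 18,
        row_labels=("HRD positive", "HRD negative"),
        col_labels=("RCB0/1", "RCB2/3"),
    ),
}

for name, table in tables.items():
    r = association(table)
    print(f"{name}: OR = {r.odds_ratio:.2f} "
          f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f}), p = {r.p_value:.3f} [{r.test}]")
# An odds ratio well above 1 with a CI excluding 1 indicates that
# HRD-positive tumors respond to the regimen more often.
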