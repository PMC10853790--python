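"""Published reference values from the genome-scale HK-CRE atlas this
package's pipeline is modeled on.

These tables are *inputs* for arithmetic reproduction (class percentages,
telomere distances, threshold accounting), not outputs of this package; the
pipeline itself runs on data supplied by the user or by the synthetic
generator.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CRE_CLASS_COUNTS",
    "CRE_CLASS_PRINTED_PCT",
    "INACTIVE_HKCP_TABLE",
    "CHR19_LENGTH_BP",
    "HKCP_VALIDATION_REPORTED",
]

#: region counts per CRE class in the reference atlas (nine clusters)
CRE_CLASS_COUNTS = {
    "CP": 28_968,
    "P": 24_233,
    "ESD": 11_445,
    "ELD": 32_564,
    "ESLD": 8_063,
    "ESDi": 5_975,
    "OMD": 5_109,
    "OLD": 19_563,
    "H3K4me1_negative": 745,
}

#: the percentages printed alongside those counts
CRE_CLASS_PRINTED_PCT = {
    "CP": 21.20,
    "P": 17.73,
    "ESD": 8.37,
    "ELD": 23.83,
    "ESLD": 5.90,
    "ESDi": 4.37,
    "OMD": 3.73,
    "OLD": 14.31,
    "H3K4me1_negative": 0.56,
}

#: hg38 chromosome 19 length, on which all reference telomere distances sit
CHR19_LENGTH_BP = 58_617_616

#: top housekeeping core promoters inactive in cancer cell lines, with their
#: gene, TSS (1-based), activity percentages and printed telomere distance
INACTIVE_HKCP_TABLE = pd.DataFrame(
    [
        ("chr19:58058989-58059488", "ZNF135", 58_059_239, 11.53, 95.23, 558_377),
        ("chr19:57935138-57935637", "ZNF418", 57_935_387, 30.76, 100.00, 682_229),
        ("chr19:57708962-57709461", "ZNF154", 57_709_204, 11.53, 95.23, 908_412),
        ("chr19:57583726-57584309", "ZIK1", 57_584_140, 26.92, 100.00, 1_033_476),
        ("chr19:56507593-56508092", "ZNF471", 56_507_850, 30.76, 95.23, 2_109_766),
        ("chr19:56477152-56478177", "ZNF667-AS1", 56_477_590, 15.38, 95.23, 2_140_026),
        ("chr19:56477152-56478177", "ZNF667", 56_477_374, 15.38, 95.23, 2_140_242),
        ("chr19:53254646-53255153", "ZNF677", 53_254_898, 23.07, 95.23, 5_362_718),
        ("chr19:51887687-51888274", "ZNF649-AS1", 51_888_025, 26.92, 95.23, 6_729_591),
        ("chr19:51887687-51888274", "ZNF577", 51_887_980, 26.92, 95.23, 6_729_636),
        ("chr19:36605027-36605554", "ZNF382", 36_605_313, 34.61, 90.47, 22_012_303),
        ("chr19:36605027-36605554", "ZNF529", 36_605_276, 34.61, 90.47, 22_012_340),
    ],
    columns=[
        "region",
        "gene",
        "tss",
        "pct_cancer",
        "pct_healthy",
        "printed_distance_to_chrom_end",
    ],
)

#: reported validation summary of housekeeping core promoters: how many kept
#: housekeeping-level activity in held-out healthy cells vs cancer cell lines
HKCP_VALIDATION_REPORTED = {
    "pass_healthy": 9_411,
    "pct_healthy": 96.94,
    "pass_cancer": 8_354,
    "pct_cancer": 86.05,
    "fail_cancer": 1_354,
}
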