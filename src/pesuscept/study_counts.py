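"""Published genotype and risk-marker counts for the IL-13 preeclampsia
case-control cohort (150 preeclampsia patients vs 150 healthy pregnant
controls), genotyped at rs2069740 (T/A) and rs34255686 (C/A).

These frozen counts are the reference inputs the association module is
expected to reproduce statistics from. Notes:

* The published allele rows for rs34255686 are inconsistent with its
  genotype rows (the group assignment appears swapped); allele counts here
  are always derived from the genotype counts (control A=44/C=256,
  case A=12/C=288). The chi-square value is unaffected by the swap, but
  the direction of the effect follows the genotypes.
* Both groups deviate grossly from Hardy-Weinberg proportions at both SNPs
  (e.g. 7 observed rs2069740 heterozygotes in controls vs ~40 expected);
  :func:`qc_warnings` surfaces this without interpreting it.
* The published multipara and gravida marker tables do not sum to the 150
  patients and are therefore excluded from :data:`RISK_MARKER_TABLES`.
"""

from __future__ import annotations

import pandas as pd

from .association import GenotypeCounts, hwe_test

__all__ = [
    "RS2069740",
    "RS34255686",
    "COMBINED_GENOTYPE_CARRIERS",
    "RISK_MARKER_TABLES",
    "expand_records",
    "qc_warnings",
]

# genotype counts (hom_ref, het, hom_alt) per group
RS2069740 = GenotypeCounts(
    snp_id="rs2069740",
    ref_allele="T",
    alt_allele="A",
    control=(123, 7, 20),
    case=(133, 8, 9),
)

RS34255686 = GenotypeCounts(
    snp_id="rs34255686",
    ref_allele="C",
    alt_allele="A",
    control=(121, 14, 15),
    case=(141, 6, 3),
)

# carriers of each published rs2069740-rs34255686 genotype combination
# (carrier count out of 150, per group)
COMBINED_GENOTYPE_CARRIERS = {
    "AA-CC": {"control": 18, "case": 9},
    "AA-AA": {"control": 2, "case": 0},
    "TT-CC": {"control": 117, "case": 106},
    "TT-AA": {"control": 0, "case": 13},
    "TT-CA": {"control": 6, "case": 14},
    "AT-CC": {"control": 6, "case": 7},
    "AT-AA": {"control": 1, "case": 1},
}


def _marker_table(rows: dict, genotype_labels) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(genotype_labels)
    ).astype(int)


# patient-group marker level x genotype counts
RISK_MARKER_TABLES = {
    "rs2069740": {
        "seizures": _marker_table(
            {"present": (1, 0, 0), "absent": (132, 8, 9)},
            RS2069740.genotype_labels(),
        ),
        "hellp": _marker_table(
            {"present": (1, 0, 0), "absent": (132, 8, 9)},
            RS2069740.genotype_labels(),
        ),
    },
    "rs34255686": {
        "hellp": _marker_table(
            {"present": (0, 1, 0), "absent": (121, 13, 15)},
            RS34255686.genotype_labels(),
        ),
        "edema": _marker_table(
            {
                "absent": (15, 4, 4),
                "grade1": (79, 8, 4),
                "grade2": (18, 1, 6),
                "grade3": (9, 1, 1),
            },
            RS34255686.genotype_labels(),
        ),
    },
}


def expand_records(marker_table: pd.DataFrame, snp_id: str, marker: str) -> pd.DataFrame:
    """Expand a patient marker x genotype count table into subject records.

    Produces one row per patient with ``status="case"``, the marker level
    and the genotype string — the subject-level form the association
    operations consume.
    """
    rows = []
    i = 0
    for level, counts in marker_table.iterrows():
        for genotype, k in counts.items():
            for _ in range(int(k)):
                rows.append(
                    {
                        "subject_id": f"X{i:04d}",
                        "status": "case",
                        marker: level,
                        snp_id: genotype,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


def qc_warnings() -> list:
    """QC findings on the published counts, as human-readable strings."""
    notes = [
        "rs34255686 published allele rows conflict with its genotype rows; "
        "allele counts are derived from genotypes (control A=44, case A=12).",
        "multipara and gravida marker tables do not sum to the 150 patients "
        "and are excluded from analysis.",
    ]
    for gc in (RS2069740, RS34255686):
        for group in ("control", "case"):
            res = hwe_test(gc.counts(group))
            if res.estimable and res.p_value < 1e-3:
                notes.append(
                    f"{gc.snp_id} {group} group violates Hardy-Weinberg "
                    f"equilibrium (chi2={res.statistic:.1f}, p={res.p_value:.2e})."
                )
    return notes
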