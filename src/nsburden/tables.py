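"""Published allele-count tables for the nine-SNP panel, and their recomputation.

The study's individual-level genotypes were never deposited, but its two
allele-frequency tables print the full risk/total allele counts for every
contrast: nephrotic syndrome cases vs. external controls (disease-risk
orientation) and SRNS vs. SSNS (steroid-resistance orientation).  Those
counts are sufficient inputs for every allele-level statistic in the
pipeline, so they are shipped here as fixture data, together with the
printed OR/CI values they should reproduce.

:func:`reproduce_printed_tables` recomputes OR, Woolf CI and chi-square p
for every row from the raw counts and checks the printed values cell by
cell at their printed (1-decimal) rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .association import (
    AlleleCounts,
    ComparisonResult,
    chi_square_independence,
    compare_groups,
    odds_ratio_2x2,
)
from .panel import ControlCounts, ControlReference

#: Cohort composition: therapy-response groups.
N_SSNS = 639
N_SRNS = 236
N_UNKNOWN = 125

#: Individuals excluded from the burden analysis for missing genotypes.
EXCLUDED_SSNS = 47
EXCLUDED_SRNS = 113

#: Published burden-threshold finding: burden >= 7 vs. SRNS.
BURDEN_TAU = 7


@dataclass(frozen=True)
class PublishedRow:
    """One printed table row: raw counts plus the printed OR and 95% CI."""

    rsid: str
    risk_allele: str
    group1_risk: int
    group1_total: int
    group2_risk: int
    group2_total: int
    or_printed: float
    ci_low_printed: float
    ci_high_printed: float
    p_printed: str
    source: str = ""


# Cases vs. external controls, disease-risk orientation.
# group1 = NS cases, group2 = external controls (gnomAD / TOPMed / ALFA).
NS_VS_CONTROLS: tuple[PublishedRow, ...] = (
    PublishedRow("rs1129740", "A", 1251, 1784, 94628, 191328, 2.4, 2.2, 2.7, "<2.2e-16", "gnomAD/TOPMed/ALFA"),
    PublishedRow("rs9348883", "A", 330, 1756, 15739, 264690, 3.7, 3.2, 4.1, "<2.2e-16", "gnomAD/TOPMed/ALFA"),
    PublishedRow("rs4642516", "T", 1211, 1752, 138950, 264690, 2.0, 1.8, 2.2, "<2.2e-16", "gnomAD/TOPMed/ALFA"),
    PublishedRow("rs3134996", "A", 1494, 1762, 94736, 264690, 10.0, 8.8, 11.4, "<2.2e-16", "gnomAD/TOPMed/ALFA"),
    PublishedRow("rs9273371", "T", 736, 1764, 67317, 264690, 2.1, 1.9, 2.3, "<2.2e-16", "gnomAD/TOPMed/ALFA"),
    PublishedRow("rs2637678", "T", 1329, 1766, 167819, 264690, 1.8, 1.6, 2.0, "<2.2e-16", "gnomAD/TOPMed/ALFA"),
    PublishedRow("rs56117924", "A", 125, 1764, 14543, 264690, 1.3, 1.1, 1.6, "3.5e-03", "gnomAD/TOPMed/ALFA"),
    PublishedRow("rs6478109", "G", 1393, 1762, 224655, 328718, 1.7, 1.6, 2.0, "<2.2e-16", "gnomAD/TOPMed/ALFA"),
    PublishedRow("rs34213471", "A", 207, 1766, 14311, 264690, 2.3, 2.0, 2.7, "<2.2e-16", "gnomAD/TOPMed/ALFA"),
)

# SRNS vs. SSNS, steroid-resistance orientation.
# group1 = SRNS, group2 = SSNS.
SRNS_VS_SSNS: tuple[PublishedRow, ...] = (
    PublishedRow("rs1129740", "G", 150, 326, 333, 1228, 2.3, 1.8, 2.9, "5.7e-11"),
    PublishedRow("rs9348883", "A", 184, 342, 125, 1198, 10.0, 7.5, 13.3, "<2.2e-16"),
    PublishedRow("rs4642516", "G", 145, 346, 339, 1194, 1.8, 1.4, 2.3, "1.9e-06"),
    PublishedRow("rs3134996", "T", 96, 352, 147, 1196, 2.7, 2.0, 3.5, "1.1e-11"),
    PublishedRow("rs9273371", "C", 231, 350, 685, 1198, 1.5, 1.1, 1.9, "3.1e-03"),
    PublishedRow("rs2637678", "C", 124, 352, 266, 1198, 1.9, 1.5, 2.5, "8.7e-07"),
    PublishedRow("rs56117924", "A", 24, 352, 80, 1198, 1.0, 0.6, 1.6, "0.9"),
    PublishedRow("rs6478109", "A", 82, 350, 244, 1198, 1.2, 0.9, 1.6, "0.2"),
    PublishedRow("rs34213471", "C", 322, 352, 1034, 1198, 1.7, 1.1, 2.6, "0.01"),
)


def _counts(rows: tuple[PublishedRow, ...], which: int, label: str,
            alleles: dict[str, str]) -> AlleleCounts:
    risk = [r.group1_risk if which == 1 else r.group2_risk for r in rows]
    total = [r.group1_total if which == 1 else r.group2_total for r in rows]
    df = pd.DataFrame({"risk": risk, "total": total},
                      index=[r.rsid for r in rows])
    return AlleleCounts(label, df, dict(alleles))


def ns_case_counts() -> AlleleCounts:
    """All-NS case allele counts, disease-risk orientation."""
    alleles = {r.rsid: r.risk_allele for r in NS_VS_CONTROLS}
    return _counts(NS_VS_CONTROLS, 1, "NS", alleles)


def control_counts() -> AlleleCounts:
    """External control allele counts, disease-risk orientation."""
    alleles = {r.rsid: r.risk_allele for r in NS_VS_CONTROLS}
    return _counts(NS_VS_CONTROLS, 2, "controls", alleles)


def default_control_reference() -> ControlReference:
    """External control counts as a :class:`ControlReference` (disease-risk
    orientation)."""
    return ControlReference(
        ControlCounts(r.rsid, r.group2_risk, r.group2_total, r.source,
                      r.risk_allele)
        for r in NS_VS_CONTROLS
    )


def srns_counts() -> AlleleCounts:
    """SRNS allele counts, steroid-resistance orientation."""
    alleles = {r.rsid: r.risk_allele for r in SRNS_VS_SSNS}
    return _counts(SRNS_VS_SSNS, 1, "SRNS", alleles)


def ssns_counts() -> AlleleCounts:
    """SSNS allele counts, steroid-resistance orientation."""
    alleles = {r.rsid: r.risk_allele for r in SRNS_VS_SSNS}
    return _counts(SRNS_VS_SSNS, 2, "SSNS", alleles)


def published_comparisons(alpha: float = 0.05) -> dict[str, ComparisonResult]:
    """The three published comparison sets recomputed from printed counts.

    - ``NS_vs_controls``: all cases vs. external controls (disease-risk
      orientation).
    - ``SSNS_vs_SRNS``: SRNS vs. SSNS (resistance orientation; SRNS is the
      numerator group, matching the printed table).
    - ``SRNS_vs_controls``: the SRNS counts re-oriented to the disease-risk
      alleles and contrasted with the external controls.  Re-orientation is
      automatic: the two count sets record different risk alleles at the
      seven flipped SNPs, so ``compare_groups`` maps risk -> total - risk.
    """
    return {
        "NS_vs_controls": compare_groups(
            ns_case_counts(), control_counts(), "NS_vs_controls", alpha
        ),
        "SSNS_vs_SRNS": compare_groups(
            srns_counts(), ssns_counts(), "SSNS_vs_SRNS", alpha
        ),
        "SRNS_vs_controls": compare_groups(
            srns_counts(), control_counts(), "SRNS_vs_controls", alpha
        ),
    }


def reproduce_printed_tables() -> pd.DataFrame:
    """Recompute OR / CI / p for every published row and check the printout.

    Returns one row per table row with the recomputed values, the printed
    values, and boolean ``or_match`` / ``ci_match`` flags at 1-decimal
    rounding.  (One printed cell is known not to round to the Woolf value:
    the SRNS-vs-SSNS rs3134996 CI upper bound computes 3.58 -> 3.6 against a
    printed 3.5.)
    """
    records = []
    for table, rows in (
        ("NS_vs_controls", NS_VS_CONTROLS),
        ("SRNS_vs_SSNS", SRNS_VS_SSNS),
    ):
        for r in rows:
            a, b = r.group1_risk, r.group1_total - r.group1_risk
            c, d = r.group2_risk, r.group2_total - r.group2_risk
            orr = odds_ratio_2x2(a, b, c, d)
            chi2, p = chi_square_independence(a, b, c, d)
            records.append(
                {
                    "table": table,
                    "rsid": r.rsid,
                    "or_computed": orr.point,
                    "or_printed": r.or_printed,
                    "or_match": round(orr.point, 1) == r.or_printed,
                    "ci_low_computed": orr.ci_low,
                    "ci_high_computed": orr.ci_high,
                    "ci_low_printed": r.ci_low_printed,
                    "ci_high_printed": r.ci_high_printed,
                    "ci_match": (
                        round(orr.ci_low, 1) == r.ci_low_printed
                        and round(orr.ci_high, 1) == r.ci_high_printed
                    ),
                    "chi2": chi2,
                    "p_raw": p,
                    "p_printed": r.p_printed,
                }
            )
    return pd.DataFrame.from_records(records)
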