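"""Risk-allele burden score and its association with steroid resistance.

The burden of an individual is the plain count of risk alleles over the
variants whose allele frequencies differ significantly (Bonferroni) between
the therapy-response groups — for the published panel these are the six
HLA-region/immune variants, so the burden ranges over 0..12.  Individuals
with any missing genotype among the selected variants are excluded
(complete-case rule) before counting.  The burden is dichotomised at a
threshold tau (default 7) and the resulting 2x2 table {>= tau, < tau} x
{SRNS, SSNS} is tested with a two-sided Fisher exact test; the OR uses the
same Woolf CI machinery as the per-variant contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .association import (
    AssociationError,
    ComparisonResult,
    OddsRatio,
    bonferroni_flags,
    odds_ratio_2x2,
)
from .genotypes import PHENOTYPES, GenotypeMatrix


class BurdenError(ValueError):
    """Raised for invalid burden-analysis inputs."""


def select_burden_variants(comparison: ComparisonResult) -> list[str]:
    """rsIDs significant after Bonferroni correction, set order preserved.

    The comparison must be the therapy-response contrast (SSNS vs. SRNS);
    with zero significant variants the burden is undefined.
    """
    selected = comparison.significant_rsids
    if not selected:
        raise BurdenError(
            "no Bonferroni-significant variants: burden undefined"
        )
    return selected


def complete_case_filter(
    gm: GenotypeMatrix, variants: Sequence[str]
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Retain individuals with a non-missing call at every listed variant.

    Returns the filtered matrix and per-phenotype-group exclusion counts.
    Retained + excluded partitions each group exactly.
    """
    unknown = [v for v in variants if v not in gm.panel]
    if unknown:
        raise BurdenError(f"variants not in panel: {unknown}")
    complete = gm.dosage[list(variants)].notna().all(axis=1)
    excluded = {
        g: int((~complete & (gm.phenotype == g)).sum()) for g in PHENOTYPES
    }
    if not complete.any():
        raise BurdenError("complete-case filter excluded every individual")
    return gm.subset(gm.dosage.index[complete]), excluded


def burden_count(gm: GenotypeMatrix, variants: Sequence[str]) -> pd.Series:
    """Per-individual risk-allele count over ``variants`` (range 0..2k).

    The matrix must already be complete-case filtered for these variants;
    a residual missing call violates that contract and raises.
    """
    sub = gm.dosage[list(variants)]
    if sub.isna().any().any():
        raise BurdenError(
            "missing dosage encountered: run complete_case_filter first"
        )
    return sub.sum(axis=1).astype(int).rename("burden")


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Defined as the sum over all tables with the observed margins of the
    hypergeometric probabilities not exceeding that of the observed table.
    """
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class BurdenResult:
    """Burden-threshold association between SRNS and SSNS."""

    included_variants: tuple[str, ...]
    excluded_missing: dict[str, int]
    tau: int
    #: 2x2 counts: a = SRNS >= tau, b = SRNS < tau, c = SSNS >= tau, d = SSNS < tau
    a: int
    b: int
    c: int
    d: int
    odds_ratio: OddsRatio
    p_fisher: float
    distribution: pd.DataFrame  # index burden 0..2k, one column per group
    burdens: pd.Series
    labels: pd.Series

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"SRNS": [self.a, self.b], "SSNS": [self.c, self.d]},
            index=[f">= {self.tau}", f"< {self.tau}"],
        )

    def to_frame(self) -> pd.DataFrame:
        orr = self.odds_ratio
        return pd.DataFrame(
            [
                {
                    "tau": self.tau,
                    "srns_ge_tau": self.a,
                    "srns_lt_tau": self.b,
                    "ssns_ge_tau": self.c,
                    "ssns_lt_tau": self.d,
                    "or": orr.point,
                    "ci_low": orr.ci_low,
                    "ci_high": orr.ci_high,
                    "p_fisher": self.p_fisher,
                    "zero_cell_corrected": orr.zero_cell_corrected,
                }
            ]
        )


def burden_distribution(
    burdens: pd.Series,
    labels: pd.Series,
    max_burden: int,
    groups: Sequence[str] = ("SRNS", "SSNS"),
) -> pd.DataFrame:
    """Histogram of burden values per group over 0..max_burden.

    An empty group yields an all-zero column with a warning.
    """
    index = pd.RangeIndex(0, max_burden + 1, name="burden")
    out = pd.DataFrame(0, index=index, columns=list(groups))
    for g in groups:
        vals = burdens[labels == g]
        if vals.empty:
            warnings.warn(f"empty group in burden distribution: {g}", stacklevel=2)
            continue
        counts = vals.value_counts()
        out.loc[counts.index, g] = counts.values
    return out


def burden_association(
    burdens: pd.Series,
    labels: pd.Series,
    tau: int = 7,
    included_variants: Sequence[str] = (),
    excluded_missing: dict[str, int] | None = None,
) -> BurdenResult:
    """Test burden >= tau against therapy response (SRNS vs. SSNS).

    ``burdens`` and ``labels`` are aligned per-individual series; labels must
    be SRNS or SSNS and both groups non-empty.  If a group falls entirely on
    one side of tau, the OR is computed with the 0.5 zero-cell correction
    and flagged.
    """
    if not burdens.index.equals(labels.index):
        raise BurdenError("burdens and labels are not aligned")
    bad = set(labels) - {"SRNS", "SSNS"}
    if bad:
        raise BurdenError(f"labels outside SRNS/SSNS: {sorted(bad)}")
    srns = burdens[labels == "SRNS"]
    ssns = burdens[labels == "SSNS"]
    if srns.empty or ssns.empty:
        raise BurdenError("both groups must be non-empty")
    a = int((srns >= tau).sum())
    b = len(srns) - a
    c = int((ssns >= tau).sum())
    d = len(ssns) - c
    orr = odds_ratio_2x2(a, b, c, d)
    p = fisher_exact_two_sided(a, b, c, d)
    max_burden = 2 * len(included_variants) if included_variants else int(burdens.max())
    return BurdenResult(
        included_variants=tuple(included_variants),
        excluded_missing=dict(excluded_missing or {}),
        tau=tau,
        a=a, b=b, c=c, d=d,
        odds_ratio=orr,
        p_fisher=p,
        distribution=burden_distribution(burdens, labels, max_burden),
        burdens=burdens,
        labels=labels,
    )


def threshold_sweep(
    burdens: pd.Series, labels: pd.Series, max_burden: int
) -> pd.DataFrame:
    """Burden-threshold 2x2 statistics for every tau in 1..max_burden.

    The >= tau cell counts are non-increasing in tau within each group.
    """
    rows = []
    srns = burdens[labels == "SRNS"]
    ssns = burdens[labels == "SSNS"]
    for tau in range(1, max_burden + 1):
        a = int((srns >= tau).sum())
        b = len(srns) - a
        c = int((ssns >= tau).sum())
        d = len(ssns) - c
        row = {"tau": tau, "srns_ge_tau": a, "srns_lt_tau": b,
               "ssns_ge_tau": c, "ssns_lt_tau": d}
        try:
            orr = odds_ratio_2x2(a, b, c, d)
            row.update(
                {"or": orr.point, "ci_low": orr.ci_low, "ci_high": orr.ci_high,
                 "zero_cell_corrected": orr.zero_cell_corrected}
            )
        except AssociationError:
            row.update({"or": math.nan, "ci_low": math.nan,
                        "ci_high": math.nan, "zero_cell_corrected": False})
        row["p_fisher"] = fisher_exact_two_sided(a, b, c, d)
        rows.append(row)
    return pd.DataFrame(rows)


def homozygosity_comparison(
    gm: GenotypeMatrix,
    group1: str = "SRNS",
    group2: str = "SSNS",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variant homozygous-risk genotype frequency contrast.

    For each panel variant the fraction of dosage-2 individuals among
    non-missing individuals is compared between the two groups with a
    two-sided Fisher exact test, Bonferroni-corrected over the variants
    tested.  A variant with zero non-missing individuals in either group is
    skipped with a warning.
    """
    rows = []
    idx1 = gm.group_samples(group1)
    idx2 = gm.group_samples(group2)
    for rsid in gm.panel.rsids:
        d1 = gm.dosage.loc[idx1, rsid].dropna()
        d2 = gm.dosage.loc[idx2, rsid].dropna()
        if d1.empty or d2.empty:
            warnings.warn(
                f"{rsid}: no non-missing individuals in a group; skipped",
                stacklevel=2,
            )
            continue
        h1, n1 = int((d1 == 2).sum()), len(d1)
        h2, n2 = int((d2 == 2).sum()), len(d2)
        orr = odds_ratio_2x2(h1, n1 - h1, h2, n2 - h2)
        p = fisher_exact_two_sided(h1, n1 - h1, h2, n2 - h2)
        rows.append(
            {
                "rsid": rsid,
                f"hom_risk_{group1}": h1,
                f"n_{group1}": n1,
                f"hom_freq_{group1}": h1 / n1,
                f"hom_risk_{group2}": h2,
                f"n_{group2}": n2,
                f"hom_freq_{group2}": h2 / n2,
                "or": orr.point,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "zero_cell_corrected": orr.zero_cell_corrected,
                "p_fisher": p,
            }
        )
    if not rows:
        raise BurdenError("no variant could be tested for homozygosity")
    df = pd.DataFrame(rows)
    df["significant_bonferroni"] = bonferroni_flags(df["p_fisher"], alpha)
    return df
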