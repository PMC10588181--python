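"""Allele-level 2x2 association statistics with Bonferroni correction.

For each variant and pair of groups the analysis forms the allele-count
table

    ==========  =========  =========
                group 1     group 2
    ==========  =========  =========
    risk            a          c
    non-risk        b          d
    ==========  =========  =========

and reports the allele frequencies a/(a+b) and c/(c+d), the odds ratio
OR = (a/b)/(c/d) with a 95% Woolf (log-OR normal approximation) confidence
interval, and the Pearson chi-square test of independence (1 df, two-sided,
no continuity correction by default).  Significance is declared per
comparison set at the Bonferroni level p < alpha/m where m is the number of
tests in the set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .panel import ControlReference, VariantPanel

#: Printed p-value floor used in report tables; raw values are kept internally.
P_FLOOR = 2.2e-16

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class AssociationError(ValueError):
    """Raised for invalid association inputs."""


class AlleleCounts:
    """Per-variant risk/total allele counts for one group.

    ``counts`` is indexed by rsid with integer columns ``risk`` and
    ``total``; ``risk_alleles`` records which allele the risk count refers
    to (may be None when the orientation is implied by context).
    """

    def __init__(
        self,
        label: str,
        counts: pd.DataFrame,
        risk_alleles: dict[str, str | None] | None = None,
    ):
        if not {"risk", "total"} <= set(counts.columns):
            raise AssociationError("counts need 'risk' and 'total' columns")
        counts = counts[["risk", "total"]].astype(int)
        if (counts["total"] <= 0).any():
            bad = counts.index[counts["total"] <= 0][0]
            raise AssociationError(f"{bad}: total allele count must be positive")
        if ((counts["risk"] < 0) | (counts["risk"] > counts["total"])).any():
            bad = counts.index[
                (counts["risk"] < 0) | (counts["risk"] > counts["total"])
            ][0]
            raise AssociationError(f"{bad}: risk count outside [0, total]")
        self.label = label
        self.counts = counts
        self.risk_alleles = dict(risk_alleles or {})

    @property
    def rsids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def af(self) -> pd.Series:
        return self.counts["risk"] / self.counts["total"]

    def risk_allele(self, rsid: str) -> str | None:
        return self.risk_alleles.get(rsid)

    def flipped(self, rsids: Sequence[str] | None = None) -> "AlleleCounts":
        """Counts re-oriented to the opposite allele (risk -> total - risk)."""
        flip = set(self.counts.index if rsids is None else rsids)
        counts = self.counts.copy()
        sel = counts.index.isin(flip)
        counts.loc[sel, "risk"] = (
            counts.loc[sel, "total"] - counts.loc[sel, "risk"]
        )
        alleles = dict(self.risk_alleles)
        for rsid in flip:
            alleles.pop(rsid, None)
        return AlleleCounts(self.label, counts, alleles)

    @classmethod
    def from_genotypes(
        cls,
        gm: GenotypeMatrix,
        groups: str | Sequence[str],
        label: str | None = None,
    ) -> "AlleleCounts":
        """Allele counts for the individuals with the given phenotype label(s).

        Individuals missing at a variant are excluded from that variant's
        denominator only: total = 2 x non-missing individuals, risk = sum of
        their dosages.
        """
        samples = gm.group_samples(groups)
        if len(samples) == 0:
            raise AssociationError(f"no individuals with phenotype {groups!r}")
        sub = gm.dosage.loc[samples]
        counts = pd.DataFrame(
            {
                "risk": sub.sum(skipna=True).astype(int),
                "total": 2 * sub.notna().sum().astype(int),
            },
            index=gm.panel.rsids,
        )
        if (counts["total"] == 0).any():
            bad = counts.index[counts["total"] == 0][0]
            raise AssociationError(
                f"{bad}: every selected individual is missing at this variant"
            )
        name = label or (groups if isinstance(groups, str) else "+".join(groups))
        return cls(name, counts, gm.panel.risk_alleles())

    @classmethod
    def from_controls(
        cls, reference: ControlReference, label: str = "controls"
    ) -> "AlleleCounts":
        counts = pd.DataFrame(
            {
                "risk": [c.risk_count for c in reference.counts],
                "total": [c.total_count for c in reference.counts],
            },
            index=reference.rsids,
        )
        alleles = {c.rsid: c.risk_allele for c in reference.counts}
        return cls(label, counts, alleles)


@dataclass(frozen=True)
class OddsRatio:
    """Odds ratio point estimate with 95% Woolf confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    zero_cell_corrected: bool = False


def odds_ratio_2x2(
    a: int, b: int, c: int, d: int, zero_cell_correction: bool = True
) -> OddsRatio:
    """OR = (a/b)/(c/d) with Woolf 95% CI exp(ln OR +/- 1.96*SE).

    SE = sqrt(1/a + 1/b + 1/c + 1/d).  If any cell is zero, 0.5 is added to
    all four cells (Haldane–Anscombe) and the result is flagged.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise AssociationError(f"cell counts must be nonnegative integers: {x}")
    if a + b == 0 or c + d == 0:
        raise AssociationError("a group has zero total alleles")
    corrected = 0 in (a, b, c, d)
    if corrected:
        if not zero_cell_correction:
            raise AssociationError(
                "zero cell with zero_cell_correction disabled"
            )
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    point = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(point)
    return OddsRatio(
        point=point,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        zero_cell_corrected=corrected,
    )


def chi_square_independence(
    a: int, b: int, c: int, d: int, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table (1 df).

    Returns (statistic, two-sided p).  No Yates continuity correction by
    default; pass ``continuity_correction=True`` to enable it.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise AssociationError("negative cell count")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise AssociationError("chi-square undefined: a zero marginal")
    stat, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return float(stat), float(p)


def bonferroni_flags(
    p_values: Sequence[float], alpha: float = 0.05
) -> list[bool]:
    """Per-test significance at the Bonferroni level alpha / m.

    m is always the number of tests in the comparison set (the length of
    ``p_values``), never the number of surviving tests.
    """
    p_values = list(p_values)
    if not p_values:
        raise AssociationError("empty p-value list")
    for p in p_values:
        if not 0 <= p <= 1:
            raise AssociationError(f"p-value outside [0,1]: {p}")
    threshold = alpha / len(p_values)
    return [p < threshold for p in p_values]


@dataclass(frozen=True)
class AssociationResult:
    """Allele-frequency contrast for one variant between two groups."""

    rsid: str
    group1: str
    group2: str
    a: int  # risk alleles, group 1
    b: int  # non-risk alleles, group 1
    c: int  # risk alleles, group 2
    d: int  # non-risk alleles, group 2
    group1_af: float
    group2_af: float
    or_point: float
    ci_low: float
    ci_high: float
    chi2_stat: float
    p_raw: float
    m_tests: int
    significant_bonferroni: bool
    zero_cell_corrected: bool = False
    reoriented: bool = False


class ComparisonResult:
    """All per-variant results of one comparison set (one Bonferroni family)."""

    def __init__(self, set_label: str, results: Sequence[AssociationResult],
                 alpha: float = 0.05):
        self.set_label = set_label
        self.results = list(results)
        self.alpha = alpha

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    @property
    def significant_rsids(self) -> list[str]:
        return [r.rsid for r in self.results if r.significant_bonferroni]

    def to_frame(self) -> pd.DataFrame:
        """Full-precision machine-readable result table."""
        df = pd.DataFrame([vars(r) for r in self.results])
        df["p_threshold"] = self.alpha / df["m_tests"]
        return df

    def report_frame(self, panel: VariantPanel | None = None) -> pd.DataFrame:
        """Publication-style table: AF to 2 decimals, OR/CI to 1 decimal,
        p-values floored at the printed limit."""
        rows = []
        for r in self.results:
            gene = risk = ""
            if panel is not None and r.rsid in panel:
                v = panel.get(r.rsid)
                gene, risk = v.gene, v.risk_allele
            rows.append(
                {
                    "rsid": r.rsid,
                    "risk_allele": risk,
                    "gene": gene,
                    f"af_{r.group1}": f"{r.a}/{r.a + r.b} ({r.group1_af:.2f})",
                    f"af_{r.group2}": f"{r.c}/{r.c + r.d} ({r.group2_af:.2f})",
                    "or_95ci": f"{r.or_point:.1f} ({r.ci_low:.1f}-{r.ci_high:.1f})",
                    "chi2": f"{r.chi2_stat:.1f}",
                    "p": format_p(r.p_raw),
                    "p_threshold": f"{self.alpha / r.m_tests:.2e}",
                    "significant": r.significant_bonferroni,
                }
            )
        return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """Render a p-value with the conventional printed floor."""
    if p < P_FLOOR:
        return "<2.2e-16"
    return f"{p:.2g}" if p < 0.001 else f"{p:.2g}"


def compare_groups(
    counts1: AlleleCounts,
    counts2: AlleleCounts,
    set_label: str,
    alpha: float = 0.05,
    continuity_correction: bool = False,
    zero_cell_correction: bool = True,
) -> ComparisonResult:
    """Per-variant 2x2 association between two allele-count sets.

    ``counts1`` is the comparison numerator (cases, or the SRNS group).  Both
    sets must cover the same variants.  If the two sets record different risk
    alleles at a variant, ``counts2`` is re-oriented there (risk -> total -
    risk); the chi-square p is orientation-invariant, the OR flips.
    """
    s1, s2 = set(counts1.rsids), set(counts2.rsids)
    if s1 != s2:
        raise AssociationError(
            f"panels differ between count sets: {sorted(s1 ^ s2)}"
        )
    results = []
    tables = []
    for rsid in counts1.rsids:
        r1, t1 = counts1.counts.at[rsid, "risk"], counts1.counts.at[rsid, "total"]
        r2, t2 = counts2.counts.at[rsid, "risk"], counts2.counts.at[rsid, "total"]
        a1 = counts1.risk_allele(rsid)
        a2 = counts2.risk_allele(rsid)
        reoriented = a1 is not None and a2 is not None and a1 != a2
        if reoriented:
            r2 = t2 - r2
        tables.append((rsid, int(r1), int(t1 - r1), int(r2), int(t2 - r2), reoriented))
    p_values = []
    stats_or = []
    for rsid, a, b, c, d, reoriented in tables:
        orr = odds_ratio_2x2(a, b, c, d, zero_cell_correction)
        chi2, p = chi_square_independence(a, b, c, d, continuity_correction)
        stats_or.append((orr, chi2, p))
        p_values.append(p)
    flags = bonferroni_flags(p_values, alpha)
    m = len(tables)
    for (rsid, a, b, c, d, reoriented), (orr, chi2, p), flag in zip(
        tables, stats_or, flags
    ):
        results.append(
            AssociationResult(
                rsid=rsid,
                group1=counts1.label,
                group2=counts2.label,
                a=a, b=b, c=c, d=d,
                group1_af=a / (a + b),
                group2_af=c / (c + d),
                or_point=orr.point,
                ci_low=orr.ci_low,
                ci_high=orr.ci_high,
                chi2_stat=chi2,
                p_raw=p,
                m_tests=m,
                significant_bonferroni=flag,
                zero_cell_corrected=orr.zero_cell_corrected,
                reoriented=reoriented,
            )
        )
    return ComparisonResult(set_label, results, alpha)
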