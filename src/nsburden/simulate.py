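"""Synthetic cohort generation under Hardy-Weinberg equilibrium.

The study's individual-level genotypes are unavailable, so the pipeline is
exercised on synthetic cohorts that reproduce the statistical structure its
methods assume: two therapy-response groups with group-specific risk allele
frequencies, Hardy-Weinberg genotype proportions, loci drawn independently,
and missing-completely-at-random genotype dropout at configurable per-group
per-variant rates.

The default cohort specification mirrors the published study: group sizes
639 (SSNS) / 236 (SRNS), per-group allele frequencies equal to the printed
SSNS-vs-SRNS table (resistance orientation), and per-group missingness rates
chosen so that complete-case filtering over the six burden variants excludes
47 SSNS and 113 SRNS individuals in expectation, i.e. the per-variant rate r
solves (1 - r)^6 = retained fraction.

Loci are independent by default although the three HLA-region SNPs are in
linkage disequilibrium in reality; an optional exchangeable Gaussian-copula
coupling of dosages is provided for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .genotypes import GenotypeMatrix, PHENOTYPES
from .panel import VariantPanel, resistance_panel
from .tables import (
    EXCLUDED_SRNS,
    EXCLUDED_SSNS,
    N_SRNS,
    N_SSNS,
    SRNS_VS_SSNS,
)


class CohortSpecError(ValueError):
    """Raised for an invalid cohort specification."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    group_sizes
        Individuals per phenotype group, e.g. ``{"SSNS": 639, "SRNS": 236,
        "UNKNOWN": 0}``; missing groups default to 0.
    af
        Risk allele frequency per variant per group:
        ``{rsid: {group: frequency}}``, oriented to the panel the cohort is
        generated against.
    missing_rate
        Per-group missing-call probability, either a scalar per group or
        ``{group: {rsid: rate}}``.  Missingness is MCAR: independent of
        genotype and of other variants.
    seed
        Seed for the generator's random streams (one named stream per stage,
        all derived from this seed).
    dosage_correlation
        Optional exchangeable across-locus correlation of the latent
        genotype draws (Gaussian copula); 0 keeps loci independent.
    """

    group_sizes: dict[str, int]
    af: dict[str, dict[str, float]]
    missing_rate: dict[str, float] | dict[str, dict[str, float]] = field(
        default_factory=dict
    )
    seed: int = 0
    dosage_correlation: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.group_sizes) - set(PHENOTYPES)
        if bad:
            raise CohortSpecError(f"unknown groups: {sorted(bad)}")
        for g in PHENOTYPES:
            self.group_sizes.setdefault(g, 0)
        if any(n < 0 for n in self.group_sizes.values()):
            raise CohortSpecError("group sizes must be nonnegative")
        if self.group_sizes["SSNS"] + self.group_sizes["SRNS"] == 0:
            raise CohortSpecError("at least one phenotyped group must be non-empty")
        for rsid, by_group in self.af.items():
            for g, p in by_group.items():
                if not 0.0 <= p <= 1.0:
                    raise CohortSpecError(f"af[{rsid}][{g}] = {p} outside [0,1]")
        if not 0.0 <= self.dosage_correlation < 1.0:
            raise CohortSpecError("dosage_correlation must be in [0, 1)")

    def group_missing_rate(self, group: str, rsid: str) -> float:
        entry = self.missing_rate.get(group, 0.0)
        rate = entry.get(rsid, 0.0) if isinstance(entry, Mapping) else entry
        if not 0.0 <= rate < 1.0:
            raise CohortSpecError(
                f"missing_rate[{group}][{rsid}] = {rate} outside [0, 1)"
            )
        return float(rate)

    def group_af(self, group: str, rsid: str) -> float:
        try:
            return float(self.af[rsid][group])
        except KeyError:
            raise CohortSpecError(
                f"no allele frequency for {rsid} in group {group}"
            ) from None

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "group_sizes": self.group_sizes,
            "af": self.af,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "dosage_correlation": self.dosage_correlation,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise CohortSpecError(f"malformed cohort spec file: {path}")
        return cls(
            group_sizes={k: int(v) for k, v in data.get("group_sizes", {}).items()},
            af=data.get("af", {}),
            missing_rate=data.get("missing_rate", {}),
            seed=int(data.get("seed", 0)),
            dosage_correlation=float(data.get("dosage_correlation", 0.0)),
        )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named random streams, all derived from the single spec seed."""
    root = np.random.SeedSequence(seed)
    genotype_ss, missing_ss = root.spawn(2)
    return {
        "genotype": np.random.default_rng(genotype_ss),
        "missing": np.random.default_rng(missing_ss),
    }


def generate_cohort(spec: CohortSpec, panel: VariantPanel) -> GenotypeMatrix:
    """Draw a cohort: dosage ~ Binomial(2, af[variant, group]) per locus (HWE),
    then MCAR dropout at the per-group per-variant missing rate.

    Fully reproducible: identical (spec, seed) gives a bit-identical matrix.
    """
    streams = _streams(spec.seed)
    rng_g, rng_m = streams["genotype"], streams["missing"]
    rho = spec.dosage_correlation
    blocks: list[pd.DataFrame] = []
    phenos: list[str] = []
    samples: list[str] = []
    for group in PHENOTYPES:
        n = spec.group_sizes.get(group, 0)
        if n == 0:
            continue
        afs = np.array([spec.group_af(group, rsid) for rsid in panel.rsids])
        if rho == 0.0:
            dosage = rng_g.binomial(2, afs, size=(n, len(afs))).astype(float)
        else:
            # Exchangeable Gaussian copula: one shared latent factor per
            # individual couples the uniform draws across loci; marginals
            # stay Binomial(2, af).
            shared = rng_g.standard_normal((n, 1))
            noise = rng_g.standard_normal((n, len(afs)))
            z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * noise
            u = stats.norm.cdf(z)
            dosage = stats.binom.ppf(u, 2, afs).astype(float)
        rates = np.array(
            [spec.group_missing_rate(group, rsid) for rsid in panel.rsids]
        )
        drop = rng_m.random((n, len(afs))) < rates
        dosage[drop] = np.nan
        ids = [f"{group}_{i:04d}" for i in range(1, n + 1)]
        blocks.append(pd.DataFrame(dosage, index=ids, columns=panel.rsids))
        phenos.extend([group] * n)
        samples.extend(ids)
    dosage = pd.concat(blocks)
    phenotype = pd.Series(phenos, index=samples, name="phenotype")
    return GenotypeMatrix(dosage, phenotype, panel)


def uniform_missing_rate(retained_fraction: float, k: int) -> float:
    """Per-variant MCAR rate r with (1 - r)^k = retained_fraction.

    This is the rate at which, applied uniformly and independently over k
    variants, complete-case filtering retains the given fraction of a group
    in expectation.
    """
    if not 0.0 < retained_fraction <= 1.0:
        raise CohortSpecError("retained fraction must be in (0, 1]")
    return 1.0 - retained_fraction ** (1.0 / k)


#: The six variants used in the published burden analysis (the Bonferroni-
#: significant SSNS-vs-SRNS variants), in panel order.
BURDEN_VARIANTS: tuple[str, ...] = (
    "rs1129740",
    "rs9348883",
    "rs4642516",
    "rs3134996",
    "rs9273371",
    "rs2637678",
)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Cohort spec matching the published therapy-response table.

    Group sizes 639 SSNS / 236 SRNS; per-group allele frequencies equal to
    the printed risk/total ratios (resistance orientation — generate against
    :func:`nsburden.panel.resistance_panel`); per-group uniform MCAR rates
    calibrated so the six-variant complete-case filter excludes 47 SSNS and
    113 SRNS individuals in expectation.
    """
    af = {
        row.rsid: {
            "SRNS": row.group1_risk / row.group1_total,
            "SSNS": row.group2_risk / row.group2_total,
        }
        for row in SRNS_VS_SSNS
    }
    k = len(BURDEN_VARIANTS)
    missing = {
        "SSNS": uniform_missing_rate((N_SSNS - EXCLUDED_SSNS) / N_SSNS, k),
        "SRNS": uniform_missing_rate((N_SRNS - EXCLUDED_SRNS) / N_SRNS, k),
    }
    return CohortSpec(
        group_sizes={"SSNS": N_SSNS, "SRNS": N_SRNS, "UNKNOWN": 0},
        af=af,
        missing_rate=missing,
        seed=seed,
    )


def generate_default_cohort(seed: int = 0) -> GenotypeMatrix:
    """Convenience: default spec generated against the resistance panel."""
    return generate_cohort(default_cohort_spec(seed), resistance_panel())
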