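"""Genotype matrices: per-individual risk-allele dosages with missingness.

Dosage is the count of the panel's risk allele per diploid genotype, so it is
0, 1 or 2; a missing call is an explicit state (NaN in the backing frame),
never a silent zero.  Phenotype labels form the closed set {SSNS, SRNS,
UNKNOWN}; individuals with unknown therapy response are kept in storage but
excluded from SSNS-vs-SRNS contrasts downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from .panel import VariantPanel

PHENOTYPES = ("SSNS", "SRNS", "UNKNOWN")

_MISSING_TOKENS = {".", "./.", ".|.", "", "NA"}


class GenotypeError(ValueError):
    """Raised for malformed genotype data."""


class DuplicatePair(NamedTuple):
    """Two sample identifiers expected to carry identical genotypes."""

    sample_a: str
    sample_b: str


class GenotypeMatrix:
    """Individuals x panel-variants risk-allele dosage matrix.

    Parameters
    ----------
    dosage
        DataFrame indexed by sample identifier with one float column per
        panel rsID; values in {0, 1, 2} or NaN for a missing call.
    phenotype
        Series aligned to ``dosage.index`` with values in
        ``{"SSNS", "SRNS", "UNKNOWN"}``.
    panel
        The :class:`~nsburden.panel.VariantPanel` that fixes which allele
        the dosages count.
    """

    def __init__(
        self, dosage: pd.DataFrame, phenotype: pd.Series, panel: VariantPanel
    ):
        if list(dosage.columns) != panel.rsids:
            raise GenotypeError(
                "dosage columns do not match panel rsids: "
                f"{list(dosage.columns)} vs {panel.rsids}"
            )
        if not dosage.index.equals(phenotype.index):
            raise GenotypeError("phenotype index does not match dosage index")
        if dosage.index.has_duplicates:
            dup = dosage.index[dosage.index.duplicated()][0]
            raise GenotypeError(f"duplicate sample identifier: {dup}")
        values = dosage.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = values[~ok].flat[0]
            raise GenotypeError(f"dosage value outside {{0,1,2,missing}}: {bad}")
        bad_labels = set(phenotype) - set(PHENOTYPES)
        if bad_labels:
            raise GenotypeError(f"unknown phenotype labels: {sorted(bad_labels)}")
        self.dosage = dosage.astype(float)
        self.phenotype = phenotype.astype(str)
        self.panel = panel

    # -- basic accessors -------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def n_individuals(self) -> int:
        return len(self.dosage)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.dosage.isna()

    def group_samples(self, groups: str | Sequence[str]) -> pd.Index:
        """Sample index for one phenotype label or a sequence of labels."""
        if isinstance(groups, str):
            groups = (groups,)
        bad = set(groups) - set(PHENOTYPES)
        if bad:
            raise GenotypeError(f"unknown phenotype labels: {sorted(bad)}")
        return self.dosage.index[self.phenotype.isin(groups)]

    def subset(self, samples: Sequence[str] | pd.Index) -> "GenotypeMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.dosage.index)
        if len(missing):
            raise GenotypeError(f"unknown samples: {list(missing)[:5]}")
        return GenotypeMatrix(
            self.dosage.loc[samples], self.phenotype.loc[samples], self.panel
        )

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.phenotype == g).sum()) for g in PHENOTYPES}

    # -- serialization ---------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        """Write the canonical TSV: sample, phenotype, one allele-pair column
        per rsID ("A/G" style, risk allele listed first; "./." if missing)."""
        rows = []
        for sample in self.samples:
            row: dict[str, str] = {
                "sample": sample,
                "phenotype": self.phenotype[sample],
            }
            for v in self.panel:
                d = self.dosage.at[sample, v.rsid]
                if math.isnan(d):
                    row[v.rsid] = "./."
                else:
                    n = int(d)
                    row[v.rsid] = "/".join(
                        [v.risk_allele] * n + [v.other_allele] * (2 - n)
                    )
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _dosage_from_call(call: str, rsid: str, sample: str, panel: VariantPanel) -> float:
    """Parse one TSV genotype cell into a risk-allele dosage."""
    call = call.strip()
    if call in _MISSING_TOKENS:
        return math.nan
    variant = panel.get(rsid)
    if call in {"0", "1", "2"}:
        return float(call)
    alleles = call.replace("|", "/").split("/")
    if len(alleles) != 2:
        raise GenotypeError(
            f"unparseable genotype {call!r} for sample {sample} at {rsid}"
        )
    dosage = 0.0
    for allele in alleles:
        if allele == variant.risk_allele:
            dosage += 1.0
        elif allele != variant.other_allele:
            raise GenotypeError(
                f"allele {allele!r} for sample {sample} at {rsid} matches "
                f"neither risk ({variant.risk_allele}) nor other "
                f"({variant.other_allele}) allele"
            )
    return dosage


def _normalize_phenotype(label: str, sample: str) -> str:
    norm = str(label).strip().upper()
    if norm not in PHENOTYPES:
        raise GenotypeError(
            f"phenotype {label!r} for sample {sample} not in {PHENOTYPES}"
        )
    return norm


def load_genotypes_tsv(path: str | Path, panel: VariantPanel) -> GenotypeMatrix:
    """Load the canonical genotype TSV.

    Columns: ``sample``, ``phenotype``, then one column per rsID holding
    either an allele pair ("A/G", phased accepted and treated as unphased),
    a dosage digit 0/1/2, or an explicit missing token ("." or "./.").
    Columns for non-panel variants are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "phenotype"):
        if col not in df.columns:
            raise GenotypeError(f"genotype file missing column {col!r}")
    extra = [c for c in df.columns if c not in ("sample", "phenotype", *panel.rsids)]
    if extra:
        warnings.warn(
            f"dropping non-panel genotype columns: {extra}", stacklevel=2
        )
    absent = [rsid for rsid in panel.rsids if rsid not in df.columns]
    if absent:
        raise GenotypeError(f"genotype file lacks panel variants: {absent}")
    samples = df["sample"].astype(str)
    phenotype = pd.Series(
        [_normalize_phenotype(p, s) for p, s in zip(df["phenotype"], samples)],
        index=samples.values,
        name="phenotype",
    )
    dosage = pd.DataFrame(index=samples.values, columns=panel.rsids, dtype=float)
    for rsid in panel.rsids:
        col = df[rsid].fillna(".")
        dosage[rsid] = [
            _dosage_from_call(call, rsid, sample, panel)
            for call, sample in zip(col, samples)
        ]
    return GenotypeMatrix(dosage, phenotype, panel)


def load_genotypes_vcf(
    path: str | Path,
    panel: VariantPanel,
    phenotypes: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Load panel genotypes from a VCF (GT field only, diploid).

    Records are matched to the panel by the ID column; non-panel records are
    skipped with a warning.  Phased and unphased calls are treated alike.
    ``phenotypes`` maps sample to label; unlisted samples become UNKNOWN.
    """
    phenotypes = dict(phenotypes or {})
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        dosage = pd.DataFrame(index=samples, columns=panel.rsids, dtype=float)
        seen: set[str] = set()
        for record in vcf:
            rsid = record.id
            if rsid is None or rsid not in panel:
                warnings.warn(
                    f"skipping non-panel VCF record {rsid or record.pos}",
                    stacklevel=2,
                )
                continue
            variant = panel.get(rsid)
            site_alleles = (record.ref, *(record.alts or ()))
            for sample in samples:
                gt = record.samples[sample]["GT"]
                if gt is None or any(idx is None for idx in gt):
                    dosage.at[sample, rsid] = math.nan
                    continue
                if len(gt) != 2:
                    raise GenotypeError(
                        f"non-diploid call for sample {sample} at {rsid}"
                    )
                d = 0.0
                for idx in gt:
                    allele = site_alleles[idx]
                    if allele == variant.risk_allele:
                        d += 1.0
                    elif allele != variant.other_allele:
                        raise GenotypeError(
                            f"allele {allele!r} for sample {sample} at {rsid} "
                            "matches neither panel allele"
                        )
                dosage.at[sample, rsid] = d
            seen.add(rsid)
    absent = [rsid for rsid in panel.rsids if rsid not in seen]
    if absent:
        raise GenotypeError(f"VCF lacks panel variants: {absent}")
    phenotype = pd.Series(
        [_normalize_phenotype(phenotypes.get(s, "UNKNOWN"), s) for s in samples],
        index=samples,
        name="phenotype",
    )
    return GenotypeMatrix(dosage, phenotype, panel)


def load_genotypes(
    path: str | Path,
    panel: VariantPanel,
    phenotypes: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Dispatch on file extension: ``.vcf`` to the VCF reader, else TSV."""
    if str(path).endswith(".vcf"):
        return load_genotypes_vcf(path, panel, phenotypes)
    return load_genotypes_tsv(path, panel)


@dataclass(frozen=True)
class ConcordanceResult:
    """Duplicate-genotyping concordance for one sample pair."""

    sample_a: str
    sample_b: str
    n_compared: int
    n_equal: int

    @property
    def concordance(self) -> float:
        """Matching fraction over mutually non-missing variants (NaN if none)."""
        if self.n_compared == 0:
            return math.nan
        return self.n_equal / self.n_compared

    @property
    def comparable(self) -> bool:
        return self.n_compared > 0


def duplicate_concordance(
    gm: GenotypeMatrix, pairs: Iterable[DuplicatePair]
) -> list[ConcordanceResult]:
    """Per-pair genotype concordance over mutually non-missing variants."""
    pairs = list(pairs)
    if not pairs:
        raise GenotypeError("no duplicate pairs supplied")
    out = []
    for a, b in pairs:
        for s in (a, b):
            if s not in gm.dosage.index:
                raise GenotypeError(f"duplicate-pair sample not in matrix: {s}")
        da = gm.dosage.loc[a]
        db = gm.dosage.loc[b]
        both = da.notna() & db.notna()
        out.append(
            ConcordanceResult(
                sample_a=a,
                sample_b=b,
                n_compared=int(both.sum()),
                n_equal=int((da[both] == db[both]).sum()),
            )
        )
    return out


def qc_gate(results: Iterable[ConcordanceResult]) -> bool:
    """Genotyping QC passes only if every duplicate pair matches 100%.

    A pair with no mutually non-missing variant is incomparable and fails
    the gate.
    """
    results = list(results)
    if not results:
        raise GenotypeError("no concordance results to gate on")
    return all(r.comparable and r.concordance == 1.0 for r in results)
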