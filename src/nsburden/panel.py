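"""Variant panel definitions and external control allele counts.

A :class:`VariantPanel` fixes, for every SNP in the study, which allele is
counted as the *risk* allele.  Every dosage in the pipeline is the number of
copies of the panel's risk allele, so the panel is the single source of truth
for allele orientation.  Two orientations of the nine-SNP childhood nephrotic
syndrome panel are shipped: the disease-risk orientation used against external
controls, and the steroid-resistance orientation used for the SSNS-vs-SRNS
contrasts (the two differ at seven of the nine SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

NUCLEOTIDES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised for an invalid or inconsistent variant panel."""


@dataclass(frozen=True)
class Variant:
    """One SNP: identifier, gene label and the risk/other allele pair."""

    rsid: str
    gene: str
    risk_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        for allele in (self.risk_allele, self.other_allele):
            if allele not in NUCLEOTIDES:
                raise PanelError(
                    f"{self.rsid}: allele {allele!r} is not one of A/C/G/T"
                )
        if self.risk_allele == self.other_allele:
            raise PanelError(f"{self.rsid}: risk and other allele are identical")

    def flipped(self) -> "Variant":
        """The same SNP with risk and other allele exchanged."""
        return Variant(self.rsid, self.gene, self.other_allele, self.risk_allele)


class VariantPanel:
    """Ordered collection of :class:`Variant` entries with unique rsIDs."""

    def __init__(self, variants: Iterable[Variant]):
        self.variants: tuple[Variant, ...] = tuple(variants)
        if not self.variants:
            raise PanelError("panel is empty")
        seen: set[str] = set()
        for v in self.variants:
            if v.rsid in seen:
                raise PanelError(f"duplicate rsid in panel: {v.rsid}")
            seen.add(v.rsid)
        self._by_rsid = {v.rsid: v for v in self.variants}

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def get(self, rsid: str) -> Variant:
        try:
            return self._by_rsid[rsid]
        except KeyError:
            raise PanelError(f"rsid not in panel: {rsid}") from None

    def reoriented(self, rsids: Sequence[str] | None = None) -> "VariantPanel":
        """Panel with risk/other swapped at ``rsids`` (all variants if None)."""
        flip = set(self.rsids if rsids is None else rsids)
        unknown = flip - set(self.rsids)
        if unknown:
            raise PanelError(f"cannot reorient unknown rsids: {sorted(unknown)}")
        return VariantPanel(
            v.flipped() if v.rsid in flip else v for v in self.variants
        )

    def risk_alleles(self) -> dict[str, str]:
        return {v.rsid: v.risk_allele for v in self.variants}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "gene": [v.gene for v in self.variants],
                "risk_allele": [v.risk_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, VariantPanel) and self.variants == other.variants

    def __repr__(self) -> str:
        return f"VariantPanel({len(self)} variants: {', '.join(self.rsids)})"


def load_panel(path: str | Path) -> VariantPanel:
    """Load a panel from a TSV with columns rsid, gene, risk_allele, other_allele."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise PanelError(f"panel file is empty: {path}") from None
    required = {"rsid", "gene", "risk_allele", "other_allele"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file missing columns: {sorted(missing)}")
    if df.empty:
        raise PanelError(f"panel file has no variants: {path}")
    dup = df["rsid"][df["rsid"].duplicated()]
    if not dup.empty:
        raise PanelError(f"duplicate rsid in panel file: {dup.iloc[0]}")
    return VariantPanel(
        Variant(r.rsid, r.gene, r.risk_allele, r.other_allele)
        for r in df.itertuples()
    )


# The nine reported childhood SSNS risk loci.  Disease-risk orientation: the
# allele over-represented in nephrotic syndrome cases relative to population
# controls.  Resistance orientation: the allele over-represented in
# steroid-resistant relative to steroid-sensitive patients; it is the opposite
# allele at every SNP except rs9348883 and rs56117924.
_PANEL_ROWS: list[tuple[str, str, str, str]] = [
    # rsid, gene, disease-risk allele, other allele
    ("rs1129740", "HLA-DQA1", "A", "G"),
    ("rs9348883", "BTNL2", "A", "T"),
    ("rs4642516", "HLA-DR/DQ", "T", "G"),
    ("rs3134996", "HLA-DR/DQ", "A", "T"),
    ("rs9273371", "Intergenic", "T", "C"),
    ("rs2637678", "CALHM6", "T", "C"),
    ("rs56117924", "NPHS1/KIRREL", "A", "G"),
    ("rs6478109", "TNFSF15", "G", "A"),
    ("rs34213471", "TNFRSF11A", "A", "C"),
]

# SNPs where the resistance-orientation risk allele is the *other* allele of
# the disease-risk orientation.
RESISTANCE_FLIPPED: frozenset[str] = frozenset(
    {
        "rs1129740",
        "rs4642516",
        "rs3134996",
        "rs9273371",
        "rs2637678",
        "rs6478109",
        "rs34213471",
    }
)


def default_panel() -> VariantPanel:
    """The nine-SNP panel in disease-risk orientation (cases vs. controls)."""
    return VariantPanel(Variant(*row) for row in _PANEL_ROWS)


def resistance_panel() -> VariantPanel:
    """The nine-SNP panel oriented to the steroid-resistance risk allele.

    This is the orientation used for SSNS-vs-SRNS association and for the
    risk-allele burden score.
    """
    return default_panel().reoriented(sorted(RESISTANCE_FLIPPED))


@dataclass(frozen=True)
class ControlCounts:
    """Allele-level counts for one variant in the external control pool."""

    rsid: str
    risk_count: int
    total_count: int
    source: str = ""
    risk_allele: str | None = None

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise PanelError(f"{self.rsid}: control total_count must be positive")
        if not 0 <= self.risk_count <= self.total_count:
            raise PanelError(
                f"{self.rsid}: control risk_count {self.risk_count} outside "
                f"[0, {self.total_count}]"
            )

    @property
    def af(self) -> float:
        return self.risk_count / self.total_count


class ControlReference:
    """Per-variant external control allele counts (haploid counts).

    Control denominators may differ per variant: the public aggregation
    databases behind them (gnomAD, TOPMed, ALFA) cover different variant sets.
    """

    def __init__(self, counts: Iterable[ControlCounts]):
        self.counts: tuple[ControlCounts, ...] = tuple(counts)
        self._by_rsid = {c.rsid: c for c in self.counts}
        if len(self._by_rsid) != len(self.counts):
            raise PanelError("duplicate rsid in control reference")

    @property
    def rsids(self) -> list[str]:
        return [c.rsid for c in self.counts]

    def get(self, rsid: str) -> ControlCounts:
        try:
            return self._by_rsid[rsid]
        except KeyError:
            raise PanelError(f"rsid not in control reference: {rsid}") from None

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "risk_count": [c.risk_count for c in self.counts],
                "total_count": [c.total_count for c in self.counts],
                "source": [c.source for c in self.counts],
                "risk_allele": [c.risk_allele or "" for c in self.counts],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_controls(path: str | Path) -> ControlReference:
    """Load control counts from a TSV: rsid, risk_count, total_count, source.

    An optional ``risk_allele`` column records the orientation of the counts;
    when absent the counts are assumed oriented like the analysis panel.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "source": str})
    required = {"rsid", "risk_count", "total_count"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"control file missing columns: {sorted(missing)}")
    has_allele = "risk_allele" in df.columns
    out = []
    for r in df.itertuples():
        allele = getattr(r, "risk_allele", None) if has_allele else None
        if isinstance(allele, float):  # NaN from an empty cell
            allele = None
        out.append(
            ControlCounts(
                rsid=r.rsid,
                risk_count=int(r.risk_count),
                total_count=int(r.total_count),
                source=str(getattr(r, "source", "") or ""),
                risk_allele=allele or None,
            )
        )
    return ControlReference(out)
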