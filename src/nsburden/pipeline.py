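"""End-to-end orchestration: config, QC gate, comparisons, report bundle.

A :class:`PipelineConfig` names the input files, the comparison sets to run
and the statistical knobs; :func:`run_pipeline` loads everything, enforces
the duplicate-genotyping QC gate if pairs are provided, runs the requested
allele-frequency contrasts, and for the therapy-response contrast also the
burden selection, complete-case filtering, burden-threshold association,
threshold sweep, histogram and homozygosity table.  Every output is a TSV
and a run manifest records parameters, input paths, counts and software
versions so each reported statistic is traceable to its raw counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .association import AlleleCounts, compare_groups
from .burden import (
    burden_association,
    burden_count,
    complete_case_filter,
    homozygosity_comparison,
    select_burden_variants,
    threshold_sweep,
)
from .genotypes import (
    DuplicatePair,
    duplicate_concordance,
    load_genotypes,
    qc_gate,
)
from .panel import load_controls, load_panel

COMPARISON_SETS = ("NS_vs_controls", "SSNS_vs_SRNS", "SRNS_vs_controls")


class ConfigError(ValueError):
    """Raised for an invalid pipeline configuration."""


class QCError(RuntimeError):
    """Raised when the duplicate-genotyping QC gate fails."""


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run."""

    panel_path: str
    genotypes_path: str
    out_dir: str
    controls_path: str | None = None
    duplicate_pairs_path: str | None = None
    comparisons: tuple[str, ...] = ("NS_vs_controls", "SSNS_vs_SRNS")
    alpha: float = 0.05
    tau: int = 7
    continuity_correction: bool = False
    zero_cell_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.comparisons:
            raise ConfigError("no comparison sets requested")
        bad = set(self.comparisons) - set(COMPARISON_SETS)
        if bad:
            raise ConfigError(f"unknown comparison sets: {sorted(bad)}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0,1): {self.alpha}")
        if self.tau < 0:
            raise ConfigError(f"tau must be nonnegative: {self.tau}")
        needs_controls = {"NS_vs_controls", "SRNS_vs_controls"}
        if needs_controls & set(self.comparisons) and not self.controls_path:
            raise ConfigError(
                "control reference required for a vs-controls comparison"
            )
        for name, path in (
            ("panel", self.panel_path),
            ("genotypes", self.genotypes_path),
            ("controls", self.controls_path),
            ("duplicate_pairs", self.duplicate_pairs_path),
        ):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"malformed config file: {path}")
        if "comparisons" in data:
            data["comparisons"] = tuple(data["comparisons"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None


def load_duplicate_pairs(path: str | Path) -> list[DuplicatePair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_a", "sample_b"} <= set(df.columns):
        raise ConfigError("duplicate-pair file needs sample_a/sample_b columns")
    return [DuplicatePair(r.sample_a, r.sample_b) for r in df.itertuples()]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured comparisons and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``) recording
    parameters, group sizes, QC results, per-comparison significant variants
    and the exact 2x2 counts behind the burden statistic.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_panel(config.panel_path)
    gm = load_genotypes(config.genotypes_path, panel)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "versions": {
            "nsburden": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "panel": panel.rsids,
        "group_sizes": gm.group_sizes(),
        "warnings": [],
    }

    if config.duplicate_pairs_path:
        pairs = load_duplicate_pairs(config.duplicate_pairs_path)
        conc = duplicate_concordance(gm, pairs)
        conc_df = pd.DataFrame(
            [
                {
                    "sample_a": r.sample_a,
                    "sample_b": r.sample_b,
                    "n_compared": r.n_compared,
                    "n_equal": r.n_equal,
                    "concordance": r.concordance,
                    "comparable": r.comparable,
                }
                for r in conc
            ]
        )
        _write(conc_df, out / "qc_duplicate_concordance.tsv")
        passed = qc_gate(conc)
        manifest["qc"] = {"duplicate_pairs": len(conc), "passed": passed}
        if not passed:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise QCError(
                "duplicate-genotyping QC gate failed: see "
                "qc_duplicate_concordance.tsv"
            )

    controls = None
    if config.controls_path:
        controls = AlleleCounts.from_controls(load_controls(config.controls_path))

    comparisons = {}
    for name in config.comparisons:
        if name == "NS_vs_controls":
            cases = AlleleCounts.from_genotypes(
                gm, ("SSNS", "SRNS", "UNKNOWN"), label="NS"
            )
            comp = compare_groups(
                cases, controls, name, config.alpha,
                config.continuity_correction, config.zero_cell_correction,
            )
        elif name == "SRNS_vs_controls":
            srns = AlleleCounts.from_genotypes(gm, "SRNS")
            comp = compare_groups(
                srns, controls, name, config.alpha,
                config.continuity_correction, config.zero_cell_correction,
            )
        else:  # SSNS_vs_SRNS: SRNS is the numerator group
            srns = AlleleCounts.from_genotypes(gm, "SRNS")
            ssns = AlleleCounts.from_genotypes(gm, "SSNS")
            comp = compare_groups(
                srns, ssns, name, config.alpha,
                config.continuity_correction, config.zero_cell_correction,
            )
        comparisons[name] = comp
        _write(comp.to_frame(), out / f"association_{name}.tsv")
        _write(comp.report_frame(panel), out / f"association_{name}_report.tsv")
        manifest.setdefault("comparisons", {})[name] = {
            "m_tests": len(comp),
            "significant": comp.significant_rsids,
        }

    if "SSNS_vs_SRNS" in comparisons:
        comp = comparisons["SSNS_vs_SRNS"]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            variants = select_burden_variants(comp)
            filtered, excluded = complete_case_filter(gm, variants)
            burden_samples = filtered.group_samples(("SRNS", "SSNS"))
            burden_gm = filtered.subset(burden_samples)
            burdens = burden_count(burden_gm, variants)
            labels = burden_gm.phenotype
            result = burden_association(
                burdens, labels, config.tau, variants, excluded
            )
            sweep = threshold_sweep(burdens, labels, 2 * len(variants))
            homozygosity = homozygosity_comparison(gm, alpha=config.alpha)
        manifest["warnings"].extend(str(w.message) for w in caught)
        burden_table = pd.DataFrame(
            {"sample": burdens.index, "group": labels.values,
             "burden": burdens.values}
        )
        _write(burden_table, out / "burden_per_individual.tsv")
        _write(result.to_frame(), out / "burden_threshold_test.tsv")
        _write(result.distribution, out / "burden_histogram.tsv", index=True)
        _write(sweep, out / "burden_threshold_sweep.tsv")
        _write(homozygosity, out / "homozygosity.tsv")
        manifest["burden"] = {
            "included_variants": list(variants),
            "excluded_missing": excluded,
            "tau": result.tau,
            "table": {"srns_ge_tau": result.a, "srns_lt_tau": result.b,
                      "ssns_ge_tau": result.c, "ssns_lt_tau": result.d},
            "or": result.odds_ratio.point,
            "ci": [result.odds_ratio.ci_low, result.odds_ratio.ci_high],
            "p_fisher": result.p_fisher,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
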